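# Methods

`detrusor` measures anterior bladder (detrusor) wall thickness from a single
transabdominal 2D B-mode frame in two stages: a polar-coordinate dynamic
program (DP) that segments the bladder sac, and a multidimensional dynamic
program (MDP) that jointly tracks the two parallel boundaries of the anterior
wall inside a small search box anchored on the sac contour. An optional
U-Net segmenter can replace the DP stage. Because no suitable public B-mode
bladder dataset with wall-thickness ground truth exists, the package ships a
synthetic phantom generator that defines the test conditions for every stage.

## Sac segmentation by dynamic programming

**Centre detection.** A band of 15 image columns (~3 mm at 0.2 mm/px)
centred on the probe axis is averaged into one depth profile. A 4th-degree
polynomial is fitted to the profile; its two interior local maxima are taken
as the anterior and posterior wall depths and the rough bladder centre `cP`
is their midpoint. The quartic is the lowest-degree polynomial that can
carry two interior maxima, which makes the detector robust to speckle but
also means the peak positions are pulled by the profile's tails; the centre
only needs to fall inside the lumen, not at its geometric centre. A profile
with fewer than two interior maxima (blank frame, no lumen in view) raises
`CenterDetectionError`.

**Maximum ray length.** No bladder point visible in a sector image can be
farther from a centre on the probe axis than the sector half-width at the
centre depth,

    rB = wP/2 + |cP| * tan(fov/2),

with probe width `wP = 30` mm and field of view `fov = 60°`. An `arctan`
variant of the angular term is selectable (`mode="arctan"`); at 60° the two
differ by ~10% and both safely over-bound the lumen radius.

**Polar cost image.** The image is Gaussian-smoothed (default σ = 1 px) and
differentiated. The default gradient is the *outward radial* directional
derivative with respect to `cP`, so the dark-lumen-to-bright-wall transition
is a positive edge on every ray; a plain depth-axis derivative is available
(`mode="depth"`) but vanishes on near-horizontal rays. The gradient is
sampled by bilinear interpolation along 360 rays at 1° increments, at radial
steps of one pixel spacing (0.2 mm) out to `rB`. Samples outside the image
or the probe sector are flagged and, after cost inversion
(`v -> max(v) − v`), receive the maximum cost so the optimal path cannot
escape the imaged region.

**DP recurrence.** On the 360 × Nr cost matrix the inner boundary is the
path `h_w` (radial index per angle) minimising

    sum_w C(w, h_w) * (1 + |h_w − h_{w−1}| / γ),    |h_w − h_{w−1}| ≤ δmax,

with `δmax = 3` and `γ = 20`, i.e. a 5% node-cost surcharge per radial step.
The first column carries no incoming penalty. Closure over 360° is enforced
*exactly*: the open recurrence is solved simultaneously for every possible
start row (a stacked (start × row) state), and the cheapest end state whose
seam gap `|h_0 − h_359| ≤ δmax` wins. This costs a factor Nr over the open
DP (seconds at Nr ≈ 300) and is preferred over heuristic seam handling
because the cohort tests rely on the optimiser being exact. Ties resolve
deterministically: smaller |δ| first, then the earlier (smaller) row.

## Wall tracking by multidimensional dynamic programming

**Search box.** The anterior wall is located from the sac contour: the box
is centred laterally on the contour's horizontal midpoint, and vertically on
the mean depth of the *anterior* (above-centroid) contour points within the
box's 6 mm lateral window, extending 8 mm above and 6 mm below that anchor —
70 × 30 px at 0.2 mm/px. Boxes that would leave the image are clipped with
a warning.

**Node costs.** Within the crop, `g` is the signed depth gradient shifted to
be nonnegative (minima on the falling wall-to-lumen edge, scoring the inner
line) and `g_inv = max(g) − g` (minima on the rising tissue-to-wall edge,
scoring the outer line). The wall stage smooths with σ = 0.5 px, lighter
than the sac stage: at 1–2 mm wall widths a σ = 1 kernel lets the two
opposite-polarity edge responses overlap and repel each other's peaks,
biasing thickness upward by about one pixel; σ = 0.5 removes that bias
without hurting speckle robustness (the MDP already integrates evidence over
30 columns).

**Joint recurrence.** The state per column is the pair (outer row y1, inner
row y2), restricted to separations `dmin < d < dmax` with `dmin = 1` mm and
`dmax = 7` mm — the adult wall-thickness range — converted to strict pixel
bounds `floor(dmin/s)+1 … floor(dmax/s)` (6…35 px at 0.2 mm/px). The
cumulative cost is

    Ĉ(x, y1, y2) = min [ Ĉ(x−1, y1−δ1, y2−δ2)
                         + C(x, y1, y2) · (1+α1)^|δ1| (1+α2)^|δ2| (1+α3|δ1−δ2|) ],

with per-line steps `δ1, δ2 ∈ {−1, 0, 1}`, `α1 = α2 = α3 = 0.2`, and node
cost `C = g_inv(x, y1) + g(x, y2)`. Each 1-px step of a line bumps that
node's cost by 20%, and `|δ1 − δ2|` — the change in separation — softly
forces the lines parallel. (The penalty multiplies the node cost, so it is
a *soft* constraint: a zero-cost node can absorb any step.) The DP is exact
over the restricted state space; ties resolve to the smallest outer row,
then the smallest separation. Mean thickness is the column-mean separation
times the pixel spacing.

Note the separation-change penalty: penalising the separation magnitude
itself would squeeze the lines to `dmin` rather than keep their distance
constant, which is why the implementation penalises `|δ1 − δ2|`.

## U-Net segmenter

The alternative segmenter is a five-level 2D U-Net: 10 encoder convolutions
(3×3, ReLU, two per level) with 4 max-pooling stages and encoder-side
dropout; 4 nearest-neighbour upsampling stages with skip concatenations and
9 decoder convolutions (eight 3×3 plus a final 1×1), ending in a two-class
softmax. Weights are Glorot-uniform initialised and trained with Adam
(default initial learning rate 1e-5) on the class-balanced weighted
categorical cross-entropy

    L = (1/n) Σ_i Σ_j −y_ij log(ŷ_ij) w_j,    w_j = max_k(n_k) / n_j.

Training data can be expanded tenfold by random elastic deformation (dense
Gaussian-smoothed displacement field, smoothing scale 20 px, RMS amplitude
4 px — chosen so a warped phantom mask keeps Dice ≥ 0.8 with the original
and stays a single connected component), and evaluation uses subject-level
k-fold cross-validation: subjects, not images, are partitioned, so no
subject contributes to both splits.

The network is implemented directly in NumPy (im2col convolutions with
hand-written backprop verified against numeric gradients; inverted dropout;
Adam). It is sized for CPU work: the desk-scale profile trains on 20
phantoms downsampled to 128 × 160 with `base_features = 8`, where 30 epochs
take under two minutes and reach validation Dice > 0.95 on held-out
subjects. Full-resolution input (880 × 1068, padded minimally to
880 × 1072 for the four pooling stages) is supported but slow on CPU; the
standard 64-wide ladder is a constructor argument away and was not used in
any shipped test. Training uses a learning rate of 1e-3 in the desk-scale
tests — from a random initialisation, 1e-5 cannot produce measurable
movement within 30 epochs × 16 images.

## Synthetic phantoms: what they do and do not show

Each phantom is a 1068 × 880 px, 0.2 mm/px sector image (60° field of view,
30 mm probe face, apex at row 0; pixels outside the sector are zero)
containing an elliptical anechoic lumen (default intensity 12) surrounded by
a bright wall ring (210) in moderate tissue (90). The wall ring is the
region between the lumen ellipse (semi-axes a, b) and the ellipse grown by
the wall thickness t on both semi-axes; along the vertical axis through the
lumen centre the anterior separation is then exactly t, which is where the
MDP measures. Degradations, in order: angular dropout arcs (wall intensity
reduced to tissue level — emulating missing boundary segments), bright
Gaussian clutter blobs in the tissue, fully developed multiplicative speckle
(Rayleigh with unit mean; `speckle_scale` interpolates toward it, default
1.0), Gaussian blur (σ = 1.5 px, standing in for the point-spread function),
8-bit quantisation. Ground truth (lumen mask, inner contour, anterior outer
contour, thickness) is recorded before degradation.

The cohort generator samples wall thickness uniformly in [1.5, 5] mm, lumen
semi-axes in [25, 45] mm, centre depth in [80, 100] mm and lateral offset in
[−5, 5] mm, and groups samples into pseudo-subjects in blocks of four for
fold construction. All randomness flows from a single seed; fixed seeds are
bit-reproducible.

These phantoms exercise the geometric and optimisation machinery — edge
polarity, speckled gradients, seam closure, the d-limits — but they are not
ultrasound physics: there is no RF-domain point-spread function, no
attenuation or shadowing, no refraction, and lumen shape is a (possibly
dropout-eroded) ellipse rather than an irregular bladder. Accuracy figures
on phantoms therefore demonstrate correctness of the method under the
modelled difficulties, not expected in-vivo performance; published in-vivo
accuracy for this class of method (Dice ≈ 0.93, thickness RMSE ≈ 0.7 mm) is
an upper bound on what should be expected from real tissue, and the phantom
cohort numbers (Dice ≈ 0.999, RMSE ≈ 0.09 mm) are consistent with, but much
better than, that bound precisely because the phantoms are cleaner than
tissue.

## Numerical choices and degenerate inputs

- DP/MDP tie-breaking is fully deterministic (documented above), so every
  pipeline output is regression-testable; the pipeline itself contains no
  randomness.
- Out-of-image or out-of-sector polar samples get the maximum inverted cost,
  never zero, so the sac path cannot leave the sector.
- Separation bounds use the strict inequalities (`dmin < d < dmax`), so a
  measured thickness can never sit outside (1, 7) mm by construction; a crop
  too short to admit any legal separation raises `MDPInfeasibleError`.
- An empty cost matrix, a degenerate (< 3 point) contour, a contour outside
  the image, or geometry that does not fit the sector all raise descriptive
  errors rather than returning best-effort results.
- `weighted_cce` clips probabilities at 1e-7 before the log; training raises
  `TrainingDivergedError` on a non-finite loss instead of continuing.

## Problem sizes used by the shipped checks

The test suite and the acceptance script use: 50 speckled phantoms for the
segmentation/thickness cohort; exhaustive-enumeration cross-checks of the
optimisers on 100 random matrices up to 6 × 6 (sac DP, open and closed) and
100 random crops up to 6 columns × 12 rows (dual-line MDP); and one
subject-level fold of 20 reduced-resolution phantoms for U-Net training.
These sizes keep a full run on a single CPU core in the minutes range while
leaving the enumeration spaces large enough (≈ 10^4–10^6 paths per instance)
to be meaningful.

## Known limitations

- Only the anterior wall is measured; posterior/lateral walls and 3-layer
  wall sub-segmentation are out of scope.
- The centre detector assumes the lumen crosses the probe axis; a far
  off-axis bladder defeats it.
- The exact closed-contour DP is O(Nr² · 360 · δmax); at much finer radial
  steps than 0.2 mm it would become the dominant cost.
- The U-Net desk-scale profile is a correctness vehicle, not a
  performance-tuned segmenter; no GPU path exists.
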