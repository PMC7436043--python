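# detrusor

Fully automated segmentation of the bladder sac and measurement of anterior
detrusor wall thickness from transabdominal 2D B-mode ultrasound images.

Bladder wall thickness (BWT) is a noninvasive biomarker for bladder outlet
obstruction, detrusor overactivity and voiding dysfunction, and it is a
required input for bladder elastography. Measuring it by hand is slow and
observer-dependent. This package automates the measurement in two stages:

1. **Sac segmentation (DP).** A rough centre point `cP` is found from the
   two wall peaks of the axial intensity profile (4th-degree polynomial
   fit). The gradient image is resampled along 360 rays from `cP` out to
   the maximum bladder radius `rB = wP/2 + |cP|·tan(fov/2)`, gradients are
   inverted into costs, and the closed inner boundary is the exact minimiser
   of

       Σ_w C(w, h_w) · (1 + |h_w − h_{w−1}|/γ),   |Δh| ≤ 3, γ = 20,

   over all 360°-continuous paths (a 5% node-cost surcharge per radial step).

2. **Wall tracking (MDP).** In a 14 × 6 mm box anchored on the mid-top of
   the sac contour, the outer and inner wall boundaries are tracked *jointly*
   as two parallel lines (y1, y2) with separation confined to the adult
   range 1 mm < d < 7 mm, minimising

       Ĉ(x,y1,y2) = min[ Ĉ(x−1, y1−δ1, y2−δ2)
                          + (g_inv(x,y1) + g(x,y2)) · (1+α1)^|δ1| (1+α2)^|δ2| (1+α3|δ1−δ2|) ],

   with α = 0.2 throughout: each 1-px step of a line costs 20% extra, and
   changes of separation are penalised so the lines stay parallel. The mean
   separation times the pixel spacing is the reported thickness.

An optional five-level U-Net (10 encoder / 9 decoder convolutions, weighted
categorical cross-entropy with class-balancing weights `w_j = max_k n_k / n_j`,
elastic-deformation augmentation, subject-level cross-validation) can replace
the DP stage; it is implemented in pure NumPy and trains on CPU at reduced
resolution. Since the study's in-vivo images are not public, the package
includes a synthetic phantom generator (sector geometry, elliptical lumen,
bright wall of known thickness, Rayleigh speckle, dropout arcs, clutter)
that provides ground truth for every stage. See `docs/methods.md` for the
full model description and its limitations.

## Worked example

Generate a speckled phantom with a known 2.6 mm wall and run the full
pipeline on it:

```python
import numpy as np, imageio.v3 as iio
from detrusor import PhantomSpec, generate_phantom

s = generate_phantom(PhantomSpec(wall_thickness_mm=2.6, seed=3))
iio.imwrite("demo_phantom.png", s.image.pixels.astype(np.uint8))
```

```sh
$ detrusor run --image demo_phantom.png --out demo
... detrusor INFO segmented (dp) in 1.60s, wall measured in 0.005s: 2.47 mm
mean thickness 2.47 mm -> demo
```

`demo/` now contains `mask.png` (the filled lumen segmentation),
`contour.csv` (the 360-point inner boundary as `angle_deg, x_px, y_px`) and
`thickness.json`, whose `mean_thickness_mm` of **2.47 mm** is the estimate
of the true 2.6 mm wall — an error of 0.13 mm, under one pixel (0.2 mm) at
this resolution, which is the expected accuracy scale of the method. The
per-column thicknesses and the two boundary polylines (in image
coordinates) are in the same JSON.

Other entry points: `detrusor phantom` (datasets with manifests),
`detrusor segment-dp` / `segment-unet` / `train`, `detrusor wall` (thickness
from an existing contour), `detrusor batch` (manifest-driven runs with a
Dice/RMSE summary), `detrusor eval` (metrics incl. Bland–Altman plots). The
same functionality is available as a library (`detrusor.segment_bladder_dp`,
`detrusor.measure_wall_from_image`, ...).

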