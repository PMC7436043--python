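"""Synthetic B-mode bladder phantoms with known ground truth.

The in-vivo volunteer images behind this method are not publicly deposited,
so every downstream stage is exercised on synthetic phantoms instead: a
curved-array sector image containing an anechoic (dark) elliptical lumen
surrounded by a bright wall ring of known thickness, over moderate-intensity
tissue, degraded by multiplicative Rayleigh speckle, Gaussian blur, optional
angular wall-dropout arcs and bright clutter blobs.

The generator is deliberately first-order: it emulates the *appearance*
features that stress gradient-based boundary tracking (speckle grain,
missing boundary segments, clutter), not ultrasound physics.  See
docs/methods.md for what that does and does not validate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import BModeImage, Contour, ProbeGeometry

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "PhantomGeometryError",
    "generate_phantom",
    "generate_dataset",
]


class PhantomGeometryError(ValueError):
    """Raised when the requested lumen + wall does not fit the imaged sector."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic bladder image.

    Geometry is physical (mm); the image grid is 1068 x 880 px at 0.2 mm/px
    by default, matching the study's display format.  ``lumen_center_mm`` is
    (depth, lateral-offset-from-probe-axis); ``lumen_semi_axes_mm`` is
    (depth semi-axis a, lateral semi-axis b).  The wall is the ring between
    the lumen ellipse and the ellipse grown by ``wall_thickness_mm`` on both
    semi-axes, which makes the anterior (and posterior) wall exactly that
    thick along the vertical axis through the lumen centre.
    """

    image_height_px: int = 880
    image_width_px: int = 1068
    pixel_spacing_mm: float = 0.2
    probe_width_mm: float = 30.0
    fov_deg: float = 60.0
    apex_column_px: int | None = None
    lumen_center_mm: tuple[float, float] = (80.0, 0.0)
    lumen_semi_axes_mm: tuple[float, float] = (35.0, 45.0)
    wall_thickness_mm: float = 2.6
    lumen_intensity: float = 12.0
    wall_intensity: float = 210.0
    tissue_intensity: float = 90.0
    speckle_scale: float = 1.0
    blur_sigma_px: float = 1.5
    dropout_arcs: tuple[tuple[float, float], ...] = ()
    clutter_blob_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.0 <= self.wall_thickness_mm <= 7.0:
            raise ValueError("wall_thickness_mm must lie in [1, 7] mm")
        if not (self.lumen_intensity < self.tissue_intensity < self.wall_intensity):
            raise ValueError("require lumen < tissue < wall intensity")
        for v in (self.lumen_intensity, self.wall_intensity, self.tissue_intensity):
            if not 0 <= v <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        if self.speckle_scale < 0 or self.blur_sigma_px < 0:
            raise ValueError("speckle_scale and blur_sigma_px must be nonnegative")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def probe(self) -> ProbeGeometry:
        return ProbeGeometry(
            probe_width_mm=self.probe_width_mm,
            fov_deg=self.fov_deg,
            apex_column_px=self.apex_column_px,
        )

    @property
    def apex_column(self) -> int:
        if self.apex_column_px is not None:
            return int(self.apex_column_px)
        return self.image_width_px // 2


@dataclass
class PhantomSample:
    """One generated phantom: image, truth mask/contours, and true thickness."""

    image: BModeImage
    lumen_mask: np.ndarray
    inner_contour: Contour
    outer_anterior_contour: Contour
    true_thickness_mm: float
    spec: PhantomSpec


def _ellipse_boundary_points(
    spec: PhantomSpec, a_mm: float, b_mm: float, angles_deg: np.ndarray
) -> np.ndarray:
    """(x_px, y_px) boundary points of the ellipse at the given ray angles.

    Angle convention matches the polar resampler: theta = 0 points down
    (posterior), 180 points up (anterior); direction (sin t, cos t) in (x, y).
    """
    t = np.deg2rad(angles_deg)
    # radius along direction (lateral = sin t scaled by b, depth = cos t scaled by a)
    r = 1.0 / np.sqrt((np.cos(t) / a_mm) ** 2 + (np.sin(t) / b_mm) ** 2)
    depth_mm = spec.lumen_center_mm[0] + r * np.cos(t)
    lateral_mm = spec.lumen_center_mm[1] + r * np.sin(t)
    x = spec.apex_column + lateral_mm / spec.pixel_spacing_mm
    y = depth_mm / spec.pixel_spacing_mm
    return np.column_stack([x, y])


def _check_geometry(spec: PhantomSpec) -> None:
    t = spec.wall_thickness_mm
    a_out = spec.lumen_semi_axes_mm[0] + t
    b_out = spec.lumen_semi_axes_mm[1] + t
    pts = _ellipse_boundary_points(spec, a_out, b_out, np.arange(0.0, 360.0, 2.0))
    h, w = spec.image_height_px, spec.image_width_px
    if (
        pts[:, 0].min() < 1
        or pts[:, 0].max() > w - 2
        or pts[:, 1].min() < 1
        or pts[:, 1].max() > h - 2
    ):
        raise PhantomGeometryError(
            "lumen ellipse plus wall extends beyond the image grid"
        )
    depth_mm = pts[:, 1] * spec.pixel_spacing_mm
    lateral_mm = (pts[:, 0] - spec.apex_column) * spec.pixel_spacing_mm
    if np.any(np.abs(lateral_mm) > spec.probe.sector_half_width_mm(depth_mm)):
        raise PhantomGeometryError(
            "lumen ellipse plus wall extends outside the imaged sector"
        )


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> PhantomSample:
    """Render one phantom; bit-identical for a fixed spec and seed.

    Rendering order: paint tissue / wall ring / lumen, apply dropout arcs
    (wall brightness reduced to tissue level over the listed angular ranges),
    add clutter blobs, multiply by normalised Rayleigh speckle, blur by
    ``blur_sigma_px``, zero everything outside the sector, and quantise to
    8 bits.

    Raises
    ------
    PhantomGeometryError
        If the lumen ellipse plus wall does not fit inside the imaged sector.
    """
    _check_geometry(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = spec.image_height_px, spec.image_width_px
    sp = spec.pixel_spacing_mm
    cd, cl = spec.lumen_center_mm
    a, b = spec.lumen_semi_axes_mm
    t = spec.wall_thickness_mm

    depth = np.arange(h)[:, None] * sp
    lateral = (np.arange(w)[None, :] - spec.apex_column) * sp
    dz = depth - cd
    dx = lateral - cl

    in_lumen = (dz / a) ** 2 + (dx / b) ** 2 <= 1.0
    in_outer = (dz / (a + t)) ** 2 + (dx / (b + t)) ** 2 <= 1.0
    in_wall = in_outer & ~in_lumen

    img = np.full((h, w), spec.tissue_intensity, dtype=float)
    img[in_wall] = spec.wall_intensity
    img[in_lumen] = spec.lumen_intensity

    if spec.dropout_arcs:
        ang = np.degrees(np.arctan2(dx, dz)) % 360.0  # 0 = down, 180 = up (anterior)
        for start, end in spec.dropout_arcs:
            start %= 360.0
            end %= 360.0
            if start <= end:
                in_arc = (ang >= start) & (ang <= end)
            else:
                in_arc = (ang >= start) | (ang <= end)
            img[in_wall & in_arc] = spec.tissue_intensity

    for _ in range(spec.clutter_blob_count):
        # bright blobs in the tissue, away from the wall ring
        br = rng.uniform(0, h - 1)
        bc = rng.uniform(0, w - 1)
        amp = rng.uniform(0.4, 1.0) * (spec.wall_intensity - spec.tissue_intensity)
        sig = rng.uniform(3.0, 8.0)
        rr = np.arange(h)[:, None] - br
        cc = np.arange(w)[None, :] - bc
        blob = amp * np.exp(-(rr**2 + cc**2) / (2 * sig**2))
        img = np.where(in_outer, img, img + blob)

    if spec.speckle_scale > 0:
        ray = rng.rayleigh(scale=1.0, size=(h, w))
        ray /= np.sqrt(np.pi / 2.0)  # unit mean
        img *= (1.0 - spec.speckle_scale) + spec.speckle_scale * ray

    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)

    sector = np.abs(lateral) <= spec.probe.sector_half_width_mm(depth)
    img[~sector] = 0.0
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    angles = np.arange(360.0)
    inner_pts = _ellipse_boundary_points(spec, a, b, angles)
    inner = Contour(points=inner_pts, closed=True, angles_deg=angles)
    ant_angles = np.arange(91.0, 270.0)  # upper half of the ring
    outer_ant = Contour(
        points=_ellipse_boundary_points(spec, a + t, b + t, ant_angles),
        closed=False,
        angles_deg=ant_angles,
    )
    lumen_mask = inner.to_mask((h, w))

    bmode = BModeImage(
        pixels=img.astype(float), pixel_spacing_mm=sp, probe=spec.probe
    )
    return PhantomSample(
        image=bmode,
        lumen_mask=lumen_mask,
        inner_contour=inner,
        outer_anterior_contour=outer_ant,
        true_thickness_mm=t,
        spec=spec,
    )


def generate_dataset(
    n: int,
    seed: int = 0,
    thickness_range_mm: tuple[float, float] = (1.5, 5.0),
    semi_axes_range_mm: tuple[float, float] = (25.0, 45.0),
    center_depth_range_mm: tuple[float, float] = (80.0, 100.0),
    lateral_offset_range_mm: tuple[float, float] = (-5.0, 5.0),
    images_per_subject: int = 4,
    **spec_overrides,
) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Generate a cohort of phantoms with a manifest table.

    Wall thickness, lumen semi-axes, centre depth and lateral offset are
    drawn uniformly from the given ranges; every other :class:`PhantomSpec`
    field can be fixed via ``spec_overrides``.  Samples are grouped into
    pseudo-subjects in blocks of ``images_per_subject`` so that subject-level
    cross-validation folds can be formed downstream.

    Returns the samples and a manifest with one row per sample
    (sample_id, subject_id, seed, thickness_mm and geometry columns).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, (lo, hi) in {
        "thickness_range_mm": thickness_range_mm,
        "semi_axes_range_mm": semi_axes_range_mm,
        "center_depth_range_mm": center_depth_range_mm,
        "lateral_offset_range_mm": lateral_offset_range_mm,
    }.items():
        if hi < lo:
            raise ValueError(f"empty range for {name}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    rows = []
    for i in range(n):
        thick = rng.uniform(*thickness_range_mm)
        a = rng.uniform(*semi_axes_range_mm)
        b = rng.uniform(*semi_axes_range_mm)
        cd = rng.uniform(*center_depth_range_mm)
        cl = rng.uniform(*lateral_offset_range_mm)
        sample_seed = int(rng.integers(0, 2**31 - 1))
        spec = dataclasses.replace(
            PhantomSpec(
                lumen_center_mm=(cd, cl),
                lumen_semi_axes_mm=(a, b),
                wall_thickness_mm=thick,
                seed=sample_seed,
            ),
            **spec_overrides,
        )
        samples.append(generate_phantom(spec))
        rows.append(
            {
                "sample_id": i,
                "subject_id": i // images_per_subject,
                "seed": sample_seed,
                "thickness_mm": thick,
                "center_depth_mm": cd,
                "lateral_offset_mm": cl,
                "semi_axis_depth_mm": a,
                "semi_axis_lateral_mm": b,
            }
        )
    return samples, pd.DataFrame(rows)
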