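"""Image model and polar-domain preprocessing for bladder boundary detection.

A transabdominal B-mode image of a filled bladder shows an anechoic (dark)
lumen surrounded by a bright muscular wall.  The boundary-detection pipeline
first locates a rough centre point inside the lumen, then re-grids an edge
(gradient) image along 360 rays cast from that centre so that the closed inner
boundary becomes a left-to-right path through a rectangular cost matrix, which
a dynamic program can then extract.

This module provides the image/probe containers and the four preprocessing
steps: centre detection from the axial intensity profile, the maximum-ray
length bound from the probe geometry, the radial gradient image, and the
polar resampling / cost inversion that produce the DP cost field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy import ndimage
from skimage.draw import polygon2mask

__all__ = [
    "ProbeGeometry",
    "BModeImage",
    "CenterEstimate",
    "CenterDetectionError",
    "PolarCostImage",
    "Contour",
    "detect_center",
    "max_ray_length",
    "radial_gradient",
    "resample_polar",
    "invert_costs",
    "contour_to_cartesian",
]


class CenterDetectionError(RuntimeError):
    """Raised when the axial intensity profile does not show two wall peaks."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Curved-array probe footprint.

    Parameters
    ----------
    probe_width_mm : float
        Physical width of the probe face (``wP``), i.e. the sector width at
        zero depth.  Default 30 mm.
    fov_deg : float
        Angular field of view of the sector. Default 60 degrees.
    apex_column_px : int or None
        Image column of the probe axis; ``None`` means the horizontal centre
        of the image.
    """

    probe_width_mm: float = 30.0
    fov_deg: float = 60.0
    apex_column_px: int | None = None

    def __post_init__(self) -> None:
        if self.probe_width_mm <= 0:
            raise ValueError("probe_width_mm must be positive")
        if not 0.0 < self.fov_deg < 180.0:
            raise ValueError("fov_deg must lie in (0, 180)")

    def sector_half_width_mm(self, depth_mm):
        """Lateral half-extent of the imaged sector at a given depth."""
        return self.probe_width_mm / 2.0 + np.maximum(depth_mm, 0.0) * np.tan(
            np.deg2rad(self.fov_deg / 2.0)
        )


@dataclass
class BModeImage:
    """A 2D grayscale B-mode frame with physical calibration.

    ``pixels`` is a (height, width) array with intensities in [0, 255];
    row 0 is the probe face (depth 0), rows increase with depth.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = 0.2
    probe: ProbeGeometry = field(default_factory=ProbeGeometry)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def apex_column(self) -> int:
        if self.probe.apex_column_px is not None:
            return int(self.probe.apex_column_px)
        return self.width // 2

    def sector_mask(self) -> np.ndarray:
        """Boolean mask of pixels inside the probe's 60-degree sector."""
        depth = np.arange(self.height)[:, None] * self.pixel_spacing_mm
        lateral = (np.arange(self.width)[None, :] - self.apex_column) * self.pixel_spacing_mm
        return np.abs(lateral) <= self.probe.sector_half_width_mm(depth)


@dataclass(frozen=True)
class CenterEstimate:
    """Rough bladder centre ``cP`` from the two wall peaks on the probe axis."""

    row_px: int
    col_px: int
    depth_mm: float
    peak_depths_px: tuple[int, int]  # (anterior, posterior)

    def __post_init__(self) -> None:
        ant, post = self.peak_depths_px
        if not ant < self.row_px < post:
            raise ValueError("centre row must lie between the anterior and posterior peaks")


@dataclass
class PolarCostImage:
    """Gradient (or cost) samples on a 360-ray polar grid around the centre.

    ``values`` has shape (360, Nr): row = ray angle in degrees, column =
    radial sample index at ``radial_step_mm`` increments from the centre.
    ``valid`` flags samples that fell inside the image (and sector, when the
    probe geometry is known); invalid samples must never attract the DP path.
    """

    values: np.ndarray
    radial_step_mm: float
    center: CenterEstimate
    max_radius_mm: float
    valid: np.ndarray | None = None
    pixel_spacing_mm: float = 0.2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 360:
            raise ValueError("values must have shape (360, Nr)")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)

    @property
    def n_radial(self) -> int:
        return self.values.shape[1]


@dataclass
class Contour:
    """Ordered (x_px, y_px) point list; closed contours are angularly ordered."""

    points: np.ndarray
    closed: bool = True
    angles_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array of (x, y)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterise the enclosed region as a filled boolean mask."""
        if len(self.points) < 3:
            return np.zeros(shape, dtype=bool)
        # polygon2mask expects (row, col) vertex order
        return polygon2mask(shape, self.points[:, ::-1])

    def to_dataframe(self):
        import pandas as pd

        angles = (
            self.angles_deg
            if self.angles_deg is not None
            else np.full(len(self.points), np.nan)
        )
        return pd.DataFrame(
            {"angle_deg": angles, "x_px": self.points[:, 0], "y_px": self.points[:, 1]}
        )


# ---------------------------------------------------------------------------
# Centre detection
# ---------------------------------------------------------------------------

def detect_center(img: BModeImage, band_columns: int = 15) -> CenterEstimate:
    """Locate the rough bladder centre from the axial intensity profile.

    Averages ``band_columns`` image columns (~3 mm at 0.2 mm/px) centred on
    the probe axis into a single depth profile, fits a 4th-degree polynomial,
    and takes its two interior local maxima as the anterior and posterior
    wall depths.  The centre ``cP`` sits midway between the two peaks, on the
    probe axis column.

    Raises
    ------
    CenterDetectionError
        If the fitted polynomial has fewer than two interior local maxima —
        e.g. on a blank frame or a monotone profile.
    """
    col = img.apex_column
    half = band_columns // 2
    lo, hi = col - half, col - half + band_columns
    if lo < 0 or hi > img.width:
        raise ValueError(
            f"image too narrow for a {band_columns}-column band at column {col}"
        )
    profile = img.pixels[:, lo:hi].mean(axis=1)
    rows = np.arange(img.height, dtype=float)

    poly = Polynomial.fit(rows, profile, deg=4)
    dpoly = poly.deriv()
    roots = dpoly.roots()
    real = roots[np.abs(roots.imag) < 1e-8].real
    interior = real[(real > 0) & (real < img.height - 1)]
    maxima = np.sort(interior[poly.deriv(2)(interior) < 0])

    if len(maxima) < 2:
        raise CenterDetectionError(
            "axial intensity profile shows fewer than two wall peaks; "
            "is the bladder lumen in the field of view?"
        )
    anterior, posterior = maxima[0], maxima[-1]
    center_row = int(round((anterior + posterior) / 2.0))
    return CenterEstimate(
        row_px=center_row,
        col_px=col,
        depth_mm=center_row * img.pixel_spacing_mm,
        peak_depths_px=(int(round(anterior)), int(round(posterior))),
    )


def max_ray_length(
    center: CenterEstimate, probe: ProbeGeometry, mode: str = "tan"
) -> float:
    """Largest possible bladder radius ``rB`` in mm, bounding the ray length.

    The sector half-width at the centre depth is wP/2 + |cP|·tan(fov/2); no
    bladder point visible in the image can be further than that from a centre
    on the probe axis.  ``mode="arctan"`` evaluates the angular term with
    arctan instead of tan (the two agree to within ~10% at fov = 60 degrees).
    """
    if center.depth_mm < 0:
        raise ValueError("centre depth must be nonnegative")
    half_fov_rad = np.deg2rad(probe.fov_deg / 2.0)
    if mode == "tan":
        ang = np.tan(half_fov_rad)
    elif mode == "arctan":
        ang = np.arctan(half_fov_rad)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return probe.probe_width_mm / 2.0 + abs(center.depth_mm) * ang


# ---------------------------------------------------------------------------
# Gradients and polar resampling
# ---------------------------------------------------------------------------

def radial_gradient(
    img: BModeImage,
    center: CenterEstimate,
    smooth_sigma_px: float = 1.0,
    mode: str = "radial",
) -> np.ndarray:
    """Signed intensity derivative field used as the boundary edge cost.

    mode="radial" (default): outward directional derivative with respect to
    the centre point, so the dark-lumen-to-bright-wall transition is a
    positive edge on every ray regardless of its direction.
    mode="depth": plain derivative along the depth (row) axis.

    The image is Gaussian-smoothed by ``smooth_sigma_px`` first; derivatives
    are central differences (``np.gradient``).
    """
    smoothed = (
        ndimage.gaussian_filter(img.pixels, smooth_sigma_px)
        if smooth_sigma_px > 0
        else img.pixels
    )
    gy, gx = np.gradient(smoothed)
    if mode == "depth":
        return gy
    if mode != "radial":
        raise ValueError(f"unknown mode {mode!r}")
    rows = np.arange(img.height)[:, None] - center.row_px
    cols = np.arange(img.width)[None, :] - center.col_px
    r = np.hypot(rows, cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        uy = np.where(r > 0, rows / r, 0.0)
        ux = np.where(r > 0, cols / r, 0.0)
    return gy * uy + gx * ux


def resample_polar(
    gradient: np.ndarray,
    center: CenterEstimate,
    max_radius_mm: float,
    radial_step_mm: float,
    pixel_spacing_mm: float,
    probe: ProbeGeometry | None = None,
) -> PolarCostImage:
    """Resample a gradient image along 360 rays cast from the centre.

    Ray ``theta`` (degrees) points in direction (sin theta, cos theta) in
    (x, y) image coordinates, i.e. theta = 0 is straight down (posterior).
    Samples are taken by bilinear interpolation at ``radial_step_mm``
    increments out to ``max_radius_mm``; samples outside the image (or the
    probe sector, when given) are flagged invalid so that cost inversion can
    assign them the maximum cost.
    """
    if max_radius_mm <= 0:
        raise ValueError("max_radius_mm must be positive")
    gradient = np.asarray(gradient, dtype=float)
    h, w = gradient.shape
    if not (0 <= center.row_px < h and 0 <= center.col_px < w):
        raise ValueError("centre lies outside the image")

    n_radial = int(np.ceil(max_radius_mm / radial_step_mm))
    radii_mm = np.arange(n_radial) * radial_step_mm
    theta = np.deg2rad(np.arange(360.0))[:, None]
    r_px = (radii_mm / pixel_spacing_mm)[None, :]

    rows = center.row_px + r_px * np.cos(theta)
    cols = center.col_px + r_px * np.sin(theta)

    values = ndimage.map_coordinates(
        gradient, [rows, cols], order=1, mode="constant", cval=np.nan
    )
    valid = ~np.isnan(values)
    if probe is not None:
        depth_mm = rows * pixel_spacing_mm
        apex = probe.apex_column_px if probe.apex_column_px is not None else w // 2
        lateral_mm = (cols - apex) * pixel_spacing_mm
        in_sector = np.abs(lateral_mm) <= probe.sector_half_width_mm(depth_mm)
        valid &= in_sector
    values = np.where(valid, values, 0.0)
    return PolarCostImage(
        values=values,
        radial_step_mm=radial_step_mm,
        center=center,
        max_radius_mm=max_radius_mm,
        valid=valid,
        pixel_spacing_mm=pixel_spacing_mm,
    )


def invert_costs(polar: PolarCostImage) -> PolarCostImage:
    """Turn the gradient field into a nonnegative cost field for minimisation.

    Each value v becomes max(v) - v over the valid samples, so strong rising
    edges (lumen to wall) become low-cost troughs; invalid (out-of-image or
    out-of-sector) samples get the maximum resulting cost so the optimal path
    avoids them.  The output minimum is 0.
    """
    vals = polar.values
    valid = polar.valid
    if not valid.any():
        raise ValueError("polar image has no valid samples")
    vmax = vals[valid].max()
    inverted = vmax - vals
    worst = inverted[valid].max()
    inverted = np.where(valid, inverted, worst)
    return PolarCostImage(
        values=inverted,
        radial_step_mm=polar.radial_step_mm,
        center=polar.center,
        max_radius_mm=polar.max_radius_mm,
        valid=valid.copy(),
        pixel_spacing_mm=polar.pixel_spacing_mm,
    )


def contour_to_cartesian(path, polar: PolarCostImage) -> Contour:
    """Map a per-angle radial-index path back to image (x, y) coordinates."""
    path = np.asarray(path)
    if len(path) != 360:
        raise ValueError("path must give one radial index per degree (length 360)")
    r_px = path * polar.radial_step_mm / polar.pixel_spacing_mm
    theta = np.deg2rad(np.arange(360.0))
    x = polar.center.col_px + r_px * np.sin(theta)
    y = polar.center.row_px + r_px * np.cos(theta)
    return Contour(
        points=np.column_stack([x, y]), closed=True, angles_deg=np.arange(360.0)
    )
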