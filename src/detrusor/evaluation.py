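"""Segmentation and thickness agreement metrics.

Dice overlap and symmetric Hausdorff distance compare automated and manual
bladder masks/contours; RMSE and Bland-Altman limits of agreement compare
paired wall-thickness measurements, including the multi-observer protocol
(each observer against the per-image mean reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "AgreementReport",
    "dice",
    "hausdorff_mm",
    "rmse",
    "bland_altman",
    "bland_altman_plot",
    "observer_table",
]


@dataclass
class AgreementReport:
    """Bland-Altman summary: bias and 95% limits of agreement."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    differences: np.ndarray
    means: np.ndarray


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks agree vacuously (1.0)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def _as_points(contour) -> np.ndarray:
    pts = getattr(contour, "points", contour)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("contour must be a non-empty (N, 2) point array")
    return pts


def hausdorff_mm(contour_a, contour_b, spacing_mm: float = 1.0) -> float:
    """Symmetric Hausdorff distance between two contours, in mm."""
    a = _as_points(contour_a)
    b = _as_points(contour_b)
    d = max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    return d * spacing_mm


def rmse(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def bland_altman(meas_a, meas_b) -> AgreementReport:
    """Agreement between paired measurements: bias and bias ± 1.96·SD limits.

    Differences are A - B; the SD is the sample (n-1) standard deviation.
    """
    a = np.asarray(meas_a, dtype=float)
    b = np.asarray(meas_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired measurement lists must have equal length")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=a.size,
        differences=diffs,
        means=(a + b) / 2.0,
    )


def bland_altman_plot(report: AgreementReport, path, title: str = "Bland-Altman"):
    """Write the standard mean-vs-difference plot to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(report.means, report.differences, s=18)
    for y, style in [(report.bias, "-"), (report.loa_low, "--"), (report.loa_high, "--")]:
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (A - B)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def observer_table(observers: dict, reference=None) -> pd.DataFrame:
    """Pairwise RMSE between observers, plus each against the mean reference.

    ``observers`` maps a name to an aligned list of per-image thickness
    values; ``reference`` defaults to the per-image mean across observers.
    """
    names = list(observers)
    arrays = {k: np.asarray(v, dtype=float) for k, v in observers.items()}
    lengths = {a.size for a in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("observer measurement lists are misaligned")
    ref = (
        np.asarray(reference, dtype=float)
        if reference is not None
        else np.mean(list(arrays.values()), axis=0)
    )
    if ref.size != lengths.pop():
        raise ValueError("reference length does not match observers")

    rows = []
    for i, a in enumerate(names):
        for b_name in names[i + 1 :]:
            rows.append(
                {"pair": f"{a} vs {b_name}", "rmse": rmse(arrays[a], arrays[b_name])}
            )
    for a in names:
        rows.append({"pair": f"{a} vs reference", "rmse": rmse(arrays[a], ref)})
    return pd.DataFrame(rows)
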