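"""Dynamic-programming extraction of the bladder sac inner boundary.

On the 360-ray polar cost image the closed inner boundary of the bladder is
a left-to-right path: one radial index per angle, constrained to move at
most ``delta_max`` radial samples between neighbouring angles.  The path
minimises the cumulative cost

    sum_w  C(w, h_w) * (1 + |h_w - h_{w-1}| / gamma)

so a step of one radial sample inflates that node's cost by 1/gamma (5% at
the default gamma = 20) — a soft continuity penalty.  The closed (360
degree) variant additionally requires the seam step |h_0 - h_{W-1}| to obey
the same bound, and is solved exactly by restarting the open recurrence once
per candidate start row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    BModeImage,
    Contour,
    contour_to_cartesian,
    detect_center,
    invert_costs,
    max_ray_length,
    radial_gradient,
    resample_polar,
)

__all__ = [
    "DPParams",
    "DPPath",
    "dp_optimal_path",
    "dp_closed_contour",
    "segment_bladder_dp",
]


@dataclass(frozen=True)
class DPParams:
    """Step bound and soft step penalty of the boundary DP."""

    delta_max: int = 3
    gamma: float = 20.0
    closed: bool = True

    def __post_init__(self) -> None:
        if self.delta_max < 0:
            raise ValueError("delta_max must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class DPPath:
    """Optimal row index per column and its total cost."""

    row_per_column: np.ndarray
    total_cost: float

    def __post_init__(self) -> None:
        self.row_per_column = np.asarray(self.row_per_column, dtype=int)


def _delta_order(delta_max: int) -> list[int]:
    # ascending |delta| so that strict improvement implements the tie-break:
    # prefer the smaller |delta|, then the negative delta of that magnitude
    order = [0]
    for d in range(1, delta_max + 1):
        order.extend([-d, d])
    return order


def _shifted(acc: np.ndarray, delta: int) -> np.ndarray:
    """shifted[h] = acc[h - delta] along the last axis, inf where undefined."""
    out = np.full_like(acc, np.inf)
    if delta == 0:
        return acc.copy()
    if delta > 0:
        out[..., delta:] = acc[..., :-delta]
    else:
        out[..., :delta] = acc[..., -delta:]
    return out


def _validate_cost(cost: np.ndarray) -> np.ndarray:
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost matrix must be non-empty and 2D (columns x rows)")
    if np.any(cost < 0):
        raise ValueError("cost values must be nonnegative")
    return cost


def dp_optimal_path(cost, params: DPParams | None = None) -> DPPath:
    """Globally optimal open path through a (W columns x H rows) cost matrix.

    Forward recurrence over columns with the step-penalised node cost; the
    first column carries no incoming-step penalty.  Backtracks from the
    cheapest last-column entry (smallest row on ties).
    """
    params = params or DPParams(closed=False)
    cost = _validate_cost(cost)
    W, H = cost.shape
    deltas = _delta_order(params.delta_max)

    acc = cost[0].copy()
    back = np.zeros((W, H), dtype=np.int8)
    for w in range(1, W):
        best = np.full(H, np.inf)
        best_d = np.zeros(H, dtype=np.int8)
        for d in deltas:
            cand = _shifted(acc, d) + cost[w] * (1.0 + abs(d) / params.gamma)
            better = cand < best
            best[better] = cand[better]
            best_d[better] = d
        acc = best
        back[w] = best_d

    end = int(np.argmin(acc))
    total = float(acc[end])
    path = np.empty(W, dtype=int)
    path[-1] = end
    for w in range(W - 1, 0, -1):
        path[w - 1] = path[w] - back[w, path[w]]
    return DPPath(row_per_column=path, total_cost=total)


def dp_closed_contour(cost, params: DPParams | None = None) -> DPPath:
    """Exact minimal closed path: seam step |h_0 - h_{W-1}| <= delta_max.

    Solves the open problem once per candidate start row (all start rows are
    propagated simultaneously as a stacked state), then keeps the cheapest
    end state whose seam gap is feasible.
    """
    params = params or DPParams()
    cost = _validate_cost(cost)
    W, H = cost.shape
    if H <= 0:
        raise ValueError("no feasible closed path: empty row range")
    if W == 1:
        return dp_optimal_path(cost, params)
    deltas = _delta_order(params.delta_max)

    # acc[s, h]: best open-path cost ending at row h having started at row s
    acc = np.full((H, H), np.inf)
    acc[np.arange(H), np.arange(H)] = cost[0]
    back = np.zeros((W, H, H), dtype=np.int8)
    for w in range(1, W):
        best = np.full((H, H), np.inf)
        best_d = np.zeros((H, H), dtype=np.int8)
        node = cost[w][None, :]
        for d in deltas:
            cand = _shifted(acc, d) + node * (1.0 + abs(d) / params.gamma)
            better = cand < best
            best[better] = cand[better]
            best_d[better] = d
        acc = best
        back[w] = best_d

    seam_ok = (
        np.abs(np.arange(H)[:, None] - np.arange(H)[None, :]) <= params.delta_max
    )
    final = np.where(seam_ok, acc, np.inf)
    if not np.isfinite(final).any():
        raise ValueError("no feasible closed path")
    s, end = np.unravel_index(np.argmin(final), final.shape)
    total = float(final[s, end])
    path = np.empty(W, dtype=int)
    path[-1] = end
    for w in range(W - 1, 0, -1):
        path[w - 1] = path[w] - back[w, s, path[w]]
    return DPPath(row_per_column=path, total_cost=total)


def segment_bladder_dp(
    img: BModeImage,
    params: DPParams | None = None,
    smooth_sigma_px: float = 1.0,
    radial_step_mm: float | None = None,
    ray_length_mode: str = "tan",
    return_intermediates: bool = False,
):
    """Full DP bladder sac segmentation of a B-mode image.

    Composes centre detection, radial gradient, polar resampling out to the
    maximum bladder radius, cost inversion, the exact closed-contour DP, and
    back-projection to image coordinates.

    Returns ``(contour, lumen_mask)``; with ``return_intermediates=True`` a
    third dict carries the centre estimate and cost images for inspection.

    Raises
    ------
    CenterDetectionError
        If no rough bladder centre can be found (propagated).
    """
    params = params or DPParams()
    center = detect_center(img)
    rB = max_ray_length(center, img.probe, mode=ray_length_mode)
    grad = radial_gradient(img, center, smooth_sigma_px=smooth_sigma_px)
    step = radial_step_mm if radial_step_mm is not None else img.pixel_spacing_mm
    polar = resample_polar(
        grad, center, rB, step, img.pixel_spacing_mm, probe=img.probe
    )
    costs = invert_costs(polar)
    path = dp_closed_contour(costs.values, params)
    contour = contour_to_cartesian(path.row_per_column, costs)
    mask = contour.to_mask(img.pixels.shape)
    if return_intermediates:
        return contour, mask, {
            "center": center,
            "max_radius_mm": rB,
            "polar": polar,
            "costs": costs,
            "path": path,
        }
    return contour, mask
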