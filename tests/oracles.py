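"""Independent brute-force oracles for the path-optimisation modules.

These enumerate every feasible path explicitly (vectorised over the
enumeration, not over DP states) and are kept free of any import from the
modules they check, apart from shared parameter containers.
"""

from itertools import product

import numpy as np


def enumerate_open_paths(cost, delta_max, gamma):
    """Minimal open-path cost by enumerating all H^W row sequences."""
    cost = np.asarray(cost, float)
    W, H = cost.shape
    paths = np.array(list(product(range(H), repeat=W)))  # (M, W)
    steps = np.diff(paths, axis=1)
    feasible = (np.abs(steps) <= delta_max).all(axis=1)
    paths = paths[feasible]
    steps = steps[feasible]
    node = cost[np.arange(W)[None, :], paths]  # (M, W)
    penal = np.concatenate(
        [np.ones((len(paths), 1)), 1.0 + np.abs(steps) / gamma], axis=1
    )
    totals = (node * penal).sum(axis=1)
    return float(totals.min())


def enumerate_closed_paths(cost, delta_max, gamma):
    """Minimal closed-path cost: open paths with a feasible 0/W-1 seam."""
    cost = np.asarray(cost, float)
    W, H = cost.shape
    paths = np.array(list(product(range(H), repeat=W)))
    steps = np.diff(paths, axis=1)
    feasible = (np.abs(steps) <= delta_max).all(axis=1)
    feasible &= np.abs(paths[:, 0] - paths[:, -1]) <= delta_max
    paths = paths[feasible]
    steps = steps[feasible]
    if len(paths) == 0:
        raise ValueError("no feasible closed path")
    node = cost[np.arange(W)[None, :], paths]
    penal = np.concatenate(
        [np.ones((len(paths), 1)), 1.0 + np.abs(steps) / gamma], axis=1
    )
    return float((node * penal).sum(axis=1).min())


def enumerate_dual_paths(g, g_inv, sep_lo, sep_hi, alpha1, alpha2, alpha3):
    """Minimal dual-line cost by enumerating all step sequences per start state.

    Lines step by at most 1 px per column; the node cost is
    g_inv[y1] + g[y2] and each transition multiplies it by
    (1+a1)^|d1| (1+a2)^|d2| (1 + a3 |d1-d2|).
    """
    g = np.asarray(g, float)
    g_inv = np.asarray(g_inv, float)
    rows, cols = g.shape
    combos = list(product((-1, 0, 1), repeat=2))
    seqs = np.array(list(product(range(9), repeat=cols - 1)))  # (M, cols-1)
    d1 = np.array([c[0] for c in combos])[seqs]
    d2 = np.array([c[1] for c in combos])[seqs]
    mult = np.array(
        [
            (1 + alpha1) ** abs(c0) * (1 + alpha2) ** abs(c1) * (1 + alpha3 * abs(c0 - c1))
            for c0, c1 in combos
        ]
    )[seqs]

    best = np.inf
    col_idx = np.arange(cols)
    for y1_0 in range(rows):
        for sep0 in range(sep_lo, sep_hi + 1):
            if y1_0 + sep0 >= rows:
                continue
            y1 = np.concatenate(
                [np.full((len(seqs), 1), y1_0), y1_0 + np.cumsum(d1, axis=1)], axis=1
            )
            y2 = np.concatenate(
                [
                    np.full((len(seqs), 1), y1_0 + sep0),
                    y1_0 + sep0 + np.cumsum(d2, axis=1),
                ],
                axis=1,
            )
            sep = y2 - y1
            ok = (
                (y1 >= 0).all(axis=1)
                & (y2 < rows).all(axis=1)
                & (sep >= sep_lo).all(axis=1)
                & (sep <= sep_hi).all(axis=1)
            )
            if not ok.any():
                continue
            yy1, yy2 = y1[ok], y2[ok]
            node = g_inv[yy1, col_idx[None, :]] + g[yy2, col_idx[None, :]]
            totals = node[:, 0] + (node[:, 1:] * mult[ok]).sum(axis=1)
            best = min(best, float(totals.min()))
    return best
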