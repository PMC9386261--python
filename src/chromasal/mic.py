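"""Maximal Information Coefficient (MIC) for color-attention association.

MIC(x, y) = max over grid shapes (n_x, n_y) with n_x * n_y < B(n) = n^0.6 of
I(x, y; grid) / log2(min(n_x, n_y)), where I is the plug-in mutual
information (bits) of the sample counts on the grid.  It captures both
linear and non-linear dependence, lies in [0, 1], and is invariant under
strictly monotone transforms of either variable because the grid search is
rank-based.

The per-shape maximization enumerates every admissible cut placement on one
axis whenever that enumeration is small, and otherwise mass-equipartitions
that axis; the other axis's cut points are then optimized exactly by dynamic
programming.  Both axis roles are tried and the maximum kept.  This is exact
for every grid shape that the B(n) bound admits at small n, where
:func:`exhaustive_mic` provides the brute-force cross-check.

Cut points never separate equal sample values: ties always share a bin.
Because B(n) < 4 for n <= 10 would leave no admissible grid at all, the
2 x 2 shape is always admitted.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .colorspace import normalize_channel, rgb_to_hsi, rgb_to_lab

#: cap on DP cut candidates per axis; beyond it clumps merge into superclumps
MAX_CLUMPS = 64
#: cap on enumerated cut placements of the non-DP axis before falling back
#: to equipartition (large enough for full enumeration of every grid shape
#: admissible at n <= 16, where the exhaustive oracle applies)
ENUM_LIMIT = 48

_CHANNELS = {
    "rgb": ("R", "G", "B"),
    "lab": ("L", "a", "b"),
    "hsi": ("H", "S", "I"),
}


def _validate_pair(x, y):
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("MIC needs at least 4 paired samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("MIC undefined for degenerate (constant) variable")
    return x, y


def grid_mutual_information(x, y, x_edges, y_edges) -> float:
    """Plug-in mutual information (bits) of the sample on an explicit grid.

    ``x_edges``/``y_edges`` are interior cut points; bin b holds samples in
    (edge[b-1], edge[b]].  Every sample must land in a bin, i.e. the grid's
    outer range is unbounded.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    x_edges = np.asarray(x_edges, dtype=np.float64)
    y_edges = np.asarray(y_edges, dtype=np.float64)
    for e in (x_edges, y_edges):
        if e.size and np.any(np.diff(e) <= 0):
            raise ValueError("grid edges must be strictly increasing")
    xi = np.searchsorted(x_edges, x, side="left")
    yi = np.searchsorted(y_edges, y, side="left")
    nx, ny = x_edges.size + 1, y_edges.size + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xi, yi), 1.0)
    return _mi_bits(joint / x.size)


def _mi_bits(p: np.ndarray) -> float:
    """I = H(row) + H(col) - H(joint) for a joint probability table."""
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())
    return ent(px) + ent(py) - ent(p.ravel())


def _clumps(sorted_vals: np.ndarray) -> np.ndarray:
    """End indices (exclusive) of maximal runs of equal values."""
    change = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    return np.append(change, sorted_vals.size)


def _superclump(ends: np.ndarray, n: int, cap: int) -> np.ndarray:
    """Thin clump boundaries to at most ``cap`` near-equal-mass candidates."""
    if ends.size <= cap:
        return ends
    targets = np.linspace(n / cap, n, cap)
    idx = np.unique(np.searchsorted(ends, targets, side="left").clip(0, ends.size - 1))
    return ends[idx] if ends[idx][-1] == n else np.append(ends[idx], n)


def _equipartition_assign(ends: np.ndarray, n: int, k: int) -> np.ndarray:
    """Greedy mass equipartition of sorted samples into <= k bins.

    Returns the bin index of each sorted sample; ties never split."""
    assign = np.zeros(n, dtype=np.int64)
    b = 0
    bin_start = 0
    clump_start = 0
    for i in range(ends.size):
        end = int(ends[i])
        assign[clump_start:end] = b
        remaining_bins = k - b
        if remaining_bins > 1 and i < ends.size - 1:
            target = (n - bin_start) / remaining_bins
            if end - bin_start >= target:
                b += 1
                bin_start = end
        clump_start = end
    return assign


def _bin_assign_from_cuts(ends: np.ndarray, cut_idx: tuple[int, ...], n: int) -> np.ndarray:
    """Bin index per sorted sample for cuts at the given clump-boundary indices."""
    bounds = [0] + [int(ends[c]) for c in cut_idx] + [n]
    assign = np.empty(n, dtype=np.int64)
    for b in range(len(bounds) - 1):
        assign[bounds[b]:bounds[b + 1]] = b
    return assign


def _dp_best_term(q_sorted_by_v: np.ndarray, n_qbins: int, ends: np.ndarray,
                  n_bins: int) -> float:
    """Exact DP: partition the DP axis into <= n_bins contiguous bins
    maximizing H(P) - H(P, Q); returns that maximum.

    ``q_sorted_by_v`` is the fixed axis's bin index of each sample, ordered
    by the DP axis's values; ``ends`` are candidate cut positions
    (clump end indices into that ordering)."""
    n = q_sorted_by_v.size
    c = ends.size
    # cumulative per-q counts at each candidate boundary (and 0)
    onehot = np.zeros((n, n_qbins))
    onehot[np.arange(n), q_sorted_by_v] = 1.0
    csum = np.vstack([np.zeros(n_qbins), np.cumsum(onehot, axis=0)])
    cum = csum[np.concatenate([[0], ends])]  # (c+1, n_qbins)

    # T[a, b]: contribution of one bin spanning candidate boundaries a..b
    # = -(n_b/n) log2(n_b/n) + sum_q (n_bq/n) log2(n_bq/n), vectorized
    nq = cum[None, :, :] - cum[:, None, :]          # (c+1, c+1, n_qbins)
    nb = nq.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pb = nb / n
        t_marg = np.where(nb > 0, -pb * np.log2(np.where(nb > 0, pb, 1.0)), 0.0)
        pq = nq / n
        t_joint = np.where(nq > 0, pq * np.log2(np.where(nq > 0, pq, 1.0)), 0.0).sum(axis=-1)
    T = t_marg + t_joint
    T[np.tril_indices(c + 1)] = -np.inf  # only forward spans are bins

    best = np.full((c + 1, n_bins + 1), -np.inf)
    best[0, 0] = 0.0
    for t in range(1, n_bins + 1):
        for i in range(1, c + 1):
            cand = best[:i, t - 1] + T[:i, i]
            best[i, t] = cand.max()
    return float(best[c, 1:].max())


def _entropy_of_assign(assign: np.ndarray) -> float:
    counts = np.bincount(assign).astype(float)
    p = counts[counts > 0] / assign.size
    return float(-(p * np.log2(p)).sum())


def _best_I_fixed_roles(v_dp: np.ndarray, v_fix: np.ndarray, n_dp: int, n_fix: int) -> float:
    """Best I for a grid with n_fix bins on the enumerated/equipartitioned
    axis and <= n_dp DP-optimized bins on the other."""
    n = v_fix.size
    order_fix = np.argsort(v_fix, kind="stable")
    ends_fix = _clumps(v_fix[order_fix])
    order_dp = np.argsort(v_dp, kind="stable")
    ends_dp = _superclump(_clumps(v_dp[order_dp]), n, MAX_CLUMPS)

    n_cand = ends_fix.size - 1  # interior clump boundaries on the fixed axis
    fix_assignments = []
    if n_cand >= n_fix - 1 and _n_combos(n_cand, n_fix - 1) <= ENUM_LIMIT:
        for cut_idx in combinations(range(n_cand), n_fix - 1):
            fix_assignments.append(_bin_assign_from_cuts(ends_fix, cut_idx, n))
    else:
        fix_assignments.append(_equipartition_assign(ends_fix, n, n_fix))

    best = 0.0
    for assign_sorted in fix_assignments:
        # fixed-axis bin index per sample, then ordered by the DP axis
        q = np.empty(n, dtype=np.int64)
        q[order_fix] = assign_sorted
        q_by_dp = q[order_dp]
        hq = _entropy_of_assign(q)
        n_qbins = int(q.max()) + 1
        val = hq + _dp_best_term(q_by_dp, n_qbins, ends_dp, n_dp)
        best = max(best, val)
    return best


def _n_combos(n: int, k: int) -> float:
    from math import comb
    return comb(n, k) if 0 <= k <= n else 0


def admissible_shapes(n: int) -> list[tuple[int, int]]:
    """Grid shapes (n_x, n_y) with n_x*n_y < n^0.6, floored so 2x2 is
    always admitted."""
    bound = max(n ** 0.6, 4.0 + 1e-9)
    shapes = []
    nx = 2
    while nx * 2 < bound or nx == 2:
        ny = 2
        while nx * ny < bound or (nx == 2 and ny == 2):
            shapes.append((nx, ny))
            ny += 1
        nx += 1
        if nx > n:
            break
    return shapes


def mic(x, y) -> float:
    """Maximal Information Coefficient of a paired sample, in [0, 1]."""
    x, y = _validate_pair(x, y)
    n = x.size
    best = 0.0
    for nx, ny in admissible_shapes(n):
        norm = np.log2(min(nx, ny))
        # both role assignments: enumerate/equipartition one axis, DP the other
        val = max(
            _best_I_fixed_roles(x, y, nx, ny),
            _best_I_fixed_roles(y, x, ny, nx),
        )
        best = max(best, val / norm)
    return float(min(best, 1.0))


def exhaustive_mic(x, y) -> float:
    """Exact MIC by full enumeration of all admissible grids (n <= 20).

    Cut points range over every placement between consecutive distinct
    sorted values on each axis; this is the definitional brute force used to
    validate :func:`mic`.
    """
    x, y = _validate_pair(x, y)
    n = x.size
    if n > 20:
        raise ValueError("exhaustive_mic is limited to n <= 20")
    order_x = np.argsort(x, kind="stable")
    order_y = np.argsort(y, kind="stable")
    ends_x = _clumps(x[order_x])
    ends_y = _clumps(y[order_y])
    rank_x = np.empty(n, dtype=np.int64)
    rank_y = np.empty(n, dtype=np.int64)

    best = 0.0
    for nx, ny in admissible_shapes(n):
        norm = np.log2(min(nx, ny))
        for cx in combinations(range(ends_x.size - 1), nx - 1):
            ax_sorted = _bin_assign_from_cuts(ends_x, cx, n)
            rank_x[order_x] = ax_sorted
            for cy in combinations(range(ends_y.size - 1), ny - 1):
                ay_sorted = _bin_assign_from_cuts(ends_y, cy, n)
                rank_y[order_y] = ay_sorted
                joint = np.zeros((nx, ny))
                np.add.at(joint, (rank_x, rank_y), 1.0)
                val = _mi_bits(joint / n) / norm
                best = max(best, val)
    return float(min(best, 1.0))


def channel_mic_profile(das, img, space: str = "lab", threshold: float = 0.1,
                        subsample: int | None = 1000, seed: int = 0):
    """MIC between each normalized color channel and DAS over salient pixels.

    Pixels with DAS > ``threshold`` are selected (the salient-color
    condition); each channel of the chosen space is normalized to [0, 1] by
    its theoretical range and its MIC with the DAS values computed.  Returns
    ``(dict channel -> MIC, total)``; the total is what the channel weights
    of the region-contrast detector are derived from.

    ``subsample`` caps the number of selected pixels (seeded, without
    replacement) to keep the grid search tractable on full images.
    """
    das = np.asarray(das, dtype=np.float64)
    space = space.lower()
    if space not in _CHANNELS:
        raise KeyError(f"unknown color space {space!r}")
    if space == "rgb":
        chan_img = np.asarray(img, dtype=np.float64)
        if np.issubdtype(np.asarray(img).dtype, np.integer) or chan_img.max() > 1.0:
            pass
        else:
            chan_img = chan_img * 255.0
    elif space == "lab":
        chan_img = rgb_to_lab(img)
    else:
        chan_img = rgb_to_hsi(img)
    if das.shape != chan_img.shape[:2]:
        raise ValueError("DAS map and image must share a shape")

    sel = das > threshold
    if sel.sum() < 4:
        raise ValueError("fewer than 4 pixels exceed the DAS threshold")
    das_sel = das[sel]
    chans = chan_img[sel]  # (n, 3)
    if subsample is not None and das_sel.size > subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(das_sel.size, size=subsample, replace=False)
        das_sel = das_sel[idx]
        chans = chans[idx]

    profile = {}
    for ci, name in enumerate(_CHANNELS[space]):
        vals = normalize_channel(chans[:, ci], space, name)
        profile[name] = mic(vals, das_sel)
    return profile, float(sum(profile.values()))
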