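"""Saliency evaluation metrics.

Salient-object metrics (map vs. binary mask): MAE, S-measure, PR curve.
Fixation metrics (map vs. fixation points / fixation map): AUC-Judd,
AUC-Borji, shuffled AUC, NSS, SIM, CC, KL divergence, EMD and information
gain.

Conventions follow the de facto saliency-benchmark code: AUC ties
contribute half (so a uniform map scores exactly 0.5), KL uses the
regularizer eps = 2.2204e-16 in the direction KL(fixations || saliency),
and EMD is the exact optimal-transport cost between the two maps
downsampled to a 32 x 24 grid with Euclidean ground distance between cell
centers.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

EPS = 2.2204e-16


def _check_pair(a, b, name="inputs"):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"{name} must share a shape, got {a.shape} vs {b.shape}")
    return a, b


def _as_distribution(m, name="map"):
    m = np.asarray(m, dtype=np.float64)
    s = m.sum()
    if s <= 0:
        raise ValueError(f"{name} has zero sum, cannot normalize to a distribution")
    return m / s


def _fixation_mask(shape, fix_points) -> np.ndarray:
    pts = np.asarray(list(fix_points), dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("need at least one fixation")
    xs = np.round(pts[:, 0]).astype(int)
    ys = np.round(pts[:, 1]).astype(int)
    H, W = shape
    if (xs < 0).any() or (xs >= W).any() or (ys < 0).any() or (ys >= H).any():
        raise ValueError("fixation outside the map")
    mask = np.zeros(shape, dtype=bool)
    mask[ys, xs] = True
    return mask


# ---------------------------------------------------------------------------
# salient-object metrics
# ---------------------------------------------------------------------------

def mae(sal, gt) -> float:
    """Mean absolute per-pixel difference between map and binary mask."""
    sal, gt = _check_pair(sal, gt)
    return float(np.abs(sal - gt).mean())


def pr_curve(sal, gt):
    """Precision/recall at the 256 integer thresholds of the 8-bit map.

    The map is binarized at each threshold t in 0..255 as sal*255 >= t.
    Returns (precision, recall) arrays of length 256.
    """
    sal, gt = _check_pair(sal, gt)
    gt = gt > 0.5
    n_pos = gt.sum()
    if n_pos == 0:
        raise ValueError("empty ground-truth mask: precision undefined")
    sal8 = np.round(sal * 255.0)
    precision = np.empty(256)
    recall = np.empty(256)
    # histogram once, threshold by cumulative counts from the top
    bins = np.arange(257)
    h_all, _ = np.histogram(sal8, bins=bins)
    h_pos, _ = np.histogram(sal8[gt], bins=bins)
    cum_all = np.cumsum(h_all[::-1])[::-1]   # #pixels with sal8 >= t
    cum_pos = np.cumsum(h_pos[::-1])[::-1]
    for t in range(256):
        pred = cum_all[t]
        tp = cum_pos[t]
        precision[t] = tp / pred if pred > 0 else 1.0
        recall[t] = tp / n_pos
    return precision, recall


def _ssim_block(sal, gt) -> float:
    """SSIM-style structural similarity of one block (region term)."""
    x, y = sal.ravel(), gt.ravel()
    n = x.size
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).sum() / max(n - 1, 1)
    vy = ((y - my) ** 2).sum() / max(n - 1, 1)
    cxy = ((x - mx) * (y - my)).sum() / max(n - 1, 1)
    alpha = 4 * mx * my * cxy
    beta = (mx**2 + my**2) * (vx + vy)
    if alpha != 0:
        return alpha / (beta + EPS)
    return 1.0 if beta == 0 else 0.0


def _object_score(x: np.ndarray) -> float:
    """Object-level similarity of foreground (or background) values."""
    if x.size == 0:
        return 0.0
    mu = x.mean()
    sigma = x.std()
    return 2.0 * mu / (mu * mu + 1.0 + sigma + EPS)


def s_measure(sal, gt, alpha: float = 0.5) -> float:
    """Structure measure: alpha*S_object + (1-alpha)*S_region.

    S_object compares foreground and background value statistics weighted
    by foreground area; S_region averages SSIM-like similarity over the four
    blocks split at the mask centroid, weighted by block mass.  All-zero and
    all-one masks fall back to mean-intensity special cases.
    """
    sal, gt = _check_pair(sal, gt)
    gt = (gt > 0.5).astype(np.float64)
    y = gt.mean()
    if y == 0:  # no foreground: reward dark maps
        return 1.0 - sal.mean()
    if y == 1:  # all foreground: reward bright maps
        return float(sal.mean())
    return float(alpha * _s_object(sal, gt) + (1 - alpha) * _s_region(sal, gt))


def _s_object(sal, gt) -> float:
    fg = gt > 0.5
    u = gt.mean()
    o_fg = _object_score(sal[fg])
    o_bg = _object_score(1.0 - sal[~fg])
    return u * o_fg + (1 - u) * o_bg


def _mask_centroid(gt) -> tuple[int, int]:
    ys, xs = np.nonzero(gt > 0.5)
    return int(np.round(xs.mean())), int(np.round(ys.mean()))


def _s_region(sal, gt) -> float:
    H, W = gt.shape
    cx, cy = _mask_centroid(gt)
    cx = min(max(cx, 1), W - 1)
    cy = min(max(cy, 1), H - 1)
    total = H * W
    score = 0.0
    for ys, xs in ((slice(0, cy), slice(0, cx)), (slice(0, cy), slice(cx, W)),
                   (slice(cy, H), slice(0, cx)), (slice(cy, H), slice(cx, W))):
        g = gt[ys, xs]
        s = sal[ys, xs]
        w = g.size / total
        score += w * _ssim_block(s, g)
    return score


# ---------------------------------------------------------------------------
# fixation metrics
# ---------------------------------------------------------------------------

def _auc_from_scores(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    pos = np.sort(pos_scores)
    neg = np.sort(neg_scores)
    greater = np.searchsorted(neg, pos, side="left")
    ge = np.searchsorted(neg, pos, side="right")
    wins = greater + 0.5 * (ge - greater)
    return float(wins.sum() / (pos.size * neg.size))


def auc_judd(sal, fix_points) -> float:
    """AUC with all non-fixated pixels as negatives (threshold sweep over
    the fixated pixels' saliency values; ties give half credit)."""
    sal = np.asarray(sal, dtype=np.float64)
    mask = _fixation_mask(sal.shape, fix_points)
    pos = sal[mask]
    neg = sal[~mask]
    if neg.size == 0:
        raise ValueError("every pixel is fixated; AUC undefined")
    return _auc_from_scores(pos, neg)


def auc_borji(sal, fix_points, n_splits: int = 100, seed: int = 0) -> float:
    """AUC with negatives sampled uniformly at random, averaged over splits."""
    sal = np.asarray(sal, dtype=np.float64)
    mask = _fixation_mask(sal.shape, fix_points)
    pos = sal[mask]
    rng = np.random.default_rng(seed)
    flat = sal.ravel()
    aucs = [
        _auc_from_scores(pos, flat[rng.integers(0, flat.size, size=pos.size)])
        for _ in range(n_splits)
    ]
    return float(np.mean(aucs))


def sauc(sal, fix_points, other_fix_points, n_splits: int = 100, seed: int = 0) -> float:
    """Shuffled AUC: negatives drawn from fixations of *other* stimuli,
    which discounts center bias."""
    sal = np.asarray(sal, dtype=np.float64)
    mask = _fixation_mask(sal.shape, fix_points)
    pos = sal[mask]
    other = np.asarray(list(other_fix_points), dtype=float).reshape(-1, 2)
    if other.shape[0] == 0:
        raise ValueError("empty other-fixation pool")
    xs = np.round(other[:, 0]).astype(int).clip(0, sal.shape[1] - 1)
    ys = np.round(other[:, 1]).astype(int).clip(0, sal.shape[0] - 1)
    pool = sal[ys, xs]
    rng = np.random.default_rng(seed)
    n_neg = min(pos.size, pool.size)
    aucs = [
        _auc_from_scores(pos, pool[rng.choice(pool.size, size=n_neg, replace=False)])
        for _ in range(n_splits)
    ]
    return float(np.mean(aucs))


def nss(sal, fix_points) -> float:
    """Normalized scanpath saliency: mean z-scored map value at fixations."""
    sal = np.asarray(sal, dtype=np.float64)
    sigma = sal.std()
    if sigma == 0:
        raise ValueError("NSS undefined, zero variance saliency map")
    z = (sal - sal.mean()) / sigma
    _fixation_mask(sal.shape, fix_points)  # bounds / non-emptiness check
    pts = np.asarray(list(fix_points), dtype=float).reshape(-1, 2)
    xs = np.round(pts[:, 0]).astype(int)
    ys = np.round(pts[:, 1]).astype(int)
    return float(z[ys, xs].mean())


def sim(sal, fixmap) -> float:
    """Similarity: sum of pixel-wise minima of the two distributions."""
    sal, fixmap = _check_pair(sal, fixmap)
    p = _as_distribution(sal, "saliency map")
    q = _as_distribution(fixmap, "fixation map")
    return float(np.minimum(p, q).sum())


def cc(sal, fixmap) -> float:
    """Pearson linear correlation between map and fixation map."""
    sal, fixmap = _check_pair(sal, fixmap)
    if sal.std() == 0 or fixmap.std() == 0:
        raise ValueError("CC undefined for a constant map")
    a = sal - sal.mean()
    b = fixmap - fixmap.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


def kl(sal, fixmap) -> float:
    """KL divergence of the fixation distribution from the saliency one:
    sum Q log(eps + Q/(P + eps))."""
    sal, fixmap = _check_pair(sal, fixmap)
    p = _as_distribution(sal, "saliency map")
    q = _as_distribution(fixmap, "fixation map")
    return float((q * np.log(EPS + q / (p + EPS))).sum())


def _downsample_mean(m: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Block-mean downsample to ``grid`` = (height, width) cells."""
    H, W = m.shape
    gh, gw = grid
    ys = (np.arange(H) * gh) // H
    xs = (np.arange(W) * gw) // W
    out = np.zeros((gh, gw))
    np.add.at(out, (ys[:, None].repeat(W, 1), xs[None, :].repeat(H, 0)), m)
    return out


def emd(sal, fixmap, grid: tuple[int, int] = (24, 32)) -> float:
    """Earth mover's distance between the two maps as distributions.

    Both maps are mass-downsampled to ``grid`` (height, width) cells,
    normalized to sum 1, and the exact optimal-transport cost is solved as a
    linear program with Euclidean ground distance between cell centers (in
    cell units of the downsampled grid).
    """
    sal, fixmap = _check_pair(sal, fixmap)
    gh, gw = grid
    if sal.shape[0] < gh or sal.shape[1] < gw:
        gh, gw = sal.shape  # tiny inputs: use native resolution
    a = _as_distribution(_downsample_mean(sal, (gh, gw)), "saliency map").ravel()
    b = _as_distribution(_downsample_mean(fixmap, (gh, gw)), "fixation map").ravel()
    ys, xs = np.mgrid[0:gh, 0:gw]
    pts = np.c_[xs.ravel(), ys.ravel()].astype(float)
    # restrict to cells carrying mass in either distribution
    keep = (a > 0) | (b > 0)
    a, b, pts = a[keep], b[keep], pts[keep]
    diff = pts[:, None, :] - pts[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=-1))
    n = a.size
    c = D.ravel()
    ones = np.ones(n * n)
    A_rows = sparse.csr_matrix(
        (ones, (np.repeat(np.arange(n), n), np.arange(n * n))), shape=(n, n * n))
    A_cols = sparse.csr_matrix(
        (ones, (np.tile(np.arange(n), n), np.arange(n * n))), shape=(n, n * n))
    A = sparse.vstack([A_rows, A_cols[:-1]])
    bvec = np.concatenate([a, b[:-1]])
    res = linprog(c, A_eq=A, b_eq=bvec, bounds=(0, None), method="highs")
    if res.status != 0:
        raise RuntimeError(f"EMD linear program failed: {res.message}")
    return float(res.fun)


def info_gain(sal, fix_points, baseline=None) -> float:
    """Information gain over a baseline, in bits per fixation.

    mean over fixations of log2(P_sal + eps) - log2(P_base + eps), with
    both maps normalized to probability distributions.  The default
    baseline is uniform; pass e.g. :func:`center_baseline` output to
    discount center bias.
    """
    sal = np.asarray(sal, dtype=np.float64)
    p = _as_distribution(sal, "saliency map")
    if baseline is None:
        base = np.full(sal.shape, 1.0 / sal.size)
    else:
        base = _as_distribution(baseline, "baseline map")
        if base.shape != p.shape:
            raise ValueError("baseline must match the saliency map's shape")
    pts = np.asarray(list(fix_points), dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("need at least one fixation")
    xs = np.round(pts[:, 0]).astype(int)
    ys = np.round(pts[:, 1]).astype(int)
    return float(np.mean(np.log2(p[ys, xs] + EPS) - np.log2(base[ys, xs] + EPS)))


def center_baseline(shape, sigma_frac: float = 0.25) -> np.ndarray:
    """Isotropic center-Gaussian baseline (sigma = sigma_frac * width)."""
    H, W = shape
    ys, xs = np.mgrid[0:H, 0:W]
    s = sigma_frac * W
    g = np.exp(-(((xs - (W - 1) / 2) ** 2) + ((ys - (H - 1) / 2) ** 2)) / (2 * s * s))
    return g / g.sum()
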