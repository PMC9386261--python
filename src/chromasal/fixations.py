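"""Fixation maps, attention scores and the color-minus-gray DAS analysis.

A fixation map is built by placing an isotropic Gaussian (sigma = one degree
of visual angle, expressed in pixels) at every recorded fixation of every
subject and max-normalizing the pooled sum to 1; the map value at a pixel is
that pixel's *attention score*.  The *difference in attention score* (DAS)
between a color stimulus and its grayscale counterpart isolates what color
alone contributes to attention: it is computed as color minus gray, so a
uniquely colored object that pops out only in the color condition carries
positive DAS.  Quantized colors whose mean DAS exceeds a threshold (0.1 by
default) are the stimulus's *salient colors*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .colorspace import quantize_lab, rgb_to_lab

#: Reference viewing geometry: 1680 px spanning 42.48 degrees.
DEFAULT_PIXELS_PER_DEGREE = 1680.0 / 42.48

FIXATION_COLUMNS = ["image_id", "subject_id", "x", "y"]


@dataclass(frozen=True)
class ViewingGeometry:
    """Stimulus geometry; ``pixels_per_degree`` sets the map's Gaussian sigma."""

    pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE

    def __post_init__(self):
        if not self.pixels_per_degree > 0:
            raise ValueError("pixels_per_degree must be strictly positive")

    @classmethod
    def from_screen(cls, pixels: float, degrees: float) -> "ViewingGeometry":
        return cls(pixels_per_degree=pixels / degrees)


def read_fixations(path) -> pd.DataFrame:
    """Read a fixation CSV with header ``image_id,subject_id,x,y`` (0-based px)."""
    df = pd.read_csv(path)
    missing = set(FIXATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation file missing columns: {sorted(missing)}")
    return df[FIXATION_COLUMNS + [c for c in df.columns if c not in FIXATION_COLUMNS]]


def write_fixations(df: pd.DataFrame, path) -> None:
    df[FIXATION_COLUMNS].to_csv(path, index=False)


def build_fixation_map(fixations, shape, geometry: ViewingGeometry | None = None) -> np.ndarray:
    """Pooled Gaussian fixation map, max-normalized to 1.

    Parameters
    ----------
    fixations : iterable of (x, y) pairs or a DataFrame with x/y columns
        All subjects' fixations for one stimulus, pooled.
    shape : (H, W)
    geometry : ViewingGeometry
        sigma_px = pixels_per_degree (one degree of visual angle).

    The Gaussians are truncated at 4 sigma; the tail beyond that contributes
    less than 4e-4 of the peak.
    """
    geometry = geometry or ViewingGeometry()
    H, W = int(shape[0]), int(shape[1])
    if isinstance(fixations, pd.DataFrame):
        pts = fixations[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(list(fixations), dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("cannot normalize an all-zero map: no fixations given")
    xs = np.round(pts[:, 0]).astype(int)
    ys = np.round(pts[:, 1]).astype(int)
    if (xs < 0).any() or (xs >= W).any() or (ys < 0).any() or (ys >= H).any():
        raise ValueError("fixation outside the image bounds")
    impulses = np.zeros((H, W), dtype=np.float64)
    np.add.at(impulses, (ys, xs), 1.0)
    smoothed = ndimage.gaussian_filter(
        impulses, sigma=geometry.pixels_per_degree, mode="constant", truncate=4.0
    )
    peak = smoothed.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero map")
    return smoothed / peak


def compute_das(map_color: np.ndarray, map_gray: np.ndarray) -> np.ndarray:
    """Per-pixel difference in attention score, color minus gray, in [-1, 1]."""
    map_color = np.asarray(map_color, dtype=np.float64)
    map_gray = np.asarray(map_gray, dtype=np.float64)
    if map_color.shape != map_gray.shape:
        raise ValueError("attention maps must share a shape")
    return map_color - map_gray


@dataclass
class SalientColorTable:
    """Quantized color code -> attention weight (mean DAS), with pixel support.

    Only codes whose mean DAS strictly exceeds the extraction threshold are
    stored, so every weight lies in (threshold, 1].
    """

    entries: dict[int, float]
    support: dict[int, int]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: int) -> bool:
        return int(code) in self.entries

    def weight(self, code: int, floor: float = 0.1) -> float:
        return self.entries.get(int(code), floor)

    def to_json(self, path) -> None:
        payload = {
            "entries": {str(k): float(v) for k, v in self.entries.items()},
            "support": {str(k): int(v) for k, v in self.support.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SalientColorTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            entries={int(k): float(v) for k, v in payload["entries"].items()},
            support={int(k): int(v) for k, v in payload.get("support", {}).items()},
        )


def extract_salient_colors(das: np.ndarray, img: np.ndarray, threshold: float = 0.1) -> SalientColorTable:
    """Salient colors of a stimulus: quantized codes with mean DAS > threshold.

    DAS is aggregated per code by the mean over the code's pixels, which is
    robust to region size.
    """
    das = np.asarray(das, dtype=np.float64)
    codes = quantize_lab(rgb_to_lab(img))
    if das.shape != codes.shape:
        raise ValueError("DAS map and image must share a shape")
    flat_codes = codes.ravel()
    flat_das = das.ravel()
    counts = np.bincount(flat_codes, minlength=4096)
    sums = np.bincount(flat_codes, weights=flat_das, minlength=4096)
    present = counts > 0
    means = np.zeros(4096)
    means[present] = sums[present] / counts[present]
    keep = present & (means > threshold)
    codes_kept = np.flatnonzero(keep)
    return SalientColorTable(
        entries={int(c): float(means[c]) for c in codes_kept},
        support={int(c): int(counts[c]) for c in codes_kept},
    )


def top_salient_colors(table: SalientColorTable, k: int):
    """The k most attractive colors: (code, weight), weight descending,
    ties broken by ascending code."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def color_pair_das(das: np.ndarray, img: np.ndarray, threshold: float = 0.1) -> dict[tuple[int, int], float]:
    """Salient color-block combinations: adjacent distinct-code pairs by DAS.

    For every 4-adjacent pixel pair whose quantized codes differ, the mean
    DAS of the two pixels is accumulated per unordered code pair; pairs whose
    overall mean exceeds ``threshold`` are returned with that mean as weight.
    """
    das = np.asarray(das, dtype=np.float64)
    codes = quantize_lab(rgb_to_lab(img))
    if das.shape != codes.shape:
        raise ValueError("DAS map and image must share a shape")

    pair_sum: dict[tuple[int, int], float] = {}
    pair_cnt: dict[tuple[int, int], int] = {}
    for axis in (0, 1):
        a = codes if axis == 0 else codes.T
        d = das if axis == 0 else das.T
        c1, c2 = a[:-1, :].ravel(), a[1:, :].ravel()
        m = (d[:-1, :].ravel() + d[1:, :].ravel()) / 2.0
        diff = c1 != c2
        lo = np.minimum(c1[diff], c2[diff])
        hi = np.maximum(c1[diff], c2[diff])
        for l, h, v in zip(lo.tolist(), hi.tolist(), m[diff].tolist()):
            key = (l, h)
            pair_sum[key] = pair_sum.get(key, 0.0) + v
            pair_cnt[key] = pair_cnt.get(key, 0) + 1
    return {
        key: pair_sum[key] / pair_cnt[key]
        for key in pair_sum
        if pair_sum[key] / pair_cnt[key] > threshold
    }


def save_map_png(values: np.ndarray, path) -> None:
    """Write a [0,1] map as 8-bit grayscale PNG (value = round(255*score))."""
    from PIL import Image

    arr = np.round(np.clip(np.asarray(values, dtype=float), 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_map_png(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back onto the [0,1] scale."""
    from PIL import Image

    return np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
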