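"""Color-space conversions, channel normalization and L'a'b' quantization.

All analysis in this package runs in CIE 1976 L*a*b* (sRGB primaries, D65
white point).  For the color statistics the Lab cube is uniformly quantized
to 16 levels per channel, giving 16**3 = 4096 discrete color codes
``code = 256*L' + 16*a' + b'`` with L', a', b' in 0..15.

Channel conventions used throughout:

========  =============  ==========================
space     channel        theoretical range
========  =============  ==========================
rgb       R, G, B        [0, 255]
lab       L              [0, 100]
lab       a, b           [-127, 127]
hsi       H              [0, 360) degrees
hsi       S, I           [0, 1]
========  =============  ==========================
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

N_LEVELS = 16
N_CODES = N_LEVELS**3

#: theoretical (space, channel) -> (lo, hi) ranges used by normalize_channel
CHANNEL_RANGES = {
    ("rgb", "R"): (0.0, 255.0),
    ("rgb", "G"): (0.0, 255.0),
    ("rgb", "B"): (0.0, 255.0),
    ("lab", "L"): (0.0, 100.0),
    ("lab", "a"): (-127.0, 127.0),
    ("lab", "b"): (-127.0, 127.0),
    ("hsi", "H"): (0.0, 360.0),
    ("hsi", "S"): (0.0, 1.0),
    ("hsi", "I"): (0.0, 1.0),
}


def _as_rgb_float(img: np.ndarray) -> np.ndarray:
    """Validate an RGB image and return it as float in [0, 1]."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if not np.all(np.isfinite(img)):
        raise ValueError("RGB image contains non-finite values")
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / 255.0
    arr = img.astype(np.float64)
    if arr.max(initial=0.0) > 1.0 + 1e-9:
        # real-valued images on the 0..255 scale
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image (uint8 0-255 or float 0-1) to CIE L*a*b*.

    Uses sRGB companding and the D65 white point. Returns a float array of
    the same spatial shape with channels (L, a, b).
    """
    return _skcolor.rgb2lab(_as_rgb_float(img))


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Convert to grayscale by Rec.601 luma, returned as a 3-channel image.

    Output has identical R=G=B channels and the same dtype family as the
    input (uint8 in, uint8 out). Idempotent: gray images pass through
    unchanged up to rounding.
    """
    arr = np.asarray(img)
    was_int = np.issubdtype(arr.dtype, np.integer)
    rgbf = _as_rgb_float(arr)
    luma = 0.299 * rgbf[..., 0] + 0.587 * rgbf[..., 1] + 0.114 * rgbf[..., 2]
    out = np.repeat(luma[..., None], 3, axis=-1)
    if was_int:
        return np.round(out * 255.0).astype(np.uint8)
    return out


def rgb_to_hsi(img: np.ndarray) -> np.ndarray:
    """Convert RGB to classical hue/saturation/intensity.

    H in [0, 360) degrees from the geometric hue formula, S = 1 - min/I,
    I = (R+G+B)/3 in [0, 1].  Achromatic pixels get H = 0 and S = 0.
    """
    rgb = _as_rgb_float(img)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    intensity = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(intensity > 0, 1.0 - mn / np.maximum(intensity, 1e-300), 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        cosang = np.clip(np.where(den > 0, num / np.maximum(den, 1e-300), 1.0), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(den > 0, hue, 0.0)
    hue = np.where(hue >= 360.0, hue - 360.0, hue)
    return np.stack([hue, sat, intensity], axis=-1)


def _validate_lab(lab: np.ndarray) -> np.ndarray:
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim < 1 or lab.shape[-1] != 3:
        raise ValueError("Lab array must have 3 channels on the last axis")
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    tol = 1e-6
    if (L.min(initial=0) < -tol or L.max(initial=0) > 100 + tol
            or min(a.min(initial=0), b.min(initial=0)) < -127 - tol
            or max(a.max(initial=0), b.max(initial=0)) > 127 + tol):
        raise ValueError("Lab values outside L in [0,100], a,b in [-127,127]")
    return lab


def quantize_lab(lab: np.ndarray) -> np.ndarray:
    """Quantize a Lab image to integer codes in [0, 4095].

    Each channel is mapped onto the 0..255 scale (L' = 2.55 L,
    a' = a + 127, b' = b + 127) and floor-divided into 16 uniform bins;
    values at the top of the range clip into bin 15. The code is
    ``256*L' + 16*a' + b'`` with the binned L', a', b' in 0..15.
    """
    lab = _validate_lab(lab)
    lq = np.clip((2.55 * lab[..., 0]) // N_LEVELS, 0, N_LEVELS - 1).astype(np.int32)
    aq = np.clip((lab[..., 1] + 127.0) // N_LEVELS, 0, N_LEVELS - 1).astype(np.int32)
    bq = np.clip((lab[..., 2] + 127.0) // N_LEVELS, 0, N_LEVELS - 1).astype(np.int32)
    return encode_color(lq, aq, bq)


def encode_color(lq, aq, bq) -> np.ndarray:
    """Pack quantized (L', a', b') in 0..15 into a single code 256L'+16a'+b'."""
    lq, aq, bq = (np.asarray(x, dtype=np.int64) for x in (lq, aq, bq))
    for comp in (lq, aq, bq):
        if comp.min(initial=0) < 0 or comp.max(initial=0) > N_LEVELS - 1:
            raise ValueError("quantized components must lie in [0, 15]")
    return (N_LEVELS * N_LEVELS * lq + N_LEVELS * aq + bq).astype(np.int32)


def decode_color(code):
    """Invert :func:`encode_color`; returns (L', a', b') arrays in 0..15."""
    code = np.asarray(code, dtype=np.int64)
    if code.min(initial=0) < 0 or code.max(initial=0) > N_CODES - 1:
        raise ValueError("color codes must lie in [0, 4095]")
    return code // 256, (code // 16) % 16, code % 16


def code_to_lab_center(code) -> np.ndarray:
    """Lab coordinates of the quantization-bin centers for given codes.

    The center of bin q on the 0..255 working scale is 16*q + 8, mapped
    back through L = scale/2.55, a = scale - 127, b = scale - 127.
    """
    lq, aq, bq = decode_color(code)
    L = (16.0 * lq + 8.0) / 2.55
    a = 16.0 * aq + 8.0 - 127.0
    b = 16.0 * bq + 8.0 - 127.0
    return np.stack([L, a, b], axis=-1)


def normalize_channel(values, space: str, channel: str) -> np.ndarray:
    """Affinely map channel values from their theoretical range onto [0, 1]."""
    key = (space.lower(), channel)
    if key not in CHANNEL_RANGES:
        raise KeyError(f"unknown space/channel {key!r}")
    lo, hi = CHANNEL_RANGES[key]
    vals = np.asarray(values, dtype=np.float64)
    tol = 1e-9 * max(1.0, hi - lo)
    if vals.size and (vals.min() < lo - tol or vals.max() > hi + tol):
        raise ValueError(f"values outside theoretical range [{lo}, {hi}] for {key}")
    return np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
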