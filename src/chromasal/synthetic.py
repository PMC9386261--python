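"""Synthetic paired color/grayscale stimuli with planted salient colors.

The generator emulates the structure of a color-vs-gray free-viewing study:
each scene is a textured background with a few geometric objects, one or
more of which carry a planted high-chroma color.  Subjects' fixations are
drawn from a mixture of a center-biased base process and object-directed
looks; objects carrying a planted salient color receive an attention boost
— but only when the stimulus is shown in color.  The color and grayscale
fixation distributions therefore differ exactly on the planted colors,
which is what a positive DAS concentrated on those colors encodes.

Default study conditions: 18 subjects, 50 fixations each, attraction boost
5 on salient-color objects.  All randomness flows through one seeded
generator; identical seeds give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as _skcolor

from .colorspace import quantize_lab, rgb_to_gray, rgb_to_lab
from .fixations import FIXATION_COLUMNS, SalientColorTable, ViewingGeometry

#: horizontal visual angle of the emulated stimuli, degrees
STIMULUS_DEGREES = 42.48


def scene_geometry(spec: "SceneSpec") -> ViewingGeometry:
    """Geometry for a synthetic scene: its width spans the study's 42.48 deg,
    so the fixation-map sigma scales with the synthetic resolution."""
    return ViewingGeometry.from_screen(spec.width, STIMULUS_DEGREES)


@dataclass(frozen=True)
class ObjectSpec:
    """One planted object: axis-aligned rectangle or ellipse in Lab color."""

    shape: str                      # "rectangle" | "ellipse"
    lab: tuple[float, float, float]
    center: tuple[float, float]     # (x, y) as fractions of (W, H)
    size: tuple[float, float]       # (half-width, half-height) fractions
    salient: bool = False           # carries a planted salient color

    def __post_init__(self):
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError("shape must be 'rectangle' or 'ellipse'")
        for c, s in zip(self.center, self.size):
            if not (0 < c < 1) or not (0 < s < 0.5):
                raise ValueError("object must lie within the image bounds")


@dataclass
class SceneSpec:
    """Scene layout and study conditions for one synthetic stimulus."""

    height: int = 120
    width: int = 160
    background_lab: tuple[float, float, float] = (55.0, 2.0, 2.0)
    noise_sigma: float = 1.5        # Lab-channel texture noise
    objects: list[ObjectSpec] = field(default_factory=list)
    attraction_boost: float = 5.0   # fixation-rate multiplier, color condition
    n_subjects: int = 18
    n_fixations: int = 50           # per subject
    base_rate: float = 0.35         # share of center-biased base fixations

    def __post_init__(self):
        if self.attraction_boost < 1:
            raise ValueError("attraction_boost must be >= 1")
        if not self.objects:
            self.objects = default_objects()


def default_objects() -> list[ObjectSpec]:
    """One vivid (salient) object and one near-isoluminant distractor."""
    return [
        ObjectSpec("ellipse", lab=(55.0, 65.0, 55.0), center=(0.3, 0.38),
                   size=(0.1, 0.12), salient=True),
        ObjectSpec("rectangle", lab=(62.0, 4.0, -2.0), center=(0.72, 0.65),
                   size=(0.1, 0.08), salient=False),
    ]


@dataclass
class SyntheticBundle:
    """Everything one synthetic stimulus pair provides for testing."""

    color_image: np.ndarray         # H x W x 3 uint8
    gray_image: np.ndarray          # H x W x 3 uint8, R=G=B
    mask: np.ndarray                # H x W binary: union of object footprints
    salient_mask: np.ndarray        # footprints of salient-color objects only
    fixations_color: pd.DataFrame   # image_id, subject_id, x, y
    fixations_gray: pd.DataFrame
    true_salient_table: SalientColorTable
    spec: SceneSpec


def _footprint(obj: ObjectSpec, H: int, W: int) -> np.ndarray:
    ys, xs = np.mgrid[0:H, 0:W]
    cx, cy = obj.center[0] * W, obj.center[1] * H
    hx, hy = obj.size[0] * W, obj.size[1] * H
    if obj.shape == "rectangle":
        return (np.abs(xs - cx) <= hx) & (np.abs(ys - cy) <= hy)
    return ((xs - cx) / hx) ** 2 + ((ys - cy) / hy) ** 2 <= 1.0


def _render(spec: SceneSpec, rng: np.random.Generator):
    H, W = spec.height, spec.width
    lab = np.empty((H, W, 3))
    lab[..., 0] = spec.background_lab[0]
    lab[..., 1] = spec.background_lab[1]
    lab[..., 2] = spec.background_lab[2]
    lab += rng.normal(0.0, spec.noise_sigma, size=lab.shape)
    masks = [_footprint(o, H, W) for o in spec.objects]
    for obj, m in zip(spec.objects, masks):
        for c in range(3):
            lab[..., c][m] = obj.lab[c] + rng.normal(0.0, spec.noise_sigma * 0.5,
                                                     size=int(m.sum()))
    lab[..., 0] = np.clip(lab[..., 0], 0, 100)
    lab[..., 1:] = np.clip(lab[..., 1:], -127, 127)
    rgb = np.clip(_skcolor.lab2rgb(lab), 0, 1)
    return (rgb * 255).round().astype(np.uint8), masks


def _sample_fixations(spec: SceneSpec, masks, condition: str,
                      rng: np.random.Generator, image_id: str) -> pd.DataFrame:
    """Mixture sampling of one condition's fixations.

    Components: a center-biased Gaussian base (share ``base_rate``), a
    uniform scatter over the image, and — in the color condition only —
    directed looks at salient-color objects, whose rate is the uniform
    chance rate of the object's area times (boost - 1).  In grayscale no
    object is special (the pop-out cue is chroma, which grayscale removes),
    so the gray distribution is just center bias + uniform scatter.
    """
    H, W = spec.height, spec.width
    uniform_share = 1.0 - spec.base_rate
    raw = [spec.base_rate, uniform_share]
    directed: list[np.ndarray] = []
    for obj, m in zip(spec.objects, masks):
        if obj.salient and condition == "color":
            area_frac = m.sum() / (H * W)
            raw.append(uniform_share * area_frac * (spec.attraction_boost - 1.0))
            directed.append(np.flatnonzero(m.ravel()))
    weights = np.asarray(raw) / np.sum(raw)

    rows = []
    for s in range(spec.n_subjects):
        comp = rng.choice(len(weights), size=spec.n_fixations, p=weights)
        for ci in comp:
            if ci == 0:    # center-biased base fixation
                while True:
                    x = rng.normal((W - 1) / 2, W / 4)
                    y = rng.normal((H - 1) / 2, W / 4)
                    xi, yi = int(round(x)), int(round(y))
                    if 0 <= xi < W and 0 <= yi < H:
                        break
            elif ci == 1:  # uniform scatter
                p = int(rng.integers(0, H * W))
                yi, xi = divmod(p, W)
            else:          # directed look at a salient-color object
                p = int(rng.choice(directed[ci - 2]))
                yi, xi = divmod(p, W)
            rows.append((image_id, f"s{s:02d}", xi, yi))
    return pd.DataFrame(rows, columns=FIXATION_COLUMNS)


def _true_table(color_image, salient_mask, background_mask) -> SalientColorTable:
    """Planted salient colors: codes specific to the salient objects.

    A code counts as planted when it covers pixels of a salient object and
    is (essentially) absent from the rest of the scene.
    """
    codes = quantize_lab(rgb_to_lab(color_image))
    inside, inside_counts = np.unique(codes[salient_mask], return_counts=True)
    outside = set(np.unique(codes[background_mask]).tolist())
    entries, support = {}, {}
    for code, cnt in zip(inside.tolist(), inside_counts.tolist()):
        if code not in outside and cnt >= 3:
            entries[int(code)] = 1.0  # placeholder weight: planted, not measured
            support[int(code)] = int(cnt)
    return SalientColorTable(entries=entries, support=support)


def generate_scene(spec: SceneSpec | None = None, seed: int = 0,
                   image_id: str = "scene0") -> SyntheticBundle:
    """Deterministically generate one paired color/gray stimulus bundle."""
    spec = spec or SceneSpec()
    rng = np.random.default_rng(seed)
    color, masks = _render(spec, rng)
    gray = rgb_to_gray(color)
    mask_all = np.zeros((spec.height, spec.width), dtype=bool)
    mask_sal = np.zeros_like(mask_all)
    for obj, m in zip(spec.objects, masks):
        mask_all |= m
        if obj.salient:
            mask_sal |= m
    fix_color = _sample_fixations(spec, masks, "color", rng, image_id)
    fix_gray = _sample_fixations(spec, masks, "gray", rng, image_id)
    table = _true_table(color, mask_sal, ~mask_sal)
    return SyntheticBundle(
        color_image=color, gray_image=gray,
        mask=mask_all.astype(np.uint8), salient_mask=mask_sal.astype(np.uint8),
        fixations_color=fix_color, fixations_gray=fix_gray,
        true_salient_table=table, spec=spec,
    )


def generate_sod_fixture(seed: int = 0, size: tuple[int, int] = (96, 128),
                         isoluminant: bool = False):
    """A salient-object fixture: high-chroma object on a plain background.

    Returns ``(rgb_image, mask)``.  With ``isoluminant`` the object shares
    the background's L so only chroma separates it — the degraded-contrast
    case a grayscale rendering collapses entirely.
    """
    H, W = size
    rng = np.random.default_rng(seed)
    obj_L = 55.0 if isoluminant else 75.0
    obj = ObjectSpec("ellipse", lab=(obj_L, 60.0, 45.0),
                     center=(float(rng.uniform(0.3, 0.7)), float(rng.uniform(0.3, 0.7))),
                     size=(0.14, 0.17), salient=True)
    spec = SceneSpec(height=H, width=W, background_lab=(55.0, 2.0, 2.0),
                     noise_sigma=1.0, objects=[obj])
    color, masks = _render(spec, rng)
    return color, masks[0].astype(np.uint8)
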