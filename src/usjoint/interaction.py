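"""Simulated user interactions and their network input encoding.

The segmentation network is click-guided: a user marks a lesion with
foreground clicks inside it and (optionally) background clicks around it.
Real click capture is impractical at training scale, so clicks are
simulated — foreground: 1–5 pixels uniform inside the lesion; background:
0–10 pixels uniform over a distance band around it.  A bounding-box
("two-click") interaction is supported by converting the box to one
foreground click at its centre and four background clicks at its corners.

Clicks enter the network as Euclidean distance maps: each pixel holds the
minimum distance to any click of that polarity, truncated at 255.  With no
click of a polarity, the map is filled with 255.  The encoded input stacks
(image, foreground map, background map), each scaled by 1/255.

Conventions used throughout: 0-based (row, col) pixel coordinates,
distances between pixel centers, boxes inclusive of both corners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

#: distance truncation value; doubles as the fill for "no clicks"
DIST_FILL = 255.0

#: default background-click band (px): near enough to inform the boundary,
#: far enough to be unambiguous background
DEFAULT_D_MIN = 5.0
DEFAULT_D_MAX = 40.0

MAX_FG_CLICKS = 5
MAX_BG_CLICKS = 10


@dataclass(frozen=True)
class Click:
    row: int
    col: int
    polarity: str = "foreground"  # or "background"


@dataclass
class ClickSet:
    foreground: list[Click] = field(default_factory=list)
    background: list[Click] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {"foreground": [[c.row, c.col] for c in self.foreground],
                "background": [[c.row, c.col] for c in self.background]}

    @classmethod
    def from_json_dict(cls, d: dict) -> "ClickSet":
        return cls(
            foreground=[Click(int(r), int(c), "foreground") for r, c in d.get("foreground", [])],
            background=[Click(int(r), int(c), "background") for r, c in d.get("background", [])],
        )


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, inclusive of both corner pixels."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self):
        if not (self.top < self.bottom and self.left < self.right):
            raise ValueError(f"degenerate box {self}")

    def to_json_dict(self) -> dict:
        return {"top": self.top, "left": self.left,
                "bottom": self.bottom, "right": self.right}

    @classmethod
    def from_json_dict(cls, d: dict) -> "BoundingBox":
        return cls(int(d["top"]), int(d["left"]), int(d["bottom"]), int(d["right"]))


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("mask is empty: no lesion to click on")
    return mask


def simulate_foreground_clicks(mask: np.ndarray, rng_seed: int) -> list[Click]:
    """Draw k ~ Uniform{1..5} distinct pixels uniformly inside the lesion."""
    mask = _check_mask(mask)
    rng = np.random.default_rng(rng_seed)
    fg = np.argwhere(mask)
    k = min(int(rng.integers(1, MAX_FG_CLICKS + 1)), len(fg))
    chosen = fg[rng.choice(len(fg), size=k, replace=False)]
    return [Click(int(r), int(c), "foreground") for r, c in chosen]


def background_band(mask: np.ndarray, d_min: float = DEFAULT_D_MIN,
                    d_max: float = DEFAULT_D_MAX) -> np.ndarray:
    """Boolean mask of background pixels whose Euclidean distance to the
    nearest lesion pixel lies in [d_min, d_max]."""
    dist = distance_transform_edt(~mask)
    return (~mask) & (dist >= d_min) & (dist <= d_max)


def simulate_background_clicks(mask: np.ndarray, d_min: float = DEFAULT_D_MIN,
                               d_max: float = DEFAULT_D_MAX,
                               rng_seed: int = 0) -> list[Click]:
    """Draw m ~ Uniform{0..10} distinct pixels uniformly over the background
    band around the lesion.  m = 0 models a user who gives no background
    clicks."""
    mask = _check_mask(mask)
    if not 0 < d_min < d_max:
        raise ValueError("need 0 < d_min < d_max")
    rng = np.random.default_rng(rng_seed)
    band = np.argwhere(background_band(mask, d_min, d_max))
    if len(band) == 0:
        warnings.warn("lesion fills the image: background band is empty")
        return []
    m = min(int(rng.integers(0, MAX_BG_CLICKS + 1)), len(band))
    if m == 0:
        return []
    chosen = band[rng.choice(len(band), size=m, replace=False)]
    return [Click(int(r), int(c), "background") for r, c in chosen]


def generate_click_sequences(mask: np.ndarray, n_sequences: int = 15,
                             d_min: float = DEFAULT_D_MIN,
                             d_max: float = DEFAULT_D_MAX,
                             rng_seed: int = 0) -> list[ClickSet]:
    """n independent (foreground draw, background draw) pairs per image,
    used to expose the network to different click styles during training."""
    mask = _check_mask(mask)
    seeds = np.random.SeedSequence([rng_seed, 271828]).generate_state(2 * max(n_sequences, 1))
    out = []
    for i in range(n_sequences):
        fg = simulate_foreground_clicks(mask, int(seeds[2 * i]) % (2 ** 31))
        bg = simulate_background_clicks(mask, d_min, d_max, int(seeds[2 * i + 1]) % (2 ** 31))
        out.append(ClickSet(foreground=fg, background=bg))
    return out


def distance_map(clicks: list[Click], shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel minimum Euclidean distance to the click set, truncated at
    255.  With no clicks the map is filled with 255."""
    h, w = shape
    if not clicks:
        return np.full(shape, DIST_FILL)
    rows = np.array([c.row for c in clicks], dtype=float)
    cols = np.array([c.col for c in clicks], dtype=float)
    if (rows < 0).any() or (rows >= h).any() or (cols < 0).any() or (cols >= w).any():
        raise ValueError("click outside image bounds")
    rr = np.arange(h, dtype=float)[:, None, None]
    cc = np.arange(w, dtype=float)[None, :, None]
    d = np.sqrt((rr - rows[None, None, :]) ** 2 + (cc - cols[None, None, :]) ** 2)
    return np.minimum(d.min(axis=2), DIST_FILL)


def encode_input(image: np.ndarray, clicks: ClickSet) -> np.ndarray:
    """Stack (image, fg distance map, bg distance map), each scaled by 1/255.

    Returns a (3, H, W) float array — the network input.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    fg = distance_map(clicks.foreground, image.shape)
    bg = distance_map(clicks.background, image.shape)
    return np.stack([image / 255.0, fg / 255.0, bg / 255.0]).astype(np.float32)


def tight_box(mask: np.ndarray) -> BoundingBox:
    """Tight axis-aligned bounding box of the mask (inclusive corners)."""
    mask = _check_mask(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    top, bottom = int(rows[0]), int(rows[-1])
    left, right = int(cols[0]), int(cols[-1])
    # guarantee a non-degenerate box even for 1-px-thin masks
    if top == bottom:
        bottom = min(bottom + 1, mask.shape[0] - 1) if bottom < mask.shape[0] - 1 else bottom
        top = max(top - 1, 0) if top == bottom else top
    if left == right:
        right = min(right + 1, mask.shape[1] - 1) if right < mask.shape[1] - 1 else right
        left = max(left - 1, 0) if left == right else left
    return BoundingBox(top, left, bottom, right)


def simulate_bbox(mask: np.ndarray, jitter_frac: float = 0.1,
                  enlarge_frac: float = 0.1, rng_seed: int = 0) -> BoundingBox:
    """A user-drawn box: the tight lesion box with positional error on each
    corner, then enlarged a little so it still includes the lesion, clamped
    to the image.  The returned box always contains every mask pixel."""
    mask = _check_mask(mask)
    h, w = mask.shape
    tb = tight_box(mask)
    bh, bw = tb.bottom - tb.top, tb.right - tb.left
    rng = np.random.default_rng(rng_seed)
    top = tb.top + rng.uniform(-jitter_frac, jitter_frac) * bh
    bottom = tb.bottom + rng.uniform(-jitter_frac, jitter_frac) * bh
    left = tb.left + rng.uniform(-jitter_frac, jitter_frac) * bw
    right = tb.right + rng.uniform(-jitter_frac, jitter_frac) * bw
    # enlarge per side, then force lesion containment and clamp to the image
    top -= enlarge_frac * bh
    bottom += enlarge_frac * bh
    left -= enlarge_frac * bw
    right += enlarge_frac * bw
    top = max(0, min(int(np.floor(top)), tb.top))
    left = max(0, min(int(np.floor(left)), tb.left))
    bottom = min(h - 1, max(int(np.ceil(bottom)), tb.bottom))
    right = min(w - 1, max(int(np.ceil(right)), tb.right))
    return BoundingBox(top, left, bottom, right)


def bbox_to_clicks(box: BoundingBox) -> ClickSet:
    """Convert a box to the five-click encoding: one foreground click at the
    centre, four background clicks at the corners."""
    cr = (box.top + box.bottom) // 2
    cc = (box.left + box.right) // 2
    fg = [Click(cr, cc, "foreground")]
    bg = [Click(box.top, box.left, "background"),
          Click(box.top, box.right, "background"),
          Click(box.bottom, box.left, "background"),
          Click(box.bottom, box.right, "background")]
    return ClickSet(foreground=fg, background=bg)


def one_click_input(mask: np.ndarray, rng_seed: int = 0) -> ClickSet:
    """One-click mode: a single foreground click uniform over the lesion,
    no background clicks."""
    mask = _check_mask(mask)
    rng = np.random.default_rng(rng_seed)
    fg = np.argwhere(mask)
    r, c = fg[rng.integers(len(fg))]
    return ClickSet(foreground=[Click(int(r), int(c), "foreground")], background=[])


def two_click_input(mask: np.ndarray, jitter_frac: float = 0.1,
                    enlarge_frac: float = 0.1, rng_seed: int = 0) -> ClickSet:
    """Two-click mode: a simulated bounding box converted to five clicks."""
    return bbox_to_clicks(simulate_bbox(mask, jitter_frac, enlarge_frac, rng_seed))
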