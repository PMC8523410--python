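"""Synthetic B-mode-like phantoms with ground-truth lesion masks.

Clinical liver ultrasound with expert lesion outlines is not publicly
redistributable, so every other part of the package is exercised on
speckled phantoms that emulate the statistical structure of such data:
four lesion classes (cyst, hemangioma, metastasis, hepatocellular
carcinoma) with class-specific size distributions and distinct
echogenicity / margin / heterogeneity phenotypes, on a speckled
background.

The four phenotypes follow standard sonographic descriptions:

* **cyst** — strongly hypoechoic interior, sharp margin;
* **hemangioma** — hyperechoic, well-defined margin;
* **metastasis** — hypoechoic, blurred irregular margin, peripheral halo;
* **hcc** — mildly hypoechoic with heterogeneous internal texture and an
  irregular, blurred margin.

Lesion outlines are ellipses with low-frequency radial perturbation;
the longest dimension is drawn from a truncated log-normal law
moment-matched to per-class mean/SD sizes in millimetres.  Speckle is
multiplicative, Rayleigh-amplitude noise smoothed by a small Gaussian
kernel — the canonical fully-developed-speckle approximation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.draw import polygon as draw_polygon

CLASS_NAMES: tuple[str, ...] = ("cyst", "hemangioma", "metastasis", "hcc")
BENIGN_CLASSES: frozenset[str] = frozenset({"cyst", "hemangioma"})

#: mean / SD of the longest lesion dimension per class, in mm
DEFAULT_SIZE_MEANS = {"cyst": 16.8, "hemangioma": 17.4, "metastasis": 26.2, "hcc": 23.3}
DEFAULT_SIZE_SDS = {"cyst": 14.9, "hemangioma": 14.5, "metastasis": 15.7, "hcc": 14.7}

#: smallest lesion generated (mm); sub-resolution lesions are not useful
MIN_LESION_MM = 4.0
#: largest lesion as a fraction of the image extent, so lesions fit the canvas
MAX_LESION_FRAC = 0.7


@dataclass(frozen=True)
class ClassPhenotype:
    """Rendering parameters for one lesion class."""

    contrast_offset: float      # interior intensity offset vs background
    margin_blur_sigma: float    # Gaussian sigma (px) softening the margin
    heterogeneity_amp: float    # amplitude of smooth interior texture
    irregularity: float         # radial perturbation amplitude of the outline
    halo_offset: float = 0.0    # intensity offset of a thin peri-lesional rim
    halo_width_px: float = 3.0


DEFAULT_PHENOTYPES = {
    "cyst": ClassPhenotype(-70.0, 0.6, 0.0, 0.03),
    "hemangioma": ClassPhenotype(45.0, 0.8, 4.0, 0.05),
    "metastasis": ClassPhenotype(-40.0, 2.5, 8.0, 0.12, halo_offset=-20.0),
    "hcc": ClassPhenotype(-15.0, 2.0, 22.0, 0.15),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for the phantom population.

    ``image_size`` is the square side in pixels; ``pixel_spacing`` maps
    pixels to millimetres so that the class size laws (in mm) land at a
    trainable pixel scale.
    """

    image_size: int = 256
    pixel_spacing: float = 0.5
    class_size_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIZE_MEANS))
    class_size_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIZE_SDS))
    background_echo: float = 120.0
    speckle_scale: float = 0.5
    phenotypes: dict[str, ClassPhenotype] = field(default_factory=lambda: dict(DEFAULT_PHENOTYPES))

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for cname in CLASS_NAMES:
            if self.class_size_means[cname] <= 0:
                raise ValueError(f"size mean for {cname!r} must be positive")

    @property
    def max_lesion_mm(self) -> float:
        return MAX_LESION_FRAC * self.image_size * self.pixel_spacing


@dataclass
class LesionRecord:
    """One phantom: image, reference mask, class label and lesion size."""

    image: np.ndarray           # (H, W) uint8
    mask: np.ndarray            # (H, W) bool
    label: str
    lesion_size_mm: float
    pixel_spacing: float

    def __post_init__(self):
        if self.label not in CLASS_NAMES:
            raise ValueError(f"unknown label {self.label!r}")
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def is_malignant(self) -> bool:
        return self.label not in BENIGN_CLASSES

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.image.tobytes())
        h.update(self.mask.tobytes())
        h.update(self.label.encode())
        return h.hexdigest()


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match (mu, sigma) of a log-normal to the given mean/SD."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def sample_lesion_size_mm(spec: PhantomSpec, label: str, rng: np.random.Generator) -> float:
    """Draw a longest-dimension size (mm) from the class law, truncated to
    [MIN_LESION_MM, spec.max_lesion_mm] by rejection."""
    lo, hi = MIN_LESION_MM, spec.max_lesion_mm
    if hi <= lo:
        raise ValueError(
            f"image of {spec.image_size}px at {spec.pixel_spacing}mm/px cannot "
            f"contain the minimum {lo}mm lesion"
        )
    sd = spec.class_size_sds[label]
    mean = spec.class_size_means[label]
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    mu, sigma = _lognormal_params(mean, sd)
    for _ in range(1000):
        s = float(rng.lognormal(mu, sigma))
        if lo <= s <= hi:
            return s
    return float(np.clip(mean, lo, hi))  # pathological parameters; fall back


def _lesion_polygon(size_px: float, irregularity: float,
                    rng: np.random.Generator, n_vertices: int = 180
                    ) -> np.ndarray:
    """Closed outline (n, 2) of a randomly deformed ellipse, centred at the
    origin, rescaled so its maximal diameter equals ``size_px``."""
    phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(phi)
    for k in range(2, 6):  # low-frequency harmonics only: lobulated, not spiky
        r += irregularity * (rng.normal() * np.cos(k * phi) + rng.normal() * np.sin(k * phi)) / np.sqrt(k)
    r = np.maximum(r, 0.2)
    aspect = rng.uniform(0.6, 1.0)
    theta = rng.uniform(0.0, np.pi)
    x = r * np.cos(phi) * 0.5
    y = r * np.sin(phi) * 0.5 * aspect
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    pts = np.stack([x, y], axis=1) @ rot.T
    d = _max_pairwise_distance(pts)
    return pts * (size_px / d)


def _max_pairwise_distance(pts: np.ndarray) -> float:
    """Maximal pairwise Euclidean distance (diameter) of a point set."""
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) sets
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def mask_longest_dimension_px(mask: np.ndarray) -> float:
    """Longest dimension of a binary mask, measured between pixel centers."""
    pts = np.argwhere(mask).astype(float)
    if len(pts) == 0:
        raise ValueError("mask is empty")
    if len(pts) == 1:
        return 0.0
    return _max_pairwise_distance(pts)


def generate_phantom(spec: PhantomSpec, label: str, rng_seed: int) -> LesionRecord:
    """Generate one phantom image/mask pair for the given lesion class.

    Deterministic for fixed ``(spec, label, rng_seed)``.
    """
    if label not in CLASS_NAMES:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, CLASS_NAMES.index(label)]))
    phen = spec.phenotypes[label]
    n = spec.image_size

    size_mm = sample_lesion_size_mm(spec, label, rng)
    size_px = size_mm / spec.pixel_spacing
    poly = _lesion_polygon(size_px, phen.irregularity, rng)

    # place the outline fully inside the canvas with a 2 px margin
    margin = 2.0
    rmin, cmin = poly.min(axis=0)
    rmax, cmax = poly.max(axis=0)
    lo_r, hi_r = margin - rmin, n - 1 - margin - rmax
    lo_c, hi_c = margin - cmin, n - 1 - margin - cmax
    if hi_r < lo_r or hi_c < lo_c:
        raise ValueError(
            f"image of {n}px too small to contain a {size_mm:.1f}mm lesion"
        )
    center = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
    poly = poly + center

    mask = np.zeros((n, n), dtype=bool)
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=(n, n))
    mask[rr, cc] = True
    if not mask.any():  # sub-pixel outline: keep at least the center pixel
        mask[int(round(center[0])), int(round(center[1]))] = True

    img = np.full((n, n), spec.background_echo, dtype=np.float64)
    soft = gaussian_filter(mask.astype(np.float64), phen.margin_blur_sigma)
    img += phen.contrast_offset * soft
    if phen.halo_offset != 0.0:
        dist_out = distance_transform_edt(~mask)
        ring = ((dist_out > 0) & (dist_out <= phen.halo_width_px)).astype(np.float64)
        img += phen.halo_offset * gaussian_filter(ring, 1.0)
    if phen.heterogeneity_amp > 0:
        tex = gaussian_filter(rng.normal(size=(n, n)), 3.0)
        tex /= max(tex.std(), 1e-9)
        img += phen.heterogeneity_amp * tex * soft

    speckle = gaussian_filter(rng.rayleigh(scale=1.0, size=(n, n)), 0.7)
    speckle /= speckle.mean()
    img *= 1.0 + spec.speckle_scale * (speckle - 1.0)

    image = np.clip(img, 0, 255).astype(np.uint8)
    actual_mm = mask_longest_dimension_px(mask) * spec.pixel_spacing
    return LesionRecord(image=image, mask=mask, label=label,
                        lesion_size_mm=actual_mm, pixel_spacing=spec.pixel_spacing)


def _record_seed(rng_seed: int, class_index: int, i: int) -> int:
    """Stable per-record child seed."""
    state = np.random.SeedSequence([rng_seed, class_index, i]).generate_state(1)[0]
    return int(state) % (2 ** 31)


def generate_dataset(spec: PhantomSpec, n_per_class: int, split_fraction: float,
                     rng_seed: int) -> tuple[list[LesionRecord], list[LesionRecord]]:
    """Generate a balanced labelled phantom collection and split it.

    The test set is stratified over lesion size within each class: records
    are ranked by mask area, cut into ``n_test`` equal-size groups, and one
    record is drawn at random from each group — so the test set spans the
    class's whole size range.  Deterministic for fixed seed.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 987654321]))
    train: list[LesionRecord] = []
    test: list[LesionRecord] = []
    n_test = int(round(n_per_class * split_fraction))
    n_test = max(1, min(n_test, n_per_class - 1))
    for ci, label in enumerate(CLASS_NAMES):
        records = [generate_phantom(spec, label, _record_seed(rng_seed, ci, i))
                   for i in range(n_per_class)]
        order = np.argsort([r.mask.sum() for r in records], kind="stable")
        groups = np.array_split(order, n_test)
        test_idx = {int(rng.choice(g)) for g in groups}
        for i, rec in enumerate(records):
            (test if i in test_idx else train).append(rec)
    return train, test


# ---------------------------------------------------------------------------
# On-disk layout: PNG images/masks, CSV labels, JSON manifest
# ---------------------------------------------------------------------------

def save_dataset(train: list[LesionRecord], test: list[LesionRecord],
                 out_dir: str | Path) -> Path:
    import imageio.v3 as iio

    out = Path(out_dir)
    rows = []
    for split, records in (("train", train), ("test", test)):
        d = out / split
        d.mkdir(parents=True, exist_ok=True)
        for i, rec in enumerate(records):
            stem = f"{split}_{i:05d}"
            iio.imwrite(d / f"{stem}_image.png", rec.image)
            iio.imwrite(d / f"{stem}_mask.png", (rec.mask * 255).astype(np.uint8))
            rows.append({"id": stem, "split": split, "label": rec.label,
                         "size_mm": round(rec.lesion_size_mm, 3),
                         "pixel_spacing": rec.pixel_spacing})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    manifest = {"n_train": len(train), "n_test": len(test),
                "classes": list(CLASS_NAMES), "layout": "PNG image/mask pairs + labels.csv"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_dataset(in_dir: str | Path) -> tuple[list[LesionRecord], list[LesionRecord]]:
    import imageio.v3 as iio

    root = Path(in_dir)
    table = pd.read_csv(root / "labels.csv")
    out: dict[str, list[LesionRecord]] = {"train": [], "test": []}
    for row in table.itertuples():
        d = root / row.split
        image = np.asarray(iio.imread(d / f"{row.id}_image.png"))
        mask = np.asarray(iio.imread(d / f"{row.id}_mask.png")) > 127
        out[row.split].append(LesionRecord(
            image=image, mask=mask, label=row.label,
            lesion_size_mm=float(row.size_mm), pixel_spacing=float(row.pixel_spacing)))
    return out["train"], out["test"]


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["phenotypes"] = {k: dataclasses.asdict(v) for k, v in spec.phenotypes.items()}
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    if "phenotypes" in d:
        d["phenotypes"] = {k: ClassPhenotype(**v) for k, v in d["phenotypes"].items()}
    return PhantomSpec(**d)
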