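"""Evaluation metrics and statistical procedures.

Covers the full protocol used to score the click-guided system: per-image
Jaccard index against the reference mask, multi-class confusion matrices
with per-class and overall accuracy, ROC curves with trapezoidal AUROC
(equal to the tie-corrected rank statistic), the Youden-index optimal
operating point, one-vs-rest multi-class ROC with macro averaging,
bootstrap confidence intervals, and a paired permutation test for
comparing two systems on the same test images.

``evaluate_system`` runs a trained network over a test set with five
simulated user inputs per image (one-click or two-click mode) and
assembles everything into an :class:`EvalReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .interaction import one_click_input, two_click_input, encode_input
from .model import predict_batch
from .phantom import CLASS_NAMES, LesionRecord

#: simulated user inputs per test image
N_USER_INPUTS = 5


# ---------------------------------------------------------------------------
# Segmentation metric
# ---------------------------------------------------------------------------

def jaccard(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B|.  Two empty masks count as 1."""
    pred_mask = np.asarray(pred_mask).astype(bool)
    ref_mask = np.asarray(ref_mask).astype(bool)
    if pred_mask.shape != ref_mask.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(pred_mask, ref_mask).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred_mask, ref_mask).sum() / union)


# ---------------------------------------------------------------------------
# Confusion matrix and accuracy
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    counts: np.ndarray            # (K, K) ints, rows = truth, cols = prediction
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def confusion(true_labels, predicted_labels, class_names) -> ConfusionMatrix:
    """counts[i, j] = number of samples with truth i predicted as j."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists differ in length")
    index = {c: i for i, c in enumerate(class_names)}
    k = len(class_names)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def accuracy_from_confusion(cm: ConfusionMatrix) -> tuple[float, np.ndarray]:
    """(overall %, per-class % vector).  Per-class = diagonal / row sum;
    a zero row yields NaN for that class."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_sums > 0,
                             np.diag(counts) / np.maximum(row_sums, 1) * 100.0,
                             np.nan)
    overall = float(np.trace(counts) / total * 100.0)
    return overall, per_class


def sensitivity_specificity_from_confusion(cm: ConfusionMatrix,
                                           positive: int = 1) -> tuple[float, float]:
    """Binary sensitivity/specificity (%) with class ``positive`` as positive."""
    c = cm.counts
    if c.shape != (2, 2):
        raise ValueError("binary confusion matrix required")
    neg = 1 - positive
    sens = c[positive, positive] / max(c[positive].sum(), 1) * 100.0
    spec = c[neg, neg] / max(c[neg].sum(), 1) * 100.0
    return float(sens), float(spec)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray       # TPR, aligned with thresholds
    one_minus_specificity: np.ndarray  # FPR
    auroc: float


def roc(scores, labels) -> ROCCurve:
    """ROC curve swept over all distinct score thresholds, AUROC by the
    trapezoidal rule (equal to the tie-corrected Mann-Whitney statistic
    U / (n+ * n-))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # keep the last point of each tied-score run
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, sensitivity=tpr,
                    one_minus_specificity=fpr, auroc=auroc)


def youden_optimum(curve: ROCCurve) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, threshold) maximizing Youden's
    J = sens + spec - 1; ties broken toward higher sensitivity."""
    j = curve.sensitivity - curve.one_minus_specificity
    best = np.flatnonzero(j == j.max())
    i = best[np.argmax(curve.sensitivity[best])]
    sens = float(curve.sensitivity[i] * 100.0)
    spec = float((1.0 - curve.one_minus_specificity[i]) * 100.0)
    return sens, spec, float(curve.thresholds[i])


def multiclass_roc(cls_probs: np.ndarray, true_labels,
                   class_names=CLASS_NAMES) -> tuple[dict[str, ROCCurve], float]:
    """One-vs-rest ROC per class plus the unweighted macro-average AUROC.
    Classes absent from the truth are skipped with a warning."""
    import warnings

    cls_probs = np.asarray(cls_probs, dtype=float)
    true_idx = np.asarray([class_names.index(t) if isinstance(t, str) else int(t)
                           for t in true_labels])
    curves: dict[str, ROCCurve] = {}
    for k, name in enumerate(class_names):
        y = (true_idx == k).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            warnings.warn(f"class {name!r} absent from truth; skipped")
            continue
        curves[name] = roc(cls_probs[:, k], y)
    if not curves:
        raise ValueError("no class with both positives and negatives")
    macro = float(np.mean([c.auroc for c in curves.values()]))
    return curves, macro


def auroc_bootstrap_ci(scores, labels, n_resamples: int = 2000,
                       seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUROC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    vals = []
    n = len(scores)
    for _ in range(n_resamples):
        idx = rng.integers(0, n, n)
        y = labels[idx]
        if y.min() == y.max():
            continue
        vals.append(roc(scores[idx], y).auroc)
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Paired comparison
# ---------------------------------------------------------------------------

def compare_paired(samples_a, samples_b, n_resamples: int = 2000,
                   seed: int = 0) -> float:
    """Two-sided paired permutation (sign-flip) p-value for the mean
    difference.  Exhaustive over all 2^n sign patterns when feasible,
    Monte Carlo otherwise; includes the identity permutation so p > 0."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    obs = abs(d.mean())
    n = len(d)
    if 2 ** n <= n_resamples:
        signs = np.array(list(product([1.0, -1.0], repeat=n)))
        stats = np.abs((signs * d).mean(axis=1))
        return float((stats >= obs - 1e-12).mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_resamples, n))
    stats = np.abs((signs * d).mean(axis=1))
    hits = int((stats >= obs - 1e-12).sum())
    return float((hits + 1) / (n_resamples + 1))


# ---------------------------------------------------------------------------
# Whole-system evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Everything measured on one (network, test set, input mode) run."""

    input_mode: str
    class_names: list[str]
    ji_values: list[float]                  # one per (record, user input)
    confusion_matrix: ConfusionMatrix | None
    overall_accuracy: float | None
    per_class_accuracy: list[float] | None
    binary_auroc: float | None              # benign vs malignant
    binary_sensitivity: float | None        # at the Youden optimum, %
    binary_specificity: float | None
    macro_auroc: float | None               # one-vs-rest average (4-class)
    per_class_auroc: dict[str, float] = field(default_factory=dict)

    @property
    def mean_ji(self) -> float:
        return float(np.mean(self.ji_values)) if self.ji_values else float("nan")

    @property
    def sd_ji(self) -> float:
        return float(np.std(self.ji_values, ddof=1)) if len(self.ji_values) > 1 else 0.0

    def to_json_dict(self) -> dict:
        return {
            "input_mode": self.input_mode,
            "class_names": self.class_names,
            "ji_values": list(self.ji_values),
            "mean_ji": None if not self.ji_values else self.mean_ji,
            "confusion_counts": (None if self.confusion_matrix is None
                                 else self.confusion_matrix.counts.tolist()),
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "binary_auroc": self.binary_auroc,
            "binary_sensitivity": self.binary_sensitivity,
            "binary_specificity": self.binary_specificity,
            "macro_auroc": self.macro_auroc,
            "per_class_auroc": self.per_class_auroc,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    @classmethod
    def from_json_dict(cls, d: dict) -> "EvalReport":
        cm = None
        if d.get("confusion_counts") is not None:
            cm = ConfusionMatrix(np.asarray(d["confusion_counts"]), d["class_names"])
        return cls(input_mode=d["input_mode"], class_names=d["class_names"],
                   ji_values=list(d["ji_values"]), confusion_matrix=cm,
                   overall_accuracy=d["overall_accuracy"],
                   per_class_accuracy=d["per_class_accuracy"],
                   binary_auroc=d["binary_auroc"],
                   binary_sensitivity=d["binary_sensitivity"],
                   binary_specificity=d["binary_specificity"],
                   macro_auroc=d["macro_auroc"],
                   per_class_auroc=dict(d.get("per_class_auroc", {})))

    @classmethod
    def load_json(cls, path: str | Path) -> "EvalReport":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def user_input_seed(image_index: int, input_index: int) -> int:
    """Seeds {0..4} offset by image index, one per simulated user input."""
    return (image_index * 1000 + input_index) % (2 ** 31)


def benign_malignant_score(cls_prob: np.ndarray, class_names=CLASS_NAMES) -> float:
    """Malignancy score from a 4-class probability vector:
    P(metastasis) + P(hcc).  For a 2-class model, P(class 1)."""
    if len(cls_prob) == 2:
        return float(cls_prob[1])
    return float(cls_prob[class_names.index("metastasis")]
                 + cls_prob[class_names.index("hcc")])


def evaluate_system(net, test_records: list[LesionRecord],
                    input_mode: str = "two_click",
                    n_user_inputs: int = N_USER_INPUTS,
                    seeds: list[int] | None = None) -> EvalReport:
    """Run a trained network over a test set with simulated user inputs.

    For each record and each of ``n_user_inputs`` seeded user inputs the
    network predicts once; Jaccard indices are collected per (record,
    input), class predictions by probability argmax, and ROC scores from
    the class probabilities.  Deterministic for fixed seeds.
    """
    if input_mode not in ("one_click", "two_click"):
        raise ValueError("input_mode must be 'one_click' or 'two_click'")
    if not test_records:
        raise ValueError("empty test set")
    variant = net.config.variant
    n_classes = net.config.n_classes
    names = (list(CLASS_NAMES) if n_classes == 4 else ["benign", "malignant"])

    ji_values: list[float] = []
    true_names: list[str] = []
    pred_names: list[str] = []
    probs: list[np.ndarray] = []
    mal_scores: list[float] = []
    mal_truth: list[int] = []

    for i, rec in enumerate(test_records):
        batch = []
        for j in range(n_user_inputs):
            seed = seeds[i * n_user_inputs + j] if seeds else user_input_seed(i, j)
            cs = (one_click_input(rec.mask, seed) if input_mode == "one_click"
                  else two_click_input(rec.mask, rng_seed=seed))
            batch.append(encode_input(rec.image, cs))
        preds = predict_batch(net, np.stack(batch))
        tname = (rec.label if n_classes == 4
                 else ("malignant" if rec.is_malignant else "benign"))
        for pr in preds:
            if pr.seg_prob is not None:
                ji_values.append(jaccard(pr.seg_mask, rec.mask))
            if pr.cls_prob is not None:
                true_names.append(tname)
                pred_names.append(names[pr.predicted_class])
                probs.append(pr.cls_prob)
                mal_scores.append(benign_malignant_score(pr.cls_prob, CLASS_NAMES))
                mal_truth.append(int(rec.is_malignant))

    cm = overall = per_class = None
    binary_auroc = sens = spec = macro = None
    per_class_auroc: dict[str, float] = {}
    if probs:
        cm = confusion(true_names, pred_names, names)
        overall, per_class_arr = accuracy_from_confusion(cm)
        per_class = [float(v) for v in per_class_arr]
        if len(set(mal_truth)) == 2:
            bcurve = roc(mal_scores, mal_truth)
            binary_auroc = bcurve.auroc
            sens, spec, _ = youden_optimum(bcurve)
        if n_classes == 4 and len(set(true_names)) >= 2:
            curves, macro = multiclass_roc(np.stack(probs), true_names, list(CLASS_NAMES))
            per_class_auroc = {k: c.auroc for k, c in curves.items()}

    return EvalReport(input_mode=input_mode, class_names=names,
                      ji_values=ji_values, confusion_matrix=cm,
                      overall_accuracy=overall, per_class_accuracy=per_class,
                      binary_auroc=binary_auroc, binary_sensitivity=sens,
                      binary_specificity=spec, macro_auroc=macro,
                      per_class_auroc=per_class_auroc)
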