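"""Metrics: Jaccard, confusion/accuracy, ROC/AUROC, Youden, paired test."""

from itertools import product

import numpy as np
import pytest

import usjoint as uj
from usjoint.evaluation import (
    ConfusionMatrix, benign_malignant_score, sensitivity_specificity_from_confusion,
)

# Published four-class confusion matrix of the joint clinical system
# (rows: truth cyst/hemangioma/metastasis/HCC; 500 test predictions per row).
PUBLISHED_CONFUSION = np.array([
    [472, 15, 5, 8],
    [1, 413, 46, 40],
    [0, 46, 423, 31],
    [0, 37, 127, 336],
])


class TestJaccard:
    def test_identical_masks(self):
        m = np.random.default_rng(0).random((8, 8)) > 0.5
        assert uj.jaccard(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert uj.jaccard(a, b) == 0.0

    def test_shifted_block_value(self):
        """2x2 block vs same block shifted one column: overlap 2, union 6."""
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[1:3, 1:3] = True
        b[1:3, 2:4] = True
        assert uj.jaccard(a, b) == pytest.approx(1 / 3)

    def test_symmetry_and_flip_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.random((6, 6)) > 0.6
            b = rng.random((6, 6)) > 0.6
            assert uj.jaccard(a, b) == uj.jaccard(b, a)
            assert uj.jaccard(a, b) == uj.jaccard(a[:, ::-1], b[:, ::-1])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            uj.jaccard(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        labels = ["a", "b", "a", "c"]
        cm = uj.confusion(labels, labels, ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_empty_input_zero_matrix(self):
        cm = uj.confusion([], [], ["a", "b"])
        assert np.array_equal(cm.counts, np.zeros((2, 2), int))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            uj.confusion(["a"], ["z"], ["a", "b"])

    def test_published_confusion_reconstruction_row_sums(self):
        """A label list built from the published counts reproduces the
        matrix; every truth row sums to its 500 test predictions."""
        names = list(uj.CLASS_NAMES)
        truths, preds = [], []
        for i, row in enumerate(PUBLISHED_CONFUSION):
            for j, n in enumerate(row):
                truths += [names[i]] * n
                preds += [names[j]] * n
        cm = uj.confusion(truths, preds, names)
        assert np.array_equal(cm.counts, PUBLISHED_CONFUSION)
        assert np.array_equal(cm.counts.sum(axis=1), [500] * 4)

    def test_matches_sklearn(self):
        from sklearn.metrics import confusion_matrix as sk_cm

        rng = np.random.default_rng(5)
        names = ["w", "x", "y"]
        t = rng.choice(names, 60)
        p = rng.choice(names, 60)
        cm = uj.confusion(t, p, names)
        assert np.array_equal(cm.counts, sk_cm(t, p, labels=names))


class TestAccuracyFromConfusion:
    def test_published_per_class_and_overall(self):
        cm = ConfusionMatrix(PUBLISHED_CONFUSION, list(uj.CLASS_NAMES))
        overall, per_class = uj.accuracy_from_confusion(cm)
        assert per_class == pytest.approx([94.4, 82.6, 84.6, 67.2])
        assert overall == pytest.approx(82.2)

    def test_identity_predictions(self):
        cm = ConfusionMatrix(np.diag([5, 5, 5, 5]), list(uj.CLASS_NAMES))
        overall, per_class = uj.accuracy_from_confusion(cm)
        assert overall == 100.0
        assert per_class == pytest.approx([100.0] * 4)

    def test_zero_row_reported_missing(self):
        cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]), ["a", "b"])
        overall, per_class = uj.accuracy_from_confusion(cm)
        assert np.isnan(per_class[1]) and per_class[0] == 100.0


def auroc_pair_counting(scores, labels):
    """Oracle: (concordant + ties/2) / (n_pos * n_neg)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    num = 0.0
    for sp in pos:
        for sn in neg:
            num += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return num / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        curve = uj.roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auroc == pytest.approx(1.0)

    def test_uninformative_all_equal(self):
        curve = uj.roc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert curve.auroc == pytest.approx(0.5)

    def test_endpoints_and_monotone(self):
        rng = np.random.default_rng(2)
        labels = np.r_[np.ones(5, int), rng.integers(0, 2, 20), np.zeros(5, int)]
        curve = uj.roc(rng.random(30), labels)
        assert curve.sensitivity[0] == 0.0 and curve.one_minus_specificity[0] == 0.0
        assert curve.sensitivity[-1] == 1.0 and curve.one_minus_specificity[-1] == 1.0
        assert (np.diff(curve.sensitivity) >= 0).all()
        assert (np.diff(curve.one_minus_specificity) >= 0).all()

    def test_toy_set_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        assert uj.roc(scores, labels).auroc == pytest.approx(
            auroc_pair_counting(scores, labels), abs=1e-10)

    def test_random_instances_match_pair_counting(self):
        """Trapezoid AUROC equals the tie-corrected rank statistic on 100
        random instances, with ties forced into the score sets."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # coarse grid -> ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            got = uj.roc(scores, labels).auroc
            assert got == pytest.approx(auroc_pair_counting(scores, labels), abs=1e-10)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = np.round(rng.random(50), 1)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert uj.roc(scores, labels).auroc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            uj.roc([0.1, 0.2], [1, 1])


class TestYouden:
    def test_perfect_separator(self):
        sens, spec, _ = uj.youden_optimum(uj.roc([0.9, 0.8, 0.2], [1, 1, 0]))
        assert (sens, spec) == (100.0, 100.0)

    def test_all_equal_scores_trivial_j(self):
        curve = uj.roc([0.5] * 4, [1, 0, 1, 0])
        sens, spec, _ = uj.youden_optimum(curve)
        assert sens + spec - 100.0 == pytest.approx(0.0)

    def test_matches_exhaustive_search(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.45, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        curve = uj.roc(scores, labels)
        sens, spec, thr = uj.youden_optimum(curve)
        best = -1.0
        for t in np.unique(scores):
            s = (scores[labels == 1] >= t).mean()
            sp = (scores[labels == 0] < t).mean()
            best = max(best, s + sp - 1.0)
        assert (sens + spec) / 100.0 - 1.0 == pytest.approx(best, abs=1e-10)


class TestMulticlassROC:
    def test_perfect_one_hot(self):
        probs = np.eye(4)[[0, 1, 2, 3, 0, 1, 2, 3]]
        truth = [uj.CLASS_NAMES[i] for i in [0, 1, 2, 3, 0, 1, 2, 3]]
        curves, macro = uj.multiclass_roc(probs, truth)
        assert macro == pytest.approx(1.0)
        assert all(c.auroc == pytest.approx(1.0) for c in curves.values())

    def test_macro_is_mean_and_reduction_to_binary(self):
        rng = np.random.default_rng(9)
        probs = rng.dirichlet(np.ones(4), size=8)
        truth_idx = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        truth = [uj.CLASS_NAMES[i] for i in truth_idx]
        curves, macro = uj.multiclass_roc(probs, truth)
        assert macro == pytest.approx(np.mean([c.auroc for c in curves.values()]))
        for k, name in enumerate(uj.CLASS_NAMES):
            want = uj.roc(probs[:, k], (truth_idx == k).astype(int)).auroc
            assert curves[name].auroc == pytest.approx(want, abs=1e-12)

    def test_absent_class_skipped_with_warning(self):
        probs = np.eye(4)[[0, 1, 0, 1]]
        truth = ["cyst", "hemangioma", "cyst", "hemangioma"]
        with pytest.warns(UserWarning):
            curves, _ = uj.multiclass_roc(probs, truth)
        assert set(curves) == {"cyst", "hemangioma"}


class TestComparePaired:
    def test_identical_samples_p_near_one(self):
        a = np.random.default_rng(0).random(12)
        assert uj.compare_paired(a, a, 2000, 0) >= 0.9

    def test_large_gap_small_p(self):
        a = np.zeros(12)
        b = np.ones(12) * 5
        assert uj.compare_paired(a, b, 2000, 0) <= 1 / 2000 + 1e-3

    def test_matches_exhaustive_enumeration(self):
        """For n <= 10 the p-value equals brute-force enumeration of all
        sign flips of the paired differences."""
        rng = np.random.default_rng(4)
        a = rng.normal(0.2, 1.0, 7)
        b = rng.normal(0.0, 1.0, 7)
        d = a - b
        obs = abs(d.mean())
        count = sum(abs((np.array(s) * d).mean()) >= obs - 1e-12
                    for s in product([1, -1], repeat=7))
        assert uj.compare_paired(a, b, 5000, 0) == pytest.approx(count / 2 ** 7)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            uj.compare_paired([1.0], [1.0, 2.0])


class TestHelpers:
    def test_benign_malignant_score(self):
        p4 = np.array([0.1, 0.2, 0.3, 0.4])
        assert benign_malignant_score(p4) == pytest.approx(0.7)
        assert benign_malignant_score(np.array([0.2, 0.8])) == pytest.approx(0.8)

    def test_sensitivity_specificity(self):
        cm = ConfusionMatrix(np.array([[90, 10], [20, 80]]), ["benign", "malignant"])
        sens, spec = sensitivity_specificity_from_confusion(cm)
        assert sens == pytest.approx(80.0) and spec == pytest.approx(90.0)


class TestEvaluateSystem:
    def test_report_shape_and_determinism(self, eight_records, tiny_net_config):
        net = uj.build_network(tiny_net_config, 0)
        rep1 = uj.evaluate_system(net, eight_records, "one_click")
        rep2 = uj.evaluate_system(net, eight_records, "one_click")
        assert len(rep1.ji_values) == 5 * len(eight_records)
        assert rep1.to_json_dict() == rep2.to_json_dict()
        assert rep1.confusion_matrix.counts.sum() == 5 * len(eight_records)

    def test_two_click_mode_runs(self, eight_records, tiny_net_config):
        net = uj.build_network(tiny_net_config, 0)
        rep = uj.evaluate_system(net, eight_records, "two_click", n_user_inputs=2)
        assert len(rep.ji_values) == 2 * len(eight_records)
        assert 0.0 <= rep.mean_ji <= 1.0
        assert rep.macro_auroc is not None

    def test_invalid_mode_and_empty_set(self, eight_records, tiny_net_config):
        net = uj.build_network(tiny_net_config, 0)
        with pytest.raises(ValueError):
            uj.evaluate_system(net, eight_records, "scribble")
        with pytest.raises(ValueError):
            uj.evaluate_system(net, [], "one_click")

    def test_report_json_roundtrip(self, tmp_path, eight_records, tiny_net_config):
        net = uj.build_network(tiny_net_config, 0)
        rep = uj.evaluate_system(net, eight_records, "two_click", n_user_inputs=1)
        rep.save_json(tmp_path / "rep.json")
        rep2 = uj.EvalReport.load_json(tmp_path / "rep.json")
        assert rep2.to_json_dict() == rep.to_json_dict()
        assert rep2.mean_ji == pytest.approx(rep.mean_ji)


def test_auroc_bootstrap_ci_brackets_point_estimate():
    rng = np.random.default_rng(1)
    scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 40)]
    labels = np.r_[np.ones(40, int), np.zeros(40, int)]
    auroc = uj.roc(scores, labels).auroc
    lo, hi = uj.auroc_bootstrap_ci(scores, labels, n_resamples=500, seed=0)
    assert lo <= auroc <= hi
    assert 0.0 <= lo < hi <= 1.0
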