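from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sleepstager.evaluation import (
    ConfusionMatrix,
    class_metrics,
    confidence_summary,
    confusion_matrix,
    cross_resolution_confusion,
)
from sleepstager.io_edf import Hypnogram, STAGES


def _hyp(stages, epoch_length_s=10.0):
    return Hypnogram("s", epoch_length_s, np.array(list(stages), dtype="U1"))


class TestConfusionMatrix:
    def test_identity_is_diagonal(self, random_hypnogram):
        h = random_hypnogram(100)
        cm = confusion_matrix(h, h)
        assert np.trace(cm.matrix) == 100
        assert cm.total_mass == 100

    def test_manual_tally(self):
        cm = confusion_matrix(_hyp("WPSW"), _hyp("PPSW"))
        # reference P predicted W is the only disagreement
        expected = np.zeros((3, 3))
        expected[0, 0] = 1  # one P correctly predicted
        expected[0, 2] = 1  # one P predicted W
        expected[1, 1] = 1
        expected[2, 2] = 1
        np.testing.assert_array_equal(cm.matrix, expected)

    def test_artifact_epochs_masked(self, rng):
        stages = np.array(["W"] * 100, dtype="U1")
        stages[rng.choice(100, 10, replace=False)] = "X"
        cm = confusion_matrix(_hyp("W" * 100), Hypnogram("s", 10.0, stages))
        assert cm.total_mass == 90

    def test_row_sums_equal_supports(self, random_hypnogram):
        pred, ref = random_hypnogram(500), random_hypnogram(500)
        cm = confusion_matrix(pred, ref)
        for i, s in enumerate(STAGES):
            assert cm.support[i] == np.sum(ref.stages == s)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion_matrix(_hyp("WW"), _hyp("WWW"))

    def test_artifact_in_predictions_rejected(self):
        with pytest.raises(ValueError, match="artifact"):
            confusion_matrix(_hyp("WX"), _hyp("WW"))


class TestClassMetrics:
    def test_perfect_diagonal(self):
        rep = class_metrics(ConfusionMatrix(np.diag([5, 7, 9])))
        assert all(v == 1.0 for v in rep.f1.values())
        assert rep.macro_f1 == 1.0

    def test_worked_example(self):
        """Rows (ref P,S,W) = [[8,2,0],[1,9,0],[0,0,10]]: metrics follow the
        per-class precision/recall/F1 equations evaluated with exact
        fractions as the independent oracle."""
        cm = ConfusionMatrix(np.array([[8, 2, 0], [1, 9, 0], [0, 0, 10]], float))
        rep = class_metrics(cm)
        assert rep.precision["P"] == pytest.approx(8 / 9)
        assert rep.recall["P"] == pytest.approx(0.8)
        f1 = {}
        for c, (tp, fp, fn) in {"P": (8, 1, 2), "S": (9, 2, 1), "W": (10, 0, 0)}.items():
            p = Fraction(tp, tp + fp)
            r = Fraction(tp, tp + fn)
            f1[c] = 2 * p * r / (p + r)
            assert rep.f1[c] == pytest.approx(float(f1[c]), abs=1e-12)
        macro = float(sum(f1.values()) / 3)
        assert rep.f1["P"] == pytest.approx(0.842105, abs=1e-6)
        assert rep.macro_f1 == pytest.approx(macro, abs=1e-12)
        assert rep.macro_f1 == pytest.approx(0.899749, abs=1e-6)

    def test_zero_support_class_flagged_and_macro_over_three(self):
        cm = ConfusionMatrix(np.array([[0, 0, 0], [0, 10, 0], [0, 0, 10]], float))
        rep = class_metrics(cm)
        assert rep.f1["P"] == 0.0
        assert any("P" in u for u in rep.undefined_metrics)
        assert rep.macro_f1 == pytest.approx(2 / 3)

    def test_agrees_with_sklearn_on_random_pairs(self, rng):
        """Independent oracle: scikit-learn's per-class P/R/F1 on raw labels."""
        from sklearn.metrics import precision_recall_fscore_support

        for _ in range(200):
            n = int(rng.integers(10, 200))
            pred = rng.integers(0, 3, n)
            ref = rng.integers(0, 3, n)
            sym = np.array(list("PSW"))
            cm = confusion_matrix(_hyp(sym[pred]), _hyp(sym[ref]))
            rep = class_metrics(cm)
            p, r, f, _ = precision_recall_fscore_support(
                ref, pred, labels=[0, 1, 2], zero_division=0)
            for i, c in enumerate(STAGES):
                assert abs(rep.precision[c] - p[i]) < 1e-12
                assert abs(rep.recall[c] - r[i]) < 1e-12
                assert abs(rep.f1[c] - f[i]) < 1e-12
            assert abs(rep.macro_f1 - f.mean()) < 1e-12

    def test_macro_f1_invariant_under_label_permutation(self, rng):
        sym = np.array(list("PSW"))
        pred, ref = rng.integers(0, 3, 300), rng.integers(0, 3, 300)
        base = class_metrics(confusion_matrix(_hyp(sym[pred]), _hyp(sym[ref])))
        perm = np.array([2, 0, 1])
        permuted = class_metrics(
            confusion_matrix(_hyp(sym[perm[pred]]), _hyp(sym[perm[ref]])))
        assert base.macro_f1 == pytest.approx(permuted.macro_f1, abs=1e-12)


class TestCrossResolution:
    def test_uniform_block(self):
        cm = cross_resolution_confusion(_hyp("WW"), _hyp("WWWWW", 4.0))
        assert cm.matrix[2, 2] == 5.0
        assert cm.total_mass == 5.0

    def test_worked_20s_block(self):
        """Predictions (P,S) vs refs (P,P,P,S,S): the straddling reference
        epoch [8 s, 12 s) splits 0.5/0.5 -> accuracy mass 4.5 of 5."""
        cm = cross_resolution_confusion(_hyp("PS"), _hyp("PPPSS", 4.0))
        assert cm.matrix[0, 0] == 2.5   # (ref P, pred P): 2 + straddler half
        assert cm.matrix[0, 1] == 0.5   # (ref P, pred S): straddler half
        assert cm.matrix[1, 1] == 2.0
        assert cm.total_mass == 5.0
        assert np.trace(cm.matrix) / cm.total_mass == pytest.approx(4.5 / 5)

    def test_24h_recording_mass(self, rng):
        n_pred, n_ref = 8640, 21600
        sym = np.array(list("PSW"))
        pred = _hyp(sym[rng.integers(0, 3, n_pred)])
        ref = _hyp(sym[rng.integers(0, 3, n_ref)], 4.0)
        assert cross_resolution_confusion(pred, ref).total_mass == n_ref

    def test_mass_conservation_random(self, rng):
        sym = np.array(list("PSW"))
        for _ in range(20):
            n_pred = int(rng.integers(1, 40)) * 2  # whole 20 s blocks
            n_ref = n_pred * 5 // 2
            cm = cross_resolution_confusion(
                _hyp(sym[rng.integers(0, 3, n_pred)]),
                _hyp(sym[rng.integers(0, 3, n_ref)], 4.0))
            assert cm.total_mass == pytest.approx(n_ref)

    def test_masked_reference_artifacts_reduce_mass(self):
        cm = cross_resolution_confusion(_hyp("PS"), _hyp("PPXSS", 4.0))
        assert cm.total_mass == pytest.approx(4.0)

    def test_aligned_limit_equals_plain_accuracy(self, rng):
        """When the two 10 s predictions of every 20 s block agree, the
        fractional procedure reduces to plain 4 s-vs-4 s accuracy after
        broadcasting the prediction."""
        sym = np.array(list("PSW"))
        blocks = rng.integers(0, 3, 30)
        pred_idx = np.repeat(blocks, 2)          # 60 pred epochs, block-constant
        ref_idx = rng.integers(0, 3, 150)
        cm = cross_resolution_confusion(_hyp(sym[pred_idx]), _hyp(sym[ref_idx], 4.0))
        broadcast = np.repeat(blocks, 5)         # one block covers five 4 s epochs
        plain_acc = np.mean(broadcast == ref_idx)
        assert cm.accuracy == pytest.approx(plain_acc, abs=1e-12)

    def test_span_mismatch_rejected(self):
        with pytest.raises(ValueError, match="span mismatch"):
            cross_resolution_confusion(_hyp("PS"), _hyp("PPP", 4.0))

    def test_wrong_epoch_lengths_rejected(self):
        with pytest.raises(ValueError, match="expected 10 s"):
            cross_resolution_confusion(_hyp("PS", 4.0), _hyp("PPPSS", 4.0))


class TestConfidenceSummary:
    def test_certain_predictions(self):
        out = confidence_summary(np.tile([1.0, 0.0, 0.0], (5, 1)))
        assert out["mean_confidence"] == 1.0

    def test_mixed_set_is_arithmetic_mean(self):
        probs = np.array([[0.34, 0.33, 0.33], [0.5, 0.25, 0.25], [0.2, 0.2, 0.6]])
        out = confidence_summary(probs)
        assert out["mean_confidence"] == pytest.approx((0.34 + 0.5 + 0.6) / 3)
        assert out["min_confidence"] == pytest.approx(0.34)
        assert out["min_confidence"] > 1 / 3

    def test_per_recording_table(self):
        out = confidence_summary({"a": np.array([[0.5, 0.3, 0.2]]),
                                  "b": np.array([[0.9, 0.05, 0.05]])})
        assert set(out["per_recording"]["recording"]) == {"a", "b"}
        assert out["mean_confidence"] == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confidence_summary(np.zeros((0, 3)))


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_metrics_equal_brute_force_tally(seed):
    """class_metrics from the confusion matrix equals a brute-force
    per-class tally over raw (pred, ref) pairs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 300))
    sym = np.array(list("PSW"))
    pred, ref = sym[rng.integers(0, 3, n)], sym[rng.integers(0, 3, n)]
    rep = class_metrics(confusion_matrix(_hyp(pred), _hyp(ref)))
    for c in STAGES:
        tp = np.sum((pred == c) & (ref == c))
        fp = np.sum((pred == c) & (ref != c))
        fn = np.sum((pred != c) & (ref == c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert abs(rep.precision[c] - prec) < 1e-12
        assert abs(rep.recall[c] - rec) < 1e-12
        assert abs(rep.f1[c] - f1) < 1e-12
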