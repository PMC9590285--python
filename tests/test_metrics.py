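"""Metric formulas against independent counting/rank-statistic oracles."""

import numpy as np
import pytest

from ecgconvit.metrics import (DEFAULT_CLASSES, confusion, evaluate, metrics,
                               roc_auc)


def loop_confusion_oracle(t, p, classes):
    """Independent tally-by-loop confusion and one-vs-rest counts."""
    m = {(a, b): 0 for a in classes for b in classes}
    for ti, pi in zip(t, p):
        m[(ti, pi)] += 1
    ovr = {}
    for c in classes:
        tp = m[(c, c)]
        fn = sum(m[(c, b)] for b in classes if b != c)
        fp = sum(m[(a, c)] for a in classes if a != c)
        tn = len(t) - tp - fn - fp
        ovr[c] = (tp, tn, fp, fn)
    return m, ovr


def formula_oracle(tp, tn, fp, fn):
    """Direct evaluation of the six definitions, written independently."""
    def div(a, b):
        return a / b if b else 0.0
    acc = div(tp + tn, tp + tn + fp + fn)
    sen = div(tp, tp + fn)
    spe = div(tn, tn + fp)
    ppv = div(tp, tp + fp)
    f1 = div(2 * ppv * sen, ppv + sen)
    den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = div(tp * tn - fp * fn, den)
    return acc, sen, spe, ppv, f1, mcc


class TestConfusion:
    def test_perfect_predictions_give_diagonal(self, rng):
        t = rng.choice(list(DEFAULT_CLASSES), size=50)
        counts = confusion(t, t)
        assert counts.matrix.sum() == 50
        assert np.array_equal(counts.matrix, np.diag(np.diag(counts.matrix)))
        for c in DEFAULT_CLASSES:
            ovr = counts.one_vs_rest(c)
            assert ovr["FP"] == 0 and ovr["FN"] == 0

    def test_single_cell_case(self):
        counts = confusion(["N"] * 10, ["V"] * 10)
        assert counts.matrix[1, 4] == 10 and counts.matrix.sum() == 10
        v = counts.one_vs_rest("V")
        assert v["TP"] == 0 and v["FP"] == 10

    def test_matches_loop_oracle_on_random_case(self, rng):
        t = rng.choice(list(DEFAULT_CLASSES), size=100)
        p = rng.choice(list(DEFAULT_CLASSES), size=100)
        counts = confusion(t, p)
        m, ovr = loop_confusion_oracle(t, p, DEFAULT_CLASSES)
        for i, a in enumerate(DEFAULT_CLASSES):
            for j, b in enumerate(DEFAULT_CLASSES):
                assert counts.matrix[i, j] == m[(a, b)]
            got = counts.one_vs_rest(a)
            assert (got["TP"], got["TN"], got["FP"], got["FN"]) == ovr[a]

    def test_length_mismatch_and_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["N"], ["N", "V"])
        with pytest.raises(ValueError):
            confusion(["N"], ["X"])


class TestMetrics:
    def test_perfect_classifier_closed_form(self, rng):
        t = rng.choice(list(DEFAULT_CLASSES), size=40)
        report = evaluate(t, t)
        assert report.overall_accuracy == 1.0
        for c in np.unique(t):
            row = report.per_class.loc[c]
            assert (row == 1.0).all()

    def test_symmetric_chance_closed_form(self):
        # TP=TN=FP=FN=25 via a crafted binary-like case on classes N/V
        t = ["N"] * 50 + ["V"] * 50
        p = ["N"] * 25 + ["V"] * 25 + ["N"] * 25 + ["V"] * 25
        report = evaluate(t, p, classes=("N", "V"))
        row = report.per_class.loc["N"]
        assert row["Acc"] == row["Sen"] == row["Spe"] == row["Ppv"] == 0.5
        assert row["MCC"] == 0.0

    def test_matches_formula_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            t = rng.choice(list(DEFAULT_CLASSES), size=60)
            p = rng.choice(list(DEFAULT_CLASSES), size=60)
            counts = confusion(t, p)
            report = metrics(counts)
            for c in DEFAULT_CLASSES:
                ovr = counts.one_vs_rest(c)
                want = formula_oracle(ovr["TP"], ovr["TN"], ovr["FP"], ovr["FN"])
                got = report.per_class.loc[c, ["Acc", "Sen", "Spe", "Ppv",
                                               "F1", "MCC"]].to_numpy()
                assert np.abs(got - np.array(want)).max() <= 1e-12

    def test_overall_accuracy_is_trace_over_total(self, rng):
        t = rng.choice(list(DEFAULT_CLASSES), size=80)
        p = rng.choice(list(DEFAULT_CLASSES), size=80)
        report = evaluate(t, p)
        assert np.isclose(report.overall_accuracy, float((t == p).mean()))

    def test_paper_literal_f1_is_half_standard(self, rng):
        t = rng.choice(list(DEFAULT_CLASSES), size=60)
        p = rng.choice(list(DEFAULT_CLASSES), size=60)
        counts = confusion(t, p)
        std = metrics(counts, "standard").per_class["F1"]
        lit = metrics(counts, "paper_literal").per_class["F1"]
        assert np.allclose(lit, std / 2)

    def test_degenerate_cells_flagged_not_nan(self):
        # class F never occurs and is never predicted: Sen/Ppv undefined
        report = evaluate(["N"] * 5, ["N"] * 5)
        row = report.per_class.loc["F"]
        assert np.isfinite(row).all()
        assert "Sen" in report.degenerate["F"]


class TestRocAuc:
    def test_perfect_ranking_gives_auc_one(self):
        t = np.array(["V"] * 5 + ["N"] * 5)
        scores = np.zeros((10, 5))
        scores[:5, 4] = 0.9
        scores[5:, 4] = 0.1
        scores[:, 1] = 1 - scores[:, 4]
        out = roc_auc(scores, t)
        assert out["V"]["auc"] == 1.0

    def test_constant_scores_give_half(self):
        t = np.array(["V"] * 5 + ["N"] * 5)
        scores = np.full((10, 5), 0.2)
        assert roc_auc(scores, t)["V"]["auc"] == 0.5

    def test_matches_mann_whitney_identity(self, rng):
        from scipy.stats import mannwhitneyu
        t = rng.choice(["N", "V"], size=20)
        if len(np.unique(t)) < 2:  # pragma: no cover - seed-stable guard
            t[0], t[1] = "N", "V"
        scores = np.zeros((20, 5))
        scores[:, 4] = rng.random(20)
        scores[:, 1] = 1 - scores[:, 4]
        got = roc_auc(scores, t)["V"]["auc"]
        pos = scores[t == "V", 4]
        neg = scores[t != "V", 4]
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert np.isclose(got, u / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self, rng):
        t = rng.choice(["N", "V"], size=30)
        t[:2] = ["N", "V"]
        s = rng.random(30)
        scores = np.stack([np.zeros(30)] * 5, axis=1)
        scores[:, 4] = s
        a1 = roc_auc(scores, t)["V"]["auc"]
        scores[:, 4] = s ** 3  # strictly monotone on [0, 1]
        a2 = roc_auc(scores, t)["V"]["auc"]
        assert np.isclose(a1, a2)

    def test_degenerate_class_flagged(self):
        t = np.array(["N"] * 10)
        scores = np.full((10, 5), 0.2)
        out = roc_auc(scores, t)
        assert out["V"]["undefined"] and out["V"]["auc"] is None
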