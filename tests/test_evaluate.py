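"""ROC curves, AUC identities, operating-point selection and DeLong test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vmatqa import evaluate
from vmatqa.anomaly import CaseScore
from vmatqa.scnn import CaseProbability


def mann_whitney_auc(neg, pos):
    """Brute-force pair counting: #(pos > neg) + 1/2 #(ties)."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestROCCurve:
    def test_perfect_separation_hits_corner(self):
        fpr, tpr, _ = evaluate.roc_curve([1, 2], [3, 4])
        assert evaluate.auc(fpr, tpr) == 1.0
        assert any(f == 0 and t == 1 for f, t in zip(fpr, tpr))
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1

    def test_identical_sets_on_diagonal(self):
        fpr, tpr, _ = evaluate.roc_curve([1, 2, 3], [1, 2, 3])
        assert np.allclose(fpr, tpr)
        assert evaluate.auc(fpr, tpr) == pytest.approx(0.5)

    def test_single_threshold_confusion_counting(self):
        neg = np.array([0.1, 0.2, 0.35, 0.4])
        pos = np.array([0.3, 0.5, 0.6])
        fpr, tpr, thr = evaluate.roc_curve(neg, pos)
        # direct counting at threshold 0.45: TP = scores > 0.45
        i = np.argmin(np.abs(thr - 0.5))
        tp = np.sum(pos >= thr[i])
        fp = np.sum(neg >= thr[i])
        assert tpr[i] == pytest.approx(tp / len(pos))
        assert fpr[i] == pytest.approx(fp / len(neg))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate.roc_curve([], [1.0])


class TestAUC:
    def test_hand_value(self):
        fpr, tpr, _ = evaluate.roc_curve([1, 2, 3], [2.5, 4, 5])
        assert evaluate.auc(fpr, tpr) == pytest.approx(8 / 9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        neg = np.round(rng.normal(size=rng.integers(2, 30)), 1)
        pos = np.round(rng.normal(0.5, 1, size=rng.integers(2, 30)), 1)
        fpr, tpr, _ = evaluate.roc_curve(neg, pos)
        assert evaluate.auc(fpr, tpr) == pytest.approx(
            mann_whitney_auc(neg, pos), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        neg, pos = rng.normal(size=20), rng.normal(0.7, 1, size=20)
        f1, t1, _ = evaluate.roc_curve(neg, pos)
        f2, t2, _ = evaluate.roc_curve(np.exp(neg), np.exp(pos))
        assert evaluate.auc(f1, t1) == pytest.approx(evaluate.auc(f2, t2))

    def test_orientation_reversal_complements_auc(self):
        rng = np.random.default_rng(2)
        neg, pos = rng.normal(size=25), rng.normal(1, 1, size=25)
        f1, t1, _ = evaluate.roc_curve(neg, pos, higher_is_anomalous=True)
        f2, t2, _ = evaluate.roc_curve(neg, pos, higher_is_anomalous=False)
        assert evaluate.auc(f2, t2) == pytest.approx(
            1.0 - evaluate.auc(f1, t1))


class TestIdealThreshold:
    def test_hand_curve(self):
        fpr = np.array([0.0, 0.1, 1.0])
        tpr = np.array([0.0, 0.9, 1.0])
        thr = np.array([np.inf, 5.0, 1.0])
        t, m = evaluate.ideal_threshold(fpr, tpr, thr, n_pos=10, n_neg=10)
        assert t == 5.0
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["accuracy"] == pytest.approx(0.9)

    def test_perfect_curve_metrics(self):
        fpr, tpr, thr = evaluate.roc_curve([1, 2], [5, 6])
        _, m = evaluate.ideal_threshold(fpr, tpr, thr, 2, 2)
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_degenerate_curve_tie_breaks_to_high_sensitivity(self):
        # identical single-valued scores: curve is {(0,0), (1,1)}
        fpr, tpr, thr = evaluate.roc_curve([1.0, 1.0], [1.0, 1.0])
        _, m = evaluate.ideal_threshold(fpr, tpr, thr, 2, 2)
        assert m["sensitivity"] == 1.0


class TestCompareAUC:
    def test_identical_methods_p_one(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=40)
        labels = (np.arange(40) < 20).astype(int)
        assert evaluate.compare_auc(s, s, labels) == 1.0

    def test_perfect_vs_chance_significant(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([1, 0], 36)
        perfect = np.concatenate([np.ones(36), np.zeros(36)])
        chance = rng.normal(size=72)
        assert evaluate.compare_auc(perfect, chance, labels) < 0.05

    def test_symmetric_two_sided(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([1, 0], 25)
        a = rng.normal(size=50) + labels
        b = rng.normal(size=50) + 0.3 * labels
        assert evaluate.compare_auc(a, b, labels) == pytest.approx(
            evaluate.compare_auc(b, a, labels))

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            evaluate.compare_auc(np.zeros(3), np.zeros(4),
                                 np.array([0, 1, 0]))


def _fake_scores(rng, n_beams=12, md_shift=2.0, p_shift=0.3, g_shift=-5.0):
    kinds = ["none", "output_plus", "setup_lng"]
    md, probs, rows = [], [], []
    for e in kinds:
        for b in range(n_beams):
            bump = 0.0 if e == "none" else 1.0
            md.append(CaseScore(b, e, 3 + bump * md_shift + rng.normal(),
                                3 + bump * md_shift + rng.normal()))
            p = np.clip(0.4 + bump * p_shift + 0.05 * rng.normal(), 0, 1)
            probs.append(CaseProbability(b, e, p, p))
            for crit in ("3%/2mm", "2%/1mm"):
                rows.append({"beam_id": b, "error": e, "criteria": crit,
                             "n_evaluated": 100,
                             "pass_rate": 98 + bump * g_shift + rng.normal()})
    return md, probs, pd.DataFrame(rows)


class TestEvaluateAll:
    def test_full_report_structure(self):
        rng = np.random.default_rng(6)
        md, probs, rates = _fake_scores(rng)
        report = evaluate.evaluate_all(md, probs, rates)
        res = report["results"]
        assert set(res["method"]) == {"vae", "scnn", "gamma 3%/2mm",
                                      "gamma 2%/1mm"}
        assert set(res["error"]) == {"output_plus", "setup_lng"}
        assert ((res["auc"] >= 0) & (res["auc"] <= 1)).all()
        assert res[res["method"] != "vae"]["p_value_vs_vae"].notna().all()
        assert (res["n_pos"] == 12).all() and (res["n_neg"] == 12).all()

    def test_constant_scores_give_chance_auc(self):
        rng = np.random.default_rng(7)
        md, probs, rates = _fake_scores(rng)
        md = [CaseScore(s.beam_id, s.error, 1.0, 1.0) for s in md]
        report = evaluate.evaluate_all(md, probs, rates)
        res = report["results"]
        assert (res[res["method"] == "vae"]["auc"] == 0.5).all()

    def test_missing_cell_listed(self):
        rng = np.random.default_rng(8)
        md, probs, rates = _fake_scores(rng)
        md = [s for s in md if s.error != "setup_lng"]
        with pytest.raises(ValueError, match="setup_lng"):
            evaluate.evaluate_all(md, probs, rates)
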