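"""ROC analysis of the three error-detection methods.

Per error type, the error-free cases form the negative class and the cases of
that error the positive class.  Anomaly orientation is unified internally:
Mahalanobis distance and error probability are higher-is-anomalous, the gamma
pass rate is negated.  The operating point ("ideal threshold") is the ROC
point closest to (0, 1); paired AUC differences are tested with the DeLong
method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCResult", "roc_curve", "auc", "ideal_threshold", "compare_auc",
    "evaluate_all",
]


@dataclass
class ROCResult:
    method: str
    error: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ideal_threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


def roc_curve(neg_scores: np.ndarray, pos_scores: np.ndarray,
              higher_is_anomalous: bool = True):
    """(fpr, tpr, thresholds) sweeping all distinct scores.

    The curve runs from (0, 0) to (1, 1).  For lower-is-anomalous scores
    (gamma pass rates) the scores are negated so a single code path serves
    both orientations; the returned thresholds are on the negated scale.
    """
    neg = np.asarray(neg_scores, dtype=float)
    pos = np.asarray(pos_scores, dtype=float)
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both score sets must be non-empty")
    sign = 1.0 if higher_is_anomalous else -1.0
    y = np.concatenate([np.zeros(len(neg)), np.ones(len(pos))])
    s = sign * np.concatenate([neg, pos])
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return fpr, tpr, thr


def auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(tpr, fpr))


def ideal_threshold(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray,
                    n_pos: int, n_neg: int):
    """Operating point closest to (0, 1) and its classification metrics.

    Ties are broken by higher sensitivity, then by lower threshold.
    """
    d = np.hypot(fpr, 1.0 - tpr)
    best = np.flatnonzero(d <= d.min() + 1e-12)
    best = best[tpr[best] >= tpr[best].max() - 1e-12]
    i = best[np.argmin(thresholds[best])]
    sens = float(tpr[i])
    spec = float(1.0 - fpr[i])
    acc = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    return float(thresholds[i]), {"accuracy": acc, "sensitivity": sens,
                                  "specificity": spec}


def _delong_placements(pos: np.ndarray, neg: np.ndarray):
    """Mid-rank placement values V10 (positives) and V01 (negatives)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = rankdata(allv)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def compare_auc(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> float:
    """Two-sided DeLong test for the paired AUC difference of two methods.

    ``scores_a``/``scores_b`` are higher-is-anomalous scores of the same
    cases; ``labels`` marks positives with 1.  Returns a p-value in [0, 1].
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (len(a) == len(b) == len(labels)):
        raise ValueError("paired scores and labels must share a length")
    pos = labels == 1
    if not np.any(pos) or np.all(pos):
        raise ValueError("both classes must be present")

    v10 = np.empty((2, int(pos.sum())))
    v01 = np.empty((2, int((~pos).sum())))
    aucs = np.empty(2)
    for i, s in enumerate((a, b)):
        p10, p01 = _delong_placements(s[pos], s[~pos])
        v10[i], v01[i] = p10, p01
        aucs[i] = p10.mean()

    m, n = v10.shape[1], v01.shape[1]
    if m < 2 or n < 2:
        raise ValueError("need at least two cases per class")
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def _roc_result(method: str, error: str, neg: np.ndarray, pos: np.ndarray,
                higher_is_anomalous: bool) -> ROCResult:
    fpr, tpr, thr = roc_curve(neg, pos, higher_is_anomalous)
    a = auc(fpr, tpr)
    t, metrics = ideal_threshold(fpr, tpr, thr, len(pos), len(neg))
    if not higher_is_anomalous:
        t = -t
    return ROCResult(method, error, fpr, tpr, thr, a, t,
                     metrics["accuracy"], metrics["sensitivity"],
                     metrics["specificity"], len(pos), len(neg))


def evaluate_all(md_scores, scnn_probs, gamma_rates: pd.DataFrame) -> dict:
    """Full per-error-type ROC report for the three methods.

    ``md_scores``: CaseScore list (Mahalanobis), ``scnn_probs``:
    CaseProbability list, ``gamma_rates``: DataFrame with beam_id / error /
    criteria / pass_rate.  Returns a dict with a tidy ``results`` frame, AUC
    and metrics pivots shaped like the usual summary tables, and the raw
    curves.  AUC-difference p-values are computed against the VAE method on
    the paired cases.
    """
    frames = {
        "vae": pd.DataFrame(
            [{"beam_id": s.beam_id, "error": s.error, "score": s.md_mean}
             for s in md_scores]).assign(higher=True),
        "scnn": pd.DataFrame(
            [{"beam_id": s.beam_id, "error": s.error, "score": s.p_error_mean}
             for s in scnn_probs]).assign(higher=True),
    }
    for crit, grp in gamma_rates.groupby("criteria"):
        frames[f"gamma {crit}"] = grp.rename(columns={"pass_rate": "score"})[
            ["beam_id", "error", "score"]].assign(higher=False)

    error_kinds = sorted(
        {e for f in frames.values() for e in f["error"]} - {"none"})
    missing = [(m, e) for m, f in frames.items()
               for e in error_kinds + ["none"] if e not in set(f["error"])]
    if missing:
        raise ValueError(f"missing (method, error) score cells: {missing}")

    rows = []
    curves = {}
    for error in error_kinds:
        paired = {}
        for method, f in frames.items():
            neg = f[f["error"] == "none"].sort_values("beam_id")
            pos = f[f["error"] == error].sort_values("beam_id")
            higher = bool(f["higher"].iloc[0])
            res = _roc_result(method, error, neg["score"].to_numpy(),
                              pos["score"].to_numpy(), higher)
            curves[(method, error)] = res
            sign = 1.0 if higher else -1.0
            paired[method] = (
                sign * np.concatenate([pos["score"], neg["score"]]),
                np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]),
            )
            rows.append({
                "error": error, "method": method, "auc": res.auc,
                "ideal_threshold": res.ideal_threshold,
                "accuracy": res.accuracy, "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "n_pos": res.n_pos, "n_neg": res.n_neg,
            })
        for method in frames:
            if method == "vae":
                p = np.nan
            else:
                sa, la = paired[method]
                sv, lv = paired["vae"]
                if not np.array_equal(la, lv):
                    raise ValueError("unpaired cases between methods")
                p = compare_auc(sa, sv, la)
            for r in rows:
                if r["error"] == error and r["method"] == method:
                    r["p_value_vs_vae"] = p

    results = pd.DataFrame(rows)
    table1 = results.pivot(index="error", columns="method", values="auc")
    table2 = results.pivot(index="error", columns="method",
                           values=["accuracy", "sensitivity", "specificity"])
    return {"results": results, "table1": table1, "table2": table2,
            "curves": curves}
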