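"""Evaluation metrics, ROC operating-point selection, confound check.

Regression (age): MAE, Pearson r with its two-sided p-value (exact t
transform, n-2 df), and prediction R^2 (q^2) computed against the
evaluation-set mean — it can be negative for models worse than the mean
predictor.  Classification (gender/diagnosis): precision, recall, F1 and
AUC-ROC, with the decision threshold chosen on *validation* scores to
maximize the harmonic mean of sensitivity and specificity and then applied
unchanged to test scores.

Positive-class encoding used in every report: gender 1 = female,
diagnosis 1 = disorder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import r2_score as _sk_r2
from sklearn.metrics import roc_auc_score as _sk_auc

__all__ = [
    "RegressionReport", "ClassificationReport", "regression_metrics",
    "auc_roc", "select_operating_point", "classification_metrics",
    "confound_check", "DegenerateScoresWarning",
]


class DegenerateScoresWarning(UserWarning):
    pass


@dataclass(frozen=True)
class RegressionReport:
    """Age-regression metrics; ``r_defined`` is False when the correlation is
    undefined (zero variance in targets or predictions) — the fields then
    hold NaN rather than a silent zero."""

    mae: float
    pearson_r: float
    p_value: float
    r2: float
    n: int
    r_defined: bool = True

    def to_dict(self) -> dict:
        return {"n": self.n, "mae": self.mae, "pearson_r": self.pearson_r,
                "p_value": self.p_value, "r2": self.r2}


@dataclass(frozen=True)
class ClassificationReport:
    precision: float
    recall: float
    f1: float
    auc: float
    threshold: float
    n_positive: int
    n_negative: int
    precision_defined: bool = True

    def to_dict(self) -> dict:
        return {"n": self.n_positive + self.n_negative, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc,
                "threshold": self.threshold}


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValueError(f"non-finite values in {name}")
    return arr


def regression_metrics(targets: Sequence[float], preds: Sequence[float]) -> RegressionReport:
    """MAE, Pearson r (+ p-value) and prediction R^2 on held-out data."""
    y = _as_1d(targets, "targets")
    p = _as_1d(preds, "preds")
    if y.shape != p.shape or y.size < 2:
        raise ValueError("need matching targets/preds with n >= 2")
    mae = float(np.mean(np.abs(y - p)))
    if np.ptp(y) == 0:
        # zero target variance: both r and R^2 are undefined (SS_tot = 0)
        return RegressionReport(mae=mae, pearson_r=np.nan, p_value=np.nan,
                                r2=np.nan, n=y.size, r_defined=False)
    if np.ptp(p) == 0:
        # constant predictions: r undefined; R^2 still well defined and is
        # exactly 0 when the constant equals the evaluation-set mean
        return RegressionReport(mae=mae, pearson_r=np.nan, p_value=np.nan,
                                r2=float(_sk_r2(y, p)), n=y.size, r_defined=False)
    r, pval = stats.pearsonr(y, p)
    r2 = _sk_r2(y, p)
    return RegressionReport(mae=mae, pearson_r=float(r), p_value=float(pval),
                            r2=float(r2), n=y.size)


def auc_roc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve; equals P(score+ > score-) + 0.5 P(tie)."""
    y = np.asarray(labels).ravel().astype(int)
    s = _as_1d(scores, "scores")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present for AUC")
    return float(_sk_auc(y, s))


def _confusion(labels: np.ndarray, scores: np.ndarray, threshold: float):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def _sens_spec_hmean(labels, scores, threshold) -> float:
    tp, fp, fn, tn = _confusion(labels, scores, threshold)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    if sens + spec == 0:
        return 0.0
    return 2.0 * sens * spec / (sens + spec)


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus one candidate
    below the minimum and one above the maximum; finite and exhaustive over
    distinct confusion tables for the ``>=`` decision rule."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def select_operating_point(val_labels: Sequence[int], val_scores: Sequence[float]) -> float:
    """Threshold maximizing the harmonic mean of sensitivity and specificity
    on validation data (ties -> lowest threshold).  Apply the returned value
    unchanged to test scores with the rule ``predict positive if
    score >= threshold``."""
    y = np.asarray(val_labels).ravel().astype(int)
    s = _as_1d(val_scores, "val_scores")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present to select a threshold")
    if np.ptp(s) == 0:
        warnings.warn("all validation scores are identical; threshold degenerate",
                      DegenerateScoresWarning, stacklevel=2)
        return float(s[0])
    cands = candidate_thresholds(s)
    values = [_sens_spec_hmean(y, s, t) for t in cands]
    return float(cands[int(np.argmax(values))])  # argmax returns first (lowest) max


def classification_metrics(labels: Sequence[int], scores: Sequence[float],
                           threshold: float) -> ClassificationReport:
    """Confusion-based metrics at a fixed threshold plus threshold-free AUC."""
    y = np.asarray(labels).ravel().astype(int)
    s = _as_1d(scores, "scores")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    tp, fp, fn, tn = _confusion(y, s, threshold)
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else np.nan
    recall = tp / (tp + fn)
    if precision_defined and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0 if precision_defined else np.nan
    return ClassificationReport(
        precision=float(precision), recall=float(recall), f1=float(f1),
        auc=auc_roc(y, s), threshold=float(threshold),
        n_positive=int(np.sum(y == 1)), n_negative=int(np.sum(y == 0)),
        precision_defined=precision_defined)


def brain_volumes(samples, mode: str = "count") -> np.ndarray:
    """Total brain volume per subject from the stacked two-channel tensors.

    ``count`` (default): number of voxels with positive density in either
    channel; ``sum``: summed density over those voxels.  Both readings of
    "sum of brain voxels" are available because the wording is ambiguous.
    """
    out = []
    for sample in samples:
        v = sample.values if hasattr(sample, "values") else np.asarray(sample)
        pos = v > 0
        out.append(float(pos.sum()) if mode == "count" else float(v[pos].sum()))
    return np.asarray(out)


def confound_check(samples, phenotypes, mode: str = "count") -> dict:
    """How much of gender/age is explained by total brain volume alone.

    Returns the AUC of per-subject brain volume for gender and the Pearson r
    (with p-value) of brain volume against age.  Values near 0.5 / 0 mean
    the model cannot be explained away by global volume.
    """
    vols = brain_volumes(samples, mode=mode)
    if len(vols) < 2:
        raise ValueError("need at least two subjects")
    genders = np.array([p.gender for p in phenotypes])
    ages = np.array([p.age for p in phenotypes])
    auc = auc_roc(genders, vols)
    if np.ptp(vols) == 0 or np.ptp(ages) == 0:
        r, pval = np.nan, np.nan
    else:
        r, pval = stats.pearsonr(vols, ages)
    return {"gender_auc": float(auc), "age_r": float(r), "age_r_p_value": float(pval),
            "mode": mode}
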