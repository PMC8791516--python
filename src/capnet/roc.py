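"""Discrimination analysis: ROC/AUC, paired AUC contrasts, cross-validation,
external transport, and metric cutoffs.

The AUC is the empirical Mann-Whitney probability (ties counted 1/2), and
its variance — and the covariance of two AUCs computed on the same eyes —
comes from the structural-components (DeLong) estimator over placement
values, giving an asymptotically chi-square test for a paired AUC
difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from ._rng import substream

__all__ = [
    "RocResult",
    "RocContrast",
    "CutoffResult",
    "CvResult",
    "roc_auc",
    "compare_auc",
    "kfold_cv_auc",
    "external_validate",
    "optimal_cutoff",
    "sens_spec_at",
]


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple
    n_pos: int
    n_neg: int

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(1 - self.specificity, self.sensitivity,
                label=f"AUC = {self.auc:.2f}", **kw)
        ax.plot([0, 1], [0, 1], ls=":", c="gray")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


@dataclass
class RocContrast:
    auc_a: float
    auc_b: float
    difference: float
    chi_square: float
    p_value: float
    variance: float


@dataclass
class CutoffResult:
    threshold: float
    correct_classification_rate: float
    direction: str
    n: int


@dataclass
class CvResult:
    mean_auc: float
    ci: tuple
    fold_aucs: list
    skipped_folds: int


def _placements(scores, labels):
    """Placement values (V10 per positive, V01 per negative); midrank method.

    V10_i is the fraction of negatives a positive outranks (ties 1/2); the
    AUC is the mean of either vector.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute an AUC")
    allr = stats.rankdata(np.r_[pos, neg])
    rpos = stats.rankdata(pos)
    rneg = stats.rankdata(neg)
    v10 = (allr[:m] - rpos) / n
    v01 = 1.0 - (allr[m:] - rneg) / m
    return v10, v01


def roc_auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """Empirical ROC curve with Mann-Whitney AUC and a DeLong CI."""
    labels = np.asarray(labels).astype(int)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1 - fpr,
        auc=auc,
        auc_ci=(max(auc - half, 0.0), min(auc + half, 1.0)),
        n_pos=m,
        n_neg=n,
    )


def compare_auc(scores_a, scores_b, labels) -> RocContrast:
    """Paired AUC contrast by the structural-components (DeLong) method.

    Both score vectors must refer to the same observations.  The difference
    is standardized by the DeLong variance of (AUC_a - AUC_b) and referred
    to chi-square with 1 df.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired AUC contrast requires equal-length score vectors")
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    diff = auc_a - auc_b
    if var <= 0:
        chi2 = 0.0 if abs(diff) < 1e-12 else math.inf
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        chi2 = diff * diff / var
        p = float(stats.chi2.sf(chi2, 1))
    return RocContrast(
        auc_a=auc_a, auc_b=auc_b, difference=diff,
        chi_square=chi2, p_value=p, variance=max(var, 0.0),
    )


def _subject_folds(df, k, seed, subject_col, y):
    """Fold labels per row: subjects stay together, strata balanced."""
    subj = df[subject_col].to_numpy()
    subj_y = pd.Series(y, index=df.index).groupby(subj).max()
    rng = substream(seed, "cv-folds")
    fold_of = {}
    for level in sorted(subj_y.unique()):
        members = np.array(sorted(subj_y.index[subj_y == level]))
        rng.shuffle(members)
        for i, s in enumerate(members):
            fold_of[s] = i % k
    return np.array([fold_of[s] for s in subj])


def kfold_cv_auc(
    df: pd.DataFrame,
    outcome_builder,
    fixed: Sequence[str],
    k: int = 10,
    seed: int = 0,
    subject_col: str = "subject_id",
    fit_kw: Optional[dict] = None,
) -> CvResult:
    """Subject-grouped, outcome-stratified k-fold cross-validated AUC.

    ``outcome_builder(df) -> (frame, y)`` recodes the table to the binary
    contrast (e.g. via :func:`capnet.model.constrained_comparison` recoding);
    each fold's model is fit on the remaining folds and its *fixed* linear
    predictor scores the held-out eyes.  Both eyes of a subject always land
    in the same fold.  Folds missing a class are skipped with a warning.
    """
    from .model import ConvergenceError, MixedLogit

    if k < 2:
        raise ValueError("k-fold cross-validation requires k >= 2")
    frame, y = outcome_builder(df)
    frame = frame.reset_index(drop=True)
    y = np.asarray(y).astype(int)
    folds = _subject_folds(frame, k, seed, subject_col, y)
    aucs, skipped = [], 0
    fit_kw = fit_kw or {}
    for f in range(k):
        test = folds == f
        if y[test].min(initial=1) == y[test].max(initial=0) or not test.any():
            warnings.warn(f"fold {f} lacks a class; skipped", stacklevel=2)
            skipped += 1
            continue
        train_df = frame[~test].assign(_y=y[~test])
        model = MixedLogit.from_dataframe(train_df, "_y", list(fixed), subject=subject_col)
        try:
            res = model.fit(**fit_kw)
        except ConvergenceError:
            # separated fold: a weakly ridged fit still ranks held-out eyes
            warnings.warn(f"fold {f} separated; refit with weak ridge", stacklevel=2)
            res = model.fit(**{**fit_kw, "ridge": 1e-4})
        lp = res.predict_linear(frame[test])
        aucs.append(roc_auc(lp, y[test]).auc)
    if not aucs:
        raise ValueError("no fold had both classes present")
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    half = 1.96 * sd / math.sqrt(len(aucs))
    return CvResult(
        mean_auc=mean,
        ci=(max(mean - half, 0.0), min(mean + half, 1.0)),
        fold_aucs=aucs,
        skipped_folds=skipped,
    )


def external_validate(fit, new_df: pd.DataFrame, y) -> RocResult:
    """Score a new cohort with coefficients frozen from a fitted model.

    ``fit`` is a MixedLogitResults built from a dataframe; a missing model
    variable in ``new_df`` raises KeyError naming it.
    """
    if len(new_df) == 0:
        raise ValueError("validation cohort is empty")
    lp = fit.predict_linear(new_df)
    return roc_auc(lp, np.asarray(y).astype(int))


def optimal_cutoff(values, labels, direction: str) -> CutoffResult:
    """Exhaustive threshold scan maximizing the correct classification rate.

    direction "below_positive" calls values below the threshold diseased
    (capillary-density-like metrics); "above_positive" the reverse
    (caliber-like metrics).  Candidate thresholds are midpoints of sorted
    distinct values; ties in the rate go to the threshold nearest the grand
    median.
    """
    if direction not in ("below_positive", "above_positive"):
        raise ValueError("direction must be 'below_positive' or 'above_positive'")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("cannot place a cutoff on constant values")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(values)
    if direction == "below_positive":
        pred = values[None, :] < mids[:, None]
    else:
        pred = values[None, :] > mids[:, None]
    rates = (pred == (labels[None, :] == 1)).mean(axis=1)
    best = rates.max()
    cand = mids[rates == best]
    med = float(np.median(values))
    thr = float(cand[np.argmin(np.abs(cand - med))])
    return CutoffResult(
        threshold=thr,
        correct_classification_rate=float(best),
        direction=direction,
        n=n,
    )


def sens_spec_at(scores, labels, rule: str = "youden", threshold: Optional[float] = None):
    """Sensitivity and specificity at an operating point on the ROC curve.

    Default rule is Youden's J (maximizes sensitivity + specificity - 1);
    pass ``rule='threshold'`` with an explicit ``threshold`` to evaluate a
    fixed cut (score >= threshold positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if rule == "youden":
        fpr, tpr, thr = roc_curve(labels, scores)
        j = tpr - fpr
        i = int(np.argmax(j))
        return float(tpr[i]), float(1 - fpr[i])
    if rule == "threshold":
        if threshold is None:
            raise ValueError("rule='threshold' requires a threshold")
        pred = scores >= threshold
        pos = labels == 1
        sens = float((pred & pos).sum() / pos.sum())
        spec = float((~pred & ~pos).sum() / (~pos).sum())
        return sens, spec
    raise ValueError(f"unknown operating rule {rule!r}")
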