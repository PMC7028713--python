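"""Cross-validated discrimination assessment of extracted scores.

The extracted scalar (GCC or first principal component) is treated as a
risk score and evaluated against the three cutoff-derived condition labels
by ROC analysis: per-fold AUC under 10-fold cross-validation with a
t-distribution 95% CI across folds, paired t-tests between reduction
methods on the shared folds, and final ROC curves with Youden-optimal
thresholds from a refit on all rows.

Leakage discipline: within each fold, the min-max scaler and the reducer
are fit on the training folds only; held-out rows are scored with those
frozen parameters.  The per-fold scaler statistics are logged so tests can
assert they never saw test rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .cohort import BIOMARKERS, CohortTable
from .exceptions import (ConfigError, OrientationError, PairingError,
                         UndefinedAUCError)
from .labels import CONDITIONS
from .reduction import (DEFAULT_ARCH, FeatureScaler, TrainConfig,
                        fit_pca, pca_score, train_autoencoder)


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney concordance probability: the chance a random
    positive scores above a random negative, ties counted one-half.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise UndefinedAUCError("AUC undefined: only one class present")
    return float(roc_auc_score(y, s))


@dataclass(frozen=True)
class FoldAssignment:
    """K-fold partition: ``fold`` gives each subject's fold in 0..K-1."""

    fold: np.ndarray
    k: int
    seed: int


def make_folds(n: int, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Random K-fold partition with fold sizes differing by at most one.

    Leave-one-out (k == n) is rejected: a singleton held-out fold has a
    single-class label vector, so per-fold AUC is undefined.
    """
    if k < 2:
        raise ConfigError("need at least 2 folds")
    if n < k:
        raise ConfigError(f"cannot make {k} folds from {n} subjects")
    if k == n:
        raise ConfigError("k == n (leave-one-out) is rejected: per-fold AUC "
                          "is undefined on singleton folds")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for i, chunk in enumerate(np.array_split(perm, k)):
        fold[chunk] = i
    return FoldAssignment(fold=fold, k=k, seed=seed)


def orient_scores(scores, anchor) -> tuple[np.ndarray, bool]:
    """Orient a score so that higher values track the anchor biomarker.

    A bottleneck (or principal-component) score has arbitrary sign; the
    score is flipped iff its Pearson correlation with the anchor (default
    fasting plasma glucose, chosen because higher FPG is unambiguously
    worse) is negative.  Idempotent; returns (scores, flipped).
    """
    s = np.asarray(scores, dtype=float)
    a = np.asarray(anchor, dtype=float)
    ok = np.isfinite(a) & np.isfinite(s)
    if ok.sum() < 10:
        raise OrientationError("anchor present for fewer than 10 subjects")
    if np.std(a[ok]) == 0 or np.std(s[ok]) == 0:
        raise OrientationError("zero-variance anchor or scores; orientation undefined")
    r = float(np.corrcoef(s[ok], a[ok])[0, 1])
    return (-s, True) if r < 0 else (s.copy(), False)


@dataclass
class AUCEstimate:
    """Fold-wise AUCs with their mean and t-distribution 95% CI."""

    fold_aucs: list[float]
    mean: float
    ci_low: float
    ci_high: float
    skipped_folds: list[int] = field(default_factory=list)


def _summarize_folds(fold_aucs: list[float], skipped: list[int],
                     level: float = 0.95) -> AUCEstimate:
    arr = np.asarray(fold_aucs, dtype=float)
    mean = float(arr.mean())
    if arr.size > 1 and arr.std(ddof=1) > 0:
        half = stats.t.ppf(0.5 + level / 2, arr.size - 1) * arr.std(ddof=1) / np.sqrt(arr.size)
    else:
        half = 0.0
    return AUCEstimate(fold_aucs=list(map(float, arr)), mean=mean,
                       ci_low=mean - half, ci_high=mean + half,
                       skipped_folds=skipped)


def cv_auc(table: CohortTable, labels: pd.DataFrame, method: str,
           folds: FoldAssignment, *,
           widths: Sequence[int] = DEFAULT_ARCH,
           train_cfg: TrainConfig | None = None,
           interval: tuple[float, float] = (0.1, 0.9),
           anchor: str = "fpg",
           ) -> tuple[dict[str, AUCEstimate], list[dict]]:
    """Per-condition cross-validated AUC for one reduction method.

    For each fold: fit the scaler and the reducer ("autoencoder" or "pca")
    on the training folds only, score the held-out rows, orient the scores
    against the anchor biomarker, and compute the AUC against each
    condition.  Folds whose held-out labels are single-class for a
    condition are skipped for that condition and recorded.

    Returns (per-condition AUCEstimate, per-fold log).  The log carries the
    scaler minima/maxima fitted in each fold so leakage can be audited.
    """
    if method not in ("autoencoder", "pca"):
        raise ConfigError(f"unknown reduction method {method!r}")
    X = table.biomarkers().to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ConfigError("cv_auc requires complete biomarker rows; "
                          "filter to complete cases first")
    anchor_vals = table.data[anchor].to_numpy(dtype=float)
    train_cfg = train_cfg or TrainConfig()
    fold_aucs: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    skipped: dict[str, list[int]] = {c: [] for c in CONDITIONS}
    logs: list[dict] = []

    for f in range(folds.k):
        te = folds.fold == f
        tr = ~te
        scaler = FeatureScaler(lo=interval[0], hi=interval[1]).fit(
            X[tr], feature_names=list(BIOMARKERS))
        if method == "autoencoder":
            cfg = TrainConfig(**{**train_cfg.__dict__, "seed": train_cfg.seed + f})
            model = train_autoencoder(scaler.transform(X[tr]), widths, cfg,
                                      scaler=scaler)
            raw_scores = model.encode_scaled(scaler.transform(X[te]))
        else:
            # PCA baseline works on raw biomarkers, centered on training
            # means (the prcomp convention); min-max scaling is a sigmoid-
            # autoencoder requirement, not part of the linear baseline
            model = fit_pca(X[tr])
            raw_scores = pca_score(model, X[te], k=1)
        scores, flipped = orient_scores(raw_scores, anchor_vals[te])
        logs.append({"fold": f, "n_train": int(tr.sum()), "n_test": int(te.sum()),
                     "scaler_mins": scaler.mins.copy(), "scaler_maxs": scaler.maxs.copy(),
                     "flipped": flipped})
        for cond in CONDITIONS:
            y = labels.loc[te, cond].to_numpy(dtype=float)
            ok = np.isfinite(y)
            try:
                fold_aucs[cond].append(auc(scores[ok], y[ok]))
            except UndefinedAUCError:
                skipped[cond].append(f)
    return ({c: _summarize_folds(fold_aucs[c], skipped[c]) for c in CONDITIONS},
            logs)


@dataclass
class MethodComparison:
    """Paired t-test of fold-wise AUCs between two methods."""

    t_stat: float
    p_value: float
    mean_difference: float


def compare_methods(a: dict[str, AUCEstimate], b: dict[str, AUCEstimate]
                    ) -> dict[str, MethodComparison]:
    """Two-tailed paired t-test on fold AUC differences, per condition.

    Both estimates must come from the same fold assignment (equal fold
    counts per condition); otherwise PairingError.  A zero-variance nonzero
    difference is reported as p = 0 (below the machine floor).
    """
    out: dict[str, MethodComparison] = {}
    for cond in a:
        fa = np.asarray(a[cond].fold_aucs, dtype=float)
        fb = np.asarray(b[cond].fold_aucs, dtype=float)
        if fa.size != fb.size:
            raise PairingError(
                f"condition {cond!r}: fold counts differ ({fa.size} vs {fb.size})")
        d = fa - fb
        md = float(d.mean())
        sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
        if sd > 0.0:
            t_stat, p = stats.ttest_rel(fa, fb)
            out[cond] = MethodComparison(float(t_stat), float(p), md)
        else:
            if md == 0.0:
                out[cond] = MethodComparison(0.0, 1.0, 0.0)
            else:
                out[cond] = MethodComparison(float(np.sign(md) * np.inf), 0.0, md)
    return out


@dataclass
class ROCCurve:
    """Full ROC: monotone (FPR, TPR) path with thresholds, trapezoidal AUC,
    and the Youden-optimal threshold (ties broken toward higher
    specificity, i.e. lower FPR, then higher threshold)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    optimal_threshold: float
    optimal_fpr: float
    optimal_tpr: float


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve swept over the unique score values.

    The trapezoidal area equals :func:`auc` to numerical precision; the
    optimal threshold maximizes Youden's J = TPR - FPR.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise UndefinedAUCError("ROC undefined: only one class present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # ties: prefer lower FPR (higher specificity), then higher threshold
    best = best[np.lexsort((-thr[best], fpr[best]))][0]
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=area,
                    optimal_threshold=float(thr[best]),
                    optimal_fpr=float(fpr[best]), optimal_tpr=float(tpr[best]))


def final_roc(table: CohortTable, labels: pd.DataFrame, scores,
              ) -> dict[str, ROCCurve]:
    """ROC per condition for final (refit-on-all-rows) oriented scores."""
    out = {}
    s = np.asarray(scores, dtype=float)
    for cond in CONDITIONS:
        y = labels[cond].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(s)
        out[cond] = roc_curve(s[ok], y[ok])
    return out
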