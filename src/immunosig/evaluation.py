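"""Predictive evaluation: MCC over repeated cross-validation with
permutation-null baselines.

Clinical outcomes (MYCN amplification, age at diagnosis dichotomized at
18 months, INRG stage, 2-year overall survival) are predicted from
marker expression and signature scores with logistic (binary) or
multinomial (multiclass) regression.  Performance is the Matthews
correlation coefficient over stratified k-fold CV repeated several
times; the null reference ("random labels mode") refits the same models
after permuting the outcome once per repeat.  Majority-class
downsampling (once per repeat) guards against imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix

from .containers import ClinicalTable, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# Matthews correlation coefficient


def mcc(confusion: np.ndarray) -> float:
    """MCC from a confusion matrix (rows true, columns predicted).

    Binary: (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Multiclass: the Gorodkin covariance generalization.  A zero
    denominator (e.g. all predictions in one class) is defined as 0.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if c.sum() <= 0:
        raise ValidationError("empty confusion matrix")
    t = c.sum(axis=1)  # true-class totals
    p = c.sum(axis=0)  # predicted-class totals
    n = c.sum()
    cov_tp = np.trace(c) * n - t @ p
    cov_tt = n * n - t @ t
    cov_pp = n * n - p @ p
    denom = np.sqrt(cov_tt) * np.sqrt(cov_pp)
    return 0.0 if denom == 0 else float(cov_tp / denom)


# ---------------------------------------------------------------------
# Classifiers


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Unpenalized ML logistic/multinomial fit with a ridge fallback.

    Complete separation makes the unpenalized likelihood monotone; a
    tiny ridge (lambda = 1e-6) restores a unique optimum, with a logged
    warning.
    """
    import warnings

    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model.fit(X, y)
        diverged = (
            any(issubclass(w.category, ConvergenceWarning) for w in caught)
            or np.abs(model.coef_).max() > 1e4
        )
    if diverged:
        log.warning("logistic fit separated/non-converged; ridge fallback")
        model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
        model.fit(X, y)
    return model


def fit_binary_logistic(X, y) -> LogisticRegression:
    """Maximum-likelihood binary logistic regression."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValidationError("binary outcome must have exactly 2 classes")
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("need n > number of covariates")
    return _fit_logistic(X, y)


def fit_multinomial(X, y) -> LogisticRegression:
    """Maximum-likelihood multinomial (softmax) regression."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome needs >= 2 classes")
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("need n > number of covariates")
    return _fit_logistic(X, y)


# ---------------------------------------------------------------------
# Repeated CV


@dataclass
class EvalResult:
    """Fold-level MCC/sensitivity/specificity with summary statistics."""

    folds: pd.DataFrame          # repeat, fold, mcc, sensitivity, specificity
    mode: str                    # true_labels | random_labels
    median_mcc: float
    ci_low: float                # 2.5 percentile of fold MCCs
    ci_high: float               # 97.5 percentile
    pooled_confusion: np.ndarray

    @property
    def mccs(self) -> np.ndarray:
        return self.folds["mcc"].to_numpy()


def _stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified fold assignment; every class spread over folds."""
    folds: list[list[int]] = [[] for _ in range(k)]
    start = int(rng.integers(k))
    pos = start
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[pos % k].append(int(i))
            pos += 1
    return [np.array(sorted(f)) for f in folds]


def _sens_spec(conf: np.ndarray) -> tuple[float, float]:
    if conf.shape != (2, 2):
        return float("nan"), float("nan")
    tn, fp, fn, tp = conf.ravel()
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return float(sens), float(spec)


def repeated_kfold_mcc(
    X, y, k: int = 3, repeats: int = 10, mode: str = "true_labels",
    downsample: bool = False, seed: int = 0,
) -> EvalResult:
    """Stratified repeated k-fold CV scored by MCC.

    ``mode="random_labels"`` permutes the outcome once per repeat
    before splitting, giving the permutation-null reference.
    ``downsample`` randomly reduces the majority class to the minority
    size once per repeat.  All randomness flows from ``seed``.
    """
    if mode not in ("true_labels", "random_labels"):
        raise ValidationError(f"unknown mode {mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValidationError(
            f"class with {counts.min()} member(s) cannot be split into {k} folds"
        )
    rng = np.random.default_rng(seed)
    binary = len(classes) == 2
    fit = fit_binary_logistic if binary else fit_multinomial
    rows = []
    pooled = np.zeros((len(classes), len(classes)))
    for rep in range(repeats):
        y_rep = rng.permutation(y) if mode == "random_labels" else y.copy()
        keep = np.arange(len(y_rep))
        if downsample:
            cls, cnt = np.unique(y_rep, return_counts=True)
            m = cnt.min()
            keep = np.concatenate([
                rng.choice(np.flatnonzero(y_rep == c), size=m, replace=False)
                for c in cls
            ])
            keep.sort()
        Xr, yr = X[keep], y_rep[keep]
        folds = _stratified_folds(yr, k, rng)
        for fi, test_idx in enumerate(folds):
            train_mask = np.ones(len(yr), dtype=bool)
            train_mask[test_idx] = False
            if len(np.unique(yr[train_mask])) < len(classes):
                log.warning("repeat %d fold %d lacks a class in training", rep, fi)
                continue
            model = fit(Xr[train_mask], yr[train_mask])
            pred = model.predict(Xr[test_idx])
            conf = confusion_matrix(yr[test_idx], pred, labels=classes)
            pooled += conf
            sens, spec = _sens_spec(conf)
            rows.append((rep, fi, mcc(conf), sens, spec))
    folds_df = pd.DataFrame(
        rows, columns=["repeat", "fold", "mcc", "sensitivity", "specificity"]
    )
    mccs = folds_df["mcc"].to_numpy()
    return EvalResult(
        folds=folds_df, mode=mode,
        median_mcc=float(np.median(mccs)),
        ci_low=float(np.percentile(mccs, 2.5)),
        ci_high=float(np.percentile(mccs, 97.5)),
        pooled_confusion=pooled,
    )


def compare_eval(true: EvalResult, random: EvalResult) -> float:
    """Two-sided Wilcoxon rank-sum p comparing fold-level MCCs."""
    a, b = true.mccs, random.mccs
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty MCC distribution")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    return float(ss.mannwhitneyu(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------
# Outcome derivations


#: days in the 2-year overall-survival window
TWO_YEARS_DAYS = 730.0


def derive_os2_outcome(c: ClinicalTable) -> tuple[pd.Series, list[str]]:
    """Binary 2-year overall-survival outcome.

    poor (1): death before 730 days; good (0): followed at least 730
    days; excluded: censored before 730 days.  Returns (labels indexed
    by sample, excluded sample ids).
    """
    t = c.table["os_time"]
    e = c.table["os_event"]
    poor = (e == 1) & (t < TWO_YEARS_DAYS)
    good = t >= TWO_YEARS_DAYS
    excluded = list(c.table.index[~poor & ~good])
    if excluded:
        log.info("%d sample(s) censored before 2 years excluded", len(excluded))
    labels = pd.Series(
        np.where(poor, 1, 0), index=c.table.index, name="os2yr_poor"
    )[poor | good]
    return labels.astype(int), excluded


def derive_age18_outcome(c: ClinicalTable) -> pd.Series:
    """Age at diagnosis dichotomized at 18 months (1 = older)."""
    age = c.table["age_months"].dropna()
    return (age > 18).astype(int)


# ---------------------------------------------------------------------
# Prognostic-improvement comparison


def _baseline_design(c: ClinicalTable, cd3e_high: pd.Series) -> pd.DataFrame:
    """Classical-predictor design: INRG dummies, MYCN, age>18mo, CD3E Hi."""
    t = c.table
    needed = ["inrg_stage", "mycn_amplified", "age_months"]
    missing = [col for col in needed if col not in t.columns]
    if missing:
        raise ValidationError(f"missing predictor column(s): {missing}")
    X = pd.get_dummies(t["inrg_stage"], prefix="inrg", dtype=float)
    X["mycn_amplified"] = t["mycn_amplified"].astype(float)
    X["age_gt18mo"] = (t["age_months"] > 18).astype(float)
    X["cd3e_high"] = cd3e_high.reindex(t.index).astype(float)
    return X.dropna()


def prognostic_improvement(
    c: ClinicalTable,
    cd3e_high: pd.Series,
    signature_scores: dict[str, pd.Series],
    k: int = 5, repeats: int = 10, seed: int = 0,
) -> pd.DataFrame:
    """Baseline vs baseline+signature models for the 2-year OS outcome.

    Trains the classical-predictor logistic model and one extra model
    per entry of ``signature_scores`` (each adding that score), all
    evaluated identically (repeated stratified k-fold CV, majority
    downsampling).  Sensitivity/specificity are reported both averaged
    over folds and pooled over the combined held-out confusion matrix.
    """
    y, _ = derive_os2_outcome(c)
    X0 = _baseline_design(c, cd3e_high)
    rows = []
    models: dict[str, pd.DataFrame] = {"baseline": X0}
    for name, score in signature_scores.items():
        Xs = X0.copy()
        if isinstance(score, pd.DataFrame):
            # sign-aware signatures enter as separate sub-scores
            for col in score.columns:
                Xs[f"{name}_{col}"] = score[col].reindex(X0.index)
        else:
            Xs[f"{name}_score"] = score.reindex(X0.index)
        models[f"baseline+{name}"] = Xs.dropna()
    for name, X in models.items():
        common = X.index.intersection(y.index)
        res = repeated_kfold_mcc(
            X.loc[common].to_numpy(), y.loc[common].to_numpy(),
            k=k, repeats=repeats, downsample=True, seed=seed,
        )
        pooled_sens, pooled_spec = _sens_spec(res.pooled_confusion)
        rows.append((
            name, res.median_mcc, res.ci_low, res.ci_high,
            float(res.folds["sensitivity"].mean()),
            float(res.folds["specificity"].mean()),
            pooled_sens, pooled_spec, len(common),
        ))
    out = pd.DataFrame(rows, columns=[
        "model", "mcc", "mcc_ci_low", "mcc_ci_high",
        "sensitivity_foldmean", "specificity_foldmean",
        "sensitivity_pooled", "specificity_pooled", "n",
    ]).set_index("model")
    out["delta_mcc"] = out["mcc"] - out.loc["baseline", "mcc"]
    return out
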