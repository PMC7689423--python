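"""Survival analysis: Kaplan-Meier, log-rank, maxstat cutpoints, Cox PH.

Patient strata defined by a continuous score can be compared either at
the median split or at a data-driven cutpoint chosen by maximally
selected rank statistics: every candidate cutpoint inside the scan
window is scored by the standardized two-sample log-rank statistic and
the maximum is taken.  Because the cutpoint is selected to maximize the
statistic, its p-value must be corrected for selection; the
Miller-Siegmund (1982) improved-Bonferroni approximation

    p ~ phi(b) (b - 1/b) ln[ (1-e_lo)(1-e_hi) / (e_lo e_hi) ] + 4 phi(b)/b

is used, where ``b`` is the maximal standardized statistic and
``e_lo``/``e_hi`` the scan-window quantile fractions.

Kaplan-Meier estimation, plain log-rank tests and (multivariate,
optionally stratified) Cox proportional-hazards fits delegate to
lifelines; the per-gene univariate Cox scan uses an in-package
Newton-Raphson with Efron tie handling for speed and is cross-checked
against lifelines in the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .containers import ExpressionMatrix, ValidationError
from .stats import benjamini_hochberg

log = logging.getLogger(__name__)


def _as_time_event(d: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(d["time"], dtype=float)
    e = np.asarray(d["event"], dtype=int)
    if (t <= 0).any():
        raise ValidationError("non-positive survival times")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("event flags must be 0/1")
    return t, e


# ---------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMEstimate:
    """Product-limit estimate with its risk table."""

    table: pd.DataFrame  # index: time; columns: survival, at_risk, events

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous."""
        times = self.table.index.to_numpy()
        below = times <= t
        if not below.any():
            return 1.0
        return float(self.table["survival"].to_numpy()[below][-1])


def kaplan_meier(d: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier estimate from a (time, event) frame.

    All-censored data yields S(t) = 1 everywhere.
    """
    t, e = _as_time_event(d)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame({
        "survival": surv,
        "at_risk": ev["at_risk"].reindex(surv.index),
        "events": ev["observed"].reindex(surv.index),
    })
    table.index.name = "time"
    return KMEstimate(table)


# ---------------------------------------------------------------------
# Log-rank


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


def logrank_test(
    groups: list[pd.DataFrame], method: str = "asymptotic"
) -> LogrankResult:
    """Unweighted log-rank test across >= 2 groups.

    ``method="asymptotic"`` refers the statistic to chi-square with
    k-1 df (the default, and the only option at realistic sample
    sizes); ``method="permutation"`` enumerates every relabeling of
    the pooled observations into the observed group sizes and returns
    the exact conditional p (small pooled samples only).
    """
    if len(groups) < 2:
        raise ValidationError("log-rank needs >= 2 groups")
    parts = [(g, i) for i, g in enumerate(groups)]
    times, events, labels = [], [], []
    for g, i in parts:
        t, e = _as_time_event(g)
        if t.size == 0:
            raise ValidationError(f"empty group {i}")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValidationError("no events in any group; log-rank undefined")
    res = multivariate_logrank_test(times, labels, events)
    stat = float(res.test_statistic)
    if method == "asymptotic":
        return LogrankResult(stat, len(groups) - 1, float(res.p_value))
    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")
    from .stats import _multiset_splits  # shared enumeration helper

    n = times.size
    sizes = [int((labels == i).sum()) for i in range(len(groups))]
    import math

    n_splits = math.factorial(n)
    for s in sizes:
        n_splits //= math.factorial(s)
    if n_splits > 50_000:
        raise ValidationError(
            f"exact log-rank infeasible: {n_splits} relabelings"
        )
    count = total = 0
    for split in _multiset_splits(tuple(range(n)), sizes):
        lab = np.empty(n, dtype=int)
        for gi, part in enumerate(split):
            lab[list(part)] = gi
        s = float(multivariate_logrank_test(times, lab, events).test_statistic)
        total += 1
        if s >= stat - 1e-12:
            count += 1
    return LogrankResult(stat, len(groups) - 1, count / total)


def pairwise_logrank(
    groups: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Unadjusted pairwise log-rank p for every group pair."""
    rows = []
    for a, b in itertools.combinations(groups, 2):
        res = logrank_test([groups[a], groups[b]])
        rows.append((a, b, res.statistic, res.p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])


# ---------------------------------------------------------------------
# Maximally selected rank statistics


def miller_siegmund_correct(
    b: float, eps_low: float = 0.1, eps_high: float = 0.1
) -> float:
    """Selection-corrected p for a maximally selected statistic ``b``.

    ``eps_low``/``eps_high`` are the scan-window fractions (the cutpoint
    was searched between the eps_low and 1 - eps_high score quantiles).
    The approximation is unstable for b <= 1; 1.0 is returned there.
    """
    if not (0 < eps_low < 1 and 0 < eps_high < 1):
        raise ValidationError("scan fractions must lie in (0, 1)")
    if b <= 1.0:
        log.warning("maxstat statistic b=%.3f <= 1; corrected p set to 1", b)
        return 1.0
    phi = ss.norm.pdf(b)
    span = np.log(((1 - eps_low) * (1 - eps_high)) / (eps_low * eps_high))
    p = phi * (b - 1.0 / b) * span + 4.0 * phi / b
    return float(np.clip(p, 0.0, 1.0))


def _logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-observation log-rank (Nelson-Aalen residual) scores.

    a_i = delta_i - H(t_i) with H the Nelson-Aalen cumulative hazard.
    The two-sample log-rank statistic for any dichotomy is the group sum
    of these scores, which makes an O(n log n) cutpoint scan possible.
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    n = time.size
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    at_risk = n - first_idx
    deaths = np.add.reduceat(e_sorted, first_idx)
    hazard = np.cumsum(deaths / at_risk)
    cumhaz_at = dict(zip(uniq, hazard))
    scores = np.array([event[i] - cumhaz_at[time[i]] for i in range(n)])
    return scores


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float          # max |standardized log-rank statistic| b
    p_corrected: float
    p_pointwise: float        # naive two-sided normal p at the chosen cut
    eps_low: float
    eps_high: float
    scan: pd.DataFrame        # cutpoint candidates with z per candidate


def maxstat_cutpoint(
    score: pd.Series, d: pd.DataFrame, eps: float = 0.1,
    eps_high: float | None = None,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint over the score's quantile window.

    Candidates are observed score values whose Low (<= cut) and High
    (> cut) groups each contain at least ``eps`` (resp. ``eps_high``)
    of the samples.  Ties in |z| break toward the smaller cutpoint.
    """
    eps_high = eps if eps_high is None else eps_high
    common = score.index.intersection(d.index)
    s = score.loc[common].to_numpy(dtype=float)
    t, e = _as_time_event(d.loc[common])
    n = s.size
    if np.ptp(s) == 0:
        raise ValidationError("constant score; no cutpoint exists")
    if e.sum() == 0:
        raise ValidationError("no events; log-rank undefined")
    a = _logrank_scores(t, e)
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    a_sorted = a[order]
    abar = a.mean()
    ssa = ((a - abar) ** 2).sum()
    k = np.arange(1, n)                         # size of the Low group
    cum = np.cumsum(a_sorted)[:-1]
    var = k * (n - k) / (n * (n - 1.0)) * ssa   # permutation variance of S_k
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (cum - k * abar) / np.sqrt(var)
    # a cut between positions k-1 and k is only real when the score changes
    distinct = s_sorted[:-1] < s_sorted[1:]
    lo_ok = k >= max(1, int(np.ceil(eps * n)))
    hi_ok = (n - k) >= max(1, int(np.ceil(eps_high * n)))
    valid = distinct & lo_ok & hi_ok & np.isfinite(z)
    if not valid.any():
        raise ValidationError(
            f"no candidate cutpoint keeps both groups above the "
            f"({eps}, {eps_high}) scan fractions"
        )
    absz = np.abs(z)
    absz[~valid] = -np.inf
    best = int(np.argmax(absz))                 # argmax takes the first = smallest cut
    b = float(absz[best])
    cut = float(s_sorted[best])                 # Low group = scores <= cut
    scan = pd.DataFrame({
        "cutpoint": s_sorted[:-1][valid],
        "z": z[valid],
    })
    p_point = float(2.0 * ss.norm.sf(b))
    return CutpointResult(cut, b, miller_siegmund_correct(b, eps, eps_high),
                          p_point, eps, eps_high, scan)


# ---------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    """Per-covariate hazard ratios from a proportional-hazards fit."""

    table: pd.DataFrame       # index covariate; coef, hr, ci_low, ci_high, se, p
    log_likelihood: float
    strata: str | None = None


def cox_fit(
    covariates: pd.DataFrame, d: pd.DataFrame, strata: str | None = None
) -> CoxResult:
    """Multivariate Cox PH fit (Efron ties, Newton-Raphson, Wald CIs).

    ``covariates`` is indexed by sample id; ``strata`` names one of its
    columns to be used for per-stratum risk sets instead of as a
    regressor.
    """
    common = covariates.index.intersection(d.index)
    df = covariates.loc[common].copy()
    surv = d.loc[common]
    df["time"], df["event"] = surv["time"], surv["event"]
    n_cov = df.shape[1] - 2 - (1 if strata else 0)
    if len(df) <= n_cov:
        raise ValidationError("need more samples than covariates")
    check_cols = [c for c in covariates.columns if c != strata]
    grouped = df.groupby(strata) if strata else [(None, df)]
    for _, part in grouped:
        for c in check_cols:
            if part[c].nunique() <= 1:
                raise ValidationError(
                    f"covariate {c!r} is constant within a stratum"
                )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event", strata=strata)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValidationError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame({
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "ci_low": summ["exp(coef) lower 95%"],
        "ci_high": summ["exp(coef) upper 95%"],
        "se": summ["se(coef)"],
        "p": summ["p"],
    })
    return CoxResult(table, float(cph.log_likelihood_), strata)


# ---------------------------------------------------------------------
# Per-gene univariate Cox scan


def _efron_neg_loglik_and_derivs(
    beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float, float]:
    """Log partial likelihood, gradient and Hessian for one covariate
    (Efron tie handling)."""
    order = np.argsort(time, kind="stable")
    x = x[order]
    t = time[order]
    e = event[order]
    eta = beta * x
    r = np.exp(eta)
    rx = r * x
    rxx = r * x * x
    # suffix sums: risk set = all with time >= t_i
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rx[::-1])[::-1]
    S2 = np.cumsum(rxx[::-1])[::-1]
    ll = grad = hess = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        deaths = np.nonzero(e[i:j])[0] + i
        m = deaths.size
        if m:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            d0 = r[deaths].sum()
            d1 = rx[deaths].sum()
            d2 = rxx[deaths].sum()
            ll += eta[deaths].sum()
            gsum = x[deaths].sum()
            for ell in range(m):
                f = ell / m
                phi0 = s0 - f * d0
                phi1 = s1 - f * d1
                phi2 = s2 - f * d2
                ll -= np.log(phi0)
                grad -= phi1 / phi0
                hess -= phi2 / phi0 - (phi1 / phi0) ** 2
            grad += gsum
        i = j
    return ll, grad, hess


def _univariate_cox(
    x: np.ndarray, time: np.ndarray, event: np.ndarray,
    max_iter: int = 50, tol: float = 1e-9,
) -> tuple[float, float, float]:
    """Newton-Raphson univariate Cox fit: (coef, se, log-likelihood)."""
    beta = 0.0
    for _ in range(max_iter):
        ll, grad, hess = _efron_neg_loglik_and_derivs(beta, x, time, event)
        if hess >= 0:
            raise ValidationError("non-concave partial likelihood")
        step = -grad / hess
        step = float(np.clip(step, -2.0, 2.0))  # damp monotone-likelihood runs
        beta += step
        if abs(step) < tol:
            break
    else:
        raise ValidationError(f"univariate Cox did not converge (beta={beta:.3g})")
    if abs(beta) > 20:
        raise ValidationError("monotone likelihood (complete separation)")
    ll, grad, hess = _efron_neg_loglik_and_derivs(beta, x, time, event)
    se = float(np.sqrt(-1.0 / hess))
    return float(beta), se, float(ll)


def per_gene_cox(
    m: ExpressionMatrix, d: pd.DataFrame, dichotomize: bool = False
) -> pd.DataFrame:
    """Univariate Cox scan: one fit per gene on z-scored expression.

    Returns a frame indexed by gene with coef, hr, ci bounds, p and BH
    q across all successfully fitted genes.  Constant or non-converging
    genes are excluded with a warning and listed via the ``status``
    column.
    """
    if m.state != "normalized":
        raise ValidationError("per-gene Cox expects a normalized matrix")
    common = [s for s in m.sample_ids if s in d.index]
    surv = d.loc[common]
    t, e = _as_time_event(surv)
    rows = []
    for gene in m.gene_ids:
        vals = m.values.loc[gene, common].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan, "constant"))
            continue
        z = (vals - vals.mean()) / vals.std(ddof=0)
        if dichotomize:
            z = (z > np.median(z)).astype(float)
            if np.ptp(z) == 0:
                rows.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan,
                             "constant"))
                continue
        try:
            coef, se, _ = _univariate_cox(z, t, e)
        except ValidationError as exc:
            log.warning("gene %s excluded from Cox scan: %s", gene, exc)
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan, "failed"))
            continue
        p = 2.0 * ss.norm.sf(abs(coef / se))
        rows.append((gene, coef, np.exp(coef), np.exp(coef - 1.96 * se),
                     np.exp(coef + 1.96 * se), p, "ok"))
    out = pd.DataFrame(
        rows, columns=["gene", "coef", "hr", "ci_low", "ci_high", "p", "status"]
    ).set_index("gene")
    ok = out["status"] == "ok"
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    n_bad = (~ok).sum()
    if n_bad:
        log.warning("%d gene(s) excluded from the Cox scan FDR", n_bad)
    return out
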