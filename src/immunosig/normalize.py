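"""NanoString-style count normalization and RNA-seq-mode quantile normalization.

The NanoString chain runs in a fixed order:

1. positive-control normalization — per-sample scaling so the geometric
   mean of the positive spike-in probes is constant across the run
   (corrects technical assay variation);
2. background subtraction — per-sample threshold = mean + 2 SD of the
   negative probes, subtracted and floored at zero;
3. housekeeping normalization — per-sample scaling by the geometric
   mean of the housekeeping genes (corrects RNA content);
4. log2(x + 1) transform.

Each scaling step multiplies sample ``s`` by
``factor_s = mean_over_samples(geomean) / geomean_s`` so the average
sample is left roughly unchanged.  The quantile normalizer equalizes
the per-sample value distributions by mapping each sample's order
statistics onto their across-sample means, ties sharing the mean
reference value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class NormalizationReport:
    """Per-sample factors and thresholds produced by the NanoString chain."""

    positive_factor: pd.Series | None = None
    background_threshold: pd.Series | None = None
    content_factor: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        if self.positive_factor is not None:
            cols["positive_factor"] = self.positive_factor
        if self.background_threshold is not None:
            cols["background_threshold"] = self.background_threshold
        if self.content_factor is not None:
            cols["content_factor"] = self.content_factor
        return pd.DataFrame(cols)


def _geomean(values: pd.DataFrame) -> pd.Series:
    """Column-wise geometric mean; zero/negative entries are an error."""
    arr = values.to_numpy(dtype=float)
    if (arr <= 0).any():
        bad = values.columns[(arr <= 0).any(axis=0)]
        raise ValidationError(
            f"geometric mean undefined (non-positive counts) in sample(s) "
            f"{list(bad)}"
        )
    return pd.Series(np.exp(np.log(arr).mean(axis=0)), index=values.columns)


def _scaling_factors(geomeans: pd.Series) -> pd.Series:
    return geomeans.mean() / geomeans


def positive_control_normalize(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Scale each sample so positive-control geometric means agree.

    Returns the scaled matrix and per-sample factors
    ``mean_s(geomean) / geomean_s``.
    """
    if m.state != "raw":
        raise ValidationError("positive-control normalization requires raw counts")
    positives = m.genes_of_class("positive")
    if not positives:
        raise ValidationError("no positive-control probes")
    factors = _scaling_factors(_geomean(m.values.loc[positives]))
    out = m.copy()
    out.values = out.values.mul(factors, axis=1)
    return out, factors


def subtract_background(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Subtract the per-sample negative-probe background, flooring at zero.

    Threshold = mean + 2 * SD (sample SD, n-1 denominator) of the
    negative probes; applied to endogenous and housekeeping probes only.
    """
    if m.state != "raw":
        raise ValidationError("background subtraction requires raw counts")
    negatives = m.genes_of_class("negative")
    if len(negatives) < 2:
        raise ValidationError("need >= 2 negative probes for a background SD")
    neg = m.values.loc[negatives]
    thresholds = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    out = m.copy()
    targets = out.genes_of_class("endogenous") + out.genes_of_class("housekeeping")
    sub = out.values.loc[targets].sub(thresholds, axis=1).clip(lower=0.0)
    out.values.loc[targets] = sub
    zero_rows = sub.index[(sub.to_numpy() == 0).all(axis=1)]
    if len(zero_rows):
        log.warning(
            "%d gene(s) entirely below background after subtraction", len(zero_rows)
        )
    return out, thresholds


def housekeeping_normalize(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Scale endogenous probes by the housekeeping geometric-mean factor."""
    if m.state != "raw":
        raise ValidationError("housekeeping normalization requires raw-scale counts")
    hks = m.genes_of_class("housekeeping")
    if not hks:
        raise ValidationError("no housekeeping probes")
    hk = m.values.loc[hks]
    arr = hk.to_numpy()
    # flag samples whose housekeeping geomean collapses to zero by name
    with np.errstate(divide="ignore"):
        gm = np.exp(np.where((arr <= 0).any(axis=0), -np.inf,
                             np.log(np.clip(arr, 1e-300, None)).mean(axis=0)))
    zero = [s for s, g in zip(hk.columns, gm) if g <= 0]
    if zero:
        raise ValidationError(f"housekeeping geometric mean is 0 in sample(s) {zero}")
    factors = _scaling_factors(pd.Series(gm, index=hk.columns))
    out = m.copy()
    endo = out.genes_of_class("endogenous")
    out.values.loc[endo] = out.values.loc[endo].mul(factors, axis=1)
    return out, factors


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform; flips the state to ``normalized``."""
    if m.state == "normalized":
        raise ValidationError("matrix already normalized (double transform)")
    out = m.copy()
    out.values = np.log2(out.values + 1.0)
    out.state = "normalized"
    return out


def nanostring_normalize(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Run the full chain: positive -> background -> housekeeping -> log2.

    Returns the normalized endogenous-probe matrix and a report with the
    per-sample factors.  The order is fixed; on a run with unit lane
    effects and zero background the chain reduces to plain log2(x + 1).
    """
    report = NormalizationReport()
    m, report.positive_factor = positive_control_normalize(m)
    m, report.background_threshold = subtract_background(m)
    m, report.content_factor = housekeeping_normalize(m)
    m = log2_transform(m)
    endo = m.genes_of_class("endogenous")
    return m.subset_genes(endo), report


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Equalize per-sample distributions (limma-style quantile normalization).

    Every sample's sorted values are replaced by the across-sample mean
    of the order statistics; tied values within a sample receive the
    mean of their reference quantiles.  Afterwards every column holds
    the same multiset of values.
    """
    if m.n_samples < 2:
        log.warning("quantile normalization skipped: single sample")
        return m.copy()
    vals = m.values.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, len(ref) + 1), ref)
    res = m.copy()
    res.values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return res
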