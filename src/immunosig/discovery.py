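"""Three-filter discovery of marker-associated prognostic gene signatures.

Starting from a marker gene dichotomy (e.g. THBD or NCR1 High vs Low),
candidate genes pass three successive filters:

1. **association** — differentially expressed between the marker strata
   (linear fold change > 2 or < -2, and BH q < 0.05 *or* raw p < 0.05);
2. **prognosis** — significant univariate Cox hazard (HR < 1 protective
   or HR > 1 risky, FDR < 0.05) on a survival cohort;
3. **cell-type specificity** — predominantly expressed by the target
   cell types (DC and/or NK) in a cell-type expression atlas:
   the gene's expression in some target type must reach at least
   ``fold`` times its median across all cell types *and* that type must
   rank in the gene's top ``top_k`` cell types.

The surviving genes form a :class:`DiscoveredSignature`; its per-sample
score is the mean log2 expression of the constituent genes, and the
combination of two signatures stratifies patients into four groups for
survival comparison.  ``cv_survival_validation`` checks the robustness
of a signature's prognostic value by repeated k-fold splitting with a
maxstat cutpoint and Miller-Siegmund-corrected log-rank on every
held-out fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError
from .signatures import GeneSignature, StratumLabels, median_split
from .stats import benjamini_hochberg, wilcoxon_rank_sum
from .survival import logrank_test, maxstat_cutpoint, per_gene_cox

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# Filter 1: marker-association (differential expression)


def differential_expression(
    m: ExpressionMatrix, labels: StratumLabels
) -> pd.DataFrame:
    """Per-gene High-vs-Low differential expression.

    log2FC = mean(High) - mean(Low); p from the two-sided Wilcoxon
    rank-sum test; q by Benjamini-Hochberg across genes.  Strata of
    size < 3 trigger a low-power warning (the exact test is used there
    automatically).
    """
    if m.state != "normalized":
        raise ValidationError("differential expression expects log2 values")
    high = [s for s in labels.high if s in m.values.columns]
    low = [s for s in labels.low if s in m.values.columns]
    if not high or not low:
        raise ValidationError("both strata must be non-empty")
    if min(len(high), len(low)) < 3:
        log.warning("stratum of size < 3: exact test, low power")
    hi = m.values[high]
    lo = m.values[low]
    log2fc = hi.mean(axis=1) - lo.mean(axis=1)
    pvals = np.array([
        wilcoxon_rank_sum(hi.loc[g], lo.loc[g])[1] for g in m.gene_ids
    ])
    out = pd.DataFrame({
        "log2fc": log2fc,
        "fc": np.power(2.0, log2fc),
        "p": pvals,
        "q": benjamini_hochberg(pvals),
    })
    out["direction"] = "ns"
    out.loc[(out["log2fc"] > 1), "direction"] = "up"
    out.loc[(out["log2fc"] < -1), "direction"] = "down"
    return out


def select_marker_associated(
    de: pd.DataFrame, fc_threshold: float = 2.0, alpha: float = 0.05
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Apply the fold-change + (q or p) filter.

    up   = linear FC > ``fc_threshold``  and (q < alpha or p < alpha)
    down = linear FC < 1/``fc_threshold`` and the same significance rule

    Returns (up, down, report); the report records which criterion (q,
    p, or both) admitted each selected gene — the disjunction is
    permissive, so the admitting route is kept visible.
    """
    sig_q = de["q"] < alpha
    sig_p = de["p"] < alpha
    sig = sig_q | sig_p
    up_mask = (de["fc"] > fc_threshold) & sig
    down_mask = (de["fc"] < 1.0 / fc_threshold) & sig
    report = de.loc[up_mask | down_mask].copy()
    report["admitted_by"] = np.where(
        sig_q.loc[report.index] & sig_p.loc[report.index], "both",
        np.where(sig_q.loc[report.index], "q", "p"),
    )
    report["direction"] = np.where(up_mask.loc[report.index], "up", "down")
    return list(de.index[up_mask]), list(de.index[down_mask]), report


# ---------------------------------------------------------------------
# Filter 2: prognostic value


def prognostic_filter(
    genes: list[str], cox_table: pd.DataFrame, fdr: float = 0.05
) -> tuple[list[str], list[str], list[str]]:
    """Split genes into protective (HR < 1), risky (HR > 1) at FDR.

    Returns (protective, risky, discarded); genes absent from the Cox
    table are reported among the discarded, not fatal.
    """
    protective, risky, discarded = [], [], []
    for g in genes:
        if g not in cox_table.index or not np.isfinite(cox_table.loc[g, "hr"]):
            log.warning("gene %s missing from Cox table", g)
            discarded.append(g)
            continue
        hr, q = cox_table.loc[g, "hr"], cox_table.loc[g, "q"]
        if q < fdr and hr < 1.0:
            protective.append(g)
        elif q < fdr and hr > 1.0:
            risky.append(g)
        else:
            discarded.append(g)
    return protective, risky, discarded


# ---------------------------------------------------------------------
# Filter 3: cell-type specificity


def cell_atlas_filter(
    genes: list[str], atlas: pd.DataFrame,
    targets: tuple[str, ...] = ("DC", "NK"),
    fold: float = 2.0, top_k: int = 3,
) -> tuple[dict[str, list[str]], list[str]]:
    """Keep genes predominantly expressed by the target cell types.

    A gene passes for target type ``t`` when expression(t, gene) is at
    least ``fold`` times the gene's median across all cell types and
    ``t`` is among the gene's ``top_k`` highest-expressing cell types.
    Returns (annotation: gene -> passing target types, uncovered genes).
    """
    missing_targets = [t for t in targets if t not in atlas.index]
    if missing_targets:
        raise ValidationError(f"atlas lacks target cell types {missing_targets}")
    annotation: dict[str, list[str]] = {}
    uncovered: list[str] = []
    for g in genes:
        if g not in atlas.columns:
            uncovered.append(g)
            continue
        col = atlas[g]
        med = float(col.median())
        top = list(col.sort_values(ascending=False).index[:top_k])
        passing = [t for t in targets
                   if col[t] >= fold * med and col[t] > 0 and t in top]
        if passing:
            annotation[g] = passing
    if uncovered:
        log.warning("%d gene(s) not covered by the atlas", len(uncovered))
    return annotation, uncovered


# ---------------------------------------------------------------------
# Assembled discovery


@dataclass
class DiscoveredSignature:
    """A marker-anchored signature with per-gene role annotation."""

    marker: str
    protective: list[str]
    risky: list[str]
    cell_types: dict[str, list[str]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return [self.marker] + [g for g in self.protective + self.risky
                                if g != self.marker]

    def as_signature(self, cell_type: str) -> GeneSignature:
        return GeneSignature(f"{self.marker}_signature", cell_type, self.genes)


def discover_signature(
    m: ExpressionMatrix,
    d: pd.DataFrame,
    marker: str,
    atlas: pd.DataFrame,
    targets: tuple[str, ...] = ("DC", "NK"),
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    fdr: float = 0.05,
    atlas_fold: float = 2.0,
    atlas_top_k: int = 3,
    cox_table: pd.DataFrame | None = None,
) -> tuple[DiscoveredSignature, pd.DataFrame]:
    """Run the full three-filter pipeline for one marker gene.

    ``m`` is the discovery expression matrix, ``d`` the (time, event)
    frame of the survival cohort (``cox_table`` may supply a
    precomputed per-gene Cox scan, e.g. from a different cohort).
    Returns the signature plus a per-gene report across all filters.
    Risky genes (HR > 1) are retained in the signature and annotated,
    not excluded.
    """
    if marker not in m.values.index:
        raise ValidationError(f"marker {marker!r} absent from matrix")
    labels = median_split(m.values.loc[marker], variable=marker)
    de = differential_expression(m, labels)
    de = de.drop(index=marker)  # the marker defines the split; exclude it
    up, down, assoc_report = select_marker_associated(de, fc_threshold, alpha)
    candidates = up + down
    if cox_table is None:
        cox_table = per_gene_cox(m, d)
    protective, risky, discarded = prognostic_filter(candidates, cox_table, fdr)
    annotation, uncovered = cell_atlas_filter(
        protective + risky, atlas, targets, atlas_fold, atlas_top_k
    )
    # the specificity filter prunes protective genes only; risky genes are
    # retained with their (typically negative) atlas verdict as annotation
    final_protective = [g for g in protective if g in annotation]
    final_risky = list(risky)
    report = de.copy()
    report["marker_associated"] = report.index.isin(candidates)
    report["hr"] = cox_table["hr"].reindex(report.index)
    report["cox_q"] = cox_table["q"].reindex(report.index)
    report["prognostic"] = report.index.isin(protective + risky)
    report["atlas_types"] = [
        ",".join(annotation.get(g, [])) for g in report.index
    ]
    report["in_signature"] = report.index.isin(final_protective + final_risky)
    sig = DiscoveredSignature(marker, final_protective, final_risky, annotation)
    return sig, report


def discovered_signature_score(
    m: ExpressionMatrix, sig: DiscoveredSignature | GeneSignature
) -> pd.Series:
    """Mean log2 expression of the signature's genes per sample."""
    from .signatures import metagene_score

    genes = sig.genes if isinstance(sig, DiscoveredSignature) else sig.genes
    gs = GeneSignature("discovered", "mixed", genes)
    return metagene_score(m, gs).scores


def signature_subscores(
    m: ExpressionMatrix, sig: DiscoveredSignature
) -> pd.DataFrame:
    """Sign-aware per-sample sub-scores of a mixed-sign signature.

    A discovered signature can mix protective (HR < 1) and risky
    (HR > 1) genes; averaging them into one score cancels opposing
    signals, so outcome models receive the protective and risky means
    as separate columns (the risky column is absent when the signature
    has no risky genes).
    """
    out = {}
    prot = [g for g in sig.protective if g in m.values.index]
    if prot:
        out["protective"] = m.values.loc[prot].mean()
    risky = [g for g in sig.risky if g in m.values.index]
    if risky:
        out["risky"] = m.values.loc[risky].mean()
    if not out:
        raise ValidationError("no signature genes present in matrix")
    return pd.DataFrame(out)


def combined_survival(
    labels4: pd.Series, d: pd.DataFrame, min_group: int = 5
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Log-rank comparison across 4-level combined strata.

    Levels with fewer than ``min_group`` samples are omitted with a
    logged note.  Returns (pairwise log-rank table, per-level survival
    frames).
    """
    from .survival import pairwise_logrank

    groups: dict[str, pd.DataFrame] = {}
    for level, idx in labels4.groupby(labels4).groups.items():
        members = [s for s in idx if s in d.index]
        if len(members) < min_group:
            log.info("omitting combined stratum %s (n=%d < %d)",
                     level, len(members), min_group)
            continue
        groups[str(level)] = d.loc[members]
    if len(groups) < 2:
        raise ValidationError("fewer than two usable combined strata")
    return pairwise_logrank(groups), groups


# ---------------------------------------------------------------------
# Cross-validated survival validation


@dataclass
class CVSurvivalResult:
    significant_fraction: float
    folds: pd.DataFrame    # repeat, fold, n, events, cutpoint, b, p_corrected
    n_evaluable: int


def cv_survival_validation(
    score: pd.Series, d: pd.DataFrame, k: int = 5, repeats: int = 10,
    seed: int = 0, eps: float = 0.1, alpha: float = 0.05,
) -> CVSurvivalResult:
    """Repeated k-fold held-out survival validation of a score.

    Each held-out fold gets its own maxstat cutpoint and a Miller-
    Siegmund-corrected log-rank p; the returned fraction counts folds
    with corrected p < ``alpha`` among evaluable folds (a fold with no
    events, a constant score or no admissible cutpoint is recorded as
    non-evaluable and excluded from the denominator).
    """
    common = score.index.intersection(d.index)
    ids = np.array(common)
    n = ids.size
    if n < 5 * k:
        raise ValidationError(f"need at least {5 * k} samples for {k}-fold CV")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fi, fold_idx in enumerate(folds):
            fold_ids = ids[fold_idx]
            sub_s = score.loc[fold_ids]
            sub_d = d.loc[fold_ids]
            events = int(sub_d["event"].sum())
            try:
                cp = maxstat_cutpoint(sub_s, sub_d, eps=eps)
                rows.append((rep, fi, len(fold_ids), events, cp.cutpoint,
                             cp.statistic, cp.p_corrected, True))
            except ValidationError as exc:
                log.info("fold %d.%d non-evaluable: %s", rep, fi, exc)
                rows.append((rep, fi, len(fold_ids), events, np.nan,
                             np.nan, np.nan, False))
    table = pd.DataFrame(rows, columns=[
        "repeat", "fold", "n", "events", "cutpoint", "b", "p_corrected",
        "evaluable",
    ])
    ev = table[table["evaluable"]]
    frac = float((ev["p_corrected"] < alpha).mean()) if len(ev) else float("nan")
    return CVSurvivalResult(frac, table, int(len(ev)))
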