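"""Immune cell-type gene signatures, metagene scoring and median-split strata.

A metagene score summarizes an immune cell type's abundance in a bulk
sample as the mean log2 expression of the signature's constituent genes
(equivalently, the log2 of the geometric mean on the linear scale).
Scores and single-marker genes are dichotomized at the cohort median
into High/Low strata for downstream survival comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set attributed to an immune cell type."""

    name: str
    cell_type: str
    genes: tuple[str, ...]

    def __init__(self, name: str, cell_type: str, genes) -> None:
        genes = tuple(genes)
        if not genes:
            raise ValidationError(f"signature {name!r} has no genes")
        if len(set(genes)) != len(genes):
            raise ValidationError(f"signature {name!r} has duplicate genes")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "cell_type", cell_type)
        object.__setattr__(self, "genes", genes)


def packaged_signature(which: str) -> GeneSignature:
    """Load a packaged discovery signature: ``"DC"`` (16 genes, THBD-
    associated) or ``"NK"`` (8 genes, NCR1-associated)."""
    from . import io as _io

    name = {"DC": "dc_signature.json", "NK": "nk_signature.json"}.get(which.upper())
    if name is None:
        raise ValidationError(f"no packaged signature {which!r}")
    with resources.as_file(resources.files("immunosig.data") / name) as p:
        return _io.read_signature(p)


@dataclass
class MetageneScores:
    """Per-sample metagene scores plus gene-coverage bookkeeping."""

    signature: str
    scores: pd.Series
    genes_used: list[str]
    genes_missing: list[str]


def metagene_score(
    m: ExpressionMatrix, sig: GeneSignature, missing_policy: str = "skip"
) -> MetageneScores:
    """Mean log2 expression of the signature genes per sample.

    Signature genes absent from the matrix are skipped and reported
    (``missing_policy="skip"``) or raise (``missing_policy="error"``).
    """
    if m.state != "normalized":
        raise ValidationError("metagene scores require a normalized matrix")
    present = [g for g in sig.genes if g in m.values.index]
    missing = [g for g in sig.genes if g not in m.values.index]
    if not present:
        raise ValidationError(
            f"no signature genes present in matrix; requested {list(sig.genes)}"
        )
    if missing and missing_policy == "error":
        raise ValidationError(f"signature genes missing from matrix: {missing}")
    if missing:
        log.info("signature %s: %d/%d genes absent, skipped",
                 sig.name, len(missing), len(sig.genes))
    scores = m.values.loc[present].mean(axis=0)
    return MetageneScores(sig.name, scores, present, missing)


@dataclass
class StratumLabels:
    """High/Low labels from a median (or explicit-threshold) split."""

    labels: pd.Series          # values in {"High", "Low"}
    variable: str
    threshold: float

    @property
    def high(self) -> list[str]:
        return list(self.labels.index[self.labels == "High"])

    @property
    def low(self) -> list[str]:
        return list(self.labels.index[self.labels == "Low"])


def median_split(values: pd.Series, variable: str = "score") -> StratumLabels:
    """Split at the median: strictly above -> High, at or below -> Low."""
    if len(values) < 2:
        raise ValidationError("median split needs >= 2 samples")
    v = values.astype(float)
    if v.nunique() == 1:
        raise ValidationError(f"cannot split constant variable {variable!r}")
    thr = float(v.median())
    labels = pd.Series(np.where(v > thr, "High", "Low"), index=v.index)
    if (labels == "High").sum() == 0:
        # pathological tie mass at the maximum; split strictly below instead
        labels = pd.Series(np.where(v >= v.max(), "High", "Low"), index=v.index)
        log.warning("median tie mass at maximum for %s; used >= max rule", variable)
    return StratumLabels(labels, variable, thr)


def threshold_split(
    values: pd.Series, threshold: float, variable: str = "score"
) -> StratumLabels:
    """Split at an explicit cutpoint (e.g. a maxstat-selected one)."""
    v = values.astype(float)
    labels = pd.Series(np.where(v > threshold, "High", "Low"), index=v.index)
    return StratumLabels(labels, variable, float(threshold))


def combined_stratify(a: StratumLabels, b: StratumLabels) -> pd.Series:
    """Four-level labels (``Hi/Hi`` .. ``Lo/Lo``) from two binary strata."""
    common = a.labels.index.intersection(b.labels.index)
    la = a.labels.loc[common].map({"High": "Hi", "Low": "Lo"})
    lb = b.labels.loc[common].map({"High": "Hi", "Low": "Lo"})
    return la.str.cat(lb, sep="/")
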