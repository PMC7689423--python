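"""Core in-memory containers for expression and clinical data.

The two central objects are :class:`ExpressionMatrix` (genes x samples,
raw counts or normalized log2 values, with per-gene probe-class labels
for NanoString-style panels) and :class:`ClinicalTable` (per-sample
survival endpoints, risk covariates and optional immunohistochemistry
cell densities).  Both are thin, validated wrappers around pandas
objects so that every downstream stage can rely on their invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed probe classes on a NanoString-style panel.
PROBE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")

#: Allowed matrix states.
STATES = ("raw", "normalized")

#: Valid International Neuroblastoma Risk Group stage labels.
INRG_STAGES = ("L1", "L2", "M", "MS")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
        Non-negative counts in ``raw`` state, real log2 units in
        ``normalized`` state.
    probe_class
        Optional per-gene label in :data:`PROBE_CLASSES`.  Required for
        NanoString-mode normalization; ``None`` for RNA-seq-mode input.
    state
        ``"raw"`` or ``"normalized"``.
    """

    values: pd.DataFrame
    probe_class: pd.Series | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite expression values")
        if self.state == "raw" and (vals < 0).any():
            bad = self.values.index[(vals < 0).any(axis=1)][0]
            raise ValidationError(f"negative raw count in gene {bad!r}")
        if self.probe_class is not None:
            pc = self.probe_class.reindex(idx)
            if pc.isna().any():
                missing = sorted(idx[pc.isna()])
                raise ValidationError(f"probe_class missing for genes: {missing}")
            unknown = set(pc.unique()) - set(PROBE_CLASSES)
            if unknown:
                raise ValidationError(f"unknown probe classes: {sorted(unknown)}")
            self.probe_class = pc

    # -- accessors -----------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def genes_of_class(self, probe_class: str) -> list[str]:
        """Gene ids carrying the given probe-class label."""
        if self.probe_class is None:
            raise ValidationError("matrix has no probe_class annotation")
        if probe_class not in PROBE_CLASSES:
            raise ValidationError(f"unknown probe class {probe_class!r}")
        return list(self.probe_class.index[self.probe_class == probe_class])

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        pc = self.probe_class.loc[genes] if self.probe_class is not None else None
        return ExpressionMatrix(self.values.loc[genes].copy(), pc, self.state)

    def copy(self) -> "ExpressionMatrix":
        pc = self.probe_class.copy() if self.probe_class is not None else None
        return ExpressionMatrix(self.values.copy(), pc, self.state)


# Required clinical columns and their value constraints.
_SURVIVAL_COLS = ("os_time", "os_event")
_OPTIONAL_COLS = (
    "efs_time",
    "efs_event",
    "mycn_amplified",
    "age_months",
    "inrg_stage",
    "high_risk",
)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation.

    Required columns: ``os_time`` (days, > 0) and ``os_event`` ({0,1}).
    Optional: ``efs_time``/``efs_event``, ``mycn_amplified``,
    ``age_months``, ``inrg_stage`` (L1/L2/M/MS), ``high_risk`` and any
    number of ``*_density`` columns (cells per mm^2, >= 0).  Missing
    optional values stay missing (NaN); nothing is imputed.
    """

    table: pd.DataFrame = field()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dupes = sorted(t.index[t.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dupes}")
        for col in _SURVIVAL_COLS:
            if col not in t.columns:
                raise ValidationError(f"missing required column {col!r}")
        for time_col, event_col in (("os_time", "os_event"), ("efs_time", "efs_event")):
            if time_col not in t.columns:
                continue
            times = t[time_col]
            present = times.notna()
            if (times[present] <= 0).any():
                rows = [int(i) for i in np.where(present & (times <= 0))[0]]
                raise ValidationError(
                    f"non-positive {time_col} at row index(es) {rows}"
                )
            events = t[event_col][present]
            if not events.isin([0, 1]).all():
                rows = list(np.where(~t[event_col].isin([0, 1]) & present)[0])
                raise ValidationError(f"{event_col} outside {{0,1}} at row(s) {rows}")
        for col in ("mycn_amplified", "high_risk"):
            if col in t.columns:
                vals = t[col].dropna()
                if not vals.isin([0, 1]).all():
                    raise ValidationError(f"{col} must be 0/1/missing")
        if "inrg_stage" in t.columns:
            vals = t["inrg_stage"].dropna()
            unknown = set(vals.unique()) - set(INRG_STAGES)
            if unknown:
                raise ValidationError(f"unknown INRG stages: {sorted(unknown)}")
        for col in self.density_columns:
            vals = t[col].dropna()
            if (vals < 0).any():
                raise ValidationError(f"negative density in column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def density_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.endswith("_density")]

    def survival(self, endpoint: str = "OS") -> pd.DataFrame:
        """Aligned (time, event) frame for the requested endpoint.

        Rows with a missing time or event flag are dropped.
        """
        endpoint = endpoint.upper()
        if endpoint == "OS":
            cols = ["os_time", "os_event"]
        elif endpoint == "EFS":
            cols = ["efs_time", "efs_event"]
        else:
            raise ValidationError(f"unknown endpoint {endpoint!r}")
        if cols[0] not in self.table.columns:
            raise ValidationError(f"endpoint {endpoint} not present")
        d = self.table[cols].dropna()
        d.columns = ["time", "event"]
        return d

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(self.table.copy())
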