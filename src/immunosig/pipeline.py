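"""Pipeline orchestration: config, stage execution, reproducible reports.

A :class:`PipelineConfig` (YAML file, flat keys under nested sections;
CLI flags override) names the inputs and the stages to run.  Stages
execute in the fixed order normalize -> score -> stratify -> survival
-> discover -> evaluate; each emits TSV outputs whose header comment
records the config hash, root seed and package version, so identical
config + seed yields byte-identical bundles.  All randomness flows
from the single root seed through named per-stage substreams: adding a
stage never perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ClinicalTable, ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)

STAGES = ("normalize", "score", "stratify", "survival", "discover", "evaluate")


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration."""

    expression: str = ""
    clinical: str = ""
    atlas: str = ""
    signatures: list[str] = field(default_factory=list)
    mode: str = "rnaseq"              # nanostring | rnaseq
    stratification: str = "median"    # median | scan
    endpoint: str = "OS"              # OS | EFS
    markers: list[str] = field(default_factory=lambda: ["THBD", "NCR1"])
    fc_threshold: float = 2.0
    alpha: float = 0.05
    fdr: float = 0.05
    atlas_fold: float = 2.0
    atlas_top_k: int = 3
    scan_eps: float = 0.1
    cv_k: int = 5
    cv_repeats: int = 10
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    outdir: str = "immunosig_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        flat.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**flat)

    def validate_paths(self) -> None:
        for name in ("expression", "clinical"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ValidationError(f"{name} file not found: {p}")
        if "discover" in self.stages and self.atlas and not Path(self.atlas).exists():
            raise ValidationError(f"atlas file not found: {self.atlas}")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stage(s): {bad}")

    def digest(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        payload = {k: v for k, v in self.__dict__.items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Per-stage substream seed derived from the root seed."""
        return int(
            np.random.SeedSequence(
                [self.seed, zlib.crc32(stage.encode())]
            ).generate_state(1)[0] % (2 ** 31)
        )


class PipelineRunner:
    """Executes enabled stages and writes the report bundle."""

    def __init__(self, cfg: PipelineConfig):
        cfg.validate_paths()
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._header = (
            f"# immunosig v{__version__} config={cfg.digest()} seed={cfg.seed}\n"
        )

    # -- helpers -------------------------------------------------------

    def _write(self, df: pd.DataFrame, name: str, index_label: str) -> Path:
        path = self.outdir / name
        tmp = path.with_suffix(path.suffix + ".partial")
        with open(tmp, "w") as fh:
            fh.write(self._header)
            df.to_csv(fh, sep="\t", index_label=index_label)
        tmp.rename(path)
        return path

    # -- stages --------------------------------------------------------

    def run(self) -> dict[str, list[str]]:
        from . import io as _io

        outputs: dict[str, list[str]] = {}
        expr = _io.read_expression(self.cfg.expression)
        clinical = _io.read_clinical(self.cfg.clinical)
        state: dict = {"expr": expr, "clinical": clinical}
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            log.info("stage %s: starting", stage)
            try:
                produced = getattr(self, f"_stage_{stage}")(state)
            except Exception as exc:
                raise ValidationError(f"stage {stage!r} failed: {exc}") from exc
            outputs[stage] = [str(p) for p in produced]
            log.info("stage %s: wrote %s", stage, outputs[stage])
        return outputs

    def _stage_normalize(self, state: dict) -> list[Path]:
        from . import io as _io
        from .normalize import nanostring_normalize, quantile_normalize

        expr = state["expr"]
        produced = []
        if self.cfg.mode == "nanostring":
            expr, report = nanostring_normalize(expr)
            produced.append(self._write(report.to_frame(),
                                        "normalization_report.tsv", "sample_id"))
        else:
            if expr.state == "raw":
                from .normalize import log2_transform

                expr = log2_transform(expr)
            expr = quantile_normalize(expr)
        state["expr"] = expr
        path = self.outdir / "expression_normalized.tsv"
        _io.write_expression(expr, path)
        produced.append(path)
        return produced

    def _stage_score(self, state: dict) -> list[Path]:
        from . import io as _io
        from .signatures import metagene_score, packaged_signature

        sigs = [_io.read_signature(p) for p in self.cfg.signatures]
        if not sigs:
            sigs = [packaged_signature("DC"), packaged_signature("NK")]
        scores = {}
        for sig in sigs:
            scores[sig.name] = metagene_score(state["expr"], sig).scores
        table = pd.DataFrame(scores)
        state["scores"] = table
        return [self._write(table, "metagene_scores.tsv", "sample_id")]

    def _stage_stratify(self, state: dict) -> list[Path]:
        from .signatures import median_split, threshold_split
        from .survival import maxstat_cutpoint

        expr = state["expr"]
        clinical = state["clinical"]
        d = clinical.survival(self.cfg.endpoint)
        strata = {}
        meta = []
        variables = {m: expr.values.loc[m] for m in self.cfg.markers
                     if m in expr.values.index}
        variables.update(state.get("scores", pd.DataFrame()).to_dict("series"))
        for name, values in variables.items():
            if self.cfg.stratification == "scan":
                cp = maxstat_cutpoint(values, d, eps=self.cfg.scan_eps)
                labels = threshold_split(values, cp.cutpoint, name)
                meta.append((name, "scan", cp.cutpoint, cp.p_corrected))
            else:
                labels = median_split(values, name)
                meta.append((name, "median", labels.threshold, np.nan))
            strata[name] = labels
        state["strata"] = strata
        table = pd.DataFrame({n: s.labels for n, s in strata.items()})
        out1 = self._write(table, "strata.tsv", "sample_id")
        meta_df = pd.DataFrame(
            meta, columns=["variable", "mode", "threshold", "scan_p_corrected"]
        ).set_index("variable")
        out2 = self._write(meta_df, "strata_meta.tsv", "variable")
        return [out1, out2]

    def _stage_survival(self, state: dict) -> list[Path]:
        from .survival import kaplan_meier, logrank_test

        clinical = state["clinical"]
        d = clinical.survival(self.cfg.endpoint)
        produced = []
        rows = []
        for name, labels in state.get("strata", {}).items():
            groups = {}
            for level in ("High", "Low"):
                members = [s for s in labels.labels.index[labels.labels == level]
                           if s in d.index]
                if members:
                    groups[level] = d.loc[members]
            if len(groups) < 2:
                continue
            res = logrank_test(list(groups.values()))
            rows.append((name, self.cfg.endpoint, res.statistic, res.df, res.p))
            for level, dd in groups.items():
                km = kaplan_meier(dd)
                produced.append(self._write(
                    km.table, f"km_{name}_{level}.tsv", "time"))
        table = pd.DataFrame(
            rows, columns=["variable", "endpoint", "chi_square", "df", "p"]
        ).set_index("variable")
        produced.append(self._write(table, "logrank_tests.tsv", "variable"))
        return produced

    def _stage_discover(self, state: dict) -> list[Path]:
        from . import io as _io
        from .discovery import discover_signature

        if not self.cfg.atlas:
            raise ValidationError("discovery requires an atlas file")
        atlas = _io.read_cell_atlas(self.cfg.atlas)
        clinical = state["clinical"]
        d = clinical.survival(self.cfg.endpoint)
        produced = []
        state["discovered"] = {}
        for marker in self.cfg.markers:
            sig, report = discover_signature(
                state["expr"], d, marker, atlas,
                fc_threshold=self.cfg.fc_threshold, alpha=self.cfg.alpha,
                fdr=self.cfg.fdr, atlas_fold=self.cfg.atlas_fold,
                atlas_top_k=self.cfg.atlas_top_k,
            )
            state["discovered"][marker] = sig
            produced.append(self._write(
                report, f"discovery_{marker}.tsv", "gene"))
            sig_path = self.outdir / f"signature_{marker}.json"
            _io.write_signature(sig.as_signature("mixed"), sig_path)
            produced.append(sig_path)
        return produced

    def _stage_evaluate(self, state: dict) -> list[Path]:
        from .discovery import (cv_survival_validation,
                                discovered_signature_score,
                                signature_subscores)
        from .evaluation import prognostic_improvement

        expr = state["expr"]
        clinical = state["clinical"]
        d = clinical.survival(self.cfg.endpoint)
        produced = []
        rows = []
        scores_for_outcome: dict[str, pd.DataFrame] = {}
        for marker, sig in state.get("discovered", {}).items():
            score = discovered_signature_score(expr, sig)
            cv = cv_survival_validation(
                score, d, k=self.cfg.cv_k, repeats=self.cfg.cv_repeats,
                seed=self.cfg.stage_seed(f"cv:{marker}"), eps=self.cfg.scan_eps,
            )
            rows.append((marker, cv.significant_fraction, cv.n_evaluable))
            produced.append(self._write(
                cv.folds, f"cv_survival_{marker}.tsv", "row"))
            scores_for_outcome[marker] = signature_subscores(expr, sig)
        if rows:
            table = pd.DataFrame(
                rows, columns=["marker", "significant_fraction", "n_evaluable"]
            ).set_index("marker")
            produced.append(self._write(table, "cv_survival_summary.tsv",
                                        "marker"))
        cd3e = "CD3E"
        if scores_for_outcome and cd3e in expr.values.index:
            cd3e_high = (expr.values.loc[cd3e]
                         > expr.values.loc[cd3e].median()).astype(int)
            tab = prognostic_improvement(
                clinical, cd3e_high, scores_for_outcome,
                k=self.cfg.cv_k, repeats=self.cfg.cv_repeats,
                seed=self.cfg.stage_seed("prognostic"),
            )
            produced.append(self._write(tab, "prognostic_improvement.tsv",
                                        "model"))
        return produced
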