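# immunosig

Immune metagene scoring, prognostic gene-signature discovery and
survival stratification for bulk tumor expression cohorts.

## Scientific problem

In several solid tumors — neuroblastoma prominently among them — the
density of tumor-infiltrating immune cells (dendritic cells, natural
killer cells, T cells) carries prognostic information beyond the
classical clinical predictors (stage, *MYCN* amplification, age at
diagnosis). Bulk expression profiling cannot count cells directly, but
the average log2 expression of a set of cell-type-specific genes (a
*metagene*) acts as a proxy for the abundance of that cell type in the
tumor microenvironment. This package implements the full analysis
chain around that idea:

1. **Normalization** of raw counts — a NanoString-style chain
   (positive-control scaling → background subtraction → housekeeping
   scaling → log2) or quantile normalization for RNA-seq-style input.
2. **Scoring** samples against gene signatures (two curated
   signatures, dendritic-cell and natural-killer, ship with the
   package) and **stratifying** patients at the median or at a
   data-driven cutpoint chosen by maximally selected rank statistics
   with the Miller–Siegmund selection correction.
3. **Survival analysis**: Kaplan–Meier, log-rank (with an exact
   permutation mode for tiny samples), and Cox proportional-hazards
   models, including a fast in-package univariate scan over thousands
   of genes with Efron tie handling.
4. **Signature discovery**: starting from a marker gene (e.g. *THBD*
   for dendritic cells, *NCR1* for NK cells), candidate genes pass
   three filters — differential expression between marker-high and
   marker-low tumors (|fold change| > 2 and Wilcoxon significance),
   univariate Cox prognostic value at FDR < 0.05, and predominant
   expression in the target cell type in a cell-type atlas.
5. **Predictive evaluation**: does adding a signature score to the
   classical predictors improve prediction of 2-year overall survival?
   Measured by the Matthews correlation coefficient (MCC) over
   repeated stratified cross-validation, against a random-label
   permutation baseline.
6. **Synthetic cohorts** with exposed ground truth (latent
   infiltration factor, planted signature genes, proportional-hazards
   survival, NanoString counting noise, cell atlas,
   immunohistochemistry densities), so the whole chain is testable
   without external data.

## Statistical model

Survival follows a proportional-hazards model with an exponential
baseline: the generator draws `T ~ Exp(λ₀ · exp(−β_L·L + β_M·MYCN +
β_R·R))` with latent infiltration `L ~ N(0,1)` and an independent
proliferation factor `R ~ N(0,1)`, under uniform censoring. A
data-driven cutpoint for a score `s` maximizes the standardized
two-sample log-rank statistic over the inner quantile window; its
p-value is corrected for selection with the Miller–Siegmund
approximation `p ≈ φ(b)(b − 1/b)·ln[(1−ε_lo)(1−ε_hi)/(ε_lo ε_hi)] +
4φ(b)/b`. Cell densities from immunohistochemistry are brought to log
scale with `y = ln(x + 1/(1+x))` and related to expression by
Huber-robust regression. Multiplicity is controlled by
Benjamini–Hochberg throughout.

## Worked example

```python
from immunosig import (median_split, logrank_test, maxstat_cutpoint,
                       discover_signature, discovered_signature_score)
from immunosig.simulate import (SimulationConfig, simulate_cell_atlas,
                                simulate_cohort)

cfg = SimulationConfig(n_samples=300, seed=7)
expr, clinical, truth = simulate_cohort(cfg)
d = clinical.survival("OS")

atlas = simulate_cell_atlas(cfg, truth.gene_roles)
sig, report = discover_signature(expr, d, "THBD", atlas,
                                 targets=("DC", "NK", "T"))
print(f"discovered {len(sig.genes)} genes "
      f"({len(sig.protective)} protective, {len(sig.risky)} risky)")

score = discovered_signature_score(expr, sig)
labels = median_split(score, variable="dc_metagene")
groups = [d.loc[[s for s in members if s in d.index]]
          for members in (labels.high, labels.low)]
res = logrank_test(groups)
print(f"median split: log-rank chi2 = {res.statistic:.2f}, p = {res.p:.3g}")

cp = maxstat_cutpoint(score, d)
print(f"scan: cut = {cp.cutpoint:.3f}, b = {cp.statistic:.2f}, "
      f"corrected p = {cp.p_corrected:.3g}")
```

Output:

```
discovered 49 genes (42 protective, 6 risky)
median split: log-rank chi2 = 31.76, p = 1.74e-08
scan: cut = 5.481, b = 6.30, corrected p = 2.65e-08
```

The same analysis is available from the command line:

```sh
immunosig simulate --n-samples 300 --seed 7 --outdir cohort/
immunosig run-all --config config.yaml --seed 7 --outdir results/
```

where `config.yaml` names the input TSVs and analysis knobs (see
`immunosig run-all --help`); every output table carries a header
recording the package version, config hash and seed, and identical
config + seed reproduces the bundle byte for byte.

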