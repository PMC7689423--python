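# Methods note

This note records the modelling assumptions, parameter defaults and
numerical design decisions behind `immunosig`, in the order the
pipeline runs.

## Normalization

NanoString-style chain, applied in a fixed order:

1. **Positive-control scaling.** Per-sample factor
   `f_s = mean_over_samples(geomean of positive probes) / geomean_s`;
   all counts in sample `s` are multiplied by `f_s`. A zero positive
   count makes the geometric mean zero and is a validation error.
2. **Background subtraction.** Threshold = mean + 2·SD of the negative
   probes per sample (sample SD, `n−1` denominator; at least two
   negative probes required); subtracted counts floor at 0.
3. **Housekeeping scaling.** Same geometric-mean construction on the
   housekeeping probes ("content" factor).
4. **log2(x+1).** The pseudocount keeps zero counts at exactly 0.

With identical controls everywhere the chain reduces to `log2(x+1)`,
which the tests verify. The product of the positive and content
factors estimates the reciprocal of the per-sample lane effect; on
simulated data the correlation with the planted lane factors exceeds
0.99. Quantile normalization (for RNA-seq-style input) maps each
column's order statistics to the cross-sample mean order statistics,
averaging ranks on ties.

## Scoring and stratification

A metagene score is the unweighted mean of the signature genes' log2
values; genes absent from the matrix are skipped and reported, and a
signature with no genes present is an error. The median split labels a
sample High iff its value is strictly greater than the cohort median,
so with an odd cohort the median sample is Low, and a tie mass at the
median goes entirely to Low. A constant score cannot be split and is
an error.

## Maximally selected rank statistics

Per-observation log-rank scores `a_i = δ_i − H(t_i)` (Nelson–Aalen
cumulative hazard at the observation's time) let every candidate
cutpoint be scored as a standardized group sum: for the Low group of
size `k`, `S_k = Σ_{i≤k} a_i` has permutation mean `k·ā` and variance
`k(n−k)/(n(n−1))·Σ(a_i−ā)²`. One sort plus cumulative sums gives all
candidates in O(n log n). Candidates keep both groups at or above the
`ε = 0.1` scan fractions; ties in |z| break toward the smaller
cutpoint. The selection-corrected p-value uses the Miller–Siegmund
approximation; it is unstable for b ≤ 1, where 1.0 is returned with a
warning. Null calibration (500 pure-noise replicates) keeps the
corrected rejection rate below the nominal 5%.

## Survival models

Kaplan–Meier, multi-group log-rank and multivariate (optionally
stratified) Cox fits delegate to lifelines. Two additions are
in-package:

- an **exact permutation mode** for the log-rank test that enumerates
  every relabeling of the pooled observations (guarded at 50,000
  relabelings), because the chi-square reference is meaningless at
  n ≤ 8 where the permutation null has granularity ~1/35;
- a **univariate Newton–Raphson Cox scan** with Efron tie handling
  (step clipped to ±2; |β| > 20 treated as monotone likelihood /
  separation), used for per-gene scans where a lifelines fit per gene
  would dominate runtime. It matches lifelines to ~1e-5 and the
  partial-likelihood optimum beats a 1e-3 coefficient grid on toy
  instances. Genes that are constant or fail to converge are excluded
  from the Benjamini–Hochberg correction and flagged in a `status`
  column.

Small-sample nonparametric tests follow the same principle: the
Kruskal–Wallis test enumerates its exact permutation null when the
pooled sample has n ≤ 9, and the Wilcoxon rank-sum test uses scipy's
exact small-sample rule.

## Robust association

Immunohistochemistry densities are transformed by
`y = ln(x + 1/(1+x))` — strictly increasing, 0 ↦ 0, asymptotically
`ln(x)`. Pairwise association uses Huber M-estimation (tuning constant
1.345, MAD scale, IRLS on coefficients, tolerance 1e-8, 50 iterations)
with a Wald F-test of the slope against F(1, n−2). The coefficient of
determination is computed on the robust fit itself,
`R² = 1 − Σw·e² / Σw·(y−ȳ_w)²` with the final IRLS weights `w`; this
definition is carried in result metadata because squared Pearson r on
the same data differs.

## Signature discovery

Three successive filters from a marker-gene median split:

1. linear fold change > 2 or < 1/2 **and** (BH q < 0.05 or raw
   p < 0.05) in a Wilcoxon differential-expression scan (the
   disjunction is permissive, so the admitting route — q, p or both —
   is recorded per gene);
2. univariate Cox hazard ratio significantly below 1 (protective) or
   above 1 (risky) at FDR < 0.05;
3. cell-type specificity in an atlas: expression in a target cell
   type at least 2× the gene's median across types **and** that type
   among the gene's top-3. The specificity filter prunes protective
   genes only; risky genes (typically tumor-intrinsic, not
   immune-specific) are retained with their atlas verdict as
   annotation.

Because a discovered signature mixes protective and risky genes whose
signals cancel in a plain mean, outcome models receive **sign-aware
sub-scores** (protective mean and risky mean as separate columns).

## Predictive evaluation

MCC is computed from the confusion matrix (Gorodkin's multiclass
generalization; a zero denominator is defined as 0). Evaluation is
stratified k-fold CV repeated R times; the random-label mode permutes
the outcome once per repeat, and majority-class downsampling (once per
repeat) guards against imbalance. The 2-year overall-survival outcome
is poor = death before 730 days, good = followed ≥ 730 days; samples
censored earlier are excluded. Logistic fits are unpenalized maximum
likelihood with a tiny-ridge fallback on separation. The baseline
model uses stage dummies, *MYCN*, age > 18 months and a T-cell
(CD3E-high) indicator.

## Synthetic cohort

Defaults emulate a ~500-patient pediatric cohort: n = 498, baseline
hazard λ₀ = 1.25e-4 per day, ten-year uniform censoring, β_L = 0.7
(infiltration, protective), β_M = 0.7 (*MYCN*), β_R = 0.5
(proliferation), marker effect 2.0 log2 units per SD of infiltration,
gene noise SD 1.0, ~25% *MYCN* amplification anti-correlated with
infiltration, event rate ~30%. NanoString mode layers Poisson counting
noise, log-normal lane factors (SD 0.25), a positive-control ladder
(2^5 … 2^10), Poisson(10) negatives and a housekeeping panel.
Densities are gamma-Poisson (negative binomial) with log-mean linear
in infiltration. Every stage draws from a named substream of the root
seed (CRC32 of the stream name), so adding genes or stages never
perturbs other draws and same config + seed is bit-reproducible.

What the generator does **not** emulate: probe-level sequence biases,
batch structure beyond a single lane factor, competing risks,
non-proportional hazards, or correlated gene–gene noise beyond the
shared latent factors.

## Problem sizes and runtime

The test suite (227 tests) runs in under a minute: per-gene Cox scans
at ~450 genes × 300 samples take a few seconds, the 500-replicate
maxstat null calibration ~15 s, and the repeated-CV evaluations a few
seconds each. The acceptance script (`scripts/acceptance.py`) takes
3–4 minutes end to end.
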