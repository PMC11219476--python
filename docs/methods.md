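# Methods

This note records the models, algorithms, numerical choices and limitations
behind `methblocks`. Notation: *n* samples, *m* CpGs, **m**ⱼ the beta-value
vector of CpG *j*, **Z** the n×q covariate matrix (first column all ones).

## 1. Storage model

A *store* is a hive-partitioned Parquet dataset, one directory per
chromosome (`chrom=1/`, `chrom=2/`, …), each file holding CpG rows with a
string CpG-id column and one float64 column per sample, plus a JSON sidecar
(`_methstore.json`) recording sample order, column roles and a conversion
report. Design points:

- **Canonical row order** is natural chromosome order (1–22, X, Y, MT,
  then others lexicographically) and source order within a chromosome.
  Every analysis emits rows in this order, which is what makes byte-identical
  invariance checks meaningful.
- **Conversion is bit-exact.** Text cells are parsed with Python's
  correctly-rounded `float()` rather than vectorized converters, which are
  not correctly rounded in all cases; a `%.17g`-formatted float64 therefore
  round-trips exactly. Duplicate CpG ids and a missing chromosome column
  abort conversion with no partial dataset left behind.
- **Pushdown.** CpG-name queries use Parquet dataset filters; chromosome
  queries use partition pruning; row-range queries skip whole files using
  footer row counts. The store counts rows actually materialized
  (`rows_materialized`), which the tests use to prove that memory touched
  scales with the query, not the store.
- **Block streaming.** Analyses consume CpGs in fixed-size blocks (default
  50 000), bounding memory independent of *m*.

## 2. Bulk OLS (methylation as outcome)

For a shared design **X** = [1 | exposure | covariates] (categorical
variables dummy-coded, sorted levels, first level dropped), the
cross-product factorization (XᵀX)⁻¹ and the hat operator (XᵀX)⁻¹Xᵀ are
computed once per design and reused for every CpG. A condition-number check
(κ > 1e10) aborts with the names of the collinear columns.

**Per-column kernels, not one wide GEMM.** Per CpG we compute
b = ((XᵀX)⁻¹Xᵀ)·y and rᵀr with BLAS-2 operations instead of multiplying the
whole block in one matrix–matrix product. GEMM kernel selection can depend
on the width of the right-hand side, which would make results depend on
block size and break the byte-identical invariance guarantee. The shared
factorization still gives the bulk speedup; the per-column loop costs O(np)
per CpG either way. Worker parallelism uses a thread pool (numpy releases
the GIL); blocks are reassembled in index order, so any worker count gives
identical bytes.

Degenerate CpGs are handled explicitly: a constant **m**ⱼ is reported with
t = 0, p = 1 (an exact intercept-only fit); a perfect fit (residual sum of
squares ≤ 1e−24·max(yᵀy, 1), i.e. rounding residue) is reported NA with
reason `zero_residual_variance`. CpGs with missing betas are refit on their
complete cases with a per-site design.

**Tests.** Continuous exposures: Wald t on the exposure coefficient,
p from t(n−p). Categorical exposures: joint F over the dummy columns from
two bulk passes (full and reduced). For a single dummy (2-level factor) the
F statistic is computed as the squared coefficient t statistic — the two are
algebraically identical and this form avoids the cancellation in
RSS_reduced − RSS_full, making F = t² exact in floating point. Per-dummy
estimates are appended as `estimate__<level>` / `se__<level>` columns.

**Robust regression.** `robust=True` runs per-site Huber IRLS with tuning
constant c = 1.345 (95% Gaussian efficiency), scale re-estimated each
iteration as MAD(r)/0.6745 (MAD about zero), and sandwich covariance
A⁻¹BA⁻¹ with an n/(n−p) small-sample correction. With c → ∞ on clean data
the estimate equals OLS.

## 3. Score tests (methylation as exposure)

The null model phenotype ~ covariates is fit once; each CpG is then scored
without refitting:

- **Linear:** residualize g against **Z** (g̃ = g − QQᵀg via the cached QR),
  U = g̃ᵀr/σ̂², V = g̃ᵀg̃/σ̂², T = U²/V ~ χ²₁. The reported effect estimate
  U/V equals the full-model OLS slope up to O(1/n).
- **GLM (logistic/Poisson):** IRLS to 1e−8; U = gᵀ(y − μ̂),
  V = gᵀWg − gᵀWZ(ZᵀWZ)⁻¹ZᵀWg computed via the QR of √W·**Z**. Quasi-complete
  separation (vanishing working weights) is a fatal error, not a warning.
- **Linear mixed model:** y = **Z**α + u + ε with cov(u) = σ²_g·K.
  Variance components by REML: eigendecompose K once, profile the restricted
  likelihood over γ = σ²_g/σ²_e on a 61-point log grid spanning [1e−6, 1e6],
  refine with bounded Brent, and check the γ = 0 boundary explicitly. The
  projection P = Σ⁻¹ − Σ⁻¹Z(ZᵀΣ⁻¹Z)⁻¹ZᵀΣ⁻¹ is cached densely (O(n²) memory,
  O(n²) per CpG) — at the sample sizes where dense REML is feasible this is
  cheaper and simpler than factored alternatives. Scores: U = gᵀPy,
  V = gᵀPg. K ≈ I (constant eigenvalues) makes γ unidentifiable: the fit
  warns and fixes total variance at the OLS estimate.

Variance components are *fixed at their null estimates* for all CpGs
(a two-stage plug-in, the standard large-m EWAS practice); the per-CpG cost
is then a handful of gemvs. CpGs whose score variance V ≤ 1e−12 (e.g. a CpG
collinear with covariates) are NA with reason `zero_score_variance`.

## 4. Methylation risk scores

sᵢ = Σⱼ wⱼ·mᵢⱼ over the weight-table CpGs present in the store (pushdown
query; memory scales with matches). A missing beta contributes 0 and is
counted per sample (`n_sites_missing`); `average` divides by the per-sample
sites used before `scale` standardizes (ddof = 1). The accumulation is an
explicit ordered sum over CpGs in canonical store order, so the
Parquet-backed score equals a naive dense weighted sum computed in the same
order *exactly*, not just to tolerance. Zero matched CpGs and zero score
variance under `scale` are fatal.

Association: linear (Wald t), logistic (IRLS, Wald z), or multinomial
baseline-category logit (full Newton with the exact blocked Hessian,
log-sum-exp stabilized) tested by likelihood ratio with df = K − 1.
`model="auto"` maps numeric → linear, 2 levels → logistic, ≥3 →
multinomial. A 2-level multinomial LRT equals the logistic LRT.

## 5. Multiple testing and diagnostics

`bh_adjust` implements Benjamini–Hochberg step-up via a single sort and a
reversed cumulative minimum; NaN p-values are excluded from the effective
test count and preserved in place. λ_gc = median(χ²₁(p))/0.4549; p-values of
exactly 0 are floored at the smallest positive double before −log10
transforms. QQ expected quantiles are −log10((i − 0.5)/m); Manhattan x
coordinates are cumulative per-chromosome offsets in canonical order.

## 6. Synthetic data

`simulate_methylation` emulates the *shape* of a post-QC array beta matrix,
not its biology:

- Per-CpG baseline means from Beta(2, 2); sample values
  inverse-logit(logit(mean) + N(0, 0.5²)) clipped to (0.001, 0.999).
- Phenotype = standardized causal-CpG effects + age and sex effects +
  (optional family random effect) + noise; binary via a logit link centered
  for balance; categorical via latent quantile cuts.
- With a family structure configured, half of the logit-scale noise variance
  is shared within family, and the phenotype gets a family random effect
  (sib-pair kinship blocks [[1, 0.5], [0.5, 1]]). Both are needed to create
  genuine confounding by relatedness: family-structured phenotypes alone do
  not inflate tests of family-independent CpGs.
- Missingness is completely at random. The same configuration and seed
  yield a byte-identical store.

What it does **not** emulate: probe-type effects, batch/chip structure,
cell-type composition, genomic position dependence, realistic effect-size
distributions. It is a test harness, not a methylation generator.

Default problem sizes used in the test-suite guarantees (n = 200 with
m = 1000–20 000 for calibration, n = 400 sib-pair designs for the mixed
model, a 50 000-CpG store for pushdown checks) were chosen so that
Monte-Carlo error is small relative to the asserted bands while the whole
suite runs in minutes on one CPU.

## 7. Limitations

- The mixed model supports one random effect (one kinship matrix) and dense
  REML, practical to a few thousand samples; no sparse/low-rank path.
- Score-test effect estimates are one-step approximations, not full-model
  MLEs; they agree with full refits to O(1/n).
- Robust EWAS accepts a single continuous exposure column.
- The store is write-once; there is no incremental append.
- p-values are asymptotic throughout; no permutation or saddlepoint options.
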