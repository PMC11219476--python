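# methblocks

Columnar Parquet storage and block-streamed association analysis for DNA
methylation data.

## The problem

Epigenome-wide association studies (EWAS) relate DNA methylation — measured
as per-CpG *beta values* in [0, 1] for each sample — to phenotypes, one
regression per CpG. A post-QC array dataset is a dense matrix of hundreds of
thousands of CpG rows by hundreds or thousands of sample columns; loading it
whole into memory for every analysis is wasteful, and looping a general
regression routine over every CpG is slow. `methblocks` addresses both ends:

- **Storage.** The beta matrix lives in a chromosome-partitioned (hive
  layout) Parquet dataset. Queries by CpG name, gene, chromosome, or row
  range use predicate/partition pushdown, so extracting 100 CpGs from a
  500k-CpG store touches 100 rows, not 500k. Conversion from delimited text
  is bit-exact for float64 values.
- **Computation.** CpGs stream through the analysis in fixed-size blocks
  (default 50 000 rows), so memory stays bounded regardless of store size.
  Within a block, ordinary least squares is *bulk*: the design matrix is
  factorized once and reused for every CpG. Results are byte-identical for
  any block size and worker count.

## Statistical models

For CpG *j* with methylation vector **m**ⱼ, covariates **Z** (always
including an intercept), and phenotype/exposure of interest:

- **Methylation as outcome** — `lm_ewas_outcome`: fits
  mⱼ = β₀ + β₁·exposure + **Z**γ + ε per CpG via bulk OLS; continuous
  exposures get a Wald *t* test on β₁, categorical exposures a joint *F*
  test over the dummy columns (for a 2-level factor, F = t² exactly).
  `robust=True` switches to per-site Huber M-estimation (IRLS, tuning
  constant 1.345, MAD scale, sandwich standard errors). `flex_ewas` accepts
  a user model function per site.
- **Methylation as exposure** — `ewas_meth_exposure`: fits a *null model*
  phenotype ~ covariates once (linear, logistic, Poisson, or a linear mixed
  model with a kinship matrix **K**, variance components by REML), then
  screens every CpG with a score test U²/V ~ χ²₁ — no per-CpG refits. The
  mixed model keeps tests calibrated under family relatedness where a naive
  linear model inflates.
- **Methylation risk scores** — `dev_meth_score`: sᵢ = Σⱼ wⱼ·mᵢⱼ over an
  external weight table, queried with pushdown; `test_mrs` then runs
  linear/logistic/multinomial association (multinomial via a
  likelihood-ratio test with df = levels − 1).
- **Results** — every analysis emits the same table schema (`cpg_id`,
  `chrom`, `position`, `estimate`, `se`, `statistic`, `stat_type`, `df`,
  `p`, `p_bh`, `n_used`, `reason`) with Benjamini–Hochberg adjustment
  across all tested CpGs, plus genomic-inflation λ and QQ/Manhattan plot
  data.
- **Simulation** — `simulate_methylation` generates seeded synthetic stores
  with known causal CpGs, covariate effects, optional family structure
  (sib-pair kinship, family-correlated methylation) and missingness; same
  seed, byte-identical store.

## Worked example

```python
import methblocks as mb
from methblocks.results import lambda_gc
from methblocks.mrs import dev_meth_score, test_mrs

cfg = mb.SimConfig(n_samples=300, n_cpgs=2000, n_chroms=4, n_causal=5,
                   effect_size=1.5, missing_rate=0.02, seed=42)
store, samples, cpgs, truth = mb.simulate_methylation(cfg, "demo")
ml = mb.create_methlist(store, samples, cpgs)

tab = mb.lm_ewas_outcome(ml, "phenotype", covariates=["age", "sex"])
print(round(lambda_gc(tab["p"]), 3))
print(tab.nsmallest(5, "p")[["cpg_id", "estimate", "se", "p", "p_bh"]])
```

Output:

```
1.009
    cpg_id  estimate       se            p         p_bh
cg00001863  0.016325 0.001648 3.891064e-20 7.782129e-17
cg00001791  0.008961 0.001066 1.957683e-15 1.957683e-12
cg00000330  0.011884 0.001452 8.897673e-15 5.931782e-12
cg00001686  0.012963 0.001845 1.528622e-11 7.643108e-09
cg00001741  0.011175 0.001712 2.985964e-10 1.194385e-07
```

The five CpGs passing BH < 0.05 are exactly the five planted causal CpGs
(`truth.causal_cpg_ids`), and the genomic inflation factor is 1.009. A risk
score built from those hits is strongly associated with the phenotype:

```python
w = tab.nsmallest(5, "p")[["cpg_id", "estimate"]].rename(columns={"estimate": "weight"})
sc = dev_meth_score(ml, w, scale=True)
res = test_mrs(sc, samples.set_index("sample_id"), "phenotype",
               covariates=["age", "sex"])
# linear wald_t: estimate=2.5017 se=0.1392 t=17.97 p=2.5e-49 n=300
```

The same pipeline is available on the command line:

```bash
methblocks simulate --n 300 --cpgs 2000 --causal 5 --effect 1.5 --seed 42 --out demo
methblocks ewas-outcome --store demo/store --samples demo/samples.tsv \
    --cpgs demo/cpgs.tsv --exposure phenotype --covariates age,sex --out ewas.tsv
```

## Documentation

`docs/methods.md` describes the statistical methods, numerical choices and
limitations in detail.
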