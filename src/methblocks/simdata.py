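"""Deterministic synthetic methylation data: stores, annotations, phenotypes,
kinship and ground truth.

The generator emulates the shape of a post-QC Illumina-array beta matrix
(CpG rows bounded in (0,1), a chromosome per CpG, sample annotations with
age/sex covariates) at reduced scale. Per-CpG baseline means are drawn from
Beta(2,2); a sample's beta is inverse-logit(logit(mean) + noise) truncated
to (0.001, 0.999). When a family structure is configured, part of the
logit-scale noise is shared within family, which makes methylation itself
family-correlated — the confounding-by-relatedness condition mixed-model
score tests exist to handle. Everything is reproducible from a single seed:
the same configuration yields a byte-identical Parquet store.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .store import MethStore, convert_to_parquet


def m_value(beta: np.ndarray) -> np.ndarray:
    """M-value transform log2(beta / (1 - beta)) of beta values."""
    beta = np.asarray(beta, dtype=float)
    return np.log2(beta / (1.0 - beta))


@dataclass
class SimConfig:
    """Study-condition parameters of one synthetic dataset."""

    n_samples: int = 200
    n_cpgs: int = 2000
    n_chroms: int = 4
    n_causal: int = 0
    effect_size: float = 0.5        # per SD of methylation (log-OR if binary)
    phenotype_family: str = "continuous"   # continuous | binary | categorical-k
    age_effect: float = 0.05
    sex_effect: float = 0.3
    noise_sd: float = 1.0
    logit_noise_sd: float = 0.5
    missing_rate: float = 0.0
    n_families: int = 0
    sibs_per_family: int = 2
    sigma2_g: float = 0.0
    sigma2_e: float = 1.0
    family_meth_share: float = 0.5  # share of logit noise variance shared within family
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_cpgs < 1:
            raise ValueError("n_samples and n_cpgs must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_causal > self.n_cpgs:
            raise ValueError("n_causal cannot exceed n_cpgs")
        if self.n_families and self.n_families * self.sibs_per_family != self.n_samples:
            raise ValueError("n_families * sibs_per_family must equal n_samples")
        if self.phenotype_family != "continuous" and self.phenotype_family != "binary" \
                and not self.phenotype_family.startswith("categorical-"):
            raise ValueError(f"unknown phenotype_family {self.phenotype_family!r}")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_cpg_ids: list[str]
    true_effects: dict[str, float]
    true_varcomps: dict[str, float]
    generating_equation: str

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")


def simulate_kinship(n_families: int, sibs_per_family: int) -> tuple[np.ndarray, list[str]]:
    """Block-diagonal sib-group kinship: 1 on the diagonal, 0.5 within
    family, 0 elsewhere. Positive semidefinite by construction."""
    s = sibs_per_family
    block = np.full((s, s), 0.5)
    np.fill_diagonal(block, 1.0)
    n = n_families * s
    K = np.zeros((n, n))
    for f in range(n_families):
        K[f * s:(f + 1) * s, f * s:(f + 1) * s] = block
    ids = [f"S{i + 1:04d}" for i in range(n)]
    return K, ids


def _logit(x):
    return np.log(x / (1.0 - x))


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(cfg: SimConfig, dest, force: bool = False):
    """Generate a full synthetic dataset and write its Parquet store.

    Returns (MethStore, sample annotation DataFrame, CpG annotation
    DataFrame, SimTruth). The store is written under ``dest/store``; the
    annotations and truth are returned (and can be saved by the CLI).
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_cpgs
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    cpg_ids = [f"cg{i + 1:08d}" for i in range(m)]
    chrom_of = np.array([str(1 + (i % cfg.n_chroms)) for i in range(m)])

    # methylation matrix on logit scale
    base = rng.beta(2.0, 2.0, size=m)
    base = np.clip(base, 0.01, 0.99)
    fam_sd = ind_sd = 0.0
    if cfg.n_families:
        fam_sd = cfg.logit_noise_sd * np.sqrt(cfg.family_meth_share)
        ind_sd = cfg.logit_noise_sd * np.sqrt(1.0 - cfg.family_meth_share)
    logit_vals = _logit(base)[:, None] + (
        rng.normal(0.0, cfg.logit_noise_sd, size=(m, n))
        if not cfg.n_families
        else (
            np.repeat(rng.normal(0.0, fam_sd, size=(m, cfg.n_families)),
                      cfg.sibs_per_family, axis=1)
            + rng.normal(0.0, ind_sd, size=(m, n))
        )
    )
    betas = np.clip(_inv_logit(logit_vals), 0.001, 0.999)

    # covariates
    age = np.round(rng.normal(50.0, 10.0, size=n), 1)
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    # phenotype
    causal_idx = rng.choice(m, size=cfg.n_causal, replace=False) if cfg.n_causal else np.array([], dtype=int)
    causal_idx.sort()
    linpred = cfg.age_effect * (age - age.mean()) + cfg.sex_effect * (sex == "M")
    for i in causal_idx:
        col = betas[i]
        linpred = linpred + cfg.effect_size * (col - col.mean()) / col.std(ddof=0)
    fam_effect = np.zeros(n)
    if cfg.n_families and cfg.sigma2_g > 0:
        shared = np.repeat(rng.normal(0.0, np.sqrt(cfg.sigma2_g * 0.5), size=cfg.n_families),
                           cfg.sibs_per_family)
        fam_effect = shared + rng.normal(0.0, np.sqrt(cfg.sigma2_g * 0.5), size=n)
    if cfg.phenotype_family == "continuous":
        noise_sd = np.sqrt(cfg.sigma2_e) if cfg.n_families else cfg.noise_sd
        pheno = linpred + fam_effect + rng.normal(0.0, noise_sd, size=n)
        pheno_col = pd.Series(np.round(pheno, 6), name="phenotype")
    elif cfg.phenotype_family == "binary":
        eta = linpred + fam_effect
        pr = _inv_logit(eta - np.median(eta))  # centered for balance
        pheno_col = pd.Series((rng.random(n) < pr).astype(int), name="phenotype")
    elif cfg.phenotype_family.startswith("categorical-"):
        k = int(cfg.phenotype_family.split("-")[1])
        latent = linpred + fam_effect + rng.normal(0.0, cfg.noise_sd, size=n)
        cuts = np.quantile(latent, np.linspace(0, 1, k + 1)[1:-1])
        pheno_col = pd.Series(
            pd.cut(latent, bins=[-np.inf, *cuts, np.inf],
                   labels=[f"L{j + 1}" for j in range(k)]).astype(str),
            name="phenotype",
        )
    else:
        raise ValueError(f"unknown phenotype_family {cfg.phenotype_family!r}")

    # missingness, completely at random
    if cfg.missing_rate > 0:
        mask = rng.random(size=(m, n)) < cfg.missing_rate
        betas = np.where(mask, np.nan, betas)

    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    src = pd.DataFrame(betas, columns=sample_ids)
    src.insert(0, "chrom", chrom_of)
    src.insert(0, "cpg_id", cpg_ids)
    csv_path = dest / "source.csv"
    src.to_csv(csv_path, index=False, float_format="%.17g")
    store = convert_to_parquet(
        csv_path, cpg_id_column="cpg_id", chrom_column="chrom",
        dest=dest / "store", write_chunk_rows=max(min(m, 50_000), 1), force=force,
    )
    csv_path.unlink()  # the store is the artifact; the staging CSV is not

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "phenotype": pheno_col.to_numpy(),
        "age": age,
        "sex": sex,
    })
    if cfg.n_families:
        samples["family"] = np.repeat(
            [f"F{f + 1:03d}" for f in range(cfg.n_families)], cfg.sibs_per_family
        )
    gene_of = [f"GENE{1 + i // 10}" for i in range(m)]
    cpgs = pd.DataFrame({
        "cpg_id": cpg_ids,
        "chrom": chrom_of,
        "position": [(i // cfg.n_chroms + 1) * 137 for i in range(m)],
        "gene": gene_of,
    })
    truth = SimTruth(
        causal_cpg_ids=[cpg_ids[i] for i in causal_idx],
        true_effects={cpg_ids[i]: cfg.effect_size for i in causal_idx},
        true_varcomps={"sigma2_g": cfg.sigma2_g if cfg.n_families else 0.0,
                       "sigma2_e": cfg.sigma2_e if cfg.n_families else cfg.noise_sd ** 2},
        generating_equation=(
            "phenotype = sum_causal effect*std(beta) + age_effect*(age-mean) "
            "+ sex_effect*1[M] + family_effect + N(0, noise)"
        ),
    )
    return store, samples, cpgs, truth
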