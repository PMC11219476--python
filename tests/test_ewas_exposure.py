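import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methblocks as mb
from methblocks.ewas_exposure import (
    NullModelError,
    ewas_meth_exposure,
    fit_null,
    score_test_block,
)
from methblocks.results import lambda_gc


def test_linear_null_residuals_orthogonal_to_covariates(small_sim):
    null = fit_null(small_sim["mlist"], "phenotype", ["age", "sex"], family="linear")
    assert np.max(np.abs(null.Z.T @ null.residuals)) < 1e-8


def test_linear_score_matches_dense_projection_oracle(small_sim):
    """Explicit projection-matrix score statistic on small n, to 1e-10."""
    null = fit_null(small_sim["mlist"], "phenotype", ["age", "sex"], family="linear")
    n = null.n
    Z = null.Z
    M = np.eye(n) - Z @ np.linalg.inv(Z.T @ Z) @ Z.T  # dense annihilator
    rng = np.random.default_rng(17)
    G = rng.uniform(0.1, 0.9, size=(n, 30))
    res = score_test_block(null, G)
    for j in range(G.shape[1]):
        g = G[:, j]
        gt = M @ g
        U = (gt @ null.residuals) / null.sigma2
        V = (gt @ gt) / null.sigma2
        assert abs(res["statistic"][j] - U * U / V) < 1e-10
        assert abs(res["estimate"][j] - U / V) < 1e-10


def test_score_effect_matches_full_ols_refit():
    """Score U/V vs the Wald slope from a full per-CpG OLS refit; the
    statistics agree to O(1/n) at n = 500."""
    rng = np.random.default_rng(23)
    n = 500
    tmp_Z = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = tmp_Z @ np.array([1.0, 0.4]) + rng.normal(size=n)
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                            "y": y, "z": tmp_Z[:, 1]})
    null = _null_from_frames(samples, "y", ["z"])
    G = rng.uniform(0.1, 0.9, size=(n, 50))
    res = score_test_block(null, G)
    for j in range(G.shape[1]):
        X = np.column_stack([np.ones(n), G[:, j], tmp_Z[:, 1]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        s2 = (r @ r) / (n - 3)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        wald_t2 = (beta[1] / se) ** 2
        assert abs(res["estimate"][j] - beta[1]) < 1e-6
        assert abs(res["statistic"][j] - wald_t2) / wald_t2 < 0.02


def _null_from_frames(samples, outcome, covs, family="linear", kinship=None):
    """Build a NullModelFit directly from a sample table (no store needed)."""
    from methblocks.methlist import MethList

    class _FakeStore:
        sample_ids = samples["sample_id"].tolist()
        chrom_values = ["1"]

    ml = MethList.__new__(MethList)
    ml.store = _FakeStore()
    ml.samples = samples.set_index("sample_id")
    ml.cpgs = pd.DataFrame(index=pd.Index([], name="cpg_id"))
    ml.sample_key, ml.cpg_key, ml.gene_column = "sample_id", "cpg_id", "gene"
    ml.unannotated_cpgs = []
    return fit_null(ml, outcome, covs, family=family, kinship=kinship)


def test_cpg_equal_to_covariate_is_na(small_sim):
    null = fit_null(small_sim["mlist"], "phenotype", ["age"], family="linear")
    g = null.Z[:, 1].copy()  # exactly the covariate
    res = score_test_block(null, g)
    assert res["reason"][0] == "zero_score_variance"
    assert np.isnan(res["p"][0])


def test_cpg_orthogonal_to_residuals_gives_p1(small_sim):
    null = fit_null(small_sim["mlist"], "phenotype", ["age"], family="linear")
    rng = np.random.default_rng(5)
    g = rng.normal(size=null.n)
    Q = null.cache["Q"]
    g = g - Q @ (Q.T @ g)                      # annihilate covariates
    r = null.residuals
    g = g - (g @ r) / (r @ r) * r              # then orthogonalize against r
    res = score_test_block(null, g)
    assert abs(res["statistic"][0]) < 1e-16
    assert res["p"][0] == pytest.approx(1.0)


def test_p_invariant_to_affine_rescaling_of_g(small_sim):
    null = fit_null(small_sim["mlist"], "phenotype", ["age"], family="linear")
    rng = np.random.default_rng(8)
    g = rng.uniform(0.1, 0.9, size=null.n)
    a = score_test_block(null, g)
    b = score_test_block(null, 5.0 * g + 2.0)
    assert a["p"][0] == pytest.approx(b["p"][0], rel=1e-10)
    assert a["statistic"][0] == pytest.approx(b["statistic"][0], rel=1e-10)


def test_glm_requires_valid_outcome(small_sim):
    with pytest.raises(NullModelError, match="0/1"):
        fit_null(small_sim["mlist"], "phenotype", family="logistic")
    with pytest.raises(NullModelError, match="kinship"):
        fit_null(small_sim["mlist"], "phenotype", family="lmm")
    with pytest.raises(NullModelError, match="kinship"):
        fit_null(small_sim["mlist"], "phenotype", family="linear",
                 kinship=np.eye(small_sim["store"].n_samples))


def test_logistic_score_matches_dense_oracle():
    rng = np.random.default_rng(31)
    n = 150
    z = rng.normal(size=n)
    eta = -0.2 + 0.5 * z
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "y": y, "z": z})
    null = _null_from_frames(samples, "y", ["z"], family="logistic")
    G = rng.uniform(0.1, 0.9, size=(n, 20))
    res = score_test_block(null, G)
    Z = null.Z
    W = np.diag(null.W)
    for j in range(G.shape[1]):
        g = G[:, j]
        U = g @ null.residuals
        V = g @ W @ g - g @ W @ Z @ np.linalg.inv(Z.T @ W @ Z) @ Z.T @ W @ g
        assert abs(res["statistic"][j] - U * U / V) < 1e-10


def test_logistic_planted_effects_detected(tmp_path):
    """Balanced binary outcome with strong planted CpG effects: all causal
    CpGs pass BH 0.05."""
    cfg = mb.SimConfig(n_samples=400, n_cpgs=800, n_chroms=4, n_causal=5,
                       effect_size=1.5, phenotype_family="binary",
                       age_effect=0.0, sex_effect=0.0, seed=37)
    store, samples, cpgs, truth = mb.simulate_methylation(cfg, tmp_path / "sim")
    ml = mb.create_methlist(store, samples, cpgs)
    null = fit_null(ml, "phenotype", ["age", "sex"], family="logistic")
    tab = ewas_meth_exposure(ml, null)
    hits = set(tab.loc[tab["p_bh"] < 0.05, "cpg_id"])
    assert set(truth.causal_cpg_ids) <= hits


def test_kinship_identity_unidentifiable_warns():
    rng = np.random.default_rng(41)
    n = 80
    z = rng.normal(size=n)
    y = 1.0 + 0.5 * z + rng.normal(size=n)
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "y": y, "z": z})
    with pytest.warns(UserWarning, match="unidentifiable"):
        null = _null_from_frames(samples, "y", ["z"], family="lmm", kinship=np.eye(n))
    # only the total variance is identified; it matches the OLS estimate
    Z = null.Z
    r = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    ols_sigma2 = (r @ r) / (n - Z.shape[1])
    total = null.varcomp["sigma2_g"] + null.varcomp["sigma2_e"]
    assert total == pytest.approx(ols_sigma2, rel=1e-6)


def test_lmm_without_structure_reduces_to_linear_score():
    """When REML drives sigma2_g to 0 the mixed-model score statistic equals
    the simple linear one."""
    rng = np.random.default_rng(43)
    n = 120
    z = rng.normal(size=n)
    y = 0.5 + 0.2 * z + rng.normal(size=n)
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "y": y, "z": z})
    K, _ = mb.simulate_kinship(n // 2, 2)
    null_lmm = _null_from_frames(samples, "y", ["z"], family="lmm", kinship=K)
    null_lin = _null_from_frames(samples, "y", ["z"], family="linear")
    if null_lmm.varcomp["sigma2_g"] > 1e-10:
        pytest.skip("REML found spurious structure for this draw")
    G = rng.uniform(0.1, 0.9, size=(n, 10))
    a = score_test_block(null_lmm, G)["statistic"].to_numpy()
    b = score_test_block(null_lin, G)["statistic"].to_numpy()
    np.testing.assert_allclose(a, b, rtol=1e-6)


def test_reml_recovers_variance_components():
    """Sib-pair kinship, sigma2_g=2, sigma2_e=1: averaged REML estimates over
    50 seeds land within 30% of truth at n=200."""
    n_fam, sibs = 100, 2
    n = n_fam * sibs
    K, _ = mb.simulate_kinship(n_fam, sibs)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    est_g, est_e = [], []
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        u = np.sqrt(2.0) * (L @ rng.normal(size=n))
        z = rng.normal(size=n)
        y = 1.0 + 0.3 * z + u + rng.normal(0, 1.0, size=n)
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "y": y, "z": z})
        null = _null_from_frames(samples, "y", ["z"], family="lmm", kinship=K)
        est_g.append(null.varcomp["sigma2_g"])
        est_e.append(null.varcomp["sigma2_e"])
    assert np.mean(est_g) == pytest.approx(2.0, rel=0.3)
    assert np.mean(est_e) == pytest.approx(1.0, rel=0.3)


def test_score_handles_missing_betas_per_cpg(small_sim):
    null = fit_null(small_sim["mlist"], "phenotype", ["age"], family="linear")
    tab = ewas_meth_exposure(small_sim["mlist"], null, block_size=128)
    store = small_sim["store"]
    full = mb.store.read_selection(store)
    n_missing = full[store.sample_ids].isna().sum(axis=1).to_numpy()
    assert np.array_equal(tab["n_used"].to_numpy(), store.n_samples - n_missing)
    assert (tab["stat_type"] == "score").all()


def test_exposure_mode_block_invariance(small_sim):
    null = fit_null(small_sim["mlist"], "phenotype", ["age", "sex"], family="linear")
    base = ewas_meth_exposure(small_sim["mlist"], null, block_size=50_000)
    for bs, wk in [(17, 1), (50_000, 4)]:
        other = ewas_meth_exposure(small_sim["mlist"], null, block_size=bs, workers=wk)
        pd.testing.assert_frame_equal(base, other, check_exact=True)
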