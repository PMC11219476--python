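import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methblocks as mb
from methblocks.ewas_outcome import (
    DesignError,
    build_design,
    drop_exposure,
    flex_ewas,
    lm_ewas_outcome,
    ols_block,
    rlm_site,
)
from methblocks.ewas_outcome import test_exposure_categorical as f_test_exposure
from methblocks.ewas_outcome import test_exposure_continuous as t_test_exposure

from conftest import make_design


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def test_build_design_layout(small_sim):
    dm = build_design(small_sim["mlist"], "phenotype", ["age", "sex"])
    assert dm.column_names == ["intercept", "phenotype", "age", "sex_M"]
    assert dm.exposure_columns == [1]
    assert np.all(dm.X[:, 0] == 1.0)


def test_build_design_complete_case(small_sim):
    samples = small_sim["samples"].copy()
    samples.loc[samples.index[3], "age"] = np.nan
    ml = mb.create_methlist(small_sim["store"], samples, small_sim["cpgs"])
    dm = build_design(ml, "phenotype", ["age"])
    assert dm.n == small_sim["store"].n_samples - 1
    assert len(dm.dropped_samples) == 1


def test_build_design_collinearity_fatal(small_sim):
    samples = small_sim["samples"].copy()
    samples["age2"] = samples["age"] * 2.0
    ml = mb.create_methlist(small_sim["store"], samples, small_sim["cpgs"])
    with pytest.raises(DesignError, match="age2|rank"):
        build_design(ml, "phenotype", ["age", "age2"])


def test_build_design_constant_exposure_fatal(small_sim):
    samples = small_sim["samples"].copy()
    samples["flat"] = 1.0
    ml = mb.create_methlist(small_sim["store"], samples, small_sim["cpgs"])
    with pytest.raises(DesignError, match="constant"):
        build_design(ml, "flat")


def test_categorical_exposure_dummy_count(small_sim):
    samples = small_sim["samples"].copy()
    rng = np.random.default_rng(0)
    samples["grp"] = rng.choice(["a", "b", "c"], size=len(samples))
    ml = mb.create_methlist(small_sim["store"], samples, small_sim["cpgs"])
    dm = build_design(ml, "grp")
    assert len(dm.exposure_columns) == 2  # k - 1 dummies, first level dropped
    assert dm.exposure_is_categorical


# ---------------------------------------------------------------------------
# bulk OLS + t test
# ---------------------------------------------------------------------------

def test_hand_worked_simple_regression():
    """x=(0,1,2,3), y=(1,2,2,4): slope 0.9, SE sqrt(0.07), t=0.9/SE, df=2."""
    dm = make_design(np.column_stack([np.ones(4), np.arange(4.0)]))
    fit = ols_block(dm, np.array([1.0, 2.0, 2.0, 4.0])[:, None])
    est, se, t, df, p, reason = t_test_exposure(fit, dm)
    # oracle: closed-form simple regression (Sxy/Sxx, RSS/(n-2))
    assert est[0] == pytest.approx(0.9, abs=1e-12)
    assert se[0] == pytest.approx(np.sqrt(0.07), abs=1e-12)
    assert t[0] == pytest.approx(0.9 / np.sqrt(0.07), abs=1e-12)
    assert p[0] == pytest.approx(2 * stats.t.sf(0.9 / np.sqrt(0.07), 2), abs=1e-12)
    assert p[0] == pytest.approx(0.0766, abs=2e-4)


def test_constant_cpg_gives_t0_p1():
    dm = make_design(np.column_stack([np.ones(5), np.arange(5.0)]))
    fit = ols_block(dm, np.full((5, 1), 0.4))
    est, se, t, df, p, reason = t_test_exposure(fit, dm)
    assert est[0] == 0.0 and t[0] == 0.0 and p[0] == 1.0


def test_perfect_fit_gives_na_not_inf():
    dm = make_design(np.column_stack([np.ones(4), np.arange(4.0)]))
    fit = ols_block(dm, (0.1 + 0.2 * np.arange(4.0))[:, None])
    est, se, t, df, p, reason = t_test_exposure(fit, dm)
    assert np.isnan(p[0]) and reason[0] == "zero_residual_variance"
    assert not np.isinf(t[0])


def test_bulk_matches_per_site_reference():
    """Bulk closed-form OLS equals an independent per-site least-squares fit."""
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    n, m = 120, 250
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    dm = make_design(X)
    Y = rng.normal(size=(n, m))
    fit = ols_block(dm, Y)
    est, se, t, df, p, _ = t_test_exposure(fit, dm)
    for j in range(0, m, 17):
        ref = sm.OLS(Y[:, j], X).fit()
        assert np.max(np.abs(ref.params - fit.B[:, j])) < 1e-10
        assert np.max(np.abs(ref.bse - fit.SE[:, j])) < 1e-10
        assert abs(ref.pvalues[1] - p[j]) < 1e-10


def test_shift_and_scale_equivariance():
    rng = np.random.default_rng(3)
    n = 80
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    dm = make_design(X)
    Y = rng.normal(size=(n, 5))
    est, se, t, df, p, _ = t_test_exposure(ols_block(dm, Y), dm)
    # shifting the outcome only moves the intercept
    est2, _, t2, _, p2, _ = t_test_exposure(ols_block(dm, Y + 3.7), dm)
    np.testing.assert_allclose(est2, est, atol=1e-12)
    np.testing.assert_allclose(p2, p, atol=1e-12)
    # scaling the exposure by c scales estimates by 1/c, leaves t and p alone
    dmc = make_design(np.column_stack([np.ones(n), 4.0 * x]))
    est3, _, t3, _, p3, _ = t_test_exposure(ols_block(dmc, Y), dmc)
    np.testing.assert_allclose(est3, est / 4.0, atol=1e-12)
    np.testing.assert_allclose(t3, t, rtol=1e-10)
    np.testing.assert_allclose(p3, p, rtol=1e-10)


# ---------------------------------------------------------------------------
# categorical exposure F test
# ---------------------------------------------------------------------------

def test_two_level_f_equals_t_squared():
    rng = np.random.default_rng(11)
    n, m = 60, 40
    grp = rng.integers(0, 2, size=n).astype(float)
    X = np.column_stack([np.ones(n), grp, rng.normal(size=n)])
    dm = make_design(X)
    dm.exposure_is_categorical = True
    Y = rng.normal(size=(n, m))
    F, df1, df2, pf, _, fit_full = f_test_exposure(dm, drop_exposure(dm), Y)
    est, se, t, df, pt, _ = t_test_exposure(fit_full, dm)
    np.testing.assert_allclose(F, t ** 2, rtol=1e-10)
    np.testing.assert_allclose(pf, pt, rtol=1e-10)


def test_f_statistic_nonnegative_nested_property():
    rng = np.random.default_rng(2)
    n, m = 50, 100
    grp = rng.integers(0, 3, size=n)
    X = np.column_stack([np.ones(n), (grp == 1).astype(float), (grp == 2).astype(float)])
    dm = make_design(X, exposure_columns=(1, 2))
    Y = rng.normal(size=(n, m))
    F, df1, df2, p, _, _ = f_test_exposure(dm, drop_exposure(dm), Y)
    assert df1 == 2
    assert np.all(F >= 0)
    assert np.all((p > 0) & (p <= 1))


# ---------------------------------------------------------------------------
# robust regression
# ---------------------------------------------------------------------------

def test_huber_reduces_to_ols_with_huge_tuning():
    rng = np.random.default_rng(9)
    n = 50
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    dm = make_design(X)
    y = 0.5 + 0.3 * X[:, 1] + rng.normal(0, 0.2, size=n)
    fit = rlm_site(dm, y, tuning_c=1e6)
    ols = dm.hat @ y
    assert np.max(np.abs(fit.beta - ols)) < 1e-8
    assert fit.converged


def test_huber_resists_gross_outlier():
    dm = make_design(np.column_stack([np.ones(4), np.arange(4.0)]))
    y_clean = np.array([1.0, 2.0, 2.0, 4.0])
    slope_clean = (dm.hat @ y_clean)[1]
    y_out = y_clean.copy()
    y_out[3] = 40.0
    slope_ols = (dm.hat @ y_out)[1]
    slope_rob = rlm_site(dm, y_out).beta[1]
    assert abs(slope_rob - slope_clean) < abs(slope_ols - slope_clean)


def test_huber_weights_flag_outliers_only():
    rng = np.random.default_rng(4)
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    dm = make_design(X)
    y = X @ np.array([1.0, 0.5]) + rng.normal(0, 0.3, size=n)
    y[5] += 5.0
    fit = rlm_site(dm, y)
    r = y - X @ fit.beta
    s = np.median(np.abs(r)) / 0.6745
    downweighted = fit.weights_final < 1.0
    assert np.array_equal(downweighted, np.abs(r / s) > fit.tuning_c)
    assert np.all((fit.weights_final > 0) & (fit.weights_final <= 1))


def test_robust_matches_statsmodels_coefficients():
    """Independent Huber-IRLS oracle: coefficients agree closely."""
    import statsmodels.api as sm

    rng = np.random.default_rng(21)
    n = 100
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    dm = make_design(X)
    y = X @ np.array([0.2, 0.8]) + rng.standard_t(df=3, size=n)
    fit = rlm_site(dm, y, max_iter=200, tol=1e-10)
    ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
        scale_est="mad", maxiter=200, tol=1e-10)
    assert np.max(np.abs(fit.beta - ref.params)) < 1e-3


# ---------------------------------------------------------------------------
# streamed drivers
# ---------------------------------------------------------------------------

def test_ewas_outcome_table_contract(small_sim):
    tab = lm_ewas_outcome(small_sim["mlist"], "phenotype", ["age", "sex"],
                          block_size=64)
    assert list(tab.columns[:12]) == mb.EWAS_COLUMNS
    ok = tab["p"].notna()
    assert np.all(tab.loc[ok, "p_bh"] >= tab.loc[ok, "p"] - 1e-15)
    # canonical CpG order
    assert tab["cpg_id"].tolist() == [
        b for blk in mb.iter_blocks(small_sim["store"]) for b in blk.cpg_ids
    ]


def test_missing_betas_use_per_site_complete_case(small_sim):
    store = small_sim["store"]
    tab = lm_ewas_outcome(small_sim["mlist"], "phenotype", ["age"])
    full = mb.store.read_selection(store)
    n_missing = full[store.sample_ids].isna().sum(axis=1).to_numpy()
    assert np.array_equal(tab["n_used"].to_numpy(), store.n_samples - n_missing)


def test_block_and_worker_invariance(small_sim):
    base = lm_ewas_outcome(small_sim["mlist"], "phenotype", ["age", "sex"],
                           block_size=50_000)
    for bs, wk in [(17, 1), (123, 1), (50_000, 4)]:
        other = lm_ewas_outcome(small_sim["mlist"], "phenotype", ["age", "sex"],
                                block_size=bs, workers=wk)
        pd.testing.assert_frame_equal(base, other, check_exact=True)


def test_planted_effects_recovered(tmp_path):
    cfg = mb.SimConfig(n_samples=300, n_cpgs=1000, n_chroms=4, n_causal=5,
                       effect_size=1.5, seed=29)
    store, samples, cpgs, truth = mb.simulate_methylation(cfg, tmp_path / "sim")
    ml = mb.create_methlist(store, samples, cpgs)
    tab = lm_ewas_outcome(ml, "phenotype", ["age", "sex"])
    hits = set(tab.loc[tab["p_bh"] < 0.05, "cpg_id"])
    assert set(truth.causal_cpg_ids) <= hits


def test_flex_matches_internal_ols(small_sim):
    def ols_fn(y, X, meta):
        n, p = X.shape
        xtx_inv = np.linalg.inv(X.T @ X)
        b = xtx_inv @ (X.T @ y)
        r = y - X @ b
        s2 = (r @ r) / (n - p)
        se = np.sqrt(s2 * np.diag(xtx_inv))
        t = b[1] / se[1]
        return b[1], se[1], t, 2 * stats.t.sf(abs(t), n - p)

    ref = lm_ewas_outcome(small_sim["mlist"], "phenotype", ["age"])
    flx = flex_ewas(small_sim["mlist"], ols_fn, "phenotype", ["age"])
    for col in ("estimate", "se", "statistic", "p", "p_bh"):
        np.testing.assert_allclose(flx[col].to_numpy(), ref[col].to_numpy(),
                                   rtol=1e-8, atol=1e-12, equal_nan=True)


def test_flex_captures_per_site_exceptions(small_sim):
    bad_ids = set(small_sim["mlist"].cpgs.index[:3])

    def flaky(y, X, meta):
        if meta["cpg_id"] in bad_ids:
            raise RuntimeError("numerical meltdown")
        return 0.0, 1.0, 0.0, 1.0

    tab = flex_ewas(small_sim["mlist"], flaky, "phenotype")
    failed = tab[tab["reason"].notna()]
    assert set(failed["cpg_id"]) == bad_ids
    assert failed["reason"].str.contains("numerical meltdown").all()
    assert tab["p"].notna().sum() == len(tab) - 3


def test_flex_rejects_bad_signature(small_sim):
    with pytest.raises(TypeError):
        flex_ewas(small_sim["mlist"], lambda y: y, "phenotype")
    with pytest.raises(TypeError):
        flex_ewas(small_sim["mlist"], "not callable", "phenotype")
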