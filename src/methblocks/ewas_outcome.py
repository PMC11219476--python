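"""Methylation-as-outcome EWAS.

For each CpG the model is

    beta_cpg = b0 + b1 * exposure + b2..bk * covariates + error

fitted by ordinary least squares for every CpG in a block at once (one
factorization of X'X shared by all CpGs), by Huber robust regression site by
site, or by an arbitrary user-supplied per-site model (``flex_ewas``).
Continuous exposures are tested with a t-test on the exposure coefficient;
categorical exposures with a joint F-test on their dummy columns.

All per-CpG linear algebra runs through per-column BLAS-2 kernels so result
tables are byte-identical for any block size and worker count.
"""

from __future__ import annotations

import inspect
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .methlist import MethList
from .results import finalize_table
from .store import ExtractionQuery, iter_blocks, resolve_query

_COND_LIMIT = 1e10  # condition-number threshold for declaring rank deficiency
_MAD_CONST = 0.6745  # MAD -> sigma consistency factor for normal errors


class DesignError(ValueError):
    """Fatal design-matrix construction error."""


@dataclass
class DesignMatrix:
    """Fixed design shared by every CpG: intercept, exposure, covariates."""

    X: np.ndarray
    column_names: list[str]
    exposure_columns: list[int]
    sample_ids: list[str]
    dropped_samples: list[str]
    exposure_is_categorical: bool = False

    def __post_init__(self):
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise DesignError(f"n ({self.n}) must exceed number of columns ({self.p})")
        # one shared factorization: explicit (X'X)^-1 with a condition check
        xtx = self.X.T @ self.X
        cond = np.linalg.cond(xtx)
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            raise DesignError(
                "design matrix is rank deficient or ill-conditioned "
                f"(cond(X'X) = {cond:.3g}); collinear columns: "
                f"{_collinear_columns(self.X, self.column_names)}"
            )
        self.xtx_inv = np.linalg.inv(xtx)
        self.hat = self.xtx_inv @ self.X.T          # p x n, maps y -> beta
        self.inv_diag = np.diag(self.xtx_inv).copy()

    @property
    def df_resid(self) -> int:
        return self.n - self.p


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan naming columns that lie in the span of earlier ones."""
    bad = []
    for j in range(1, X.shape[1]):
        sub = X[:, : j + 1]
        if np.linalg.matrix_rank(sub) <= np.linalg.matrix_rank(X[:, :j]):
            bad.append(names[j])
    return bad


def _is_categorical(series: pd.Series) -> bool:
    return (
        isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == object
        or pd.api.types.is_bool_dtype(series)
        or pd.api.types.is_string_dtype(series)
    )


def _encode(series: pd.Series, name: str, categorical: bool) -> tuple[np.ndarray, list[str]]:
    """Encode one annotation column: passthrough or dummy (drop first level)."""
    if not categorical:
        return series.to_numpy(dtype=float)[:, None], [name]
    levels = sorted(pd.unique(series.astype(str)))
    if len(levels) < 2:
        raise DesignError(f"categorical column {name!r} has a single level after complete-case")
    cols = [
        (series.astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]
    ]
    return np.column_stack(cols), [f"{name}_{lev}" for lev in levels[1:]]


def build_design(
    mlist: MethList,
    exposure: str,
    covariates: list[str] | tuple[str, ...] = (),
    categorical: set[str] | None = None,
    continuous: set[str] | None = None,
) -> DesignMatrix:
    """Build the n x p design matrix [intercept | exposure | covariates].

    Samples with any missing exposure/covariate value are dropped
    (complete-case); sample order is the store's column order. String-typed
    columns are treated as categorical and dummy-encoded dropping the first
    (lexicographically smallest) level; override with ``categorical`` /
    ``continuous`` name sets.
    """
    categorical = set(categorical or ())
    continuous = set(continuous or ())
    cols = [exposure] + list(covariates)
    missing = [c for c in cols if c not in mlist.samples.columns]
    if missing:
        raise DesignError(f"columns not in sample annotation: {missing}")
    sub = mlist.samples[cols]
    keep = sub.notna().all(axis=1)
    dropped = list(sub.index[~keep])
    sub = sub.loc[keep]
    if len(sub) == 0:
        raise DesignError("no samples remain after complete-case filtering")

    def cat(name: str) -> bool:
        if name in categorical:
            return True
        if name in continuous:
            return False
        return _is_categorical(sub[name])

    exp_cat = cat(exposure)
    exp_block, exp_names = _encode(sub[exposure], exposure, exp_cat)
    if not exp_cat and np.ptp(exp_block) == 0:
        raise DesignError(f"exposure {exposure!r} is constant after complete-case filtering")
    blocks = [np.ones((len(sub), 1)), exp_block]
    names = ["intercept"] + exp_names
    for cov in covariates:
        blk, nms = _encode(sub[cov], cov, cat(cov))
        blocks.append(blk)
        names.extend(nms)
    X = np.hstack(blocks)
    exposure_columns = list(range(1, 1 + exp_block.shape[1]))
    return DesignMatrix(
        X=X,
        column_names=names,
        exposure_columns=exposure_columns,
        sample_ids=list(sub.index),
        dropped_samples=dropped,
        exposure_is_categorical=exp_cat,
    )


def drop_exposure(dm: DesignMatrix) -> DesignMatrix:
    """The nested design without the exposure columns (for F tests)."""
    keep = [j for j in range(dm.p) if j not in dm.exposure_columns]
    return DesignMatrix(
        X=dm.X[:, keep],
        column_names=[dm.column_names[j] for j in keep],
        exposure_columns=[],
        sample_ids=dm.sample_ids,
        dropped_samples=dm.dropped_samples,
    )


@dataclass
class OlsBlockFit:
    """Closed-form OLS fits for a block of CpGs sharing one design."""

    B: np.ndarray        # p x m coefficients
    RSS: np.ndarray      # length m
    sigma2: np.ndarray   # RSS / (n - p)
    SE: np.ndarray       # p x m
    df_resid: int


def ols_block(dm: DesignMatrix, Y: np.ndarray) -> OlsBlockFit:
    """Fit every column of ``Y`` (n x m, one CpG per column) by OLS.

    Uses the design's single precomputed factorization; each CpG costs two
    matrix-vector products. Identical to per-site least squares.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != dm.n:
        raise ValueError(f"Y has {Y.shape[0]} rows, design has {dm.n}")
    m = Y.shape[1]
    B = np.empty((dm.p, m))
    RSS = np.empty(m)
    # per-column gemv keeps results independent of block width (bit-stable
    # across block sizes / worker counts); factorization still shared
    for j in range(m):
        y = Y[:, j]
        if np.ptp(y) == 0.0:
            # constant outcome: exact solution is intercept-only, zero RSS
            B[:, j] = 0.0
            B[0, j] = y[0]
            RSS[j] = 0.0
            continue
        b = dm.hat @ y
        r = y - dm.X @ b
        B[:, j] = b
        rss = r @ r
        # a numerically perfect fit leaves only rounding residue; snap it to
        # zero so degenerate CpGs are flagged instead of yielding huge t
        RSS[j] = 0.0 if rss <= 1e-24 * max(y @ y, 1.0) else rss
    df = dm.df_resid
    sigma2 = RSS / df
    SE = np.sqrt(sigma2[None, :] * dm.inv_diag[:, None])
    return OlsBlockFit(B=B, RSS=RSS, sigma2=sigma2, SE=SE, df_resid=df)


def test_exposure_continuous(fit: OlsBlockFit, dm: DesignMatrix):
    """Per-CpG t-test on the (single) exposure coefficient.

    Returns (estimate, se, t, df, p, reason) arrays. CpGs with zero residual
    variance get t = 0, p = 1 when the estimate is also zero (constant CpG),
    otherwise NA with a reason code (perfect fit leaves the test undefined).
    """
    if len(dm.exposure_columns) != 1:
        raise ValueError("continuous exposure test requires exactly one exposure column")
    j = dm.exposure_columns[0]
    est = fit.B[j].copy()
    se = fit.SE[j].copy()
    m = est.size
    t = np.full(m, np.nan)
    p = np.full(m, np.nan)
    reason = np.array([None] * m, dtype=object)
    zero_var = fit.sigma2 <= 0
    ok = ~zero_var
    t[ok] = est[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), fit.df_resid)
    const = zero_var & (est == 0)
    t[const], p[const] = 0.0, 1.0
    degen = zero_var & (est != 0)
    est[degen] = np.nan
    se[zero_var] = np.nan
    se[const] = np.nan
    reason[degen] = "zero_residual_variance"
    return est, se, t, np.full(m, fit.df_resid, dtype=float), p, reason


def test_exposure_categorical(dm_full: DesignMatrix, dm_reduced: DesignMatrix, Y: np.ndarray):
    """Joint F-test of the exposure dummy columns via two bulk OLS passes.

    Returns (F, df1, df2, p, reason, fit_full). F = [(RSS_r - RSS_f)/df1] /
    [RSS_f/df2]; a perfectly fitted CpG (RSS_f = 0) is reported NA.
    """
    fit_full = ols_block(dm_full, Y)
    fit_red = ols_block(dm_reduced, Y)
    df1 = dm_full.p - dm_reduced.p
    df2 = fit_full.df_resid
    num = np.maximum(fit_red.RSS - fit_full.RSS, 0.0) / df1
    m = Y.shape[1] if Y.ndim == 2 else 1
    F = np.full(m, np.nan)
    p = np.full(m, np.nan)
    reason = np.array([None] * m, dtype=object)
    ok = fit_full.RSS > 0
    if df1 == 1:
        # single dummy: the joint F test is algebraically the squared
        # coefficient t statistic; computing it that way avoids the
        # cancellation in RSS_r - RSS_f and makes F == t^2 an exact identity
        j = dm_full.exposure_columns[0]
        tstat = fit_full.B[j][ok] / fit_full.SE[j][ok]
        F[ok] = tstat * tstat
    else:
        F[ok] = num[ok] / (fit_full.RSS[ok] / df2)
    p[ok] = stats.f.sf(F[ok], df1, df2)
    const = (~ok) & (fit_red.RSS <= 0)
    F[const], p[const] = 0.0, 1.0
    reason[(~ok) & (fit_red.RSS > 0)] = "zero_residual_variance"
    return F, df1, df2, p, reason, fit_full


@dataclass
class RobustFit:
    """Huber M-estimate for one CpG."""

    beta: np.ndarray
    se: np.ndarray
    weights_final: np.ndarray
    iterations: int
    converged: bool
    tuning_c: float
    df_resid: int

    @property
    def t(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    def p_values(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.t), self.df_resid)


def rlm_site(
    dm: DesignMatrix,
    y: np.ndarray,
    tuning_c: float = 1.345,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> RobustFit:
    """Huber IRLS M-estimation for a single CpG.

    Scale is re-estimated each iteration as MAD(residuals)/0.6745 (MAD about
    zero, the usual robust-regression convention). Standard errors come from
    the M-estimator sandwich with Huber psi weights.
    """
    X = dm.X
    n, p = X.shape
    y = np.asarray(y, dtype=float)
    beta = dm.hat @ y
    w = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        s = np.median(np.abs(r)) / _MAD_CONST
        if s <= 0:
            converged = True  # perfect fit; nothing left to reweight
            w = np.ones(n)
            break
        u = r / s
        absu = np.abs(u)
        w = np.where(absu <= tuning_c, 1.0, tuning_c / absu)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new

    r = y - X @ beta
    s = np.median(np.abs(r)) / _MAD_CONST
    if s <= 0:
        se = np.zeros(p)
    else:
        u = r / s
        psi = np.clip(u, -tuning_c, tuning_c) * s
        psi_prime = (np.abs(u) <= tuning_c).astype(float)
        A = X.T @ (X * psi_prime[:, None])
        Bmat = X.T @ (X * (psi ** 2)[:, None])
        Ainv = np.linalg.pinv(A)
        cov = (n / (n - p)) * Ainv @ Bmat @ Ainv.T
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return RobustFit(
        beta=beta,
        se=se,
        weights_final=w,
        iterations=it,
        converged=converged,
        tuning_c=tuning_c,
        df_resid=n - p,
    )


# ---------------------------------------------------------------------------
# block-streamed drivers
# ---------------------------------------------------------------------------

_NA_ROW_KEYS = ("estimate", "se", "statistic", "df", "p", "n_used")


def _design_on_subset(dm: DesignMatrix, mask: np.ndarray) -> DesignMatrix | None:
    """Rebuild the design on a complete-case row subset; None if degenerate."""
    X = dm.X[mask]
    if X.shape[0] <= X.shape[1]:
        return None
    try:
        return DesignMatrix(
            X=X,
            column_names=dm.column_names,
            exposure_columns=list(dm.exposure_columns),
            sample_ids=[s for s, k in zip(dm.sample_ids, mask) if k],
            dropped_samples=dm.dropped_samples,
            exposure_is_categorical=dm.exposure_is_categorical,
        )
    except DesignError:
        return None


def _block_rows_ols(block, Yb: np.ndarray, dm_full: DesignMatrix,
                    dm_red: DesignMatrix | None) -> pd.DataFrame:
    """Test one block: bulk path for complete CpGs, per-site for the rest."""
    m = Yb.shape[1]
    categorical = dm_full.exposure_is_categorical
    out = {
        "cpg_id": block.cpg_ids,
        "chrom": block.chrom,
        "estimate": np.full(m, np.nan),
        "se": np.full(m, np.nan),
        "statistic": np.full(m, np.nan),
        "stat_type": ["F" if categorical else "t"] * m,
        "df": np.full(m, np.nan),
        "p": np.full(m, np.nan),
        "n_used": np.full(m, dm_full.n, dtype=int),
        "reason": np.array([None] * m, dtype=object),
    }
    dummy_names = (
        [dm_full.column_names[j] for j in dm_full.exposure_columns] if categorical else []
    )
    dummy_est = {nm: np.full(m, np.nan) for nm in dummy_names}
    dummy_se = {nm: np.full(m, np.nan) for nm in dummy_names}

    complete = np.isfinite(Yb).all(axis=0)

    def fill(idx, est, se, statistic, df, p, reason, n_used, per_dummy=None):
        out["estimate"][idx] = est
        out["se"][idx] = se
        out["statistic"][idx] = statistic
        out["df"][idx] = df
        out["p"][idx] = p
        out["reason"][idx] = reason
        out["n_used"][idx] = n_used
        if per_dummy is not None:
            for nm, (e, s_) in per_dummy.items():
                dummy_est[nm][idx] = e
                dummy_se[nm][idx] = s_

    if complete.any():
        idx = np.flatnonzero(complete)
        Yc = Yb[:, idx]
        if categorical:
            F, df1, df2, p, reason, fit_full = test_exposure_categorical(dm_full, dm_red, Yc)
            j0 = dm_full.exposure_columns[0]
            est0 = fit_full.B[j0] if len(dm_full.exposure_columns) == 1 else np.full(len(idx), np.nan)
            se0 = fit_full.SE[j0] if len(dm_full.exposure_columns) == 1 else np.full(len(idx), np.nan)
            per_dummy = {
                dm_full.column_names[j]: (fit_full.B[j], fit_full.SE[j])
                for j in dm_full.exposure_columns
            }
            fill(idx, est0, se0, F, df2, p, reason, dm_full.n, per_dummy)
        else:
            fit = ols_block(dm_full, Yc)
            est, se, t, df, p, reason = test_exposure_continuous(fit, dm_full)
            fill(idx, est, se, t, df, p, reason, dm_full.n)

    for j in np.flatnonzero(~complete):
        y = Yb[:, j]
        mask = np.isfinite(y)
        sub = _design_on_subset(dm_full, mask)
        if sub is None:
            out["reason"][j] = "insufficient_complete_samples"
            out["n_used"][j] = int(mask.sum())
            continue
        if categorical:
            sub_red = _design_on_subset(dm_red, mask)
            if sub_red is None:
                out["reason"][j] = "insufficient_complete_samples"
                out["n_used"][j] = sub.n
                continue
            F, df1, df2, p, reason, fit_full = test_exposure_categorical(sub, sub_red, y[mask][:, None])
            j0 = sub.exposure_columns[0]
            est0 = fit_full.B[j0, 0] if len(sub.exposure_columns) == 1 else np.nan
            se0 = fit_full.SE[j0, 0] if len(sub.exposure_columns) == 1 else np.nan
            per_dummy = {
                sub.column_names[k]: (fit_full.B[k, 0], fit_full.SE[k, 0])
                for k in sub.exposure_columns
            }
            fill(j, est0, se0, F[0], df2, p[0], reason[0], sub.n, per_dummy)
        else:
            fit = ols_block(sub, y[mask][:, None])
            est, se, t, df, p, reason = test_exposure_continuous(fit, sub)
            fill(j, est[0], se[0], t[0], df[0], p[0], reason[0], sub.n)

    df = pd.DataFrame(out)
    for nm in dummy_names:
        df[f"estimate__{nm}"] = dummy_est[nm]
        df[f"se__{nm}"] = dummy_se[nm]
    return df


def _block_rows_robust(block, Yb: np.ndarray, dm_full: DesignMatrix,
                       tuning_c: float) -> pd.DataFrame:
    m = Yb.shape[1]
    if dm_full.exposure_is_categorical and len(dm_full.exposure_columns) > 1:
        raise ValueError("robust path supports a single exposure column (continuous or 2-level)")
    jexp = dm_full.exposure_columns[0]
    out = {
        "cpg_id": block.cpg_ids,
        "chrom": block.chrom,
        "estimate": np.full(m, np.nan),
        "se": np.full(m, np.nan),
        "statistic": np.full(m, np.nan),
        "stat_type": ["t"] * m,
        "df": np.full(m, np.nan),
        "p": np.full(m, np.nan),
        "n_used": np.zeros(m, dtype=int),
        "reason": np.array([None] * m, dtype=object),
    }
    for j in range(m):
        y = Yb[:, j]
        mask = np.isfinite(y)
        sub = dm_full if mask.all() else _design_on_subset(dm_full, mask)
        if sub is None:
            out["reason"][j] = "insufficient_complete_samples"
            out["n_used"][j] = int(mask.sum())
            continue
        fit = rlm_site(sub, y[mask], tuning_c=tuning_c)
        out["n_used"][j] = sub.n
        if fit.se[jexp] <= 0:
            if fit.beta[jexp] == 0:
                out["estimate"][j], out["statistic"][j], out["p"][j] = 0.0, 0.0, 1.0
                out["df"][j] = fit.df_resid
            else:
                out["reason"][j] = "zero_residual_variance"
            continue
        out["estimate"][j] = fit.beta[jexp]
        out["se"][j] = fit.se[jexp]
        out["statistic"][j] = fit.t[jexp]
        out["df"][j] = fit.df_resid
        out["p"][j] = fit.p_values()[jexp]
        if not fit.converged:
            out["reason"][j] = "irls_not_converged"
    return pd.DataFrame(out)


def _block_rows_flex(block, Yb: np.ndarray, dm_full: DesignMatrix, model_fn) -> pd.DataFrame:
    m = Yb.shape[1]
    out = {
        "cpg_id": block.cpg_ids,
        "chrom": block.chrom,
        "estimate": np.full(m, np.nan),
        "se": np.full(m, np.nan),
        "statistic": np.full(m, np.nan),
        "stat_type": ["custom"] * m,
        "df": np.full(m, np.nan),
        "p": np.full(m, np.nan),
        "n_used": np.zeros(m, dtype=int),
        "reason": np.array([None] * m, dtype=object),
    }
    for j in range(m):
        y = Yb[:, j]
        mask = np.isfinite(y)
        out["n_used"][j] = int(mask.sum())
        meta = {
            "cpg_id": block.cpg_ids[j],
            "chrom": block.chrom[j],
            "column_names": dm_full.column_names,
            "exposure_columns": dm_full.exposure_columns,
        }
        try:
            est, se, statistic, p = model_fn(y[mask], dm_full.X[mask], meta)
            out["estimate"][j] = est
            out["se"][j] = se
            out["statistic"][j] = statistic
            out["p"][j] = p
        except Exception as exc:  # per-site failure never aborts the scan
            out["reason"][j] = f"model_error: {exc}"
    return pd.DataFrame(out)


def _run_blocks(mlist: MethList, analysis_sample_ids: list[str], block_fn,
                block_size: int, workers: int,
                query: ExtractionQuery | None) -> pd.DataFrame:
    """Stream blocks, apply ``block_fn`` (optionally in a thread pool), and
    concatenate per-block tables in block order (deterministic output)."""
    store = mlist.store
    col_idx = [store.sample_ids.index(s) for s in analysis_sample_ids]
    if query is not None:
        query = resolve_query(mlist, query)

    def task(block):
        Yb = block.values[:, col_idx].T  # n x m
        return block.block_index, block_fn(block, np.ascontiguousarray(Yb))

    blocks = iter_blocks(store, block_size=block_size, query=query)
    pieces: dict[int, pd.DataFrame] = {}
    if workers <= 1:
        for block in blocks:
            i, df = task(block)
            pieces[i] = df
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            pending = []
            for block in blocks:
                pending.append(pool.submit(task, block))
                if len(pending) >= workers * 2:  # bound in-flight blocks
                    i, df = pending.pop(0).result()
                    pieces[i] = df
            for fut in pending:
                i, df = fut.result()
                pieces[i] = df
    if not pieces:
        raise ValueError("query selected zero CpGs; nothing to test")
    ordered = [pieces[i] for i in sorted(pieces)]
    rows = pd.concat(ordered, ignore_index=True)
    return _attach_annotation(mlist, rows)


def _attach_annotation(mlist: MethList, rows: pd.DataFrame) -> pd.DataFrame:
    pos_col = "position" if "position" in mlist.cpgs.columns else None
    if pos_col:
        rows["position"] = (
            mlist.cpgs[pos_col].reindex(rows["cpg_id"]).to_numpy(dtype=float)
        )
    else:
        rows["position"] = np.nan
    return finalize_table(rows)


def lm_ewas_outcome(
    mlist: MethList,
    exposure: str,
    covariates: list[str] | tuple[str, ...] = (),
    block_size: int = 50_000,
    robust: bool = False,
    workers: int = 1,
    query: ExtractionQuery | None = None,
    tuning_c: float = 1.345,
    **design_kwargs,
) -> pd.DataFrame:
    """EWAS with methylation as the outcome, streamed in CpG blocks.

    ``robust=False`` dispatches complete CpGs to the bulk closed-form OLS
    path and CpGs with missing betas to per-site complete-case OLS;
    ``robust=True`` runs Huber regression site by site. BH adjustment is
    applied once over all tested CpGs; the table is in canonical CpG order.
    """
    dm = build_design(mlist, exposure, covariates, **design_kwargs)
    dm_red = drop_exposure(dm) if dm.exposure_is_categorical else None
    if robust:
        fn = lambda blk, Yb: _block_rows_robust(blk, Yb, dm, tuning_c)
    else:
        fn = lambda blk, Yb: _block_rows_ols(blk, Yb, dm, dm_red)
    return _run_blocks(mlist, dm.sample_ids, fn, block_size, workers, query)


def flex_ewas(
    mlist: MethList,
    model_fn,
    exposure: str,
    covariates: list[str] | tuple[str, ...] = (),
    block_size: int = 50_000,
    workers: int = 1,
    query: ExtractionQuery | None = None,
    **design_kwargs,
) -> pd.DataFrame:
    """Site-by-site EWAS with a user-supplied model.

    ``model_fn(y, X, metadata)`` must return ``(estimate, se, statistic,
    p)``; per-site exceptions become NA rows carrying the message. BH runs
    over successfully tested CpGs only.
    """
    if not callable(model_fn):
        raise TypeError("model_fn must be callable")
    try:
        sig = inspect.signature(model_fn)
        positional = [
            p for p in sig.parameters.values()
            if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD, p.VAR_POSITIONAL)
        ]
        if not positional or (len(positional) < 3 and positional[-1].kind != inspect.Parameter.VAR_POSITIONAL):
            raise TypeError("model_fn must accept (y, X, metadata)")
    except ValueError:
        pass  # builtins without introspectable signatures: trust the caller
    dm = build_design(mlist, exposure, covariates, **design_kwargs)
    fn = lambda blk, Yb: _block_rows_flex(blk, Yb, dm, model_fn)
    return _run_blocks(mlist, dm.sample_ids, fn, block_size, workers, query)
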