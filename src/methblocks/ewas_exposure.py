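"""Methylation-as-exposure EWAS via null-model score tests.

The phenotype model

    y = Z alpha + g beta_g + error

is fitted once *without* any CpG (the null model: simple linear, logistic or
Poisson GLM, or a linear mixed model with a relatedness matrix K inducing
covariance sigma2_g * K + sigma2_e * I). Every CpG g is then evaluated with
an efficient score test against that single fit, so the per-CpG cost is a
few matrix-vector products instead of a full model refit:

    linear:   g~ = g - Z(Z'Z)^-1 Z'g,  U = g~'r / s2,  V = g~'g~ / s2
    GLM:      U = g'(y - mu),  V = g'Wg - g'WZ (Z'WZ)^-1 Z'Wg
    LMM:      with P = S^-1 - S^-1 Z (Z'S^-1 Z)^-1 Z'S^-1 (S the fitted
              covariance): U = g'Py, V = g'Pg

T = U^2/V is chi-square(1) under the null; U/V is a score-based effect
estimate. Variance components are held fixed at their null-model REML
estimates for all CpGs (the standard two-stage approximation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .methlist import MethList
from .store import ExtractionQuery

logger = logging.getLogger(__name__)

_FAMILIES = ("linear", "logistic", "poisson", "lmm")
_V_FLOOR = 1e-12
_GLM_TOL = 1e-8
_GLM_MAX_ITER = 100
_REML_LOG_RATIO_BOUNDS = (np.log(1e-6), np.log(1e6))


class NullModelError(ValueError):
    """Fatal null-model fitting error."""


@dataclass
class NullModelFit:
    """Fitted phenotype null model plus the projections score tests need."""

    family: str
    Z: np.ndarray                 # n x q covariate design, intercept included
    alpha: np.ndarray
    residuals: np.ndarray         # y - yhat (linear/lmm) or y - mu (GLM)
    W: np.ndarray                 # working weights (ones for linear)
    y: np.ndarray
    sample_ids: list[str]
    column_names: list[str]
    sigma2: float | None = None            # residual variance (linear)
    varcomp: dict | None = None            # {"sigma2_g", "sigma2_e"} for lmm
    K: np.ndarray | None = None
    cache: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def q(self) -> int:
        return self.Z.shape[1]


def _build_Z(mlist: MethList, outcome: str, covariates, categorical, continuous):
    from .ewas_outcome import DesignError, _encode, _is_categorical

    categorical = set(categorical or ())
    continuous = set(continuous or ())
    cols = [outcome] + list(covariates)
    missing = [c for c in cols if c not in mlist.samples.columns]
    if missing:
        raise NullModelError(f"columns not in sample annotation: {missing}")
    sub = mlist.samples[cols].dropna()
    if len(sub) == 0:
        raise NullModelError("no samples remain after complete-case filtering")

    def cat(name):
        if name in categorical:
            return True
        if name in continuous:
            return False
        return _is_categorical(sub[name])

    blocks = [np.ones((len(sub), 1))]
    names = ["intercept"]
    for cov in covariates:
        blk, nms = _encode(sub[cov], cov, cat(cov))
        blocks.append(blk)
        names.extend(nms)
    Z = np.hstack(blocks)
    y = sub[outcome].to_numpy(dtype=float)
    return Z, y, names, list(sub.index)


def _reml_lmm(y: np.ndarray, Z: np.ndarray, K: np.ndarray):
    """REML fit of y ~ Z alpha + u, u ~ N(0, sigma2_g K), via the
    eigendecomposition of K and 1-D optimization of the variance ratio."""
    n, q = Z.shape
    evals, U = np.linalg.eigh(K)
    if evals.min() < -1e-8:
        raise NullModelError(
            f"kinship matrix is not positive semidefinite (min eigenvalue {evals.min():.3g})"
        )
    evals = np.maximum(evals, 0.0)
    if np.ptp(evals) < 1e-8:
        warnings.warn(
            "kinship eigenvalues are constant (K proportional to I): variance "
            "components are unidentifiable, only their sum is estimated"
        )
    yt = U.T @ y
    Zt = U.T @ Z

    def profile(gamma: float):
        v = gamma * evals + 1.0
        wi = 1.0 / v
        ZtWZ = Zt.T @ (Zt * wi[:, None])
        ZtWy = Zt.T @ (yt * wi)
        alpha = np.linalg.solve(ZtWZ, ZtWy)
        r = yt - Zt @ alpha
        rss = r @ (r * wi)
        sigma2_e = rss / (n - q)
        sign, logdet_ZtWZ = np.linalg.slogdet(ZtWZ)
        ll = -0.5 * (
            (n - q) * np.log(sigma2_e)
            + np.sum(np.log(v))
            + logdet_ZtWZ
            + (n - q)
        )
        return ll, alpha, sigma2_e

    # grid bracket on log gamma, then Brent refinement; gamma = 0 boundary too
    lo, hi = _REML_LOG_RATIO_BOUNDS
    grid = np.linspace(lo, hi, 61)
    lls = np.array([profile(np.exp(g))[0] for g in grid])
    best = int(np.argmax(lls))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -profile(np.exp(g))[0], bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    gamma = float(np.exp(res.x))
    ll_opt = -res.fun
    ll0, _, _ = profile(0.0)
    if ll0 >= ll_opt:
        gamma = 0.0
    ll, alpha, sigma2_e = profile(gamma)
    sigma2_g = gamma * sigma2_e
    return gamma, sigma2_g, sigma2_e, alpha, U, evals, ll


def fit_null(
    mlist: MethList,
    outcome: str,
    covariates: list[str] | tuple[str, ...] = (),
    family: str = "linear",
    kinship: pd.DataFrame | np.ndarray | None = None,
    categorical=None,
    continuous=None,
) -> NullModelFit:
    """Fit the phenotype null model (no CpG terms).

    ``family`` is one of linear, logistic, poisson, lmm; ``kinship`` is
    required for (and only for) the lmm family and may be a DataFrame
    indexed/columned by sample id (realigned automatically) or an ndarray
    already in analysis sample order.
    """
    if family not in _FAMILIES:
        raise NullModelError(f"family must be one of {_FAMILIES}")
    if (kinship is None) != (family != "lmm"):
        raise NullModelError("kinship is required iff family == 'lmm'")
    Z, y, names, ids = _build_Z(mlist, outcome, covariates, categorical, continuous)
    n, q = Z.shape
    fit = NullModelFit(
        family=family, Z=Z, alpha=np.zeros(q), residuals=np.zeros(n),
        W=np.ones(n), y=y, sample_ids=ids, column_names=names,
    )

    if family == "linear":
        Q, _ = np.linalg.qr(Z)
        alpha, *_ = np.linalg.lstsq(Z, y, rcond=None)
        r = y - Z @ alpha
        fit.alpha, fit.residuals = alpha, r
        fit.sigma2 = float(r @ r) / (n - q)
        fit.cache["Q"] = Q
        return fit

    if family in ("logistic", "poisson"):
        if family == "logistic":
            uniq = np.unique(y)
            if not np.all(np.isin(uniq, [0.0, 1.0])):
                raise NullModelError("logistic family requires a 0/1 outcome")
        alpha = np.zeros(q)
        if family == "logistic":
            alpha[0] = np.log((y.mean() + 1e-8) / (1 - y.mean() + 1e-8))
        else:
            if np.any(y < 0):
                raise NullModelError("poisson family requires nonnegative counts")
            alpha[0] = np.log(max(y.mean(), 1e-8))
        ll_prev = -np.inf
        trace = []
        for it in range(1, _GLM_MAX_ITER + 1):
            eta = Z @ alpha
            if family == "logistic":
                mu = 1.0 / (1.0 + np.exp(-eta))
                w = mu * (1.0 - mu)
                ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
            else:
                mu = np.exp(eta)
                w = mu
                ll = float(np.sum(y * eta - mu))
            w = np.maximum(w, 1e-10)
            z_work = eta + (y - mu) / w
            Zw = Z * w[:, None]
            alpha_new = np.linalg.solve(Zw.T @ Z, Zw.T @ z_work)
            trace.append(ll)
            if np.max(np.abs(alpha_new - alpha)) < _GLM_TOL * (1 + np.max(np.abs(alpha))):
                alpha = alpha_new
                break
            alpha = alpha_new
            if not np.isfinite(ll):
                raise NullModelError(f"GLM diverged (family {family}); trace: {trace[-5:]}")
            ll_prev = ll
        else:
            raise NullModelError(
                f"GLM IRLS did not converge in {_GLM_MAX_ITER} iterations; "
                f"log-likelihood trace tail: {trace[-5:]}"
            )
        eta = Z @ alpha
        mu = 1.0 / (1.0 + np.exp(-eta)) if family == "logistic" else np.exp(eta)
        W = mu * (1.0 - mu) if family == "logistic" else mu
        if np.min(W) < 1e-9:
            raise NullModelError(
                "fitted GLM is separated (weights collapse to 0); score test undefined"
            )
        fit.alpha = alpha
        fit.residuals = y - mu
        fit.W = W
        sw = np.sqrt(W)
        Qw, _ = np.linalg.qr(Z * sw[:, None])
        fit.cache["Qw"] = Qw
        fit.cache["sqrtW"] = sw
        return fit

    # lmm
    if isinstance(kinship, pd.DataFrame):
        missing = [s for s in ids if s not in kinship.index]
        if missing:
            raise NullModelError(f"kinship matrix lacks samples: {missing[:10]}")
        K = kinship.loc[ids, ids].to_numpy(dtype=float)
    else:
        K = np.asarray(kinship, dtype=float)
        if K.shape != (n, n):
            raise NullModelError(
                f"kinship shape {K.shape} does not match {n} analysis samples; "
                "pass a DataFrame with sample-id index/columns to realign"
            )
    K = 0.5 * (K + K.T)
    gamma, s2g, s2e, alpha, U, evals, ll = _reml_lmm(y, Z, K)
    Sigma_inv = (U * (1.0 / (s2g * evals + s2e))[None, :]) @ U.T
    SiZ = Sigma_inv @ Z
    ZtSiZ_inv = np.linalg.inv(Z.T @ SiZ)
    P = Sigma_inv - SiZ @ ZtSiZ_inv @ SiZ.T
    fit.alpha = alpha
    fit.residuals = y - Z @ alpha
    fit.varcomp = {"sigma2_g": s2g, "sigma2_e": s2e, "gamma": gamma, "reml_loglik": ll}
    fit.K = K
    fit.cache["P"] = P
    fit.cache["Py"] = P @ y
    logger.info("REML: sigma2_g=%.4g sigma2_e=%.4g", s2g, s2e)
    return fit


def _score_one_complete(null: NullModelFit, g: np.ndarray):
    if null.family == "linear":
        Q = null.cache["Q"]
        gt = g - Q @ (Q.T @ g)
        U = float(gt @ null.residuals) / null.sigma2
        V = float(gt @ gt) / null.sigma2
    elif null.family in ("logistic", "poisson"):
        sw, Qw = null.cache["sqrtW"], null.cache["Qw"]
        gw = g * sw
        proj = Qw.T @ gw
        U = float(g @ null.residuals)
        V = float(gw @ gw - proj @ proj)
    else:
        P, Py = null.cache["P"], null.cache["Py"]
        U = float(g @ Py)
        V = float(g @ (P @ g))
    return U, V


def _score_one_subset(null: NullModelFit, g: np.ndarray, mask: np.ndarray):
    """Score test for a CpG observed only on a subsample: the projection is
    recomputed on the subset, null-model parameters stay fixed."""
    Zs = null.Z[mask]
    gs = g[mask]
    if Zs.shape[0] <= Zs.shape[1] + 1:
        return np.nan, np.nan
    if null.family == "linear":
        Qs, _ = np.linalg.qr(Zs)
        gt = gs - Qs @ (Qs.T @ gs)
        U = float(gt @ null.residuals[mask]) / null.sigma2
        V = float(gt @ gt) / null.sigma2
    elif null.family in ("logistic", "poisson"):
        sw = null.cache["sqrtW"][mask]
        Qs, _ = np.linalg.qr(Zs * sw[:, None])
        gw = gs * sw
        proj = Qs.T @ gw
        U = float(gs @ null.residuals[mask])
        V = float(gw @ gw - proj @ proj)
    else:
        s2g, s2e = null.varcomp["sigma2_g"], null.varcomp["sigma2_e"]
        Sigma = s2g * null.K[np.ix_(mask, mask)] + s2e * np.eye(int(mask.sum()))
        Si = np.linalg.inv(Sigma)
        SiZ = Si @ Zs
        Ps = Si - SiZ @ np.linalg.inv(Zs.T @ SiZ) @ SiZ.T
        U = float(gs @ (Ps @ null.y[mask]))
        V = float(gs @ (Ps @ gs))
    return U, V


def score_test_block(null: NullModelFit, G: np.ndarray) -> pd.DataFrame:
    """Score-test each column of ``G`` (n x m, CpGs as columns) against the
    null model. Returns a DataFrame of U, V, statistic, p, estimate, se and
    an NA reason where the score variance vanishes."""
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[0] != null.n:
        raise ValueError(f"G has {G.shape[0]} rows, null model has {null.n} samples")
    m = G.shape[1]
    out = {
        "U": np.full(m, np.nan), "V": np.full(m, np.nan),
        "statistic": np.full(m, np.nan), "p": np.full(m, np.nan),
        "estimate": np.full(m, np.nan), "se": np.full(m, np.nan),
        "n_used": np.zeros(m, dtype=int),
        "reason": np.array([None] * m, dtype=object),
    }
    for j in range(m):
        g = G[:, j]
        mask = np.isfinite(g)
        if mask.all():
            U, V = _score_one_complete(null, g)
            out["n_used"][j] = null.n
        else:
            U, V = _score_one_subset(null, g, mask)
            out["n_used"][j] = int(mask.sum())
            if np.isnan(V):
                out["reason"][j] = "insufficient_complete_samples"
                continue
        if V <= _V_FLOOR:
            out["reason"][j] = "zero_score_variance"
            continue
        T = U * U / V
        out["U"][j], out["V"][j] = U, V
        out["statistic"][j] = T
        out["p"][j] = stats.chi2.sf(T, 1)
        out["estimate"][j] = U / V
        out["se"][j] = 1.0 / np.sqrt(V)
    return pd.DataFrame(out)


def ewas_meth_exposure(
    mlist: MethList,
    null: NullModelFit,
    block_size: int = 50_000,
    workers: int = 1,
    query: ExtractionQuery | None = None,
) -> pd.DataFrame:
    """EWAS treating each CpG as the exposure for the null-model phenotype.

    Streams the store in blocks, score-tests every CpG against the fixed
    null fit, and applies BH over all tested CpGs. Output is byte-identical
    across block sizes and worker counts.
    """
    from .ewas_outcome import _run_blocks

    missing = [s for s in null.sample_ids if s not in set(mlist.store.sample_ids)]
    if missing:
        raise NullModelError(f"null-model samples absent from store: {missing[:10]}")

    def block_fn(block, Gb):
        res = score_test_block(null, Gb)
        res.insert(0, "chrom", block.chrom)
        res.insert(0, "cpg_id", block.cpg_ids)
        res["stat_type"] = "score"
        res["df"] = 1.0
        return res.drop(columns=["U", "V"])

    from .ewas_outcome import _attach_annotation  # noqa: F401 (used via _run_blocks)

    return _run_blocks(mlist, null.sample_ids, block_fn, block_size, workers, query)


def read_kinship(path, sep: str | None = None) -> pd.DataFrame:
    """Read a kinship matrix: square with id header row+column, or
    long-format (id1, id2, value) which is symmetrized with unit diagonal
    unless self-pairs are given."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=None)
    if df.shape[1] == 3 and not np.issubdtype(df.dtypes.iloc[0], np.number):
        id1, id2, val = df.columns
        ids = sorted(set(df[id1].astype(str)) | set(df[id2].astype(str)))
        K = pd.DataFrame(0.0, index=ids, columns=ids)
        np.fill_diagonal(K.values, 1.0)
        for _, row in df.iterrows():
            a, b, v = str(row[id1]), str(row[id2]), float(row[val])
            K.loc[a, b] = v
            K.loc[b, a] = v
        return K
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
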