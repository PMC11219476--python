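"""Methylation risk scores: weighted sums of CpG beta values.

A methylation risk score for sample i is s_i = sum_j w_j * m_ij over the
CpGs of an externally supplied weight table (weights are signed per CpG;
there is no effect-allele or strand logic as in genetic risk scores). Only
the weight-table CpGs are queried from the Parquet store, so memory scales
with the number of matched CpGs, not the store size. The score can then be
tested against an outcome with linear, logistic or multinomial regression
(the multinomial test is a likelihood-ratio test on the score term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methlist import MethList
from .store import ExtractionQuery, read_selection


class MrsError(ValueError):
    """Fatal MRS construction or testing error."""


def read_weights(path, sep: str | None = None) -> pd.DataFrame:
    """Read a weight table: first column CpG id, second column weight;
    extra columns are ignored with a notice."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.shape[1] < 2:
        raise MrsError("weight table needs at least (cpg_id, weight) columns")
    if df.shape[1] > 2:
        warnings.warn(f"ignoring extra weight-table columns: {list(df.columns[2:])}")
    out = df.iloc[:, :2].copy()
    out.columns = ["cpg_id", "weight"]
    out["cpg_id"] = out["cpg_id"].astype(str)
    out["weight"] = out["weight"].astype(float)
    if out["cpg_id"].duplicated().any():
        dup = out["cpg_id"][out["cpg_id"].duplicated()].iloc[0]
        raise MrsError(f"duplicate CpG id in weight table: {dup!r}")
    if not np.isfinite(out["weight"]).all():
        raise MrsError("weights must be finite")
    return out


def dev_meth_score(
    mlist: MethList,
    weights: pd.DataFrame,
    scale: bool = False,
    average: bool = False,
) -> pd.DataFrame:
    """Compute per-sample methylation risk scores.

    Queries only the weight CpGs from the store (predicate pushdown). A
    missing beta contributes 0 to the sample's score and is counted in
    ``n_sites_missing``; ``average`` divides by the per-sample number of
    sites used; ``scale`` standardizes across samples (applied last).

    Returns a DataFrame indexed by sample id with columns score,
    n_sites_used, n_sites_missing.
    """
    if weights["cpg_id"].duplicated().any():
        raise MrsError("duplicate CpG ids in weight table")
    store = mlist.store
    wanted = weights["cpg_id"].tolist()
    data = read_selection(store, ExtractionQuery.by_cpg(wanted))
    matched = data[store.cpg_id_column].tolist()
    if not matched:
        raise MrsError(
            f"none of the {len(wanted)} weight CpGs are present in the store; "
            f"first unmatched: {wanted[:10]}"
        )
    unmatched = len(wanted) - len(matched)
    w = weights.set_index("cpg_id")["weight"].loc[matched].to_numpy()
    sample_ids = mlist.sample_ids
    M = data[sample_ids].to_numpy(dtype=float).T  # samples x matched CpGs
    miss = ~np.isfinite(M)
    M = np.where(miss, 0.0, M)
    # explicit ordered accumulation over CpGs (canonical store order): the
    # Parquet-backed score is then exactly the naive dense weighted sum
    score = np.zeros(len(sample_ids))
    for j in range(M.shape[1]):
        score += w[j] * M[:, j]
    n_missing_beta = miss.sum(axis=1)
    n_used = len(matched) - n_missing_beta
    if average:
        if np.any(n_used == 0):
            raise MrsError("some samples have no observed weight CpGs; cannot average")
        score = score / n_used
    if scale:
        sd = score.std(ddof=1)
        if sd <= 0:
            raise MrsError("scores have zero variance; cannot scale")
        score = (score - score.mean()) / sd
    return pd.DataFrame(
        {
            "score": score,
            "n_sites_used": n_used,
            "n_sites_missing": len(wanted) - n_used,
        },
        index=pd.Index(sample_ids, name=mlist.sample_key),
    ).assign(scaled=scale, averaged=average, n_unmatched_cpgs=unmatched)


# ---------------------------------------------------------------------------
# association testing
# ---------------------------------------------------------------------------


@dataclass
class MRSAssocResult:
    """Association of an MRS with an outcome."""

    model: str                 # linear | logistic | multinomial
    test: str                  # wald_t | wald_z | lrt
    estimate: float | np.ndarray
    se: float | np.ndarray
    statistic: float
    df: float
    p: float
    n: int
    outcome_levels: list | None = None


def _ols_wald(X, y):
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sigma2 = (r @ r) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov)), n - p


def _logistic_fit(X, y, tol=1e-10, max_iter=100):
    """IRLS logistic fit; returns (beta, cov, loglik)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-8) / (1 - y.mean() + 1e-8))
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    else:
        raise MrsError("logistic regression did not converge")
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-10)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, cov, ll


def _multinomial_fit(X, Y_onehot, tol=1e-10, max_iter=200):
    """Newton fit of a baseline-category logit model.

    ``Y_onehot`` is n x K (first category is the baseline). Returns
    (B ((K-1) x p), loglik).
    """
    n, p = X.shape
    K = Y_onehot.shape[1]
    B = np.zeros((K - 1, p))
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = X @ B.T                       # n x (K-1)
        emax = np.maximum(eta.max(axis=1, keepdims=True), 0.0)
        denom = np.exp(-emax)[:, 0] + np.exp(eta - emax).sum(axis=1)
        logden = emax[:, 0] + np.log(denom)
        Pi = np.exp(eta - logden[:, None])  # n x (K-1), baseline = 1 - sum
        ll = float(np.sum(Y_onehot[:, 1:] * eta) - np.sum(logden))
        grad = np.zeros((K - 1) * p)
        H = np.zeros(((K - 1) * p, (K - 1) * p))
        for k in range(K - 1):
            grad[k * p:(k + 1) * p] = X.T @ (Y_onehot[:, k + 1] - Pi[:, k])
            for l in range(K - 1):
                wkl = Pi[:, k] * ((1.0 if k == l else 0.0) - Pi[:, l])
                H[k * p:(k + 1) * p, l * p:(l + 1) * p] = X.T @ (X * wkl[:, None])
        step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), grad)
        B = B + step.reshape(K - 1, p)
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            break
        ll_prev = ll
    else:
        raise MrsError("multinomial regression did not converge")
    eta = X @ B.T
    emax = np.maximum(eta.max(axis=1, keepdims=True), 0.0)
    logden = emax[:, 0] + np.log(np.exp(-emax)[:, 0] + np.exp(eta - emax).sum(axis=1))
    ll = float(np.sum(Y_onehot[:, 1:] * eta) - np.sum(logden))
    return B, ll


def test_mrs(
    mrs: pd.DataFrame,
    samples: pd.DataFrame,
    outcome: str,
    covariates: list[str] | tuple[str, ...] = (),
    model: str = "auto",
) -> MRSAssocResult:
    """Test the association between an MRS and an outcome.

    ``model='auto'`` maps a numeric outcome to linear regression, a 2-level
    outcome to logistic and a >=3-level outcome to multinomial. Linear and
    logistic report Wald tests on the MRS coefficient; multinomial reports
    a likelihood-ratio test with df = levels - 1 comparing the model with
    and without the MRS term (covariates in both).
    """
    from .ewas_outcome import _encode, _is_categorical

    if outcome not in samples.columns:
        raise MrsError(f"outcome column {outcome!r} not in sample annotation")
    score = mrs["score"] if isinstance(mrs, pd.DataFrame) else pd.Series(mrs)
    idx = [s for s in score.index if s in samples.index]
    df = samples.loc[idx, [outcome] + list(covariates)].copy()
    df["__mrs__"] = score.loc[idx]
    df = df.dropna()
    if len(df) == 0:
        raise MrsError("no overlapping, complete samples between MRS and annotation")
    y_raw = df[outcome]

    if model == "auto":
        if _is_categorical(y_raw):
            model = "logistic" if y_raw.nunique() == 2 else "multinomial"
        else:
            k = y_raw.nunique()
            if k < 2:
                raise MrsError("outcome is constant")
            model = "linear"
    if model not in ("linear", "logistic", "multinomial"):
        raise MrsError(f"unknown model {model!r}")
    if y_raw.nunique() < 2:
        raise MrsError("outcome is constant")

    blocks = [np.ones((len(df), 1)), df["__mrs__"].to_numpy(dtype=float)[:, None]]
    for cov in covariates:
        blk, _ = _encode(df[cov], cov, _is_categorical(df[cov]))
        blocks.append(blk)
    X = np.hstack(blocks)
    X0 = np.delete(X, 1, axis=1)  # nested model without the MRS term
    n = len(df)

    if model == "linear":
        beta, se, dof = _ols_wald(X, y_raw.to_numpy(dtype=float))
        t = beta[1] / se[1]
        p = 2 * stats.t.sf(abs(t), dof)
        return MRSAssocResult("linear", "wald_t", float(beta[1]), float(se[1]),
                              float(t), float(dof), float(p), n)

    levels = sorted(y_raw.astype(str).unique())
    if model == "logistic":
        if len(levels) != 2:
            raise MrsError(f"logistic model needs a 2-level outcome, got {len(levels)}")
        y = (y_raw.astype(str) == levels[1]).to_numpy(dtype=float)
        beta, cov, _ = _logistic_fit(X, y)
        se = float(np.sqrt(cov[1, 1]))
        z = float(beta[1]) / se
        p = 2 * stats.norm.sf(abs(z))
        return MRSAssocResult("logistic", "wald_z", float(beta[1]), se, z, 1.0,
                              float(p), n, outcome_levels=levels)

    K = len(levels)
    Y = np.column_stack([(y_raw.astype(str) == lev).to_numpy(dtype=float) for lev in levels])
    B_full, ll_full = _multinomial_fit(X, Y)
    _, ll_null = _multinomial_fit(X0, Y)
    lrt = 2.0 * (ll_full - ll_null)
    dof = K - 1
    p = stats.chi2.sf(lrt, dof)
    return MRSAssocResult("multinomial", "lrt", B_full[:, 1].copy(),
                          np.full(K - 1, np.nan), float(lrt), float(dof),
                          float(p), n, outcome_levels=levels)
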