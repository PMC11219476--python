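"""Standardized EWAS result tables, BH adjustment and plot-ready data.

Every association routine in the package emits the same tab-friendly table
(one row per tested CpG) so that QQ/Manhattan plotting and downstream
filtering never depend on which regression produced the results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical column order of an EWAS result table.
EWAS_COLUMNS = [
    "cpg_id",
    "chrom",
    "position",
    "estimate",
    "se",
    "statistic",
    "stat_type",
    "df",
    "p",
    "p_bh",
    "n_used",
    "reason",
]

# median of chi-square(1); denominator of the genomic-inflation factor
_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)

#: Smallest positive double; p-values of exactly 0 are floored here before
#: any -log10 transform so plots never see infinities.
P_FLOOR = np.nextafter(0.0, 1.0)


def bh_adjust(p, n_tests: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaN entries are excluded from the effective number of tests and
    preserved in place (the convention of the major statistical packages).

    Parameters
    ----------
    p : array-like of float
        Raw p-values in [0, 1]; NaN allowed.
    n_tests : int, optional
        Override the effective number of tests (must be >= number of
        non-NaN p-values). Used when adjusting a partial vector.

    Returns
    -------
    numpy.ndarray
        Adjusted p-values, same shape and order as ``p``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = int(ok.sum())
    if m == 0:
        return out
    if n_tests is not None:
        if n_tests < m:
            raise ValueError("n_tests smaller than number of p-values")
        m = int(n_tests)
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, pv.size + 1)
    # enforce monotonicity from the largest p downward (step-up)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty_like(q)
    adj[order] = q
    out[ok] = adj
    return out


def finalize_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Apply BH adjustment over all tested CpGs and order the columns.

    ``rows`` must contain all :data:`EWAS_COLUMNS` except ``p_bh``; extra
    columns (e.g. per-dummy estimates) are kept after the canonical ones.
    """
    rows = rows.copy()
    rows["p_bh"] = bh_adjust(rows["p"].to_numpy(dtype=float))
    extra = [c for c in rows.columns if c not in EWAS_COLUMNS]
    return rows[EWAS_COLUMNS + extra].reset_index(drop=True)


def write_ewas_table(table: pd.DataFrame, path) -> None:
    """Write an EWAS table as TSV with full float precision."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def lambda_gc(p) -> float:
    """Genomic inflation factor: median observed chi-square(1) / null median."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no non-missing p-values")
    p = np.maximum(p, P_FLOOR)
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


@dataclass
class PlotData:
    """QQ and Manhattan coordinates derived from an EWAS table."""

    qq: pd.DataFrame          # columns: expected, observed (-log10 p, sorted)
    manhattan: pd.DataFrame   # columns: x, neglog10p, chrom, cpg_id
    lambda_gc: float


def make_plot_data(table: pd.DataFrame, chrom_order: list[str] | None = None) -> PlotData:
    """Build QQ/Manhattan-ready coordinates from an EWAS result table.

    Expected QQ quantile for rank i of m is -log10((i - 0.5) / m).
    Manhattan x-coordinates place each chromosome after the previous one's
    last position (cumulative offsets in canonical chromosome order), so
    coordinates never overlap across chromosomes.
    """
    from .store import chrom_sort_key

    p = table["p"].to_numpy(dtype=float)
    ok = ~np.isnan(p)
    if not ok.any():
        raise ValueError("all p-values are missing; nothing to plot")
    pv = np.maximum(p[ok], P_FLOOR)
    m = pv.size
    observed = -np.log10(np.sort(pv))
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected": expected[::-1], "observed": observed[::-1]})

    sub = table.loc[ok, ["cpg_id", "chrom", "position", "p"]].copy()
    sub["chrom"] = sub["chrom"].astype(str)
    if chrom_order is None:
        chrom_order = sorted(sub["chrom"].unique(), key=chrom_sort_key)
    offset = 0.0
    xs = np.empty(len(sub))
    for chrom in chrom_order:
        mask = (sub["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = sub.loc[mask, "position"].to_numpy(dtype=float)
        xs[mask] = pos + offset
        offset += pos.max()
    sub["x"] = xs
    sub["neglog10p"] = -np.log10(np.maximum(sub["p"].to_numpy(dtype=float), P_FLOOR))
    manhattan = sub[["x", "neglog10p", "chrom", "cpg_id"]].reset_index(drop=True)
    return PlotData(qq=qq, manhattan=manhattan, lambda_gc=lambda_gc(pv))


def plot_qq(plot_data: PlotData, path) -> None:
    """Render a QQ plot to ``path`` (PNG). Plotting is a convenience; the
    guaranteed contract is the PlotData numbers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(plot_data.qq["expected"], plot_data.qq["observed"], s=4, color="k")
    lim = max(plot_data.qq["expected"].max(), plot_data.qq["observed"].max())
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel("expected -log10(p)")
    ax.set_ylabel("observed -log10(p)")
    ax.set_title(f"lambda_gc = {plot_data.lambda_gc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_manhattan(plot_data: PlotData, path) -> None:
    """Render a Manhattan plot to ``path`` (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    for i, (chrom, grp) in enumerate(plot_data.manhattan.groupby("chrom", sort=False)):
        ax.scatter(grp["x"], grp["neglog10p"], s=3,
                   color="steelblue" if i % 2 == 0 else "darkorange", label=None)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("-log10(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
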