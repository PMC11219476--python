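"""Binding of a methylation store to sample- and CpG-level annotations.

A MethList is the unit every analysis consumes: the open store connection
plus validated annotation tables. Sample alignment is single-sourced — all
downstream design matrices are built in the store's column order restricted
to the samples present in the annotation, so annotation row order can never
silently misalign phenotypes with methylation columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .store import MethStore

logger = logging.getLogger(__name__)

#: Column names reserved for result tables; annotations may not use them.
RESERVED_COLUMNS = {"estimate", "se", "statistic", "stat_type", "df", "p", "p_bh", "reason"}


class MethListError(ValueError):
    """Fatal annotation-validation error."""


def read_annotation(path, key_column: str, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited annotation table (comma/tab autodetected)."""
    df = pd.read_csv(Path(path), sep=sep, engine="python" if sep is None else "c")
    if key_column not in df.columns:
        raise MethListError(f"key column {key_column!r} not in {path}")
    return df


@dataclass
class MethList:
    """Validated binding of store + sample annotation + CpG annotation.

    ``samples`` is indexed by sample id and ordered like the store's sample
    columns (restricted to the intersection); ``cpgs`` is indexed by CpG id.
    """

    store: MethStore
    samples: pd.DataFrame
    cpgs: pd.DataFrame
    sample_key: str = "sample_id"
    cpg_key: str = "cpg_id"
    gene_column: str = "gene"
    unannotated_cpgs: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        """Analysis-facing sample order (store order, intersected)."""
        return list(self.samples.index)


def create_methlist(
    store: MethStore,
    samples: pd.DataFrame,
    cpgs: pd.DataFrame,
    sample_key: str = "sample_id",
    cpg_key: str = "cpg_id",
    gene_column: str = "gene",
    sample_cols: list[str] | None = None,
    cpg_cols: list[str] | None = None,
    missing_cpg_policy: str = "error",
) -> MethList:
    """Validate and bind annotations to a store.

    Samples are intersected with the store's columns (dropped annotations
    and unannotated store samples are logged/warned); store CpGs absent from
    the CpG annotation are fatal unless ``missing_cpg_policy`` is
    ``"annotate-missing-as-unknown"``, in which case they are flagged and
    carried with empty annotation.
    """
    if missing_cpg_policy not in ("error", "annotate-missing-as-unknown"):
        raise MethListError(f"unknown missing_cpg_policy {missing_cpg_policy!r}")
    for name, df, key in (("sample", samples, sample_key), ("CpG", cpgs, cpg_key)):
        if key not in df.columns:
            raise MethListError(f"{name} annotation lacks key column {key!r}")
        dup = df[key][df[key].duplicated()]
        if len(dup):
            raise MethListError(f"duplicate {name} annotation key: {dup.iloc[0]!r}")

    bad = RESERVED_COLUMNS.intersection(samples.columns)
    if bad:
        raise MethListError(f"sample annotation uses reserved result-column names: {sorted(bad)}")

    samples = samples.copy()
    samples[sample_key] = samples[sample_key].astype(str)
    samples = samples.set_index(sample_key)
    if sample_cols is not None:
        samples = samples[list(sample_cols)]
    store_samples = [str(s) for s in store.sample_ids]
    matched = [s for s in store_samples if s in samples.index]
    if not matched:
        raise MethListError("no overlap between store sample columns and sample annotation ids")
    dropped_store = [s for s in store_samples if s not in samples.index]
    unused_ann = [s for s in samples.index if s not in set(store_samples)]
    samples = samples.loc[matched]
    logger.info(
        "samples: %d matched, %d store samples without annotation, %d unused annotation rows",
        len(matched), len(dropped_store), len(unused_ann),
    )
    if dropped_store:
        warnings.warn(
            f"{len(dropped_store)} store sample(s) missing from annotation are "
            f"excluded from analysis: {dropped_store[:10]}"
        )

    cpgs = cpgs.copy()
    cpgs[cpg_key] = cpgs[cpg_key].astype(str)
    cpgs = cpgs.set_index(cpg_key)
    if cpg_cols is not None:
        cpgs = cpgs[list(cpg_cols)]
    # identify store CpGs without annotation (reads only the id column)
    store_ids = _store_cpg_ids(store)
    known = set(cpgs.index)
    missing = [c for c in store_ids if c not in known]
    if missing:
        if missing_cpg_policy == "error":
            raise MethListError(
                f"{len(missing)} store CpGs missing from CpG annotation "
                f"(first: {missing[:5]}); use policy 'annotate-missing-as-unknown' to keep them"
            )
        logger.info("%d store CpGs carried without annotation", len(missing))
    logger.info("CpGs: %d annotated, %d unannotated", len(store_ids) - len(missing), len(missing))

    return MethList(
        store=store,
        samples=samples,
        cpgs=cpgs,
        sample_key=sample_key,
        cpg_key=cpg_key,
        gene_column=gene_column,
        unannotated_cpgs=missing,
    )


def _store_cpg_ids(store: MethStore) -> list[str]:
    """All CpG ids in canonical order (reads only the id column)."""
    import pyarrow.parquet as pq

    ids: list[str] = []
    for _, path in store.files():
        ids.extend(
            pq.read_table(path, columns=[store.cpg_id_column])
            .column(store.cpg_id_column)
            .to_pylist()
        )
    return ids
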