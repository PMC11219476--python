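"""Chromosome-partitioned Parquet storage for CpG x sample methylation matrices.

The store holds one float64 column per sample plus a string CpG-identifier
column, hive-partitioned by chromosome (``chrom=1/``, ``chrom=X/`` ...).
All reads stream fixed-size CpG blocks so memory stays bounded by the block
size times the sample count, never by the full matrix. CpG-subset reads use
Parquet predicate pushdown; sample-subset reads are column projections.

Canonical row order is: partitions sorted with natural chromosome ordering
(1..22 numerically, then X, Y, MT, then anything else lexicographically),
and within a partition the original source row order. Row indices in
``by_rows`` queries are 0-based, half-open over this canonical order.
"""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.dataset as pads
import pyarrow.parquet as pq

META_FILENAME = "_methstore.json"
_ROW_GROUP_ROWS = 50_000
_MISSING_TOKENS = {"", "na", "nan", "null", "none", "n/a", "."}


class StoreError(ValueError):
    """Fatal store-format or store-content error."""


def chrom_sort_key(label: str):
    """Sort key giving natural chromosome order: 1..22, X, Y, MT, others."""
    s = str(label)
    core = s[3:] if s.lower().startswith("chr") else s
    if core.isdigit():
        return (0, int(core), s)
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if core.upper() in special:
        return (0, special[core.upper()], s)
    return (1, 0, s)


@dataclass
class ExtractionQuery:
    """A row selector over a store: exactly one of the four modes."""

    mode: str
    cpg_names: list[str] | None = None
    genes: list[str] | None = None
    chroms: list[str] | None = None
    row_range: tuple[int, int] | None = None

    def __post_init__(self):
        selectors = {
            "by_cpg": self.cpg_names,
            "by_gene": self.genes,
            "by_chrom": self.chroms,
            "by_rows": self.row_range,
        }
        if self.mode not in selectors:
            raise ValueError(f"unknown query mode {self.mode!r}")
        populated = [m for m, v in selectors.items() if v is not None]
        if populated != [self.mode]:
            raise ValueError(
                f"query mode {self.mode!r} requires exactly its own selector; got {populated}"
            )
        if self.mode == "by_rows":
            start, stop = self.row_range
            if start < 0 or stop < start:
                raise ValueError("row_range must be a half-open interval [start, stop) with 0 <= start <= stop")

    @classmethod
    def by_cpg(cls, names: Sequence[str]) -> "ExtractionQuery":
        return cls(mode="by_cpg", cpg_names=list(names))

    @classmethod
    def by_gene(cls, genes: Sequence[str]) -> "ExtractionQuery":
        return cls(mode="by_gene", genes=list(genes))

    @classmethod
    def by_chrom(cls, chroms: Sequence[str]) -> "ExtractionQuery":
        return cls(mode="by_chrom", chroms=[str(c) for c in chroms])

    @classmethod
    def by_rows(cls, start: int, stop: int) -> "ExtractionQuery":
        return cls(mode="by_rows", row_range=(int(start), int(stop)))


@dataclass
class CpGBlock:
    """An in-memory slab of CpG rows: values is m x n (rows=CpGs, cols=samples)."""

    cpg_ids: list[str]
    chrom: list[str]
    values: np.ndarray
    block_index: int

    @property
    def m(self) -> int:
        return len(self.cpg_ids)


@dataclass
class MethStore:
    """Handle on a chromosome-partitioned Parquet methylation dataset.

    Opening a store reads only schema and metadata; values are streamed on
    demand through :func:`iter_blocks` or :func:`extract`.
    """

    root_uri: str
    sample_ids: list[str]
    cpg_id_column: str
    chrom_column: str
    n_cpgs: int
    chrom_values: list[str]
    conversion_report: dict = field(default_factory=dict)
    rows_materialized: int = 0  # I/O accounting: value rows decoded so far

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def files(self) -> list[tuple[str, Path]]:
        """Partition files in canonical order: (chrom, path) pairs."""
        root = Path(self.root_uri)
        out: list[tuple[str, Path]] = []
        prefix = f"{self.chrom_column}="
        dirs = [d for d in root.iterdir() if d.is_dir() and d.name.startswith(prefix)]
        for d in sorted(dirs, key=lambda d: chrom_sort_key(d.name[len(prefix):])):
            chrom = d.name[len(prefix):]
            for f in sorted(d.glob("*.parquet")):
                out.append((chrom, f))
        return out

    def partition_row_counts(self) -> list[tuple[str, Path, int]]:
        """Per-file row counts from Parquet footers (no value reads)."""
        return [
            (chrom, path, pq.ParquetFile(path).metadata.num_rows)
            for chrom, path in self.files()
        ]


def _coerce_numeric_chunk(chunk: pd.DataFrame, sample_cols: list[str], row_offset: int) -> pd.DataFrame:
    """Coerce sample columns to float64; fatal on any non-numeric cell.

    String cells are parsed with Python's ``float`` (correctly rounded), so
    text sources round-trip bit-exact through the store.
    """
    out = {}
    for col in sample_cols:
        raw = chunk[col]
        if pd.api.types.is_numeric_dtype(raw):
            out[col] = raw.astype(np.float64)
            continue
        parsed = np.empty(len(raw), dtype=np.float64)
        for i, v in enumerate(raw.to_numpy()):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                parsed[i] = np.nan
                continue
            s = str(v).strip()
            if s.lower() in _MISSING_TOKENS:
                parsed[i] = np.nan
                continue
            try:
                parsed[i] = float(s)
            except ValueError:
                raise StoreError(
                    f"non-numeric value {v!r} in sample column {col!r} "
                    f"at source row {row_offset + i}"
                ) from None
        out[col] = pd.Series(parsed, index=raw.index)
    return pd.DataFrame(out, index=chunk.index)


def _iter_source_chunks(source, chunk_rows: int, sep: str | None) -> Iterator[pd.DataFrame]:
    src = Path(source)
    if src.suffix == ".parquet":
        pf = pq.ParquetFile(src)
        for batch in pf.iter_batches(batch_size=chunk_rows):
            yield batch.to_pandas()
    else:
        yield from pd.read_csv(src, sep=sep, engine="python" if sep is None else "c",
                               chunksize=chunk_rows, dtype="object")


def convert_to_parquet(
    source,
    cpg_id_column: str,
    chrom_column: str,
    dest,
    write_chunk_rows: int = 10_000,
    sep: str | None = None,
    force: bool = False,
) -> MethStore:
    """Convert a delimited-text or Parquet methylation table into a store.

    The source is streamed in chunks of at most ``write_chunk_rows`` rows, so
    the full matrix is never resident. Requires a chromosome column (the
    store is partitioned by it) and a unique CpG identifier column; every
    other column is one sample's methylation values, parsed as float64.

    On any validation error the partially written destination is removed.
    """
    if write_chunk_rows < 1:
        raise ValueError("write_chunk_rows must be >= 1")
    dest = Path(dest)
    if dest.exists() and any(dest.iterdir()):
        if not force:
            raise StoreError(f"destination {dest} exists and is not empty (use force=True)")
        shutil.rmtree(dest)
    dest.mkdir(parents=True, exist_ok=True)

    seen_ids: set[str] = set()
    sample_ids: list[str] | None = None
    n_cpgs = 0
    chrom_values: set[str] = set()
    max_chunk = 0
    n_chunks = 0
    try:
        for chunk in _iter_source_chunks(source, write_chunk_rows, sep):
            if sample_ids is None:
                cols = list(chunk.columns)
                if chrom_column not in cols:
                    raise StoreError(
                        f"required chromosome column {chrom_column!r} not found: the "
                        "methylation table must contain a column giving each CpG's "
                        f"chromosome (columns present: {cols[:6]}...)"
                    )
                if cpg_id_column not in cols:
                    raise StoreError(f"CpG identifier column {cpg_id_column!r} not found")
                sample_ids = [c for c in cols if c not in (cpg_id_column, chrom_column)]
                if not sample_ids:
                    raise StoreError("no sample columns found besides the id/chromosome columns")
            ids = chunk[cpg_id_column].astype(str)
            for cid in ids:
                if cid in seen_ids:
                    raise StoreError(f"duplicate CpG identifier {cid!r} in source")
                seen_ids.add(cid)
            chroms = chunk[chrom_column].astype(str)
            values = _coerce_numeric_chunk(chunk, sample_ids, n_cpgs)
            arrays = [pa.array(ids, type=pa.string())]
            names = [cpg_id_column]
            for col in sample_ids:
                arrays.append(pa.array(values[col].to_numpy(), type=pa.float64(), from_pandas=True))
                names.append(col)
            arrays.append(pa.array(chroms, type=pa.string()))
            names.append(chrom_column)
            table = pa.table(dict(zip(names, arrays)))
            pads.write_dataset(
                table,
                dest,
                format="parquet",
                partitioning=pads.partitioning(
                    pa.schema([(chrom_column, pa.string())]), flavor="hive"
                ),
                basename_template=f"chunk-{n_chunks:06d}-{{i}}.parquet",
                existing_data_behavior="overwrite_or_ignore",
                max_rows_per_group=_ROW_GROUP_ROWS,
            )
            chrom_values.update(chroms)
            n_cpgs += len(chunk)
            max_chunk = max(max_chunk, len(chunk))
            n_chunks += 1
        if n_cpgs == 0:
            raise StoreError("source contains no rows")
    except Exception:
        shutil.rmtree(dest, ignore_errors=True)
        raise

    meta = {
        "format": "methblocks-store-v1",
        "cpg_id_column": cpg_id_column,
        "chrom_column": chrom_column,
        "sample_ids": sample_ids,
        "n_cpgs": n_cpgs,
        "chrom_values": sorted(chrom_values, key=chrom_sort_key),
    }
    (dest / META_FILENAME).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return MethStore(
        root_uri=str(dest),
        sample_ids=list(sample_ids),
        cpg_id_column=cpg_id_column,
        chrom_column=chrom_column,
        n_cpgs=n_cpgs,
        chrom_values=meta["chrom_values"],
        conversion_report={
            "n_rows": n_cpgs,
            "n_chunks": n_chunks,
            "max_chunk_rows": max_chunk,
        },
    )


def open_store(root_uri) -> MethStore:
    """Open an existing store, reading only schema and footer metadata."""
    root = Path(root_uri)
    meta_path = root / META_FILENAME
    if not root.is_dir() or not meta_path.exists():
        raise StoreError(f"{root} is not a methylation store: missing {META_FILENAME}")
    meta = json.loads(meta_path.read_text())
    store = MethStore(
        root_uri=str(root),
        sample_ids=list(meta["sample_ids"]),
        cpg_id_column=meta["cpg_id_column"],
        chrom_column=meta["chrom_column"],
        n_cpgs=int(meta["n_cpgs"]),
        chrom_values=list(meta["chrom_values"]),
    )
    files = store.files()
    if not files:
        raise StoreError(f"{root} is not a methylation store: no hive partitions found")
    schema = pq.ParquetFile(files[0][1]).schema_arrow
    expected = [store.cpg_id_column] + store.sample_ids
    if schema.names != expected:
        raise StoreError(
            "not a methylation store: file schema columns "
            f"{schema.names[:5]}... do not match the recorded "
            "{cpg_id} + sample column layout"
        )
    if schema.field(store.cpg_id_column).type != pa.string():
        raise StoreError("not a methylation store: CpG id column is not string-typed")
    for sid in store.sample_ids:
        if schema.field(sid).type != pa.float64():
            raise StoreError(f"not a methylation store: sample column {sid!r} is not float64")
    n = sum(cnt for _, _, cnt in store.partition_row_counts())
    if n != store.n_cpgs:
        raise StoreError(
            f"not a methylation store: partition row counts ({n}) disagree "
            f"with recorded n_cpgs ({store.n_cpgs})"
        )
    return store


def _scan_tables(store: MethStore, query: ExtractionQuery | None) -> Iterator[tuple[str, pa.Table]]:
    """Yield (chrom, table) pieces in canonical order, filtered per query.

    CpG-name queries are pushed down to the Parquet reader; row-range
    queries skip whole files using footer row counts before decoding.
    """
    mode = query.mode if query is not None else None
    if mode == "by_gene":
        raise ValueError("by_gene queries must be resolved to CpG names via a MethList")
    columns = [store.cpg_id_column] + store.sample_ids

    if mode == "by_rows":
        start, stop = query.row_range
        offset = 0
        for chrom, path, count in store.partition_row_counts():
            lo, hi = max(start - offset, 0), min(stop - offset, count)
            if lo < hi:
                table = pq.read_table(path, columns=columns).slice(lo, hi - lo)
                store.rows_materialized += table.num_rows
                yield chrom, table
            offset += count
            if offset >= stop:
                break
        return

    wanted_chroms = set(query.chroms) if mode == "by_chrom" else None
    filt = None
    if mode == "by_cpg":
        filt = pads.field(store.cpg_id_column).isin(query.cpg_names)

    for chrom, path in store.files():
        if wanted_chroms is not None and chrom not in wanted_chroms:
            continue
        if filt is not None:
            frag = pads.dataset(path, format="parquet")
            table = frag.to_table(columns=columns, filter=filt)
        else:
            table = pq.read_table(path, columns=columns)
        if table.num_rows:
            store.rows_materialized += table.num_rows
            yield chrom, table


def _table_to_values(table: pa.Table, sample_ids: list[str]) -> np.ndarray:
    cols = [
        table.column(sid).to_numpy(zero_copy_only=False).astype(np.float64, copy=False)
        for sid in sample_ids
    ]
    return np.column_stack(cols) if cols else np.empty((table.num_rows, 0))


def iter_blocks(
    store: MethStore,
    block_size: int = 50_000,
    query: ExtractionQuery | None = None,
) -> Iterator[CpGBlock]:
    """Stream the selected CpG rows as blocks of at most ``block_size`` rows.

    The concatenation of yielded blocks equals the selection in canonical
    order regardless of block size; a query selecting zero rows yields an
    empty sequence. Missing betas surface as NaN, never as silent zeros.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    buf_ids: list[str] = []
    buf_chroms: list[str] = []
    buf_vals: list[np.ndarray] = []
    buffered = 0
    block_index = 0

    def flush(m: int) -> CpGBlock:
        nonlocal buf_ids, buf_chroms, buf_vals, buffered, block_index
        ids = buf_ids[:m]
        chroms = buf_chroms[:m]
        vals = np.vstack(buf_vals)
        block_vals = vals[:m]
        rest = vals[m:]
        buf_ids, buf_chroms = buf_ids[m:], buf_chroms[m:]
        buf_vals = [rest] if rest.shape[0] else []
        buffered -= m
        blk = CpGBlock(cpg_ids=ids, chrom=chroms, values=block_vals, block_index=block_index)
        block_index += 1
        return blk

    for chrom, table in _scan_tables(store, query):
        buf_ids.extend(table.column(store.cpg_id_column).to_pylist())
        buf_chroms.extend([chrom] * table.num_rows)
        buf_vals.append(_table_to_values(table, store.sample_ids))
        buffered += table.num_rows
        while buffered >= block_size:
            yield flush(block_size)
    if buffered:
        yield flush(buffered)


def read_selection(store: MethStore, query: ExtractionQuery | None = None) -> pd.DataFrame:
    """Materialize a selection as a DataFrame (cpg_id, chrom, sample columns)."""
    frames = []
    for blk in iter_blocks(store, block_size=max(store.n_cpgs, 1), query=query):
        df = pd.DataFrame(blk.values, columns=store.sample_ids)
        df.insert(0, store.chrom_column, blk.chrom)
        df.insert(0, store.cpg_id_column, blk.cpg_ids)
        frames.append(df)
    if not frames:
        cols = [store.cpg_id_column, store.chrom_column] + store.sample_ids
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def resolve_query(mlist, query: ExtractionQuery) -> ExtractionQuery:
    """Resolve a query against a MethList's CpG annotation.

    ``by_gene`` becomes ``by_cpg`` via the annotation's gene column
    (";"-separated multi-gene entries are split). Unknown gene or CpG names
    produce a warning and the resolvable subset is used.
    """
    if query.mode == "by_gene":
        ann = mlist.cpgs
        gene_col = mlist.gene_column
        if gene_col not in ann.columns:
            raise ValueError(f"CpG annotation has no gene column {gene_col!r}")
        exploded = ann[gene_col].fillna("").astype(str).str.split(";")
        membership = exploded.explode().str.strip()
        wanted = set(query.genes)
        found_genes = set(membership[membership.isin(wanted)])
        missing = sorted(wanted - found_genes)
        if missing:
            warnings.warn(f"genes not found in CpG annotation: {missing}")
        if not found_genes:
            return ExtractionQuery.by_cpg([])
        hit = membership.isin(found_genes).groupby(level=0).any()
        cpg_names = ann.index[hit.reindex(ann.index, fill_value=False)].tolist()
        return ExtractionQuery.by_cpg(cpg_names)
    if query.mode == "by_cpg":
        known = set(mlist.cpgs.index)
        store_known = None  # annotation is authoritative for warnings
        missing = [c for c in query.cpg_names if c not in known]
        if missing:
            warnings.warn(f"CpG names not found in annotation: {missing[:10]}")
        return query
    return query


def extract(mlist, query: ExtractionQuery) -> pd.DataFrame:
    """Extract matching rows with merged CpG annotation columns.

    Returns a DataFrame of CpG annotation columns followed by one column per
    sample, in canonical row order; an empty selection returns an empty
    table with the correct schema.
    """
    resolved = resolve_query(mlist, query)
    store = mlist.store
    if resolved.mode == "by_cpg" and not resolved.cpg_names:
        cols = list(mlist.cpgs.reset_index().columns) + store.sample_ids
        return pd.DataFrame(columns=cols)
    data = read_selection(store, resolved)
    ann = mlist.cpgs.reset_index()
    merged = data.merge(ann, how="left", left_on=store.cpg_id_column,
                        right_on=mlist.cpg_key, suffixes=("", "_ann"))
    ann_cols = [c for c in ann.columns if c in merged.columns]
    lead = [store.cpg_id_column] if store.cpg_id_column not in ann_cols else []
    return merged[lead + ann_cols + store.sample_ids]
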