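"""Shared data model and on-disk formats.

The pipeline's universal input is a raw integer gene x cell count matrix
with per-cell metadata (mouse, developmental time point, oxygen condition,
sex).  On disk this is a MatrixMarket coordinate file plus two TSV
sidecars (one row per gene, one row per cell); ligand-receptor pair
databases and all result tables are plain TSV.  These formats are
language-agnostic and diffable, which keeps every fixture in this package
text-only.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

TIMEPOINTS = ("E18.5", "P1", "P7", "P21")
CONDITIONS = ("normoxia", "hyperoxia")
SEXES = ("F", "M", "unknown")

CELL_META_COLUMNS = ["mouse_id", "timepoint", "condition", "sex"]


class FormatError(ValueError):
    """Raised when an on-disk file or in-memory object violates the data contract."""


def _check_axis(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        raise FormatError(f"duplicate {what}: {dupes[dupes > 1].index.tolist()[:5]}")
    return ids


def _validate_meta(cell_meta: pd.DataFrame, cell_ids: list[str]) -> pd.DataFrame:
    missing = [c for c in CELL_META_COLUMNS if c not in cell_meta.columns]
    if missing:
        raise FormatError(f"cell metadata missing required columns: {missing}")
    meta = cell_meta.copy()
    meta.index = pd.Index(cell_ids, name="cell_id")
    for col, allowed in (("timepoint", TIMEPOINTS), ("condition", CONDITIONS)):
        bad = set(meta[col].astype(str)) - set(allowed)
        if bad:
            raise FormatError(f"invalid {col} values {sorted(bad)}; allowed: {allowed}")
        if meta[col].isna().any():
            raise FormatError(f"every cell must have a {col}")
    meta["sex"] = meta["sex"].fillna("unknown").astype(str)
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise FormatError(f"invalid sex values {sorted(bad_sex)}; allowed: {SEXES}")
    return meta


@dataclasses.dataclass
class CountMatrix:
    """Raw integer gene x cell counts plus axis identifiers and cell metadata.

    counts : (n_genes, n_cells) int array of read counts
    gene_ids : ordered unique gene symbols (case-sensitive, no mapping)
    cell_ids : ordered unique cell barcodes
    cell_meta : DataFrame indexed by cell_id with columns
        mouse_id, timepoint (E18.5/P1/P7/P21), condition
        (normoxia/hyperoxia), sex (F/M/unknown)

    Cells with zero total counts are legal here (QC removes them) but are
    rejected by CPM normalization.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = _check_axis(self.gene_ids, "gene_ids")
        self.cell_ids = _check_axis(self.cell_ids, "cell_ids")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.asarray(counts) == np.floor(counts)):
                raise FormatError("counts must be integer")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise FormatError("counts must be non-negative")
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)
        self.cell_meta = _validate_meta(self.cell_meta, self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = _cell_indexer(self.cell_ids, mask_or_ids)
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_meta=self.cell_meta.iloc[idx],
        )


@dataclasses.dataclass
class NormalizedMatrix:
    """Counts-per-million matrix: each cell column sums to 1e6.

    Same axes and metadata as :class:`CountMatrix`; zero-total cells are
    disallowed (run QC first).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = _check_axis(self.gene_ids, "gene_ids")
        self.cell_ids = _check_axis(self.cell_ids, "cell_ids")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError("values shape does not match gene/cell ids")
        if values.size and values.min() < 0:
            raise FormatError("CPM values must be non-negative")
        colsums = values.sum(axis=0)
        if values.shape[1] and not np.allclose(colsums, 1e6, rtol=1e-9, atol=0):
            raise FormatError("every cell column must sum to 1e6 (CPM)")
        self.values = values
        self.cell_meta = _validate_meta(self.cell_meta, self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not present in matrix") from None

    def subset_cells(self, mask_or_ids) -> "NormalizedMatrix":
        idx = _cell_indexer(self.cell_ids, mask_or_ids)
        return NormalizedMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_meta=self.cell_meta.iloc[idx],
        )


def _cell_indexer(cell_ids: list[str], mask_or_ids) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape != (len(cell_ids),):
            raise ValueError("boolean cell mask has wrong length")
        return np.flatnonzero(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(int)
    lookup = {c: i for i, c in enumerate(cell_ids)}
    return np.array([lookup[str(c)] for c in arr], dtype=int)


@dataclasses.dataclass
class LRDatabase:
    """Ligand-receptor pair table (user-supplied; e.g. exported from CellPhoneDB).

    Absent genes are legal: a gene missing from a count matrix simply counts
    as expressed by 0% of cells.
    """

    pairs: pd.DataFrame  # columns pair_id, ligand_gene, receptor_gene

    def __post_init__(self) -> None:
        required = ["pair_id", "ligand_gene", "receptor_gene"]
        missing = [c for c in required if c not in self.pairs.columns]
        if missing:
            raise FormatError(f"LR table missing columns: {missing}")
        pairs = self.pairs[required].astype(str).reset_index(drop=True)
        if pairs["pair_id"].duplicated().any():
            raise FormatError("duplicate pair_id in LR table")
        if (pairs["ligand_gene"].str.len() == 0).any() or (
            pairs["receptor_gene"].str.len() == 0
        ).any():
            raise FormatError("ligand/receptor gene symbols must be non-empty")
        self.pairs = pairs

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read a CountMatrix from MatrixMarket + gene/cell TSV sidecars."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as e:  # noqa: BLE001 - normalize scipy's error surface
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {e}") from e
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if not np.all(dense == np.floor(dense)):
        raise FormatError("matrix contains non-integer entries")
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise FormatError("genes TSV must have a gene_id column")
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    if "cell_id" not in cells.columns:
        raise FormatError("cells TSV must have a cell_id column")
    if dense.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix is {dense.shape} but sidecars describe "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    return CountMatrix(
        counts=dense.astype(np.int64),
        gene_ids=genes["gene_id"].tolist(),
        cell_ids=cells["cell_id"].tolist(),
        cell_meta=cells.drop(columns=["cell_id"]),
    )


def write_counts(cm: CountMatrix, matrix_path, genes_path, cells_path) -> None:
    """Write a CountMatrix as MatrixMarket coordinate integer + TSV sidecars."""
    coo = scipy.sparse.coo_matrix(cm.counts)
    scipy.io.mmwrite(str(matrix_path), coo, field="integer")
    pd.DataFrame({"gene_id": cm.gene_ids}).to_csv(genes_path, sep="\t", index=False)
    cells = cm.cell_meta.reset_index()
    cells.to_csv(cells_path, sep="\t", index=False)


def read_lr_pairs(path) -> LRDatabase:
    """Read a ligand-receptor pair TSV (pair_id, ligand_gene, receptor_gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and set(df.columns) >= {"pair_id", "ligand_gene", "receptor_gene"}:
        return LRDatabase(pairs=df)
    return LRDatabase(pairs=df)


def write_lr_pairs(db: LRDatabase, path) -> None:
    db.pairs.to_csv(path, sep="\t", index=False)


def write_table(records: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a result table as TSV with >= 10 significant digits.

    ``provenance`` key/value pairs are emitted as leading ``#`` comment
    lines so every output records the seed/config that produced it.
    """
    buf = io.StringIO()
    if provenance:
        for k, v in provenance.items():
            buf.write(f"# {k}: {v}\n")
    records.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping provenance comments."""
    return pd.read_csv(path, sep="\t", comment="#")
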