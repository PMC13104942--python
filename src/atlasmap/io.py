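"""Readers/writers for expression matrices, metadata tables and annotation exports.

The on-disk dialects are the ones query cohorts ship in: 10x-style MatrixMarket
triplets (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, optionally
gzipped, genes as rows), dense delimited matrices, and plain TSV/CSV metadata.
Everything is held in memory as a dense cells x genes :class:`ExpressionMatrix`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

if TYPE_CHECKING:  # pragma: no cover
    from .consensus import CellAnnotation

log = logging.getLogger(__name__)

LAYERS = ("counts", "lognorm", "scaled")

#: literal written for unassigned cells in annotation exports
NA_TOKEN = "NA"


class FormatError(ValueError):
    """Raised when an input file's shape/contents violate its format contract."""


class SchemaError(ValueError):
    """Raised when a metadata table lacks a required column."""


def _dedupe(names: Iterable[str]) -> list[str]:
    """Disambiguate duplicate identifiers by suffixing ``.1``, ``.2``, ... in file order."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        n = seen.get(name, 0)
        out.append(name if n == 0 else f"{name}.{n}")
        seen[name] = n + 1
    return out


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression values with a layer tag.

    Parameters
    ----------
    values : ndarray, shape (n_cells, n_genes)
    gene_ids, cell_ids : ordered unique identifiers
    layer : one of ``counts`` (nonnegative), ``lognorm``, ``scaled``
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes array")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in expression matrix")
        if self.layer == "counts" and np.any(self.values < 0):
            raise ValueError("negative entries in a counts matrix")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionMatrix(
            self.values[idx],
            self.gene_ids,
            [self.cell_ids[i] for i in idx],
            self.layer,
        )

    def subset_genes(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[:, idx],
            [self.gene_ids[i] for i in idx],
            self.cell_ids,
            self.layer,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_triplet_file(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"{stem}(.gz) not found in {directory}")


def _read_mtx_triplet(directory: Path) -> ExpressionMatrix:
    mtx_path = _find_triplet_file(directory, "matrix.mtx")
    feat_path = _find_triplet_file(directory, "features.tsv")
    bc_path = _find_triplet_file(directory, "barcodes.tsv")

    with _open_maybe_gz(mtx_path) as fh:
        mat = scipy_io.mmread(fh)
    mat = sparse.coo_matrix(mat)

    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    # 10x features files carry (id, symbol[, type]); use the symbol column when present
    symbols = features.iloc[:, 1] if features.shape[1] >= 2 else features.iloc[:, 0]
    gene_ids = _dedupe(symbols.tolist())
    barcodes = _dedupe(
        pd.read_csv(bc_path, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()
    )

    # genes are rows on disk (10x convention); transpose to cells x genes
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"matrix.mtx is {mat.shape[0]} x {mat.shape[1]} but features/barcodes "
            f"list {len(gene_ids)} genes and {len(barcodes)} cells"
        )
    values = np.asarray(mat.T.todense(), dtype=float)
    return ExpressionMatrix(values, gene_ids, barcodes, layer="counts")


def _read_dense(path: Path) -> ExpressionMatrix:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        _dedupe([str(c) for c in df.columns]),
        _dedupe([str(i) for i in df.index]),
        layer="counts",
    )


def read_counts(path: str | Path, format: str = "mtx_triplet") -> ExpressionMatrix:
    """Read a raw-count matrix.

    ``mtx_triplet`` expects a directory holding ``matrix.mtx(.gz)``,
    ``features.tsv(.gz)`` and ``barcodes.tsv(.gz)`` with genes as MTX rows;
    ``dense_tsv`` expects a delimited cells x genes table with cell ids in the
    first column and gene ids in the header. Duplicate identifiers are
    disambiguated by suffixing ``.1``, ``.2``, ... in file order.
    """
    path = Path(path)
    if format == "mtx_triplet":
        return _read_mtx_triplet(path)
    if format == "dense_tsv":
        return _read_dense(path)
    raise ValueError(f"unknown counts format {format!r}")


def write_counts_mtx(m: ExpressionMatrix, directory: str | Path) -> None:
    """Write a counts matrix as a 10x-style MTX triplet (genes as rows)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(m.values.T)
    field = "integer" if np.allclose(m.values, np.round(m.values)) else "real"
    if field == "integer":
        mat = mat.astype(np.int64)
    scipy_io.mmwrite(str(directory / "matrix.mtx"), mat, field=field)
    pd.DataFrame({0: m.gene_ids, 1: m.gene_ids, 2: "Gene Expression"}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(m.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)


_RESPONSE_LEVELS = ("R", "NR")

TABLE_SCHEMAS = {
    "cell_meta": ("cell_id", "sample_id", "cohort_label"),
    "sample_meta": ("sample_id", "response"),
    "gene_set": ("set_name", "gene_id"),
}


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_table(path: str | Path, schema: str):
    """Read a typed metadata table.

    ``cell_meta`` -> DataFrame (cell_id, sample_id, cohort_label[, compartment]);
    ``sample_meta`` -> DataFrame (sample_id, response in {R, NR, unknown}[, timepoint]),
    any response value outside {R, NR} (e.g. the '-' convention) maps to unknown;
    ``gene_set`` -> dict set_name -> ordered gene list.
    """
    path = Path(path)
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = _read_delimited(path)
    missing = [c for c in TABLE_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} lacks required column(s) {missing} for schema {schema}")
    if schema == "gene_set":
        sets: dict[str, list[str]] = {}
        for name, sub in df.groupby("set_name", sort=False):
            sets[str(name)] = sub["gene_id"].astype(str).tolist()
        return sets
    if schema == "sample_meta":
        df = df.copy()
        df["response"] = [
            r if r in _RESPONSE_LEVELS else "unknown" for r in df["response"].astype(str)
        ]
    return df


def write_annotations(annotations: Sequence["CellAnnotation"], path: str | Path) -> None:
    """Write per-cell annotations as TSV, in input order.

    Columns: cell_id, assigned_label (literal ``NA`` when unassigned), n_match,
    identifiability (empty for unassigned cells).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id\tassigned_label\tn_match\tidentifiability\n")
        for ann in annotations:
            if ann.assigned_label is None:
                label, ident = NA_TOKEN, ""
            else:
                label, ident = ann.assigned_label, format(ann.identifiability, ".6g")
            fh.write(f"{ann.cell_id}\t{label}\t{ann.n_match}\t{ident}\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV back into a DataFrame (``NA`` kept as the literal label)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "assigned_label": str},
                     keep_default_na=False)
    missing = [c for c in ("cell_id", "assigned_label", "n_match") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} lacks required annotation column(s) {missing}")
    df["n_match"] = pd.to_numeric(df["n_match"]).astype(int)
    if "identifiability" in df.columns:
        df["identifiability"] = pd.to_numeric(df["identifiability"], errors="coerce")
    return df
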