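"""Reading, writing and preprocessing of expression matrices and proportions.

Expression data arrive either as dense CSV/TSV tables (header row of gene or
cell ids, first column of row ids) or as a MatrixMarket coordinate triplet
with companion row/column id files. Internally everything is a dense
cells-or-spots × genes float matrix with string identifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Raised when an input file does not meet the expected on-disk layout."""


@dataclass
class ExpressionMatrix:
    """Nonnegative cells-or-spots × genes matrix with string identifiers."""

    values: np.ndarray
    row_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D")
        n, m = self.values.shape
        if len(self.row_ids) != n or len(self.gene_ids) != m:
            raise ValueError(
                f"id lengths ({len(self.row_ids)}, {len(self.gene_ids)}) do not "
                f"match matrix shape {self.values.shape}"
            )
        if len(set(self.row_ids)) != n:
            raise ValueError("row_ids are not unique")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids are not unique")
        if n and m and self.values.min() < 0:
            raise ValueError("expression matrix contains negative entries")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.gene_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (in the given order); unknown genes raise KeyError."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], list(self.row_ids), list(genes))

    def subset_rows(self, rows: Sequence[int]) -> "ExpressionMatrix":
        rows = list(rows)
        return ExpressionMatrix(
            self.values[rows, :], [self.row_ids[i] for i in rows], list(self.gene_ids)
        )


@dataclass
class CellTypeLabels:
    """Per-cell type assignments plus a fixed ordering of the k type names."""

    assignments: dict[str, str]
    types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignments = {str(c): str(t) for c, t in self.assignments.items()}
        if not self.types:
            self.types = sorted(set(self.assignments.values()))
        if len(self.types) < 2:
            raise ValueError("at least 2 cell types are required")
        unknown = set(self.assignments.values()) - set(self.types)
        if unknown:
            raise ValueError(f"assignments use types not in the type list: {sorted(unknown)}")

    @property
    def k(self) -> int:
        return len(self.types)

    def vector(self, row_ids: Sequence[str]) -> np.ndarray:
        """Integer type codes (index into ``types``) for the given cells."""
        missing = [r for r in row_ids if r not in self.assignments]
        if missing:
            raise KeyError(f"cells without a type label: {missing[:5]}")
        code = {t: i for i, t in enumerate(self.types)}
        return np.array([code[self.assignments[r]] for r in row_ids], dtype=int)


@dataclass
class ProportionMatrix:
    """Spots × k cell-type proportions; every row sums to 1."""

    values: np.ndarray
    spot_ids: list[str]
    types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.types = [str(t) for t in self.types]
        if self.values.ndim != 2:
            raise ValueError("proportion matrix must be 2-D")
        if self.values.shape != (len(self.spot_ids), len(self.types)):
            raise ValueError("proportion matrix shape does not match ids")
        if self.values.size:
            if self.values.min() < 0:
                raise ValueError("proportions must be nonnegative")
            sums = self.values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"proportion rows must sum to 1 (spot {self.spot_ids[bad]} sums to {sums[bad]:.8f})"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.spot_ids, columns=self.types)


def _read_id_file(path: Path) -> list[str]:
    ids = [line.strip().split("\t")[0] for line in path.read_text().splitlines() if line.strip()]
    return ids


def _collapse_duplicate_genes(values: np.ndarray, gene_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    if len(set(gene_ids)) == len(gene_ids):
        return values, gene_ids
    # Duplicate ids are summed so no counts are silently dropped.
    order: dict[str, int] = {}
    for g in gene_ids:
        order.setdefault(g, len(order))
    out = np.zeros((values.shape[0], len(order)))
    for j, g in enumerate(gene_ids):
        out[:, order[g]] += values[:, j]
    return out, list(order)


def read_expression(
    path: str | Path,
    format: Literal["mtx", "csv", "tsv"] = "csv",
    orientation: Literal["cells_by_genes", "genes_by_cells"] = "cells_by_genes",
    row_ids_path: str | Path | None = None,
    col_ids_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix, returning it in cells/spots × genes orientation.

    ``orientation`` describes the on-disk layout. For ``mtx`` the companion id
    files default to ``<path>.rows`` and ``<path>.cols`` (one id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        rows_file = Path(row_ids_path) if row_ids_path else path.with_suffix(path.suffix + ".rows")
        cols_file = Path(col_ids_path) if col_ids_path else path.with_suffix(path.suffix + ".cols")
        for f, which in ((rows_file, "row"), (cols_file, "column")):
            if not f.exists():
                raise FormatError(f"MTX {which} id file missing: {f}")
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        row_ids = _read_id_file(rows_file)
        col_ids = _read_id_file(cols_file)
        if values.shape != (len(row_ids), len(col_ids)):
            raise FormatError(
                f"MTX shape {values.shape} does not match id files "
                f"({len(row_ids)} rows, {len(col_ids)} cols)"
            )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        # header parsed by hand: pandas mangles duplicate column ids (g1 -> g1.1)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        col_ids = [c.strip() for c in header[1:]]
        df = pd.read_csv(path, sep=sep, index_col=0, header=None, skiprows=1)
        if df.shape[1] != len(col_ids):
            raise FormatError(
                f"header names {len(col_ids)} columns but data rows have {df.shape[1]}"
            )
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError):
            for i, (_, row) in enumerate(df.iterrows()):
                for j, v in enumerate(row):
                    try:
                        float(v)
                    except (TypeError, ValueError):
                        raise FormatError(
                            f"non-numeric entry {v!r} at data row {i}, column {col_ids[j]!r}"
                        ) from None
            raise
        row_ids = [str(i) for i in df.index]
    else:
        raise ValueError(f"unknown format {format!r}")

    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    values, col_ids = _collapse_duplicate_genes(values, col_ids)
    return ExpressionMatrix(values, row_ids, col_ids)


def write_expression(Q: ExpressionMatrix, path: str | Path, format: Literal["mtx", "csv", "tsv"] = "csv") -> None:
    """Write in cells × genes orientation; MTX gets ``.rows``/``.cols`` id files."""
    path = Path(path)
    if format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(Q.values))
        path.with_suffix(path.suffix + ".rows").write_text("\n".join(Q.row_ids) + "\n")
        path.with_suffix(path.suffix + ".cols").write_text("\n".join(Q.gene_ids) + "\n")
    else:
        sep = "," if format == "csv" else "\t"
        Q.to_dataframe().to_csv(path, sep=sep)


def read_cell_metadata(path: str | Path) -> CellTypeLabels:
    """Two-column CSV (cell_id, cell_type); type order is first appearance."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("metadata CSV needs at least two columns: cell_id, cell_type")
    cells = df.iloc[:, 0].astype(str)
    types_col = df.iloc[:, 1].astype(str)
    seen: list[str] = []
    for t in types_col:
        if t not in seen:
            seen.append(t)
    return CellTypeLabels(dict(zip(cells, types_col)), seen)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("spot_id", "x", "y"):
        if needed not in cols:
            raise FormatError(f"coordinates CSV missing column {needed!r}")
    out = df[[cols["spot_id"], cols["x"], cols["y"]]].copy()
    out.columns = ["spot_id", "x", "y"]
    return out


def qc_filter_genes(
    Q: ExpressionMatrix, labels: CellTypeLabels, min_rate: float = 0.20
) -> ExpressionMatrix:
    """Drop genes whose detection rate is below ``min_rate`` in every cell type.

    The detection rate of a gene within a type is the fraction of that type's
    cells with a strictly positive value. A gene survives if it reaches
    ``min_rate`` in at least one type. Gene order is preserved.
    """
    codes = labels.vector(Q.row_ids)
    keep = np.zeros(Q.n_genes, dtype=bool)
    for t in range(labels.k):
        mask = codes == t
        if not mask.any():
            continue
        rates = (Q.values[mask] > 0).mean(axis=0)
        keep |= rates >= min_rate
    if not keep.any():
        raise ValueError(
            f"no gene reaches a detection rate of {min_rate} in any cell type; "
            "lower min_rate"
        )
    cols = np.flatnonzero(keep)
    return ExpressionMatrix(
        Q.values[:, cols], list(Q.row_ids), [Q.gene_ids[j] for j in cols]
    )


def normalize(
    Q: ExpressionMatrix, target_sum: float = 1e4, log1p: bool = True
) -> ExpressionMatrix:
    """Scale each row to ``target_sum`` total counts, optionally log1p-transform.

    All-zero rows cannot be scaled and are left as zeros with a warning.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = Q.values.sum(axis=1)
    if Q.n_rows and not np.any(totals > 0):
        raise ValueError("normalize requires at least one nonzero row")
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero row(s) left unnormalized", stacklevel=2
        )
    scale = np.where(zero, 1.0, target_sum / np.where(zero, 1.0, totals))
    values = Q.values * scale[:, None]
    if log1p:
        values = np.log1p(values)
    return ExpressionMatrix(values, list(Q.row_ids), list(Q.gene_ids))


def write_proportions(P: ProportionMatrix, path: str | Path) -> None:
    """CSV with a spot_id column followed by one column per cell type."""
    df = P.to_dataframe()
    df.index.name = "spot_id"
    df.to_csv(path)


def read_proportions(path: str | Path) -> ProportionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ProportionMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])
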