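"""Core data containers, input/output, and gene filtering.

The unified input for an individual-level differential-expression analysis is
a genes x cells matrix of non-negative integer UMI counts plus two metadata
tables: one keyed by cell (which individual each cell belongs to, optional
numeric cell-level covariates such as log read depth) and one keyed by
individual (the variable of interest, e.g. case/control status, plus optional
individual-level covariates such as age or batch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CellData",
    "load_cell_data",
    "from_anndata",
    "filter_genes",
    "write_results",
    "read_results",
]

#: name of the mandatory individual-id column in the cell metadata table
INDIVIDUAL_COL = "individual"

#: default name of the log read-depth cell covariate attached at load time
LOG_RD_COL = "log_rd"

#: tolerance when coercing float-valued count files to integers
INT_TOL = 1e-8

RESULT_COLUMNS = ["gene_id", "F_stat", "pvalue", "n_perm_used", "status", "qvalue"]


@dataclass
class CellData:
    """Counts plus cell- and individual-level metadata.

    Attributes
    ----------
    counts
        Dense integer array, genes in rows, cells in columns.
    gene_ids, cell_ids
        Unique row/column labels matching the matrix dimensions.
    cell_meta
        DataFrame indexed by cell id; must contain an ``individual`` column;
        any additional numeric columns are cell-level covariates.
    indiv_meta
        DataFrame indexed by individual id; contains the variable of interest
        and any individual-level covariates.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame
    indiv_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.validate()

    # ------------------------------------------------------------------
    # invariants
    # ------------------------------------------------------------------
    def validate(self) -> None:
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene id list length {len(self.gene_ids)} != matrix rows {g}"
            )
        if len(self.cell_ids) != c:
            raise ValueError(
                f"cell id list length {len(self.cell_ids)} != matrix columns {c}"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicated gene ids")
        if len(set(self.cell_ids)) != c:
            raise ValueError("duplicated cell ids")
        if np.any(self.counts < 0):
            raise ValueError("negative count entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if np.max(np.abs(self.counts - rounded), initial=0) > INT_TOL:
                raise ValueError("non-integer count entries")
            self.counts = rounded.astype(np.int64)
        if INDIVIDUAL_COL not in self.cell_meta.columns:
            raise ValueError(f"cell_meta lacks '{INDIVIDUAL_COL}' column")
        missing_cells = [c_ for c_ in self.cell_ids if c_ not in self.cell_meta.index]
        if missing_cells:
            raise ValueError(
                f"cells present in counts but absent from cell_meta: {missing_cells[:5]}"
            )
        # align metadata row order with the matrix
        self.cell_meta = self.cell_meta.loc[self.cell_ids]
        indiv = self.cell_meta[INDIVIDUAL_COL].astype(str)
        self.cell_meta[INDIVIDUAL_COL] = indiv
        self.indiv_meta.index = self.indiv_meta.index.astype(str)
        missing_indiv = sorted(set(indiv) - set(self.indiv_meta.index))
        if missing_indiv:
            raise ValueError(
                f"individuals in cell_meta absent from indiv_meta: {missing_indiv}"
            )

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def read_depth(self) -> np.ndarray:
        """Per-cell total count (column sums of the matrix)."""
        return self.counts.sum(axis=0)

    @property
    def individuals(self) -> list[str]:
        """Individual ids in indiv_meta order, restricted to those with cells."""
        present = set(self.cell_meta[INDIVIDUAL_COL])
        return [i for i in self.indiv_meta.index if i in present]

    def cell_indices_of(self, individual: str) -> np.ndarray:
        mask = (self.cell_meta[INDIVIDUAL_COL] == individual).to_numpy()
        return np.flatnonzero(mask)

    def attach_log_read_depth(self) -> None:
        """Attach log read depth as a cell covariate unless already present."""
        if LOG_RD_COL in self.cell_meta.columns:
            return
        rd = self.read_depth
        if np.any(rd <= 0):
            raise ValueError("cannot take log read depth of zero-count cells")
        self.cell_meta[LOG_RD_COL] = np.log(rd)

    def drop_zero_cells(self) -> "CellData":
        """Return a copy without cells whose total count is zero.

        Log read depth is undefined for such cells, so they are excluded from
        analysis by default; a warning reports how many were dropped.
        """
        rd = self.read_depth
        keep = rd > 0
        if keep.all():
            return self
        n_drop = int((~keep).sum())
        dropped = [self.cell_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"excluding {n_drop} zero-count cell(s): {dropped[:5]}"
            + ("..." if n_drop > 5 else "")
        )
        keep_ids = [self.cell_ids[i] for i in np.flatnonzero(keep)]
        return CellData(
            counts=self.counts[:, keep],
            gene_ids=list(self.gene_ids),
            cell_ids=keep_ids,
            cell_meta=self.cell_meta.loc[keep_ids].copy(),
            indiv_meta=self.indiv_meta.copy(),
        )


# ----------------------------------------------------------------------
# loading
# ----------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})


def _read_counts(path: Path, orientation: str) -> tuple[np.ndarray, list[str], list[str]]:
    if path.suffix.lower() == ".mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        genes_path = path.with_name("genes.tsv")
        if not genes_path.exists():
            genes_path = path.with_name("features.tsv")
        barcodes_path = path.with_name("barcodes.tsv")
        for p in (genes_path, barcodes_path):
            if not p.exists():
                raise FileNotFoundError(f"sidecar name file missing: {p}")
        gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        cell_ids = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    else:
        df = _read_table(path)
        mat = df.to_numpy()
        gene_ids = df.index.astype(str).tolist()
        cell_ids = df.columns.astype(str).tolist()
    if orientation == "cells_by_genes":
        mat = mat.T
        gene_ids, cell_ids = cell_ids, gene_ids
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match id files "
            f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
        )
    return mat, gene_ids, cell_ids


def load_cell_data(
    counts_path: str | Path,
    cell_meta_path: str | Path,
    indiv_meta_path: str | Path,
    *,
    orientation: str = "genes_by_cells",
    drop_zero_cells: bool = True,
) -> CellData:
    """Load a validated :class:`CellData` from disk.

    ``counts_path`` may be MatrixMarket MTX (with ``genes.tsv``/``barcodes.tsv``
    sidecars in the same directory) or a dense delimited table with gene ids in
    the first column and cell ids in the header. Metadata files are TSV/CSV with
    a header row; the first column is the key. Log read depth is attached as the
    ``log_rd`` cell covariate unless a column of that name already exists.
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    counts, gene_ids, cell_ids = _read_counts(Path(counts_path), orientation)
    cell_meta = _read_table(Path(cell_meta_path))
    cell_meta.index = cell_meta.index.astype(str)
    indiv_meta = _read_table(Path(indiv_meta_path))
    data = CellData(counts, gene_ids, cell_ids, cell_meta, indiv_meta)
    if drop_zero_cells:
        data = data.drop_zero_cells()
    data.attach_log_read_depth()
    return data


# ----------------------------------------------------------------------
# gene filter
# ----------------------------------------------------------------------

def from_anndata(
    adata,
    indiv_meta: pd.DataFrame,
    *,
    individual_col: str = INDIVIDUAL_COL,
    drop_zero_cells: bool = True,
) -> CellData:
    """Optional import from an AnnData object (cells x genes, raw counts in X).

    ``adata.obs`` must carry the individual-id column; its numeric columns
    become cell covariates. The AnnData ecosystem is otherwise not used.
    """
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    cell_meta = adata.obs.copy()
    if individual_col != INDIVIDUAL_COL:
        cell_meta = cell_meta.rename(columns={individual_col: INDIVIDUAL_COL})
    data = CellData(
        counts=np.asarray(X).T,
        gene_ids=adata.var_names.tolist(),
        cell_ids=adata.obs_names.tolist(),
        cell_meta=cell_meta,
        indiv_meta=indiv_meta,
    )
    if drop_zero_cells:
        data = data.drop_zero_cells()
    data.attach_log_read_depth()
    return data


def filter_genes(data: CellData, min_frac: float = 0.20) -> CellData:
    """Retain genes expressed (nonzero) in at least ``min_frac`` of all cells.

    The comparison is inclusive: a gene nonzero in exactly ``min_frac`` of the
    cells is retained. Cells and metadata are preserved unchanged.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    frac = (data.counts > 0).mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        warnings.warn("gene filter removed every gene")
    return CellData(
        counts=data.counts[keep],
        gene_ids=[g for g, k in zip(data.gene_ids, keep) if k],
        cell_ids=list(data.cell_ids),
        cell_meta=data.cell_meta.copy(),
        indiv_meta=data.indiv_meta.copy(),
    )


# ----------------------------------------------------------------------
# results IO
# ----------------------------------------------------------------------

def write_results(results: Sequence, path: str | Path) -> None:
    """Write per-gene test results as TSV, one row per gene in input order.

    Failed genes carry their status with empty F/p fields. Floats are written
    at full precision so a read-back reproduces the values exactly.
    """
    if len(results) == 0:
        raise ValueError("no results to write")
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "F_stat": r.F_obs if r.status == "ok" else np.nan,
                "pvalue": r.pvalue if r.status == "ok" else np.nan,
                "n_perm_used": r.n_perm_used if r.status == "ok" else np.nan,
                "status": r.status,
                "qvalue": getattr(r, "qvalue", None),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if df["qvalue"].isna().all():
        df = df.drop(columns=["qvalue"])
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def write_cell_data(data: CellData, out_prefix: str | Path) -> dict[str, Path]:
    """Write counts (MTX + sidecars) and both metadata tables under a prefix.

    Returns the mapping of logical name to written path. Counts are written as
    integer MatrixMarket coordinate format so a round trip is integer-exact.
    """
    out = Path(out_prefix)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
        "cell_meta": out / "cell_meta.tsv",
        "indiv_meta": out / "indiv_meta.tsv",
    }
    spio.mmwrite(paths["counts"], sparse.coo_matrix(data.counts), field="integer")
    pd.Series(data.gene_ids).to_csv(paths["genes"], sep="\t", header=False, index=False)
    pd.Series(data.cell_ids).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    data.cell_meta.to_csv(paths["cell_meta"], sep="\t", index_label="cell_id")
    data.indiv_meta.to_csv(paths["indiv_meta"], sep="\t", index_label="individual_id")
    return paths
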