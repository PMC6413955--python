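"""Single-cell expression matrices: loading, cell filtering, bulk reconciliation.

The matrix ``T`` holds normalized read counts (TPM) for genes (rows) by cells
(columns).  Zero entries in scRNA-seq may be dropouts; when a bulk profile is
available each all-zero gene row is reconciled against it under three
scenarios (off everywhere / replaced by bulk / heterogeneous zeros).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GeneStatus",
    "ExpressionData",
    "load_expression",
    "filter_cells",
    "reconcile_with_bulk",
]

log = logging.getLogger(__name__)


class GeneStatus(str, Enum):
    OFF_EVERYWHERE = "OFF_EVERYWHERE"
    BULK_REPLACED = "BULK_REPLACED"
    HETEROGENEOUS_ZEROS = "HETEROGENEOUS_ZEROS"
    EXPRESSED = "EXPRESSED"


@dataclass(frozen=True)
class ExpressionData:
    """Genes x cells TPM matrix with optional bulk vector and gene statuses."""

    values: pd.DataFrame  # genes x cells, float, >= 0
    bulk: Optional[pd.Series] = None
    gene_status: Optional[pd.Series] = None  # gene -> GeneStatus, set by reconcile

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[bad[0]]!r}, "
                f"cell {self.values.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.values.index[bad[0]]!r}, "
                f"cell {self.values.columns[bad[1]]!r}"
            )
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell columns: {dupes}")
        if self.values.shape[1] < 1:
            raise ValueError("expression matrix must have at least one cell")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def cells(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def load_expression(path: str, bulk_path: Optional[str] = None) -> ExpressionData:
    """Load a genes x cells matrix from TSV/CSV or MatrixMarket MTX.

    TSV/CSV: header row of cell IDs, first column gene IDs.  MTX: triplet file
    plus ``<stem>.genes.txt`` and ``<stem>.cells.txt`` index files alongside.
    A bulk profile (two columns: gene, TPM, no header requirement) may be
    supplied separately; alternatively a matrix column named ``bulk`` (any
    case) is split off as the bulk vector.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if p.suffix.lower() == ".mtx":
        values = _read_mtx(p)
    else:
        sep = "," if p.suffix.lower() == ".csv" else "\t"
        values = pd.read_csv(p, sep=sep, index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
    values.index.name = None
    values.columns.name = None
    non_numeric = values.select_dtypes(exclude=[np.number]).columns.tolist()
    if non_numeric:
        raise ValueError(f"non-numeric expression columns: {non_numeric}")

    bulk: Optional[pd.Series] = None
    bulk_cols = [c for c in values.columns if str(c).lower() == "bulk"]
    if bulk_cols:
        bulk = values[bulk_cols[0]].astype(float)
        values = values.drop(columns=bulk_cols)
    if bulk_path is not None:
        bp = Path(bulk_path)
        if not bp.exists():
            raise FileNotFoundError(f"bulk file not found: {bulk_path}")
        sep = "," if bp.suffix.lower() == ".csv" else "\t"
        table = pd.read_csv(bp, sep=sep, index_col=0)
        bulk = table.iloc[:, 0].astype(float)
        bulk.index = bulk.index.astype(str)
    return ExpressionData(values=values.astype(float), bulk=bulk)


def _read_mtx(path: Path):
    from scipy.io import mmread

    matrix = mmread(str(path))
    stem = path.with_suffix("")
    genes_file = Path(str(stem) + ".genes.txt")
    cells_file = Path(str(stem) + ".cells.txt")
    if not genes_file.exists() or not cells_file.exists():
        raise FileNotFoundError(
            f"MTX index files missing: expected {genes_file} and {cells_file}"
        )
    genes = genes_file.read_text().split()
    cells = cells_file.read_text().split()
    dense = np.asarray(matrix.todense() if hasattr(matrix, "todense") else matrix, dtype=float)
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"MTX shape {dense.shape} does not match index files "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return pd.DataFrame(dense, index=genes, columns=cells)


def filter_cells(data: ExpressionData, min_genes_detected: int = 5000) -> ExpressionData:
    """Drop cells detecting (strictly) fewer than *min_genes_detected* genes.

    A gene is detected in a cell when its value is > 0.  The gene set is
    unchanged.
    """
    if min_genes_detected < 0:
        raise ValueError("min_genes_detected must be >= 0")
    detected = (data.values > 0).sum(axis=0)
    keep = detected >= min_genes_detected
    if not keep.any():
        raise ValueError(
            f"all {data.n_cells} cells detect fewer than {min_genes_detected} genes; "
            "lower the threshold"
        )
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_cells: dropped %d of %d cells", dropped, data.n_cells)
    return replace(data, values=data.values.loc[:, keep])


def reconcile_with_bulk(data: ExpressionData) -> Tuple[ExpressionData, Set[str]]:
    """Reconcile single-cell zeros against the bulk profile.

    Per gene: (i) bulk 0 and all cells 0 -> OFF_EVERYWHERE, gene collected in
    ``G_off`` (to be deleted from the template network); (ii) bulk > 0 and all
    cells 0 -> BULK_REPLACED, every cell's value set to the bulk value;
    (iii) bulk > 0 and some cells 0 -> HETEROGENEOUS_ZEROS, values kept (the
    epsilon flux floor handles the risk downstream); otherwise EXPRESSED.

    Without a bulk vector, every all-zero gene becomes OFF_EVERYWHERE and no
    replacement occurs (a warning is logged).  Bulk zero is tested exactly.
    """
    values = data.values.copy()
    all_zero = (values == 0).all(axis=1)
    any_zero = (values == 0).any(axis=1)
    status = pd.Series(GeneStatus.EXPRESSED, index=values.index, dtype=object)
    g_off: Set[str] = set()

    if data.bulk is None:
        log.warning("reconcile_with_bulk: no bulk profile; all-zero genes treated as off")
        for gene in values.index[all_zero]:
            status[gene] = GeneStatus.OFF_EVERYWHERE
            g_off.add(gene)
        return replace(data, values=values, gene_status=status), g_off

    missing = set(values.index) - set(data.bulk.index)
    if missing:
        raise ValueError(f"bulk profile missing genes: {sorted(missing)}")
    bulk = data.bulk.reindex(values.index)

    for gene in values.index:
        if all_zero[gene]:
            if bulk[gene] == 0:
                status[gene] = GeneStatus.OFF_EVERYWHERE
                g_off.add(gene)
            else:
                status[gene] = GeneStatus.BULK_REPLACED
                values.loc[gene, :] = float(bulk[gene])
        elif any_zero[gene] and bulk[gene] > 0:
            status[gene] = GeneStatus.HETEROGENEOUS_ZEROS
        elif any_zero[gene]:
            # nonzero in some cells but bulk reads 0: trust the cells
            status[gene] = GeneStatus.HETEROGENEOUS_ZEROS
    return replace(data, values=values, gene_status=status), g_off
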