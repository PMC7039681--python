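"""Count-matrix I/O and the robust gene/cell filter.

The "robust gene set" filter removes sparsely detected genes and
low-complexity cells: cells are kept when they detect at least
``min_genes_per_cell`` distinct genes (UMI count > 0), and genes are then
kept when detected in at least ``min_gene_detection_fraction`` of all
retained cells, both conditions pooled.  Cells are filtered first, on the
full gene universe, which makes the filter idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["CountMatrix", "FilterReport", "read_matrix", "write_matrix", "robust_filter"]


@dataclass
class CountMatrix:
    """Genes x cells integer UMI counts with per-cell condition labels."""

    counts: sparse.csr_matrix      # genes x cells
    gene_ids: np.ndarray           # str array, length n_genes
    cell_ids: np.ndarray           # str array, length n_cells
    condition: np.ndarray          # str label per cell

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows")
        if len(self.cell_ids) != n_cells or len(self.condition) != n_cells:
            raise ValueError("cell id / condition length does not match matrix columns")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=np.int64)

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        idx = self._gene_index(mask_or_ids)
        return CountMatrix(self.counts[idx, :], self.gene_ids[idx],
                           self.cell_ids, self.condition)

    def subset_cells(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(self.counts[:, idx], self.gene_ids,
                           self.cell_ids[idx], self.condition[idx])

    def _gene_index(self, mask_or_ids) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        if arr.dtype.kind in "iu":
            return arr
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in arr if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([pos[g] for g in arr])

    @staticmethod
    def concat_cells(a: "CountMatrix", b: "CountMatrix") -> "CountMatrix":
        if not np.array_equal(a.gene_ids, b.gene_ids):
            raise ValueError("matrices must share the same gene universe, in order")
        return CountMatrix(
            sparse.hstack([a.counts, b.counts]).tocsr(),
            a.gene_ids,
            np.concatenate([a.cell_ids, b.cell_ids]),
            np.concatenate([a.condition, b.condition]),
        )


@dataclass
class FilterReport:
    """Provenance record for one robust_filter run."""

    n_genes_in: int
    n_genes_out: int
    n_cells_in: dict
    n_cells_out: dict
    min_gene_detection_fraction: float
    min_genes_per_cell: int
    pooled_gene_filter: bool = True

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_matrix(mtx_path, genes_path, barcodes_path, condition_label: str) -> CountMatrix:
    """Read a 10x-style MTX triplet (matrix + genes.tsv + barcodes.tsv)."""
    mtx_path, genes_path, barcodes_path = Path(mtx_path), Path(genes_path), Path(barcodes_path)
    for p in (mtx_path, genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(p)
    counts = sparse.csr_matrix(spio.mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    if genes.empty or barcodes.empty:
        raise ValueError("empty gene or barcode sidecar file")
    gene_ids = genes.iloc[:, 0].astype(str).to_numpy()
    cell_ids = barcodes.iloc[:, 0].astype(str).to_numpy()
    if counts.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"MTX shape {counts.shape} does not match sidecars "
            f"({len(gene_ids)} genes, {len(cell_ids)} barcodes)"
        )
    if counts.nnz and not np.allclose(counts.data, np.rint(counts.data)):
        raise ValueError("MTX contains non-integer values")
    counts = counts.astype(np.int64)
    condition = np.repeat(condition_label, len(cell_ids))
    return CountMatrix(counts, gene_ids, cell_ids, condition)


def write_matrix(matrix: CountMatrix, outdir, prefix: str = "") -> dict:
    """Write a CountMatrix as MTX triplet; returns the three paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": outdir / f"{prefix}matrix.mtx",
        "genes": outdir / f"{prefix}genes.tsv",
        "barcodes": outdir / f"{prefix}barcodes.tsv",
    }
    spio.mmwrite(str(paths["mtx"]), sparse.coo_matrix(matrix.counts), field="integer")
    pd.Series(matrix.gene_ids).to_csv(paths["genes"], sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": matrix.cell_ids, "condition": matrix.condition}).to_csv(
        paths["barcodes"], sep="\t", header=False, index=False)
    return paths


def robust_filter(wt: CountMatrix, ko: CountMatrix,
                  min_gene_detection_fraction: float = 0.10,
                  min_genes_per_cell: int = 500,
                  pooled_gene_filter: bool = True) -> tuple[CountMatrix, FilterReport]:
    """Build the robust gene set from two condition matrices.

    Cells are filtered first (>= ``min_genes_per_cell`` detected genes on the
    full gene universe), then genes are kept when detected in a fraction
    >= ``min_gene_detection_fraction`` of retained cells.  With
    ``pooled_gene_filter`` the detection fraction is computed over both
    conditions pooled ("all cells"); otherwise per condition, keeping genes
    that pass in both.
    """
    if not np.array_equal(wt.gene_ids, ko.gene_ids):
        raise ValueError("WT and KO matrices must share the same gene universe")
    joint = CountMatrix.concat_cells(wt, ko)
    labels = sorted(set(joint.condition))
    cells_in = {lab: int(np.sum(joint.condition == lab)) for lab in labels}

    detected = joint.counts > 0
    genes_per_cell = np.asarray(detected.sum(axis=0)).ravel()
    keep_cells = genes_per_cell >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError("no cells pass the detected-genes threshold")
    joint = joint.subset_cells(keep_cells)

    detected = joint.counts > 0
    if pooled_gene_filter:
        frac = np.asarray(detected.sum(axis=1)).ravel() / joint.n_cells
        keep_genes = frac >= min_gene_detection_fraction
    else:
        keep_genes = np.ones(joint.n_genes, dtype=bool)
        for lab in labels:
            cols = joint.condition == lab
            sub = detected[:, np.flatnonzero(cols)]
            frac = np.asarray(sub.sum(axis=1)).ravel() / cols.sum()
            keep_genes &= frac >= min_gene_detection_fraction
    if not keep_genes.any():
        raise ValueError("no genes pass the detection-fraction threshold")
    joint = joint.subset_genes(keep_genes)

    cells_out = {lab: int(np.sum(joint.condition == lab)) for lab in labels}
    report = FilterReport(
        n_genes_in=wt.n_genes, n_genes_out=joint.n_genes,
        n_cells_in=cells_in, n_cells_out=cells_out,
        min_gene_detection_fraction=min_gene_detection_fraction,
        min_genes_per_cell=min_genes_per_cell,
        pooled_gene_filter=pooled_gene_filter,
    )
    return joint, report
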