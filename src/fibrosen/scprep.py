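"""Single-cell containers, QC filtering, normalization, and marker detection.

The conventions follow the common Seurat-style defaults: cells with fewer
than 500 detected genes or more than 5% mitochondrial counts are removed;
counts are depth-normalized and natural-log transformed; cluster markers are
called with a Wilcoxon rank-sum test, a log2 fold-change threshold of 0.25
on pseudocounted back-transformed means, and a minimum detection fraction of
0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy import stats

MITO_PREFIX = "MT-"

REQUIRED_META = ("dataset_id", "cell_type")


@dataclass
class CellDataset:
    """A genes x cells count matrix with per-cell metadata.

    ``counts`` is dense int (genes in rows, cells in columns), ``gene_ids``
    holds unique symbols aligned to rows, and ``cell_meta`` is indexed by
    cell barcode with at least ``dataset_id`` and ``cell_type`` columns. QC
    columns ``n_genes_detected`` and ``pct_mito`` (percent, 0-100) are
    computed from the counts when absent.
    """

    counts: np.ndarray
    gene_ids: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if not self.gene_ids.is_unique:
            raise ValueError("gene_ids must be unique")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length must match count-matrix rows")
        if len(self.cell_meta) != self.counts.shape[1]:
            raise ValueError("cell_meta rows must match count-matrix columns")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        missing = [c for c in REQUIRED_META if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta missing required columns: {missing}")
        if not {"n_genes_detected", "pct_mito"} <= set(self.cell_meta.columns):
            self.cell_meta = self.cell_meta.join(self.qc_metrics())

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def qc_metrics(self) -> pd.DataFrame:
        """Per-cell detected-gene count and mitochondrial percentage."""
        n_detected = (self.counts > 0).sum(axis=0)
        totals = self.counts.sum(axis=0).astype(float)
        mito_rows = self.gene_ids.str.startswith(MITO_PREFIX)
        mito = self.counts[np.asarray(mito_rows)].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * mito / totals, 0.0)
        return pd.DataFrame(
            {"n_genes_detected": n_detected, "pct_mito": pct},
            index=self.cell_meta.index,
        )

    def to_dir(self, out_dir: str | Path) -> None:
        """Write matrix.mtx, genes.tsv, barcodes.tsv and cells.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(out / "matrix.mtx", sparse.csc_matrix(self.counts))
        pd.Series(self.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(self.cell_meta.index).to_csv(
            out / "barcodes.tsv", sep="\t", index=False, header=False
        )
        self.cell_meta.to_csv(out / "cells.tsv", sep="\t", index_label="barcode")

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "CellDataset":
        src = Path(in_dir)
        counts = np.asarray(spio.mmread(src / "matrix.mtx").todense())
        genes = pd.read_csv(src / "genes.tsv", sep="\t", header=None)[0]
        meta = pd.read_csv(src / "cells.tsv", sep="\t", index_col="barcode")
        return cls(counts=counts.astype(np.int64), gene_ids=pd.Index(genes), cell_meta=meta)


@dataclass
class QCLog:
    """Record of a QC filtering pass."""

    n_input: int
    n_kept: int
    n_dropped_low_genes: int
    n_dropped_high_mito: int

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept


class AllCellsFilteredError(RuntimeError):
    pass


def qc_filter_cells(
    ds: CellDataset,
    min_genes: int = 500,
    max_pct_mito: float = 5.0,
    return_log: bool = False,
):
    """Drop low-quality cells.

    Keeps exactly the cells with ``n_genes_detected >= min_genes`` and
    ``pct_mito <= max_pct_mito`` (cells with fewer than 500 detected genes,
    or mitochondrial content above 5%, are removed under the defaults).
    Cell order is preserved; idempotent.
    """
    qc = ds.cell_meta
    if not {"n_genes_detected", "pct_mito"} <= set(qc.columns):
        qc = qc.join(ds.qc_metrics())
    low = qc["n_genes_detected"].to_numpy() < min_genes
    hi_mito = qc["pct_mito"].to_numpy() > max_pct_mito
    keep = ~(low | hi_mito)
    if not keep.any():
        raise AllCellsFilteredError(
            f"all {ds.n_cells} cells filtered (min_genes={min_genes}, "
            f"max_pct_mito={max_pct_mito})"
        )
    out = CellDataset(
        counts=ds.counts[:, keep],
        gene_ids=ds.gene_ids,
        cell_meta=ds.cell_meta.loc[keep].copy(),
    )
    log = QCLog(
        n_input=ds.n_cells,
        n_kept=int(keep.sum()),
        n_dropped_low_genes=int(low.sum()),
        n_dropped_high_mito=int((hi_mito & ~low).sum()),
    )
    return (out, log) if return_log else out


def lognormalize(ds: CellDataset | np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Depth-normalize and log-transform counts.

    Per cell: ``x -> log(1 + scale * count / cell_total)`` (natural log).
    Zeros map to zero, and multiplying all of a cell's counts by a constant
    leaves the result unchanged.
    """
    counts = ds.counts if isinstance(ds, CellDataset) else np.asarray(ds)
    totals = counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell(s) with zero total counts at column(s) {zero[:5].tolist()}")
    return np.log1p(scale * counts / totals)


def _detection_fraction(norm: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return (norm[:, mask] > 0).mean(axis=1)


def find_cluster_markers(
    norm: np.ndarray,
    gene_ids: pd.Index | np.ndarray,
    labels: np.ndarray | pd.Series,
    cluster: str,
    min_logfc: float = 0.25,
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """Upregulated marker genes for one cluster versus the rest.

    Per gene, a two-sided Wilcoxon rank-sum test compares log-normalized
    values inside versus outside the cluster (normal approximation with tie
    correction at realistic sizes, exact null at tiny sizes). The fold
    change is ``log2((mean_in + 1) / (mean_out + 1))`` on expm1
    back-transformed normalized means. Genes are retained when
    ``log2fc > min_logfc`` (upregulated only) and
    ``max(pct_in, pct_out) >= min_pct``; Benjamini-Hochberg adjustment is
    applied over the retained tests.
    """
    labels = np.asarray(labels)
    gene_ids = pd.Index(gene_ids)
    in_mask = labels == cluster
    if not in_mask.any():
        raise ValueError(f"cluster {cluster!r} not present in labels")
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise ValueError("need >= 3 cells inside and outside the cluster")

    pct_in = _detection_fraction(norm, in_mask)
    pct_out = _detection_fraction(norm, ~in_mask)
    mean_in = np.expm1(norm[:, in_mask]).mean(axis=1)
    mean_out = np.expm1(norm[:, ~in_mask]).mean(axis=1)
    log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))

    keep = (log2fc > max(min_logfc, 0.0)) & (np.maximum(pct_in, pct_out) >= min_pct)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["log2fc", "pct_in", "pct_out", "p_value", "p_adj"],
            index=pd.Index([], name="gene"),
        )

    res = stats.mannwhitneyu(
        norm[np.ix_(idx, in_mask)],
        norm[np.ix_(idx, ~in_mask)],
        axis=1,
        alternative="two-sided",
        method="auto",
    )
    pvals = np.atleast_1d(res.pvalue)
    table = pd.DataFrame(
        {
            "log2fc": log2fc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p_value": pvals,
            "p_adj": stats.false_discovery_control(pvals, method="bh"),
        },
        index=pd.Index(gene_ids[idx], name="gene"),
    )
    return table.sort_values(["p_value", "gene"], kind="stable")
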