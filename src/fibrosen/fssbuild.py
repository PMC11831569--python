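"""Fibroblast senescence signature (FSS) construction.

Per dataset, two fibroblast gene sets are intersected:

* ``FS_x`` - genes whose expression correlates positively with the per-cell
  senescence score within fibroblasts (Spearman R > 0, BH FDR < 0.05,
  restricted to genes detected in at least 10% of fibroblast cells);
* ``FS_y`` - genes differentially upregulated in the fibroblast cluster
  (log2FC > 0.25, min.pct > 0.1, Wilcoxon rank-sum).

The intersection ``FS_n`` carries the FS_x Spearman R. Across datasets, a
gene's geometric mean of its per-dataset R values (over the datasets whose
FS_n contains it) must exceed a cutoff (default 0.25), together with a
minimum support fraction, for the gene to enter the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet

logger = logging.getLogger(__name__)


def compute_fsx(
    fibro_expr: np.ndarray,
    gene_ids: pd.Index | np.ndarray,
    scores: np.ndarray | pd.Series,
    min_detect: float = 0.1,
    fdr: float = 0.05,
    exclude_genes=None,
) -> pd.DataFrame:
    """Senescence-score-correlated genes within fibroblasts (FS_x).

    ``fibro_expr`` is genes x fibroblast-cells (log-normalized). Genes
    detected in at least ``min_detect`` of cells are tested with a
    tie-corrected Spearman correlation against the per-cell senescence
    score; two-sided p-values come from the t approximation, BH adjustment
    is applied over the tested genes, and only genes with R > 0 and
    FDR < ``fdr`` are returned. ``exclude_genes`` (typically the scoring
    gene set itself) are removed from the candidates before testing, so the
    signature cannot trivially recover the genes that define the score.
    """
    expr = np.asarray(fibro_expr, dtype=float)
    scores = np.asarray(scores, dtype=float)
    gene_ids = pd.Index(gene_ids)
    n = expr.shape[1]
    if n < 10:
        raise ValueError(f"need >= 10 fibroblast cells, got {n}")
    if scores.shape[0] != n:
        raise ValueError("scores must align with fibroblast cells")
    if np.all(scores == scores[0]):
        raise ValueError("constant senescence-score vector")

    detected = (expr > 0).mean(axis=1) >= min_detect
    if exclude_genes is not None:
        detected &= ~gene_ids.isin(list(exclude_genes))
    idx = np.flatnonzero(detected)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["spearman_r", "p_value", "fdr"], index=pd.Index([], name="gene")
        )

    # Spearman = Pearson on (tie-corrected, midrank) ranks, vectorized over genes
    gr = stats.rankdata(expr[idx], axis=1)
    sr = stats.rankdata(scores)
    gr = gr - gr.mean(axis=1, keepdims=True)
    sr = sr - sr.mean()
    denom = np.sqrt((gr**2).sum(axis=1) * (sr**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, gr @ sr / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    q = stats.false_discovery_control(p, method="bh")

    keep = (r > 0) & (q < fdr)
    table = pd.DataFrame(
        {"spearman_r": r[keep], "p_value": p[keep], "fdr": q[keep]},
        index=pd.Index(gene_ids[idx[keep]], name="gene"),
    )
    return table.sort_values("spearman_r", ascending=False, kind="stable")


def compute_fsn(fsx: pd.DataFrame, fsy: pd.DataFrame) -> pd.Series:
    """Intersection of FS_x and FS_y, carrying the FS_x Spearman R."""
    common = fsx.index.intersection(fsy.index)
    if common.empty:
        logger.info("empty FS_x/FS_y intersection")
    return fsx.loc[common, "spearman_r"].rename("spearman_r").sort_index()


@dataclass
class PerDatasetSignature:
    """FS_x / FS_y / FS_n tables for one single-cell dataset."""

    dataset_id: str
    fsx: pd.DataFrame
    fsy: pd.DataFrame
    fsn: pd.Series


@dataclass
class FibroblastSenescenceSignature:
    """The aggregated signature with per-gene geometric-mean R and support."""

    table: pd.DataFrame  # index gene; columns gmean_r, support
    members: list[str]
    cutoff: float
    min_support: int

    def to_gene_set(self, name: str = "FSS") -> GeneSet:
        return GeneSet(name=name, genes=tuple(self.members))


def aggregate_fss(
    fsn_list: list[pd.Series],
    cutoff: float = 0.25,
    min_support_frac: float = 0.25,
) -> FibroblastSenescenceSignature:
    """Aggregate per-dataset FS_n tables into the final signature.

    For each gene, support counts the datasets whose FS_n contains it and
    the geometric mean is taken over those datasets' (positive) Spearman R
    values. Membership requires ``gmean > cutoff`` and support of at least
    ``ceil(min_support_frac * n_datasets)``.
    """
    if not fsn_list:
        raise ValueError("need at least one per-dataset FS_n table")
    n_datasets = len(fsn_list)
    min_support = int(np.ceil(min_support_frac * n_datasets))
    logs: dict[str, list[float]] = {}
    for fsn in fsn_list:
        for gene, r in fsn.items():
            if r <= 0:
                raise ValueError(f"FS_n entry for {gene} has non-positive R {r}")
            logs.setdefault(gene, []).append(np.log(r))
    if logs:
        genes = sorted(logs)
        gmean = np.exp([np.mean(logs[g]) for g in genes])
        support = np.array([len(logs[g]) for g in genes])
    else:
        genes, gmean, support = [], np.array([]), np.array([], dtype=int)
    table = pd.DataFrame(
        {"gmean_r": gmean, "support": support}, index=pd.Index(genes, name="gene")
    ).sort_values("gmean_r", ascending=False, kind="stable")
    members = sorted(
        table.index[(table["gmean_r"] > cutoff) & (table["support"] >= min_support)]
    )
    return FibroblastSenescenceSignature(
        table=table, members=members, cutoff=cutoff, min_support=min_support
    )
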