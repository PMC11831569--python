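"""Single-sample gene-set enrichment (GSVA-style) and senescence scoring.

The enrichment statistic is the weighted Kolmogorov-Smirnov-like random walk
of GSVA, computed per sample over gene-level rank statistics:

1. Per gene, expression is transformed to a non-parametric statistic
   ``z`` across samples: either the empirical CDF (``ecdf``, exact and
   deterministic, the default for log-normalized single-cell data) or a
   Gaussian-kernel CDF estimate (``gauss``, for continuous bulk profiles).
2. Per sample, genes are ordered by decreasing ``z`` (ties broken by
   ascending gene index) and assigned the symmetric rank weight
   ``r = |p/2 - position|``.
3. The walk increments by the normalized weight ``r^tau`` at member genes
   and decrements by ``1/(p - |set|)`` at non-members; the enrichment score
   is ``max(0, max walk) + min(0, min walk)``, which lies in [-1, 1].

Scores are min-max normalized within the scored population ("senescence
scores"), and populations are split into high-/low-senescence groups at the
median (ties to the low group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .genesets import GeneSet

logger = logging.getLogger(__name__)

_GAUSS_CHUNK = 64  # genes per chunk when building the kernel-CDF statistic


def gene_level_stat(
    expr: np.ndarray,
    mode: str = "ecdf",
    bandwidth: np.ndarray | float | None = None,
) -> np.ndarray:
    """Rank-transform a p x n expression matrix gene-wise.

    ``ecdf``: z_ij = (1/n) #{k : x_ik <= x_ij}. ``gauss``: z_ij =
    (1/n) sum_k Phi((x_ij - x_ik) / h_i) with bandwidth h_i = sd_i / 4
    (sample sd; 1e-12 for constant genes, so all z collapse to the same
    value). ``bandwidth`` overrides the per-gene h_i.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.ndim != 2:
        raise ValueError("expr must be a 2-D genes x samples matrix")
    p, n = expr.shape
    if n == 0:
        raise ValueError("need at least one sample")
    if p < 2:
        raise ValueError("need at least two genes")
    if mode == "ecdf":
        return stats.rankdata(expr, method="max", axis=1) / n
    if mode != "gauss":
        raise ValueError(f"unknown mode {mode!r}")
    if bandwidth is None:
        sd = expr.std(axis=1, ddof=1) if n > 1 else np.zeros(p)
        h = np.where(sd > 0, sd / 4.0, 1e-12)
    else:
        h = np.broadcast_to(np.asarray(bandwidth, dtype=float), (p,)).copy()
        if np.any(h <= 0):
            raise ValueError("bandwidth must be positive")
    z = np.empty_like(expr)
    for start in range(0, p, _GAUSS_CHUNK):
        sl = slice(start, min(start + _GAUSS_CHUNK, p))
        block = expr[sl]  # b x n
        diffs = (block[:, :, None] - block[:, None, :]) / h[sl, None, None]
        z[sl] = special.ndtr(diffs).mean(axis=2)
    return z


def _walk_components(p: int, tau: float) -> np.ndarray:
    positions = np.arange(1, p + 1, dtype=float)
    return np.abs(p / 2.0 - positions) ** tau


def gsva_es(
    z: np.ndarray,
    gene_set: GeneSet | np.ndarray,
    universe: pd.Index | np.ndarray | None = None,
    tau: float = 1.0,
) -> np.ndarray:
    """Enrichment score per sample from a gene-level statistic matrix.

    ``gene_set`` may be a :class:`GeneSet` (resolved against ``universe``)
    or a boolean/int membership index over the rows of ``z``. When every
    member lands at a zero rank weight (possible only at tiny p), members
    are weighted uniformly so the walk remains defined.
    """
    z = np.asarray(z, dtype=float)
    p, n = z.shape
    if isinstance(gene_set, GeneSet):
        if universe is None:
            raise ValueError("universe required to resolve a GeneSet")
        universe = pd.Index(universe)
        member = universe.isin(gene_set.genes)
    else:
        member = np.zeros(p, dtype=bool)
        member[np.asarray(gene_set)] = True
    k = int(member.sum())
    if k == 0:
        raise ValueError("gene set has empty intersection with the universe")
    if k >= p:
        raise ValueError("gene set covers every gene; decrement term undefined")

    # Decreasing z with ties broken by ascending gene index: stable sort on -z.
    order = np.argsort(-z, axis=0, kind="stable")
    weights = _walk_components(p, tau)[:, None]  # by position, shared across samples
    member_sorted = member[order]  # p x n

    inc_raw = np.where(member_sorted, weights, 0.0)
    denom = inc_raw.sum(axis=0)
    degenerate = denom == 0.0
    if np.any(degenerate):
        uniform = np.where(member_sorted[:, degenerate], 1.0 / k, 0.0)
        inc_raw[:, degenerate] = uniform
        denom = inc_raw.sum(axis=0)
    walk = np.cumsum(inc_raw / denom, axis=0) - np.cumsum(~member_sorted, axis=0) / (p - k)
    return np.maximum(walk.max(axis=0), 0.0) + np.minimum(walk.min(axis=0), 0.0)


def minmax_normalize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Map to [0, 1] by (x - min)/(max - min); constant input maps to 0.5."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        logger.warning("min-max normalization of a constant vector; returning 0.5")
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def split_by_median(scores: np.ndarray | pd.Series, ids=None) -> pd.Series:
    """Median split into 'HS' (score > median) and 'LS' (score <= median)."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("median split needs at least two samples")
    if np.all(arr == arr[0]):
        raise ValueError("median split undefined for constant scores")
    med = np.median(arr)
    labels = np.where(arr > med, "HS", "LS")
    index = pd.Index(ids) if ids is not None else pd.RangeIndex(arr.size)
    return pd.Series(labels, index=index, name="group")


@dataclass
class SenescenceScores:
    """Per-sample enrichment scores with normalized score and HS/LS flag."""

    table: pd.DataFrame  # columns: es, score, group

    @property
    def es(self) -> pd.Series:
        return self.table["es"]

    @property
    def score(self) -> pd.Series:
        return self.table["score"]

    @property
    def group(self) -> pd.Series:
        return self.table["group"]


def score_samples(
    expr: np.ndarray,
    universe: pd.Index | np.ndarray,
    gene_set: GeneSet,
    sample_ids=None,
    mode: str = "ecdf",
    tau: float = 1.0,
    split: bool = True,
) -> SenescenceScores:
    """Full scoring pass: rank statistic, enrichment, min-max, median split."""
    z = gene_level_stat(expr, mode=mode)
    es = gsva_es(z, gene_set, universe=universe, tau=tau)
    score = minmax_normalize(es)
    index = pd.Index(sample_ids) if sample_ids is not None else pd.RangeIndex(es.size)
    table = pd.DataFrame({"es": es, "score": score}, index=index)
    table["group"] = split_by_median(score, index).values if split else pd.NA
    return SenescenceScores(table=table)
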