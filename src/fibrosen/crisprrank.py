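"""CRISPR-screen integration: z-scoring, rank aggregation, enrichment, hubs.

Each screen's gene-level logFC values are z-scored within the dataset
(sample standard deviation) to remove dataset-specific location and scale.
Genes are ranked ascending by the mean z across the datasets measuring
them: the most negative aggregated z ranks first, since depletion under
immune pressure marks knockouts that enhance antitumor immunity. The top
fraction (default 10%) is flagged; signature over-representation among the
flags is tested with the hypergeometric upper tail (one-sided Fisher), and
candidate targets are intersected with prognostic-model genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScreenMatrix:
    """One screen dataset: gene -> logFC (missing values allowed as NaN)."""

    dataset_id: str
    logfc: pd.Series

    def __post_init__(self) -> None:
        finite = np.isfinite(self.logfc.to_numpy(dtype=float))
        if finite.sum() < 2:
            raise ValueError(f"screen {self.dataset_id} needs >= 2 finite logFC values")


def zscore_screens(screens: list[ScreenMatrix]) -> list[ScreenMatrix]:
    """Within-dataset z-scoring of logFC (ddof=1) over finite entries."""
    out = []
    for sm in screens:
        vals = sm.logfc.astype(float)
        finite = np.isfinite(vals.to_numpy())
        sd = vals[finite].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"screen {sm.dataset_id} has zero logFC variance")
        z = (vals - vals[finite].mean()) / sd
        out.append(ScreenMatrix(dataset_id=sm.dataset_id, logfc=z))
    return out


@dataclass
class GeneRanking:
    """Aggregated z, support, ascending rank, and top-fraction flag per gene."""

    table: pd.DataFrame  # index gene; columns agg_z, support, rank, flagged
    fraction: float

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def aggregate_rank(
    screens: list[ScreenMatrix],
    min_support: int = 1,
    fraction: float = 0.10,
) -> GeneRanking:
    """Mean-z aggregation and ascending ranking across normalized screens.

    Rank 1 is the most negative aggregated z (strongest immune-resistance
    candidate); ties break by gene id. Exactly ``ceil(fraction * G)`` genes
    are flagged.
    """
    if not screens:
        raise ValueError("need at least one screen")
    wide = pd.DataFrame({sm.dataset_id: sm.logfc for sm in screens})
    support = wide.notna().sum(axis=1)
    agg = wide.mean(axis=1, skipna=True)
    keep = support >= min_support
    if not keep.any():
        raise ValueError(f"no gene measured in >= {min_support} datasets")
    table = pd.DataFrame({"agg_z": agg[keep], "support": support[keep]})
    table = table.iloc[np.lexsort((table.index.to_numpy(), table["agg_z"].to_numpy()))]
    table["rank"] = np.arange(1, len(table) + 1)
    n_flag = int(np.ceil(fraction * len(table)))
    table["flagged"] = table["rank"] <= n_flag
    return GeneRanking(table=table, fraction=fraction)


def enrichment_test(ranking: GeneRanking, signature) -> tuple[int, float, float]:
    """Hypergeometric over-representation of a signature among flagged genes.

    Returns ``(k, expected, p)`` where k is the flagged-signature overlap,
    expected its null mean K*n/N, and p the upper tail P(X >= k) — identical
    to a one-sided Fisher exact test on the 2x2 table.
    """
    universe = ranking.table.index
    sig_genes = set(signature.genes if hasattr(signature, "genes") else signature)
    in_universe = [g for g in universe if g in sig_genes]
    if not in_universe:
        raise ValueError("signature has empty intersection with the ranked universe")
    N = len(universe)
    K = int(ranking.table["flagged"].sum())
    n_sig = len(in_universe)
    k = int(ranking.table.loc[in_universe, "flagged"].sum())
    expected = K * n_sig / N
    p = float(stats.hypergeom.sf(k - 1, N, K, n_sig))
    return k, expected, p


def intersect_hub(candidate_genes, prognostic_genes) -> list[str]:
    """Intersection of screen candidates and prognostic genes, sorted by id."""
    cand = list(candidate_genes)
    prog = list(prognostic_genes)
    if not cand or not prog:
        raise ValueError("both candidate and prognostic gene lists must be non-empty")
    hubs = sorted(set(cand) & set(prog))
    return hubs
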