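"""Bulk-cohort scoring, immune abundance, pathway correlation, stratification.

Bulk samples are scored with the fibroblast senescence signature using the
same enrichment engine as the single-cell scoring (Gaussian-kernel gene
statistic for continuous profiles). Immune-population abundance uses a
marker-mean score over user-supplied marker gene sets. Samples are
stratified into high/low FSS x high/low TMB subgroups at pooled medians,
and subgroup score differences are compared with pairwise Mann-Whitney U
tests under BH correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet
from .senescore import gene_level_stat, gsva_es

logger = logging.getLogger(__name__)


@dataclass
class BulkCohort:
    """Samples x genes log-scale expression plus clinical covariates.

    Clinical columns: ``cohort``, ``os_time`` (days, > 0), ``os_event``
    (0/1); optional ``tmb``, ``response`` ('R'/'NR'), ``stage``.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.expression.index.equals(self.clinical.index):
            raise ValueError("expression and clinical tables must share sample ids")
        if "os_time" in self.clinical and (self.clinical["os_time"] <= 0).any():
            raise ValueError("os_time must be positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns


def score_cohort_fss(
    cohort: BulkCohort, fss: GeneSet, mode: str = "gauss", tau: float = 1.0
) -> pd.Series:
    """Per-sample enrichment score of the signature over the cohort."""
    if len(cohort.sample_ids) < 2:
        raise ValueError("need at least two samples")
    present = fss.intersect(cohort.genes)
    if not present:
        raise ValueError("signature has no overlap with cohort genes")
    coverage = len(present) / len(fss)
    if coverage < 0.5:
        logger.warning("signature coverage only %.0f%% of members", 100 * coverage)
    z = gene_level_stat(cohort.expression.to_numpy().T, mode=mode)
    es = gsva_es(z, fss, universe=cohort.genes, tau=tau)
    return pd.Series(es, index=cohort.sample_ids, name="fss_score")


def immune_scores(cohort: BulkCohort, marker_sets: list[GeneSet]) -> pd.DataFrame:
    """Marker-mean abundance score per sample for each population set."""
    out = {}
    for gs in marker_sets:
        present = gs.intersect(cohort.genes)
        if not present:
            logger.warning("marker set %s has no overlap; skipped", gs.name)
            continue
        out[gs.name] = cohort.expression[present].mean(axis=1)
    return pd.DataFrame(out, index=cohort.sample_ids)


def pathway_correlation(
    fss_scores: pd.Series, pathway_scores: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of the FSS score against each pathway score."""
    common = fss_scores.index.intersection(pathway_scores.index)
    if len(common) < 5:
        raise ValueError("need at least 5 aligned samples")
    x = fss_scores.loc[common].to_numpy()
    rows = {}
    for name in pathway_scores.columns:
        y = pathway_scores.loc[common, name].to_numpy()
        if np.all(y == y[0]) or np.all(x == x[0]):
            rows[name] = (np.nan, np.nan)
            continue
        r, p = stats.spearmanr(x, y)
        rows[name] = (r, p)
    table = pd.DataFrame(rows, index=["spearman_r", "p_value"]).T
    valid = table["p_value"].notna()
    table["fdr"] = np.nan
    if valid.any():
        table.loc[valid, "fdr"] = stats.false_discovery_control(
            table.loc[valid, "p_value"].to_numpy(), method="bh"
        )
    return table


@dataclass
class SubgroupAssignment:
    """Per-sample FSS / TMB marginal labels and the combined subgroup."""

    table: pd.DataFrame  # columns fss_label (HF/LF), tmb_label (HT/LT), combined

    @property
    def combined(self) -> pd.Series:
        return self.table["combined"]


def stratify_fss_tmb(
    fss_scores: pd.Series, tmb: pd.Series, pooled: bool = True, cohort: pd.Series | None = None
) -> SubgroupAssignment:
    """Median-split stratification into HFHT / HFLT / LFHT / LFLT.

    High-FSS (HF) means score strictly above the median (ties to LF);
    likewise HT/LT for TMB. Medians are pooled across cohorts by default;
    with ``pooled=False`` a ``cohort`` series is required and medians are
    taken within each cohort.
    """
    common = fss_scores.index.intersection(tmb.index)
    if len(common) < 4:
        raise ValueError("need at least 4 samples with both FSS score and TMB")
    s = fss_scores.loc[common]
    t = tmb.loc[common]
    if pooled:
        hf = s > s.median()
        ht = t > t.median()
    else:
        if cohort is None:
            raise ValueError("per-cohort stratification requires a cohort series")
        grp = cohort.loc[common]
        hf = s > s.groupby(grp).transform("median")
        ht = t > t.groupby(grp).transform("median")
    table = pd.DataFrame(
        {
            "fss_label": np.where(hf, "HF", "LF"),
            "tmb_label": np.where(ht, "HT", "LT"),
        },
        index=common,
    )
    table["combined"] = table["fss_label"] + table["tmb_label"]
    return SubgroupAssignment(table=table)


def compare_subgroups(
    scores: pd.DataFrame | pd.Series,
    assignment: SubgroupAssignment | pd.Series,
    min_group: int = 3,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between subgroups, with BH."""
    labels = assignment.combined if isinstance(assignment, SubgroupAssignment) else assignment
    frame = scores.to_frame() if isinstance(scores, pd.Series) else scores
    groups = sorted(labels.unique())
    rows = []
    for col in frame.columns:
        for a, b in itertools.combinations(groups, 2):
            va = frame.loc[labels.index[labels == a], col].dropna()
            vb = frame.loc[labels.index[labels == b], col].dropna()
            if len(va) < min_group or len(vb) < min_group:
                logger.warning("pair (%s, %s) skipped for %s: group too small", a, b, col)
                continue
            u, p = stats.mannwhitneyu(va, vb, alternative="two-sided", method="auto")
            rows.append((col, a, b, float(u), float(p)))
    table = pd.DataFrame(rows, columns=["score", "group_a", "group_b", "u_stat", "p_value"])
    if len(table):
        table["p_adj"] = stats.false_discovery_control(table["p_value"].to_numpy(), method="bh")
    else:
        table["p_adj"] = []
    return table
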