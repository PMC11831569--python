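"""Seeded synthetic data with planted ground truth.

Three generators emulate the statistical structure the downstream analysis
assumes, with every latent quantity recorded so recovery can be measured:

* ``generate_sc_datasets`` - cell-type-structured negative-binomial count
  matrices in which each cell carries a latent senescence state ``s_c`` in
  [0, 1] (higher in fibroblasts). A senescence gene program responds to
  ``s_c`` in every cell type; a disjoint planted fibroblast-senescence gene
  set responds to ``s_c`` in fibroblasts only and is additionally
  fibroblast-upregulated; each cell type gets disjoint marker genes; a
  fraction of cells is planted at 5% sequencing depth to exercise QC, and
  mitochondrial genes carry the conventional ``MT-`` prefix.
* ``generate_bulk_cohorts`` - pseudo-bulk cohorts whose survival hazard is
  exponential and increasing in a latent senescence burden ``S_i``, with an
  independently calibrated censoring rate, a response probability
  decreasing in ``S_i``, an independent log-normal tumor mutation burden,
  per-cohort batch shifts, and cytotoxic-marker genes decreasing in ``S_i``
  and increasing in log TMB.
* ``generate_crispr_screens`` - per-dataset gene-level logFC tables with
  dataset-specific location and scale and planted immune-resistance genes
  shifted down by ``screen_effect``; a configurable subset of these overlap
  the planted fibroblast-senescence genes (and receive a boosted bulk
  prognostic effect) so they carry triple evidence for end-to-end target
  nomination.

All randomness derives from ``SimConfig.seed``; equal configurations give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bulkscore import BulkCohort
from .crisprrank import ScreenMatrix
from .scprep import MITO_PREFIX, CellDataset

CELL_TYPES = ("fibroblast", "malignant", "tcell", "bcell", "myeloid", "endothelial")

# Stream labels keep the per-generator RNGs independent of one another.
_STREAM_PLANT, _STREAM_SC, _STREAM_BULK, _STREAM_SCREEN = 11, 23, 37, 53


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, index]))


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults defining its conditions."""

    # single-cell
    n_datasets: int = 8
    n_cells_per_dataset: int = 1500
    n_genes: int = 1500
    cell_type_props: dict = field(
        default_factory=lambda: {
            "fibroblast": 0.25,
            "malignant": 0.30,
            "tcell": 0.20,
            "bcell": 0.10,
            "myeloid": 0.10,
            "endothelial": 0.05,
        }
    )
    n_senescence_genes: int = 50
    n_planted_fss_genes: int = 40
    n_marker_genes: int = 20
    senescence_effect: float = 1.0  # gamma: senescence-set log-mean slope on s_c, all cells
    fss_effect: float = 1.0  # beta: planted-gene log-mean slope on s_c, fibroblasts only
    marker_effect: float = 1.3  # log-scale shift of marker genes in their own cell type
    gene_logmean_sd: float = 0.8
    nb_dispersion: float = 0.08
    mean_depth: float = 15000.0
    depth_log_sd: float = 0.3
    mito_gene_count: int = 10
    mito_shift: float = 1.3
    mito_logmean_sd: float = 0.3
    lowdepth_cell_frac: float = 0.10
    lowdepth_scale: float = 0.05
    # bulk cohorts
    bulk_n_samples: int = 400
    bulk_n_cohorts: int = 4
    batch_sd: float = 0.5
    bulk_effect: float = 2.0  # planted-gene log-expression slope on S_i
    bulk_noise_sd: float = 0.5
    hazard_coef: float = 3.0  # beta_s: log-hazard slope on S_i
    baseline_hazard: float = 1e-3  # events per day
    censor_frac: float = 0.30
    response_coef: float = 3.0  # beta_r: drop in logit response per unit S_i
    n_cytotoxic_genes: int = 15
    cytotoxic_senescence_coef: float = 1.0
    cytotoxic_tmb_coef: float = 0.15
    tmb_meanlog: float = 1.0
    tmb_sdlog: float = 0.5
    # CRISPR screens
    screen_n_datasets: int = 17
    screen_effect: float = 2.0  # delta: depletion of planted resistant genes
    screen_n_resistant: int = 15
    screen_fss_overlap: int = 5
    hub_effect_boost: float = 2.0  # bulk-effect multiplier for overlap (hub) genes
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_datasets": self.n_datasets,
            "n_cells_per_dataset": self.n_cells_per_dataset,
            "n_genes": self.n_genes,
            "n_senescence_genes": self.n_senescence_genes,
            "n_planted_fss_genes": self.n_planted_fss_genes,
            "n_marker_genes": self.n_marker_genes,
            "mito_gene_count": self.mito_gene_count,
            "bulk_n_samples": self.bulk_n_samples,
            "bulk_n_cohorts": self.bulk_n_cohorts,
            "n_cytotoxic_genes": self.n_cytotoxic_genes,
            "screen_n_datasets": self.screen_n_datasets,
            "screen_n_resistant": self.screen_n_resistant,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("lowdepth_cell_frac", "censor_frac"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {value}")
        props = self.cell_type_props
        if set(props) != set(CELL_TYPES):
            raise ValueError(f"cell_type_props must cover exactly {CELL_TYPES}")
        vals = np.array([props[t] for t in CELL_TYPES], dtype=float)
        if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0):
            raise ValueError("cell_type_props must be non-negative and sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.screen_effect < 0:
            raise ValueError("screen_effect must be non-negative")
        if self.screen_fss_overlap > min(self.screen_n_resistant, self.n_planted_fss_genes):
            raise ValueError("screen_fss_overlap exceeds the planted set sizes")
        reserved = (
            self.n_senescence_genes
            + self.n_planted_fss_genes
            + len(CELL_TYPES) * self.n_marker_genes
            + self.n_cytotoxic_genes
            + (self.screen_n_resistant - self.screen_fss_overlap)
        )
        free = self.n_genes - self.mito_gene_count
        if reserved > free:
            raise ValueError(
                f"n_genes too small: {reserved} planted genes requested but only "
                f"{free} non-mitochondrial genes available (deficit {reserved - free})"
            )


@dataclass
class PlantedSets:
    """Disjoint planted gene programs shared by all three generators."""

    gene_ids: pd.Index
    senescence_genes: list[str]
    fss_genes: list[str]
    marker_genes: dict[str, list[str]]
    cytotoxic_genes: list[str]
    resistant_genes: list[str]
    overlap_genes: list[str]  # resistant AND planted-FSS (triple-evidence hub genes)
    mito_genes: list[str]


def planted_sets(config: SimConfig) -> PlantedSets:
    """Deterministically lay out the gene universe and planted programs."""
    n_regular = config.n_genes - config.mito_gene_count
    width = len(str(config.n_genes))
    regular = [f"G{i + 1:0{width}d}" for i in range(n_regular)]
    mito = [f"{MITO_PREFIX}{i + 1}" for i in range(config.mito_gene_count)]
    gene_ids = pd.Index(regular + mito)

    rng = _rng(config.seed, _STREAM_PLANT)
    pool = list(rng.permutation(regular))

    def take(n: int) -> list[str]:
        taken = pool[:n]
        del pool[:n]
        return taken

    senescence = sorted(take(config.n_senescence_genes))
    fss = sorted(take(config.n_planted_fss_genes))
    markers = {t: sorted(take(config.n_marker_genes)) for t in CELL_TYPES}
    cytotoxic = sorted(take(config.n_cytotoxic_genes))
    overlap = sorted(fss[: config.screen_fss_overlap])
    extra = sorted(take(config.screen_n_resistant - config.screen_fss_overlap))
    resistant = sorted(overlap + extra)
    return PlantedSets(
        gene_ids=gene_ids,
        senescence_genes=senescence,
        fss_genes=fss,
        marker_genes=markers,
        cytotoxic_genes=cytotoxic,
        resistant_genes=resistant,
        overlap_genes=overlap,
        mito_genes=mito,
    )


@dataclass
class ScTruth:
    """Latent single-cell ground truth for one generated dataset."""

    dataset_id: str
    latent_senescence: np.ndarray  # s_c per cell, in [0, 1]
    lowdepth_cells: np.ndarray  # boolean planted-QC mask per cell
    senescence_genes: list[str]
    fss_genes: list[str]
    marker_genes: dict[str, list[str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dataset_id": self.dataset_id,
            "latent_senescence": self.latent_senescence.tolist(),
            "lowdepth_cells": self.lowdepth_cells.astype(int).tolist(),
            "senescence_genes": self.senescence_genes,
            "fss_genes": self.fss_genes,
            "marker_genes": self.marker_genes,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            dataset_id=d["dataset_id"],
            latent_senescence=np.asarray(d["latent_senescence"], dtype=float),
            lowdepth_cells=np.asarray(d["lowdepth_cells"], dtype=bool),
            senescence_genes=d["senescence_genes"],
            fss_genes=d["fss_genes"],
            marker_genes=d["marker_genes"],
        )


def generate_sc_datasets(config: SimConfig) -> list[tuple[CellDataset, ScTruth]]:
    """Generate ``config.n_datasets`` single-cell datasets with planted truth."""
    plants = planted_sets(config)
    gene_ids = plants.gene_ids
    gene_pos = pd.Series(np.arange(len(gene_ids)), index=gene_ids)
    sen_idx = gene_pos[plants.senescence_genes].to_numpy()
    fss_idx = gene_pos[plants.fss_genes].to_numpy()
    mito_idx = gene_pos[plants.mito_genes].to_numpy()
    marker_idx = {t: gene_pos[g].to_numpy() for t, g in plants.marker_genes.items()}
    props = np.array([config.cell_type_props[t] for t in CELL_TYPES])

    out = []
    for d in range(config.n_datasets):
        rng = _rng(config.seed, _STREAM_SC, d)
        n_cells = config.n_cells_per_dataset
        types = rng.choice(np.array(CELL_TYPES), size=n_cells, p=props)
        fibro = types == "fibroblast"
        s_c = np.where(fibro, rng.beta(5.0, 2.0, n_cells), rng.beta(2.0, 5.0, n_cells))

        # per-dataset gene baselines emulate platform differences
        log_mean = rng.normal(0.0, config.gene_logmean_sd, size=config.n_genes)
        log_mean[mito_idx] = config.mito_shift + rng.normal(
            0.0, config.mito_logmean_sd, size=mito_idx.size
        )

        lograte = np.repeat(log_mean[:, None], n_cells, axis=1)
        lograte[sen_idx] += config.senescence_effect * s_c[None, :]
        lograte[np.ix_(fss_idx, np.flatnonzero(fibro))] += (
            config.fss_effect * s_c[fibro][None, :] + config.marker_effect
        )
        for t in CELL_TYPES:
            cols = np.flatnonzero(types == t)
            if cols.size:
                lograte[np.ix_(marker_idx[t], cols)] += config.marker_effect

        weights = np.exp(lograte)
        depth = rng.lognormal(np.log(config.mean_depth), config.depth_log_sd, n_cells)
        lowdepth = rng.random(n_cells) < config.lowdepth_cell_frac
        depth = np.where(lowdepth, depth * config.lowdepth_scale, depth)
        mean = weights * (depth / weights.sum(axis=0))[None, :]

        # NB with mean mu and variance mu + dispersion * mu^2
        size = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mean)).astype(np.int64)

        dataset_id = f"sc{d + 1:02d}"
        barcodes = pd.Index([f"{dataset_id}_c{i + 1:04d}" for i in range(n_cells)])
        meta = pd.DataFrame(
            {"dataset_id": dataset_id, "cell_type": types}, index=barcodes
        )
        ds = CellDataset(counts=counts, gene_ids=gene_ids, cell_meta=meta)
        truth = ScTruth(
            dataset_id=dataset_id,
            latent_senescence=s_c,
            lowdepth_cells=lowdepth,
            senescence_genes=plants.senescence_genes,
            fss_genes=plants.fss_genes,
            marker_genes=plants.marker_genes,
        )
        out.append((ds, truth))
    return out


@dataclass
class BulkTruth:
    """Latent bulk ground truth: burden, hazard, response probability, batches."""

    latent_burden: pd.Series  # S_i in [0, 1]
    hazard: pd.Series
    response_prob: pd.Series
    fibroblast_fraction: pd.Series
    cohort_offsets: pd.DataFrame  # cohorts x genes
    fss_genes: list[str]
    cytotoxic_genes: list[str]
    overlap_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "latent_burden": self.latent_burden.to_dict(),
            "hazard": self.hazard.to_dict(),
            "response_prob": self.response_prob.to_dict(),
            "fibroblast_fraction": self.fibroblast_fraction.to_dict(),
            "fss_genes": self.fss_genes,
            "cytotoxic_genes": self.cytotoxic_genes,
            "overlap_genes": self.overlap_genes,
        }
        Path(path).write_text(json.dumps(payload))


def _calibrate_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Bisect the exponential censoring rate to the target censored fraction.

    With independent exponential death and censoring times, a sample with
    death hazard h is censored with probability c/(c + h); the expected
    censored fraction is the mean over samples, which is monotone in c.
    """
    if target <= 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    lo, hi = 1e-12, float(hazards.max())
    while frac(hi) < target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_bulk_cohorts(config: SimConfig) -> tuple[BulkCohort, BulkTruth]:
    """Generate a multi-cohort bulk dataset with survival, TMB and response."""
    plants = planted_sets(config)
    rng = _rng(config.seed, _STREAM_BULK)
    n, g = config.bulk_n_samples, config.n_genes
    gene_ids = plants.gene_ids
    gene_pos = pd.Series(np.arange(g), index=gene_ids)

    sample_ids = pd.Index([f"s{i + 1:04d}" for i in range(n)])
    cohorts = np.array([f"cohort{(i % config.bulk_n_cohorts) + 1}" for i in range(n)])
    S = rng.beta(2.0, 2.0, n)
    mixture = rng.dirichlet(np.full(len(CELL_TYPES), 2.0), size=n)  # n x types
    f = mixture[:, CELL_TYPES.index("fibroblast")]
    tmb = rng.lognormal(config.tmb_meanlog, config.tmb_sdlog, n)
    ztmb = (np.log(tmb) - config.tmb_meanlog) / config.tmb_sdlog

    base = rng.normal(0.0, config.gene_logmean_sd, g)
    expr = np.repeat(base[None, :], n, axis=0)
    for t, genes in plants.marker_genes.items():
        expr[:, gene_pos[genes].to_numpy()] += 2.0 * mixture[:, [CELL_TYPES.index(t)]]
    boost = np.ones(len(plants.fss_genes))
    overlap_mask = np.isin(plants.fss_genes, plants.overlap_genes)
    boost[overlap_mask] = config.hub_effect_boost
    expr[:, gene_pos[plants.fss_genes].to_numpy()] += (
        config.bulk_effect * S[:, None] * boost[None, :]
    )
    expr[:, gene_pos[plants.cytotoxic_genes].to_numpy()] += (
        -config.cytotoxic_senescence_coef * S[:, None]
        + config.cytotoxic_tmb_coef * ztmb[:, None]
    )
    offsets = rng.normal(0.0, config.batch_sd, size=(config.bulk_n_cohorts, g))
    cohort_names = [f"cohort{c + 1}" for c in range(config.bulk_n_cohorts)]
    cohort_of = {name: i for i, name in enumerate(cohort_names)}
    expr += offsets[[cohort_of[c] for c in cohorts]]
    expr += rng.normal(0.0, config.bulk_noise_sd, size=(n, g))

    hazard = config.baseline_hazard * np.exp(config.hazard_coef * S)
    death = rng.exponential(1.0 / hazard)
    censor_rate = _calibrate_censor_rate(hazard, config.censor_frac)
    if censor_rate > 0:
        censor = rng.exponential(1.0 / censor_rate, n)
    else:
        censor = np.full(n, np.inf)
    os_time = np.minimum(death, censor)
    os_event = (death <= censor).astype(int)

    # response logit drops by response_coef per SD of burden (Beta(2,2) sd)
    z_burden = (S - 0.5) / np.sqrt(0.05)
    p_resp = 1.0 / (1.0 + np.exp(config.response_coef * z_burden))
    response = np.where(rng.random(n) < p_resp, "R", "NR")
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.2, 0.3, 0.3, 0.2])

    clinical = pd.DataFrame(
        {
            "cohort": cohorts,
            "os_time": np.maximum(os_time, 1e-3),
            "os_event": os_event,
            "tmb": tmb,
            "response": response,
            "stage": stage,
        },
        index=sample_ids,
    )
    cohort_obj = BulkCohort(
        expression=pd.DataFrame(expr, index=sample_ids, columns=gene_ids),
        clinical=clinical,
    )
    truth = BulkTruth(
        latent_burden=pd.Series(S, index=sample_ids),
        hazard=pd.Series(hazard, index=sample_ids),
        response_prob=pd.Series(p_resp, index=sample_ids),
        fibroblast_fraction=pd.Series(f, index=sample_ids),
        cohort_offsets=pd.DataFrame(offsets, index=cohort_names, columns=gene_ids),
        fss_genes=plants.fss_genes,
        cytotoxic_genes=plants.cytotoxic_genes,
        overlap_genes=plants.overlap_genes,
    )
    return cohort_obj, truth


@dataclass
class ScreenTruth:
    """Planted immune-resistance genes and per-dataset location/scale."""

    resistant_genes: list[str]
    overlap_genes: list[str]
    locations: pd.Series  # mu_d per dataset
    scales: pd.Series  # sigma_d per dataset

    def to_json(self, path: str | Path) -> None:
        payload = {
            "resistant_genes": self.resistant_genes,
            "overlap_genes": self.overlap_genes,
            "locations": self.locations.to_dict(),
            "scales": self.scales.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))


def generate_crispr_screens(config: SimConfig) -> tuple[list[ScreenMatrix], ScreenTruth]:
    """Generate per-dataset gene-level logFC tables with planted depletions."""
    plants = planted_sets(config)
    gene_ids = plants.gene_ids
    resistant_mask = gene_ids.isin(plants.resistant_genes)

    screens, mus, sigmas = [], {}, {}
    for d in range(config.screen_n_datasets):
        rng = _rng(config.seed, _STREAM_SCREEN, d)
        dataset_id = f"screen{d + 1:02d}"
        mu = rng.normal(0.0, 0.5)
        sigma = rng.uniform(0.5, 2.0)
        logfc = rng.normal(mu, sigma, size=len(gene_ids))
        logfc[resistant_mask] -= config.screen_effect
        screens.append(
            ScreenMatrix(dataset_id=dataset_id, logfc=pd.Series(logfc, index=gene_ids))
        )
        mus[dataset_id], sigmas[dataset_id] = mu, sigma
    truth = ScreenTruth(
        resistant_genes=plants.resistant_genes,
        overlap_genes=plants.overlap_genes,
        locations=pd.Series(mus),
        scales=pd.Series(sigmas),
    )
    return screens, truth


def write_simulation(config: SimConfig, out_dir: str | Path) -> None:
    """Run all three generators and write their artifacts under ``out_dir``."""
    out = Path(out_dir)
    sc_dir = out / "sc"
    for ds, truth in generate_sc_datasets(config):
        d = sc_dir / truth.dataset_id
        ds.to_dir(d)
        truth.to_json(d / "truth.json")
    bulk, bulk_truth = generate_bulk_cohorts(config)
    bulk_dir = out / "bulk"
    bulk_dir.mkdir(parents=True, exist_ok=True)
    bulk.expression.to_csv(bulk_dir / "expr.tsv", sep="\t", index_label="sample_id")
    bulk.clinical.to_csv(bulk_dir / "clinical.tsv", sep="\t", index_label="sample_id")
    bulk_truth.to_json(bulk_dir / "truth.json")
    screens, screen_truth = generate_crispr_screens(config)
    screen_dir = out / "screens"
    screen_dir.mkdir(parents=True, exist_ok=True)
    for sm in screens:
        sm.logfc.rename("logfc").to_csv(
            screen_dir / f"{sm.dataset_id}.tsv", sep="\t", index_label="gene"
        )
    screen_truth.to_json(screen_dir / "truth.json")
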