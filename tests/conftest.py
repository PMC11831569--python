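from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibrosen import (
    GeneSet,
    SimConfig,
    compute_fsn,
    compute_fsx,
    find_cluster_markers,
    generate_sc_datasets,
    lognormalize,
    qc_filter_cells,
    score_samples,
)
from fibrosen.fssbuild import aggregate_fss
from fibrosen.scprep import CellDataset


def tiny_cell_dataset(n_genes=30, n_cells=40, seed=0) -> tuple[CellDataset, np.ndarray]:
    """A small random dataset with two cell types for unit tests."""
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:03d}" for i in range(n_genes - 2)] + ["MT-1", "MT-2"])
    counts = rng.poisson(5.0, size=(n_genes, n_cells))
    types = np.where(rng.random(n_cells) < 0.5, "fibroblast", "tcell")
    meta = pd.DataFrame(
        {"dataset_id": "tiny", "cell_type": types},
        index=pd.Index([f"c{i:03d}" for i in range(n_cells)]),
    )
    return CellDataset(counts=counts, gene_ids=genes, cell_meta=meta), types


@pytest.fixture
def tiny_dataset():
    return tiny_cell_dataset()[0]


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A scaled-down simulation for fast unit tests (not the study defaults)."""
    return SimConfig(
        n_datasets=2,
        n_cells_per_dataset=400,
        n_genes=700,
        n_senescence_genes=25,
        n_planted_fss_genes=15,
        n_marker_genes=8,
        n_cytotoxic_genes=8,
        screen_n_datasets=5,
        screen_n_resistant=8,
        screen_fss_overlap=3,
        mito_shift=0.5,
        bulk_n_samples=120,
        bulk_n_cohorts=3,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sc_data(small_sim_config):
    return generate_sc_datasets(small_sim_config)


@pytest.fixture(scope="session")
def default_sc_pipeline():
    """The full per-dataset single-cell analysis at the study defaults, seed 1.

    Shared by the signature-recovery and score-recovery checks so the heavy
    simulation runs once per session. Returns per-dataset records and the
    aggregated signature.
    """
    config = SimConfig(seed=1)
    data = generate_sc_datasets(config)
    records = []
    fsn_list = []
    for ds, truth in data:
        filtered = qc_filter_cells(ds)
        norm = lognormalize(filtered)
        senescence_set = GeneSet("senescence", tuple(truth.senescence_genes))
        scores = score_samples(
            norm, filtered.gene_ids, senescence_set, sample_ids=filtered.cell_meta.index
        )
        kept = ds.cell_meta.index.isin(filtered.cell_meta.index)
        s_c = truth.latent_senescence[kept]
        fibro = (filtered.cell_meta["cell_type"] == "fibroblast").to_numpy()
        fsy = find_cluster_markers(
            norm, filtered.gene_ids, filtered.cell_meta["cell_type"].to_numpy(), "fibroblast"
        )
        fsx = compute_fsx(
            norm[:, fibro],
            filtered.gene_ids,
            scores.score.to_numpy()[fibro],
            exclude_genes=truth.senescence_genes,
        )
        fsn = compute_fsn(fsx, fsy)
        fsn_list.append(fsn)
        records.append(
            {
                "dataset": filtered,
                "norm": norm,
                "truth": truth,
                "scores": scores,
                "s_c": s_c,
                "fibro_mask": fibro,
                "fsx": fsx,
                "fsy": fsy,
                "fsn": fsn,
            }
        )
    signature = aggregate_fss(fsn_list)
    return {"config": config, "records": records, "signature": signature}
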