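"""Generator determinism, planted structure, and marginal sanity checks."""

import numpy as np
import pytest
from scipy import stats

from fibrosen.synthdata import (
    CELL_TYPES,
    ScTruth,
    SimConfig,
    generate_bulk_cohorts,
    generate_crispr_screens,
    generate_sc_datasets,
    planted_sets,
    write_simulation,
)
from fibrosen.mtlrsurv import concordance
from fibrosen.icimodel import roc_auc


class TestConfigValidation:
    def test_bad_props_rejected(self):
        props = {t: 1.0 / 6 for t in CELL_TYPES}
        props["fibroblast"] = 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(cell_type_props=props)

    def test_sizing_error_names_deficit(self):
        with pytest.raises(ValueError, match="deficit"):
            SimConfig(n_genes=120)

    def test_censor_frac_bound(self):
        with pytest.raises(ValueError, match="censor_frac"):
            SimConfig(censor_frac=1.0)

    def test_negative_screen_effect_rejected(self):
        with pytest.raises(ValueError, match="screen_effect"):
            SimConfig(screen_effect=-1.0)


class TestPlantedSets:
    def test_programs_disjoint(self, small_sim_config):
        plants = planted_sets(small_sim_config)
        fss = set(plants.fss_genes)
        for t, markers in plants.marker_genes.items():
            assert not fss & set(markers)
        assert not fss & set(plants.senescence_genes)
        assert set(plants.overlap_genes) <= fss
        assert set(plants.overlap_genes) <= set(plants.resistant_genes)


class TestScGenerator:
    def test_deterministic(self, small_sim_config, small_sc_data):
        again = generate_sc_datasets(small_sim_config)
        for (ds1, t1), (ds2, t2) in zip(small_sc_data, again):
            np.testing.assert_array_equal(ds1.counts, ds2.counts)
            np.testing.assert_array_equal(t1.latent_senescence, t2.latent_senescence)

    def test_fibroblasts_more_senescent(self, small_sc_data):
        for ds, truth in small_sc_data:
            fibro = (ds.cell_meta["cell_type"] == "fibroblast").to_numpy()
            assert truth.latent_senescence[fibro].mean() > max(
                truth.latent_senescence[ds.cell_meta["cell_type"].to_numpy() == t].mean()
                for t in CELL_TYPES
                if t != "fibroblast" and (ds.cell_meta["cell_type"] == t).any()
            )

    def test_cell_type_frequencies(self, small_sim_config, small_sc_data):
        types = np.concatenate([ds.cell_meta["cell_type"].to_numpy() for ds, _ in small_sc_data])
        n = len(types)
        for t in CELL_TYPES:
            p = small_sim_config.cell_type_props[t]
            se = np.sqrt(p * (1 - p) / n)
            assert abs((types == t).mean() - p) <= 3 * se + 1e-9

    def test_mito_fraction_realistic(self, small_sc_data):
        for ds, truth in small_sc_data:
            normal = ~truth.lowdepth_cells
            assert ds.cell_meta["pct_mito"].to_numpy()[normal].mean() < 5.0

    def test_null_effect_decorrelates_planted_genes(self):
        from fibrosen import lognormalize, qc_filter_cells

        cfg = SimConfig(seed=5, n_datasets=1, fss_effect=0.0)
        ds, truth = generate_sc_datasets(cfg)[0]
        filt = qc_filter_cells(ds)
        norm = lognormalize(filt)
        kept = ds.cell_meta.index.isin(filt.cell_meta.index)
        s_c = truth.latent_senescence[kept]
        fibro = (filt.cell_meta["cell_type"] == "fibroblast").to_numpy()
        gidx = filt.gene_ids.get_indexer(truth.fss_genes)
        rs = [stats.spearmanr(norm[g, fibro], s_c[fibro]).statistic for g in gidx]
        assert np.mean(np.abs(rs)) < 0.1

    def test_planted_correlation_regression_value(self, default_sc_pipeline):
        """Mean within-fibroblast Spearman of planted genes at the defaults."""
        vals = []
        for rec in default_sc_pipeline["records"]:
            fibro = rec["fibro_mask"]
            s_c = rec["s_c"]
            gidx = rec["dataset"].gene_ids.get_indexer(rec["truth"].fss_genes)
            vals += [
                stats.spearmanr(rec["norm"][g, fibro], s_c[fibro]).statistic for g in gidx
            ]
        mean_r = float(np.mean(vals))
        assert mean_r > 0.3
        assert mean_r == pytest.approx(0.336, abs=0.05)

    def test_truth_roundtrip(self, small_sc_data, tmp_path):
        _, truth = small_sc_data[0]
        truth.to_json(tmp_path / "truth.json")
        back = ScTruth.from_json(tmp_path / "truth.json")
        np.testing.assert_array_equal(back.latent_senescence, truth.latent_senescence)
        np.testing.assert_array_equal(back.lowdepth_cells, truth.lowdepth_cells)
        assert back.fss_genes == truth.fss_genes


class TestBulkGenerator:
    def test_deterministic_clinical(self, small_sim_config):
        b1, _ = generate_bulk_cohorts(small_sim_config)
        b2, _ = generate_bulk_cohorts(small_sim_config)
        assert b1.clinical.equals(b2.clinical)
        assert b1.expression.equals(b2.expression)

    def test_hazard_monotone_in_burden(self, small_sim_config):
        _, truth = generate_bulk_cohorts(small_sim_config)
        order = truth.latent_burden.sort_values().index
        hz = truth.hazard.loc[order].to_numpy()
        assert np.all(np.diff(hz) > 0)
        pr = truth.response_prob.loc[order].to_numpy()
        assert np.all(np.diff(pr) < 0)

    def test_censoring_calibrated(self):
        cfg = SimConfig(seed=9, bulk_n_samples=500)
        bulk, _ = generate_bulk_cohorts(cfg)
        censored = 1 - bulk.clinical["os_event"].mean()
        assert censored == pytest.approx(cfg.censor_frac, abs=0.07)

    def test_null_hazard_gives_chance_concordance(self):
        cfg = SimConfig(seed=10, bulk_n_samples=500, hazard_coef=0.0)
        bulk, truth = generate_bulk_cohorts(cfg)
        c = concordance(
            bulk.clinical["os_time"].to_numpy(),
            bulk.clinical["os_event"].to_numpy(),
            truth.latent_burden.to_numpy(),
        )
        assert c == pytest.approx(0.5, abs=0.05)

    def test_true_burden_auc_regression_value(self):
        cfg = SimConfig(seed=12, bulk_n_samples=800)
        bulk, truth = generate_bulk_cohorts(cfg)
        auc = roc_auc(-truth.latent_burden, bulk.clinical["response"])
        assert auc > 0.8
        assert auc == pytest.approx(0.903, abs=0.03)

    def test_tmb_independent_of_burden(self):
        cfg = SimConfig(seed=13, bulk_n_samples=800)
        bulk, truth = generate_bulk_cohorts(cfg)
        r = stats.spearmanr(bulk.clinical["tmb"], truth.latent_burden).statistic
        assert abs(r) < 0.1


class TestScreenGenerator:
    def test_deterministic(self, small_sim_config):
        s1, _ = generate_crispr_screens(small_sim_config)
        s2, _ = generate_crispr_screens(small_sim_config)
        for a, b in zip(s1, s2):
            assert a.logfc.equals(b.logfc)

    def test_null_effect_centers_planted_genes(self):
        from fibrosen import aggregate_rank, zscore_screens

        cfg = SimConfig(seed=3, screen_effect=0.0)
        screens, truth = generate_crispr_screens(cfg)
        ranking = aggregate_rank(zscore_screens(screens))
        planted_z = ranking.table.loc[truth.resistant_genes, "agg_z"]
        assert abs(planted_z.mean()) < 3.0 / np.sqrt(17 * len(truth.resistant_genes)) * 3


def test_write_simulation_roundtrip(tmp_path, small_sim_config):
    from fibrosen.scprep import CellDataset

    write_simulation(small_sim_config, tmp_path)
    first = sorted((tmp_path / "sc").iterdir())[0]
    ds = CellDataset.from_dir(first)
    orig, truth = generate_sc_datasets(small_sim_config)[0]
    np.testing.assert_array_equal(ds.counts, orig.counts)
    back = ScTruth.from_json(first / "truth.json")
    np.testing.assert_array_equal(back.latent_senescence, truth.latent_senescence)
    assert (tmp_path / "bulk" / "expr.tsv").exists()
    assert len(list((tmp_path / "screens").glob("screen*.tsv"))) == small_sim_config.screen_n_datasets
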