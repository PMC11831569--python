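"""End-to-end pipeline: simulate -> QC -> scoring -> signature -> bulk ->
response model -> survival model -> screen ranking -> hub nomination.

Every random stage derives its seed deterministically from the master seed,
so identical configurations produce identical reports.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulkscore, crisprrank, fssbuild, icimodel, mtlrsurv, scprep, senescore
from .genesets import GeneSet, write_gmt
from .synthdata import SimConfig, generate_bulk_cohorts, generate_crispr_screens, generate_sc_datasets

STAGES = ("simulate", "qc", "score_cells", "fss", "bulk", "ici", "mtlr", "crispr")


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    return int((int(master) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclass
class PipelineConfig:
    """All thresholds and stage toggles of the end-to-end analysis."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    min_genes: int = 500
    max_pct_mito: float = 5.0
    min_logfc: float = 0.25
    min_pct: float = 0.1
    min_detect: float = 0.1
    fdr: float = 0.05
    gmean_cutoff: float = 0.25
    min_support_frac: float = 0.25
    top_fraction: float = 0.10
    train_frac: float = 0.8
    cv_folds: int = 10
    cv_repeats: int = 5
    ici_model: str = "gbm"
    n_features: int = 10
    mtlr_c1: float = 1.0
    mtlr_c2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in STAGES:
            self.stages.setdefault(name, True)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        self.sim.seed = derive_seed(self.seed, "simulate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


class StageDependencyError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the enabled stages in order and return the run report."""
    on = config.stages
    report: dict = {"seed": config.seed, "stages": [s for s in STAGES if on[s]]}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if not on["simulate"]:
        raise StageDependencyError("this pipeline runs on simulated inputs; enable 'simulate'")
    sc_data = generate_sc_datasets(config.sim)
    bulk, bulk_truth = generate_bulk_cohorts(config.sim)
    screens, screen_truth = generate_crispr_screens(config.sim)
    senescence_set = GeneSet("senescence", tuple(sc_data[0][1].senescence_genes))
    report["simulate"] = {
        "n_sc_datasets": len(sc_data),
        "n_bulk_samples": len(bulk.sample_ids),
        "n_screens": len(screens),
    }

    # --- single-cell QC, scoring, per-dataset signatures ---
    prepared = []  # (dataset_id, norm, kept_meta, scores, truth)
    if on["qc"] or on["score_cells"] or on["fss"]:
        if not on["qc"]:
            raise StageDependencyError("score_cells/fss require the qc stage")
        qc_counts = []
        for ds, truth in sc_data:
            filtered, log = scprep.qc_filter_cells(
                ds, min_genes=config.min_genes, max_pct_mito=config.max_pct_mito,
                return_log=True,
            )
            qc_counts.append({"dataset_id": truth.dataset_id, "kept": log.n_kept,
                              "dropped": log.n_dropped})
            norm = scprep.lognormalize(filtered)
            prepared.append((truth.dataset_id, filtered, norm, truth))
        report["qc"] = qc_counts

    scored = {}
    if on["score_cells"]:
        for dataset_id, filtered, norm, truth in prepared:
            scores = senescore.score_samples(
                norm, filtered.gene_ids, senescence_set,
                sample_ids=filtered.cell_meta.index,
            )
            scored[dataset_id] = scores
        report["score_cells"] = {"n_datasets": len(scored)}

    signature = None
    if on["fss"]:
        if not scored:
            raise StageDependencyError("fss requires the score_cells stage")
        fsn_list = []
        per_dataset = []
        for dataset_id, filtered, norm, truth in prepared:
            fibro = (filtered.cell_meta["cell_type"] == "fibroblast").to_numpy()
            fsy = scprep.find_cluster_markers(
                norm, filtered.gene_ids, filtered.cell_meta["cell_type"].to_numpy(),
                "fibroblast", min_logfc=config.min_logfc, min_pct=config.min_pct,
            )
            fsx = fssbuild.compute_fsx(
                norm[:, fibro], filtered.gene_ids,
                scored[dataset_id].score.to_numpy()[fibro],
                min_detect=config.min_detect, fdr=config.fdr,
                exclude_genes=senescence_set.genes,
            )
            fsn = fssbuild.compute_fsn(fsx, fsy)
            fsn_list.append(fsn)
            per_dataset.append(
                fssbuild.PerDatasetSignature(dataset_id=dataset_id, fsx=fsx, fsy=fsy, fsn=fsn)
            )
        signature = fssbuild.aggregate_fss(
            fsn_list, cutoff=config.gmean_cutoff, min_support_frac=config.min_support_frac
        )
        report["fss"] = {
            "n_members": len(signature.members),
            "members": signature.members,
        }
        if out is not None and signature.members:
            write_gmt([signature.to_gene_set()], out / "fss.gmt")
            signature.table.to_csv(out / "fss_table.tsv", sep="\t")

    # --- bulk scoring and stratification ---
    fss_scores = None
    std_expr = None
    if on["bulk"] or on["ici"] or on["mtlr"]:
        std_expr = icimodel.batch_standardize(bulk.expression, bulk.clinical["cohort"])
    if on["bulk"]:
        if signature is None or not signature.members:
            raise StageDependencyError("bulk scoring requires a non-empty signature from fss")
        std_cohort = bulkscore.BulkCohort(expression=std_expr, clinical=bulk.clinical)
        fss_scores = bulkscore.score_cohort_fss(std_cohort, signature.to_gene_set())
        cyto_set = GeneSet("cytotoxic", tuple(bulk_truth.cytotoxic_genes))
        imm = bulkscore.immune_scores(std_cohort, [cyto_set])
        assignment = bulkscore.stratify_fss_tmb(fss_scores, bulk.clinical["tmb"])
        group_means = imm["cytotoxic"].groupby(assignment.combined).mean()
        comparisons = bulkscore.compare_subgroups(imm, assignment)
        report["bulk"] = {
            "cytotoxic_group_means": group_means.to_dict(),
            "subgroup_sizes": assignment.combined.value_counts().to_dict(),
        }
        if out is not None:
            fss_scores.to_frame().join(assignment.table).to_csv(
                out / "fss_scores.tsv", sep="\t", index_label="sample_id"
            )
            comparisons.to_csv(out / "subgroup_tests.tsv", sep="\t", index=False)

    # --- ICI response model ---
    if on["ici"]:
        if signature is None or not signature.members:
            raise StageDependencyError("ici stage requires a non-empty signature from fss")
        feats = [g for g in signature.members if g in std_expr.columns]
        seed = derive_seed(config.seed, "ici")
        train_ids, val_ids = icimodel.partition_cohort(
            bulk.sample_ids, labels=bulk.clinical["response"],
            train_frac=config.train_frac, seed=seed,
        )
        model = icimodel.train_response_classifier(
            std_expr.loc[train_ids, feats], bulk.clinical.loc[train_ids, "response"],
            model=config.ici_model, cv=(config.cv_folds, config.cv_repeats), seed=seed,
        )
        val_scores = model.predict_score(std_expr.loc[val_ids])
        auc = icimodel.roc_auc(val_scores, bulk.clinical.loc[val_ids, "response"])
        risk_group = np.where(val_scores > np.median(val_scores), "low-risk", "high-risk")
        km = icimodel.kaplan_meier_logrank(
            bulk.clinical.loc[val_ids, "os_time"],
            bulk.clinical.loc[val_ids, "os_event"],
            risk_group,
        )
        report["ici"] = {
            "n_train": len(train_ids),
            "n_validation": len(val_ids),
            "cv_auc": model.cv_auc,
            "validation_auc": auc,
            "logrank_p": km.p_value,
            "best_params": model.best_params,
        }
        if out is not None:
            val_scores.to_frame().to_csv(out / "predictions.tsv", sep="\t", index_label="sample_id")

    # --- MTLR_DE survival model ---
    prognostic = None
    if on["mtlr"]:
        times = bulk.clinical["os_time"].to_numpy()
        events = bulk.clinical["os_event"].to_numpy()
        prognostic = mtlrsurv.select_de_features(
            std_expr, times, events, n_features=config.n_features
        )
        grid = mtlrsurv.make_time_grid(times, events)
        Xsel = std_expr[prognostic].to_numpy()
        Xsel = (Xsel - Xsel.mean(axis=0)) / np.where(Xsel.std(axis=0) > 0, Xsel.std(axis=0), 1.0)
        params = mtlrsurv.fit_mtlr(
            Xsel, times, events, grid, c1=config.mtlr_c1, c2=config.mtlr_c2
        )
        pred = mtlrsurv.predict_survival(params, Xsel)
        cindex = mtlrsurv.concordance(times, events, pred.risk, method="harrell")
        report["mtlr"] = {
            "features": prognostic,
            "m_intervals": grid.m,
            "harrell_c": cindex,
            "converged": params.converged,
        }
        if out is not None:
            pd.Series(pred.risk, index=bulk.sample_ids, name="risk").to_csv(
                out / "risks.tsv", sep="\t", index_label="sample_id"
            )

    # --- CRISPR ranking and hub intersection ---
    if on["crispr"]:
        normalized = crisprrank.zscore_screens(screens)
        ranking = crisprrank.aggregate_rank(normalized, fraction=config.top_fraction)
        hub_report = {"n_flagged": int(ranking.table["flagged"].sum())}
        if signature is not None and signature.members:
            k, expected, p = crisprrank.enrichment_test(ranking, signature.to_gene_set())
            flagged_sig = [g for g in ranking.flagged if g in set(signature.members)]
            hub_report.update({"signature_overlap": k, "expected": expected, "enrichment_p": p})
            if prognostic is not None:
                hubs = crisprrank.intersect_hub(flagged_sig, prognostic)
                hub_report["hub_genes"] = hubs
        report["crispr"] = hub_report
        if out is not None:
            ranking.table.to_csv(out / "ranking.tsv", sep="\t", index_label="gene")

    if out is not None:
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
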