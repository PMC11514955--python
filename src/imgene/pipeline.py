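"""Stage orchestration: simulate -> genomics -> phenotype -> spatial ->
subtype -> imgene, with per-stage summaries collected into a run report.

Each stage is idempotent given the seed; a stage failure is recorded and
downstream stages are skipped rather than crashing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from imgene import genomics, io, phenotyping, predictor, spatial, subtyping
from imgene.config import PipelineConfig
from imgene.simulate import SimConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Per-stage summaries plus provenance (config hash, seed)."""

    seed: int
    config_hash: str
    stages: dict = field(default_factory=dict)
    failed: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "config_hash": self.config_hash,
             "stages": self.stages, "failed": self.failed},
            indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig | None = None,
                 write_outputs: bool = True) -> tuple[RunReport, dict]:
    """Run the configured stages in order.

    Returns the report plus a dict of in-memory artifacts (tables, models)
    for programmatic use.  With ``write_outputs`` the stage tables are also
    written under ``config.outdir``.
    """
    config = config or PipelineConfig()
    report = RunReport(seed=config.seed, config_hash=_config_hash(config))
    art: dict = {}
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    order = ["simulate", "genomics", "phenotype", "spatial", "subtype", "imgene"]
    halted = False
    for stage in order:
        if stage not in config.stages:
            continue
        if halted:
            report.failed[stage] = "skipped: upstream failure"
            continue
        try:
            _STAGES[stage](config, art, report, outdir if write_outputs else None)
        except Exception as exc:  # stage failure halts downstream stages
            logger.error("stage %s failed: %s", stage, exc)
            report.failed[stage] = f"{type(exc).__name__}: {exc}"
            logger.debug(traceback.format_exc())
            halted = True
    if write_outputs:
        report.to_json(outdir / "run_report.json")
    return report, art


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, art, report, outdir):
    sim = SimConfig(n_patients=config.n_patients,
                    n_pn_positive=config.n_pn_positive,
                    n_mihc_patients=config.n_mihc_patients,
                    cells_per_roi=config.cells_per_roi,
                    seed=config.seed)
    cohort = generate_cohort(sim)
    art["clinical"] = cohort.clinical
    art["mutations"] = cohort.mutations
    art["cells"] = cohort.cells
    art["truth"] = cohort.truth
    if outdir:
        cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
        io.write_mutation_table(cohort.mutations, outdir / "mutations.tsv")
        io.write_cell_table(cohort.cells, outdir / "cells.csv")
        (outdir / "ground_truth.json").write_text(
            json.dumps(cohort.truth, indent=2, default=_jsonable))
    report.stages["simulate"] = {
        "n_patients": len(cohort.clinical),
        "n_mutations": len(cohort.mutations),
        "n_cells": len(cohort.cells),
        "n_rois": cohort.cells["roi_id"].nunique(),
    }


def _load_inputs(config, art):
    if "clinical" not in art:
        art["clinical"] = io.read_clinical_table(config.clinical_table)
    if "mutations" not in art:
        art["mutations"] = io.read_mutation_table(config.mutation_table)
    if "cells" not in art and config.cell_table:
        art["cells"] = io.read_cell_table(config.cell_table)


def _stage_genomics(config, art, report, outdir):
    _load_inputs(config, art)
    clinical, muts = art["clinical"], art["mutations"]
    panel = genomics.PanelConfig()
    groups = clinical.set_index("patient_id")["pn_status"]
    summary = genomics.genomic_summary(muts, panel, patients=list(groups.index))
    freq = genomics.compare_gene_frequencies(
        muts, groups, genes=sorted(set(muts["gene"]) & set(genomics.DEFAULT_PATHWAYS)))
    pathways = genomics.pathway_alteration_frequency(muts, panel, groups)
    actionability = genomics.actionability_summary(
        muts, panel, patients=list(groups.index))
    art.update(panel=panel, genomic_summary=summary, gene_frequency=freq,
               pathway_freq=pathways, actionability=actionability)
    med = summary.join(groups).groupby("pn_status")[["tmb", "math",
                                                     "mutation_count"]].median()
    if outdir:
        summary.to_csv(outdir / "genomic_summary.tsv", sep="\t")
        freq.to_csv(outdir / "gene_frequency.tsv", sep="\t")
        pathways.to_csv(outdir / "pathway_frequency.tsv", sep="\t")
    report.stages["genomics"] = {
        "tmb_median_by_group": med["tmb"].to_dict(),
        "math_median_by_group": med["math"].to_dict(),
        "n_significant_genes": int(freq["significant"].sum()) if len(freq) else 0,
        "pct_actionable_samples": actionability["pct_actionable_samples"],
    }


def _stage_phenotype(config, art, report, outdir):
    _load_inputs(config, art)
    cells = art["cells"]
    rules = phenotyping.GatingRules(threshold=config.gate_threshold)
    labeled, emb = phenotyping.phenotype_cells(
        cells, cofactor=config.cofactor, rules=rules, seed=config.seed)
    art["cells"] = labeled
    art["embedding"] = emb
    groups = art["clinical"].set_index("patient_id")["pn_status"]
    comp = phenotyping.patient_composition(labeled)
    compare = phenotyping.composition_compare(
        labeled, groups.loc[labeled["patient_id"].unique()])
    art["composition"] = comp
    art["composition_tests"] = compare
    if outdir:
        io.write_cell_table(labeled, outdir / "cells_labeled.csv")
        compare.to_csv(outdir / "composition_tests.tsv", sep="\t")
    report.stages["phenotype"] = {
        "n_cells": len(labeled),
        "metacluster_counts": labeled["metacluster"].value_counts().to_dict(),
    }


def _stage_spatial(config, art, report, outdir):
    cells = art["cells"]
    labels = cells["metacluster"]
    graphs = spatial.build_graphs(cells)
    windows = spatial.neighborhood_windows(cells, labels, k=config.knn_k)
    assignment = spatial.cluster_cns(windows, k_cn=config.k_cn, seed=config.seed)
    annotation = spatial.annotate_cns(assignment)
    cn_freq = spatial.cn_frequencies(cells, assignment)
    groups = art["clinical"].set_index("patient_id")["pn_status"]
    analysis = spatial.cn_group_analysis(
        cn_freq, groups, annotation, composition=art.get("composition"),
        muts=art.get("mutations"),
        genes=["TP53", "PIK3CG", "EGFR", "KRAS", "ATM"])
    rois = sorted(graphs)
    if config.max_interaction_rois is not None:
        rng = np.random.default_rng(config.seed)
        rois = sorted(rng.choice(rois, size=min(config.max_interaction_rois,
                                                len(rois)), replace=False))
    inter = spatial.interaction_test(
        cells[cells["roi_id"].isin(rois)], labels,
        {r: g for r, g in graphs.items() if r in rois},
        n_perm=config.n_perm, seed=config.seed)
    cells = cells.copy()
    cells["cn"] = assignment.labels
    art.update(cells=cells, graphs=graphs, cn_assignment=assignment,
               cn_annotation=annotation, cn_freq=cn_freq,
               cn_analysis=analysis, interactions=inter)
    if outdir:
        annotation.to_csv(outdir / "cn_annotation.tsv", sep="\t")
        cn_freq.to_csv(outdir / "cn_frequencies.tsv", sep="\t")
        inter.table.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
        roi0 = cells["roi_id"].iloc[0]
        sub = cells[cells["roi_id"] == roi0]
        size = float(np.ceil(max(sub["x_um"].max(), sub["y_um"].max())))
        spatial.plot_voronoi(sub[["x_um", "y_um"]].to_numpy(),
                             sub["cn"].to_numpy(), (0, 0, size, size),
                             path=outdir / "voronoi_example.svg")
    report.stages["spatial"] = {
        "n_cns": assignment.k,
        "functional_groups": annotation["functional_group"].value_counts().to_dict(),
        "n_interacting_pairs": int((inter.table["direction"] == "interaction").sum())
        if len(inter.table) else 0,
    }


def _stage_subtype(config, art, report, outdir):
    cells = art["cells"]
    comp = subtyping.roi_composition(cells)
    result = subtyping.cnmf(comp, rank=config.rank,
                            iterations=config.cnmf_iterations, seed=config.seed)
    roi_to_patient = cells.drop_duplicates("roi_id").set_index("roi_id")["patient_id"]
    patient_labels = subtyping.integrate_roi_labels(result, roi_to_patient)
    groups = art["clinical"].set_index("patient_id")["pn_status"]
    assoc = subtyping.subtype_associations(
        patient_labels, groups, composition=art.get("composition"),
        muts=art.get("mutations"),
        genes=["TP53", "PIK3CG", "ATM", "BRD4", "KMT2B", "CTNNB1"])
    art.update(subtype_result=result, patient_subtypes=patient_labels,
               subtype_assoc=assoc)
    if outdir:
        pd.DataFrame(result.consensus, index=comp.index,
                     columns=comp.index).to_csv(outdir / "consensus.tsv", sep="\t")
        patient_labels.to_csv(outdir / "patient_subtypes.tsv", sep="\t")
    report.stages["subtype"] = {
        "silhouette": result.silhouette,
        "subtype_sizes": patient_labels.value_counts().to_dict(),
        "pn_association_p": assoc["pn_test"].p_value if assoc["pn_test"] else None,
    }


def _stage_imgene(config, art, report, outdir):
    genes = sorted(set(art["mutations"]["gene"]) & set(genomics.DEFAULT_PATHWAYS))
    im, gene = predictor.build_feature_blocks(
        art["composition"], art.get("cn_freq"), art["mutations"],
        art["genomic_summary"], genes)
    labels = art["clinical"].set_index("patient_id")["pn_status"]
    model, reports = predictor.train_imgene(
        im, gene, labels, seed=config.seed, val_fraction=config.val_fraction,
        k_features=config.k_features)
    art["imgene_model"] = model
    art["imgene_reports"] = reports
    if outdir:
        card = {
            "im_block": {"features": model.im_block.features,
                         "C": model.im_block.C, "kernel": model.im_block.kernel,
                         "gamma": model.im_block.gamma,
                         "loocv_accuracy": model.im_block.loocv_accuracy,
                         "cutoff": model.im_block.cutoff},
            "gene_block": {"features": model.gene_block.features,
                           "C": model.gene_block.C,
                           "kernel": model.gene_block.kernel,
                           "gamma": model.gene_block.gamma,
                           "loocv_accuracy": model.gene_block.loocv_accuracy,
                           "cutoff": model.gene_block.cutoff},
            "integration": {"intercept": model.intercept,
                            "beta_im": model.beta_im,
                            "beta_gene": model.beta_gene,
                            "cutoff": model.cutoff},
            "evaluation": {k: asdict(v) for k, v in reports.items()},
        }
        (outdir / "imgene_model.json").write_text(
            json.dumps(card, indent=2, default=_jsonable))
    report.stages["imgene"] = {
        k: {"auc": v.auc, "f1": v.f1, "accuracy": v.accuracy}
        for k, v in reports.items()
    }


_STAGES = {
    "simulate": _stage_simulate,
    "genomics": _stage_genomics,
    "phenotype": _stage_phenotype,
    "spatial": _stage_spatial,
    "subtype": _stage_subtype,
    "imgene": _stage_imgene,
}
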