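"""Panel-NGS summary statistics and nodal-status association analyses.

Covers per-patient alteration counts, tumor mutational burden (TMB,
nonsynonymous small variants per sequenced megabase), the MATH intratumor
heterogeneity score (scaled dispersion of the VAF distribution),
group-wise gene frequency comparisons with FDR control, pairwise
co-occurrence / mutual-exclusivity tests, oncogenic-pathway aggregation,
therapeutic-actionability tallies, and caliper-based propensity matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from imgene import stats
from imgene.stats import FdrResult, InputError, TestResult

logger = logging.getLogger(__name__)

ALTERATION_CLASSES = {"nonsynonymous_snv", "indel", "cnv", "fusion"}
ONCOGENIC_FLAGS = {"oncogenic", "likely", "predicted", "vus"}
#: therapeutic-evidence tiers, strongest first
ACTIONABILITY_LEVELS = ["L1", "L3A", "L3B", "L4"]

#: static OncoKB-style evidence-level table (editable via PanelConfig)
DEFAULT_ACTIONABILITY: dict[str, str] = {
    "EGFR": "L1", "ALK": "L1", "ROS1": "L1", "RET": "L1", "BRAF": "L1",
    "MET": "L1", "KRAS": "L1", "ERBB2": "L3A", "PIK3CA": "L3B",
    "NF1": "L3B", "FGFR1": "L3B", "FGFR2": "L3B", "FGFR3": "L3B",
    "ATM": "L4", "PTEN": "L4", "CDKN2A": "L4", "MDM2": "L4", "CDK4": "L4",
}

#: gene -> oncogenic signaling pathway map (one pathway per gene)
DEFAULT_PATHWAYS: dict[str, str] = {
    "EGFR": "RTK/RAS", "KRAS": "RTK/RAS", "BRAF": "RTK/RAS", "NF1": "RTK/RAS",
    "HGF": "RTK/RAS", "MET": "RTK/RAS", "ALK": "RTK/RAS", "RET": "RTK/RAS",
    "ROS1": "RTK/RAS", "ERBB2": "RTK/RAS", "ERBB4": "RTK/RAS",
    "FGFR1": "RTK/RAS", "FGFR2": "RTK/RAS", "FGFR3": "RTK/RAS",
    "NTRK3": "RTK/RAS",
    "PIK3CA": "PI3K", "PIK3CG": "PI3K", "PTEN": "PI3K", "STK11": "PI3K",
    "AKT1": "PI3K", "MTOR": "PI3K", "TSC1": "PI3K", "TSC2": "PI3K",
    "TP53": "p53", "ATM": "p53", "MDM2": "p53", "CHEK2": "p53",
    "KEAP1": "NRF2", "NFE2L2": "NRF2", "CUL3": "NRF2",
    "CTNNB1": "Wnt", "APC": "Wnt",
    "RB1": "Cell cycle", "CDKN2A": "Cell cycle", "CCND1": "Cell cycle",
    "CDK4": "Cell cycle",
    "ARID1A": "Epigenetic", "SETD2": "Epigenetic", "KMT2B": "Epigenetic",
    "KMT2D": "Epigenetic", "BRD4": "Epigenetic", "SMARCA4": "Epigenetic",
    "RBM10": "RNA splicing", "SF3B1": "RNA splicing",
}


@dataclass
class PanelConfig:
    """Targeted-panel metadata: coverage, pathway map, evidence levels."""

    name: str = "HR457"
    covered_mb: float = 1.21
    pathways: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PATHWAYS))
    actionability: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ACTIONABILITY))

    def __post_init__(self) -> None:
        if self.covered_mb <= 0:
            raise InputError("covered megabases must be positive")


# ---------------------------------------------------------------------------
# per-patient summaries
# ---------------------------------------------------------------------------

def compute_tmb(muts: pd.DataFrame, panel: PanelConfig, patient: str) -> float:
    """Nonsynonymous small-variant count / covered Mb for one patient.

    CNVs and fusions contribute to the alteration count but not to TMB.
    """
    if patient not in set(muts["patient_id"]):
        raise InputError(f"unknown patient {patient!r}")
    sub = muts[(muts["patient_id"] == patient)
               & muts["alteration_class"].isin(["nonsynonymous_snv", "indel"])]
    return float(len(sub) / panel.covered_mb)


def compute_math(vafs) -> float | None:
    """MATH score: 100 * 1.4826 * MAD(VAF) / median(VAF).

    Returns ``None`` (flagged absent) for fewer than 3 VAFs or a
    non-positive median.  Invariant to rescaling of the VAF vector.
    """
    v = np.asarray(pd.Series(vafs).dropna(), dtype=float)
    if v.size < 3:
        return None
    med = float(np.median(v))
    if med <= 0:
        return None
    mad = float(np.median(np.abs(v - med)))
    return 100.0 * 1.4826 * mad / med


def genomic_summary(muts: pd.DataFrame, panel: PanelConfig,
                    patients: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-patient alteration count, TMB and MATH.

    ``patients`` lets zero-alteration patients appear with count 0.
    """
    if patients is None:
        patients = sorted(muts["patient_id"].unique())
    rows = []
    grouped = dict(tuple(muts.groupby("patient_id")))
    for pid in patients:
        sub = grouped.get(pid, muts.iloc[0:0])
        small = sub[sub["alteration_class"].isin(["nonsynonymous_snv", "indel"])]
        rows.append({
            "patient_id": pid,
            "mutation_count": int(len(sub)),
            "tmb": float(len(small) / panel.covered_mb),
            "math": compute_math(small["vaf"]),
        })
    return pd.DataFrame(rows).set_index("patient_id")


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _mutated_matrix(muts: pd.DataFrame, patients: Sequence[str],
                    genes: Sequence[str]) -> pd.DataFrame:
    m = (muts[muts["gene"].isin(genes)]
         .assign(val=1)
         .pivot_table(index="patient_id", columns="gene", values="val",
                      aggfunc="max", fill_value=0))
    return m.reindex(index=patients, columns=genes, fill_value=0).astype(int)


def compare_gene_frequencies(muts: pd.DataFrame, groups: pd.Series,
                             genes: Sequence[str] | None = None,
                             fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Per-gene 2x2 Fisher test of mutation frequency across two groups.

    ``groups`` maps patient_id -> binary group label.  Genes absent in all
    patients are skipped with a log entry.  Benjamini-Hochberg q-values are
    appended in gene order.
    """
    groups = pd.Series(groups)
    patients = list(groups.index)
    if genes is None:
        genes = sorted(muts["gene"].unique())
    mat = _mutated_matrix(muts, patients, genes)
    gvals = sorted(groups.unique())
    if len(gvals) != 2:
        raise InputError("compare_gene_frequencies requires exactly two groups")
    rows = []
    for gene in genes:
        col = mat[gene]
        if col.sum() == 0:
            logger.info("gene %s absent in all patients; skipped", gene)
            continue
        a = int(col[groups == gvals[1]].sum()); na = int((groups == gvals[1]).sum())
        b = int(col[groups == gvals[0]].sum()); nb = int((groups == gvals[0]).sum())
        res = stats.fisher_exact([[a, na - a], [b, nb - b]])
        rows.append({"gene": gene,
                     f"freq_{gvals[0]}": b / nb, f"freq_{gvals[1]}": a / na,
                     "odds_ratio": res.estimate, "p_value": res.p_value})
    out = pd.DataFrame(rows).set_index("gene")
    if len(out):
        fdr: FdrResult = stats.bh_fdr(out["p_value"].to_numpy(), fdr_threshold)
        out["q_value"] = fdr.q_values
        out["significant"] = fdr.rejected()
    return out


def cooccurrence_analysis(muts: pd.DataFrame, patients: Sequence[str],
                          genes: Sequence[str]) -> pd.DataFrame:
    """Pairwise co-occurrence (+) / mutual exclusivity (-) of mutations.

    Per gene pair: 2x2 Fisher on mutated/wild-type patient counts; the sign
    of the log odds ratio labels the direction.  Monomorphic genes are
    skipped.
    """
    if len(genes) < 2:
        raise InputError("need at least two genes")
    mat = _mutated_matrix(muts, patients, genes)
    keep = [g for g in genes if 0 < mat[g].sum() < len(patients)]
    rows = []
    for i, g1 in enumerate(keep):
        for g2 in keep[i + 1:]:
            a = int(((mat[g1] == 1) & (mat[g2] == 1)).sum())
            b = int(((mat[g1] == 1) & (mat[g2] == 0)).sum())
            c = int(((mat[g1] == 0) & (mat[g2] == 1)).sum())
            d = int(((mat[g1] == 0) & (mat[g2] == 0)).sum())
            res = stats.fisher_exact([[a, b], [c, d]])
            with np.errstate(divide="ignore"):
                lor = float(np.log(res.estimate)) if res.estimate is not None else np.nan
            rows.append({"gene_a": g1, "gene_b": g2, "log_odds": lor,
                         "odds_ratio": res.estimate, "p_value": res.p_value,
                         "direction": ("co-occurrence" if lor > 0
                                       else "exclusivity" if lor < 0 else "none")})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = stats.bh_fdr(out["p_value"].to_numpy()).q_values
    return out


def pathway_alteration_frequency(muts: pd.DataFrame, panel: PanelConfig,
                                 groups: pd.Series,
                                 oncogenic_only: bool = True) -> pd.DataFrame:
    """Per-pathway alteration frequency by group, with Fisher tests + FDR.

    A patient is pathway-altered if it carries >= 1 retained alteration in
    any mapped pathway gene; with ``oncogenic_only`` variants of unknown
    significance are discarded first.  Unmapped genes are tallied under
    ``"unmapped"`` (logged).
    """
    groups = pd.Series(groups)
    sub = muts[muts["oncogenic"] != "vus"] if oncogenic_only else muts
    pw = sub["gene"].map(lambda g: panel.pathways.get(g, "unmapped"))
    n_unmapped = int((pw == "unmapped").sum())
    if n_unmapped:
        logger.info("%d alterations in genes missing from the pathway map", n_unmapped)
    sub = sub.assign(pathway=pw.values)
    gvals = sorted(groups.unique())
    if len(gvals) != 2:
        raise InputError("pathway comparison requires exactly two groups")
    rows = []
    for pathway, block in sub.groupby("pathway"):
        altered = set(block["patient_id"])
        flags = groups.index.to_series().isin(altered).astype(int)
        a = int(flags[groups == gvals[1]].sum()); na = int((groups == gvals[1]).sum())
        b = int(flags[groups == gvals[0]].sum()); nb = int((groups == gvals[0]).sum())
        res = stats.fisher_exact([[a, na - a], [b, nb - b]])
        rows.append({"pathway": pathway,
                     f"freq_{gvals[0]}": b / nb, f"freq_{gvals[1]}": a / na,
                     "p_value": res.p_value})
    out = pd.DataFrame(rows).set_index("pathway")
    if len(out):
        out["q_value"] = stats.bh_fdr(out["p_value"].to_numpy()).q_values
    return out


# ---------------------------------------------------------------------------
# actionability
# ---------------------------------------------------------------------------

def actionability_summary(muts: pd.DataFrame, panel: PanelConfig,
                          patients: Sequence[str] | None = None) -> dict:
    """Tally actionable alterations by evidence level, pathway, and sample.

    A sample is classified by its single highest-evidence alteration
    (L1 > L3A > L3B > L4).  Returns counts plus the derived percentages.
    """
    bad = set(muts["level"].dropna()) - set(ACTIONABILITY_LEVELS) - {"none"}
    if bad:
        raise InputError(f"unknown actionability levels: {sorted(bad)}")
    if patients is None:
        patients = sorted(muts["patient_id"].unique())
    actionable = muts[muts["level"].isin(ACTIONABILITY_LEVELS)].copy()
    by_level = {lvl: int((actionable["level"] == lvl).sum())
                for lvl in ACTIONABILITY_LEVELS}
    total = int(len(actionable))

    actionable["pathway"] = actionable["gene"].map(
        lambda g: panel.pathways.get(g, "unmapped"))
    by_pathway = actionable.groupby("pathway").size().to_dict()

    rank = {lvl: i for i, lvl in enumerate(ACTIONABILITY_LEVELS)}
    best = (actionable.assign(rank=actionable["level"].map(rank))
            .groupby("patient_id")["rank"].min())
    sample_level = {pid: ACTIONABILITY_LEVELS[r] for pid, r in best.items()}
    samples_by_level = {lvl: sum(1 for v in sample_level.values() if v == lvl)
                        for lvl in ACTIONABILITY_LEVELS}
    n_actionable_samples = len(sample_level)
    n_samples = len(patients)
    return {
        "alterations_by_level": by_level,
        "total_actionable_alterations": total,
        "alterations_by_pathway": by_pathway,
        "sample_highest_level": sample_level,
        "samples_by_level": samples_by_level,
        "n_actionable_samples": n_actionable_samples,
        "n_samples": n_samples,
        "pct_level1_alterations": 100.0 * by_level["L1"] / total if total else np.nan,
        "pct_actionable_samples": 100.0 * n_actionable_samples / n_samples,
        "pct_level1_samples": (100.0 * samples_by_level["L1"] / n_actionable_samples
                               if n_actionable_samples else np.nan),
    }


# ---------------------------------------------------------------------------
# propensity matching
# ---------------------------------------------------------------------------

def standardized_mean_difference(x_case, x_control) -> float:
    a = np.asarray(x_case, dtype=float)
    b = np.asarray(x_control, dtype=float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def propensity_match(table: pd.DataFrame, case_col: str,
                     covariates: Sequence[str], caliper: float = 0.2,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbour matching on the logit propensity score.

    The propensity is a logistic regression of case status on the listed
    covariates; controls are matched without replacement within a caliper
    of ``caliper`` standard deviations of the logit score.  Case order is
    randomized (tie-breaking is otherwise arbitrary); unmatched cases are
    reported with NaN controls.
    """
    if table[covariates].isna().any().any():
        raise InputError("covariates must be complete for all subjects")
    rng = rng if rng is not None else np.random.default_rng(0)
    model = stats.fit_logistic(table[case_col].to_numpy(), table[covariates])
    pr = stats.score_logistic(model, table[covariates])
    logit = np.log(pr / (1 - pr))
    width = caliper * float(np.std(logit, ddof=1))

    ids = table["patient_id"].to_numpy()
    is_case = table[case_col].to_numpy().astype(bool)
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = list(np.flatnonzero(~is_case))
    order = rng.permutation(len(case_idx))
    rows = []
    for ci in case_idx[order]:
        if not ctrl_idx:
            rows.append({"case_id": ids[ci], "control_id": np.nan,
                         "distance": np.nan})
            continue
        d = np.abs(logit[ctrl_idx] - logit[ci])
        j = int(np.argmin(d))
        if d[j] <= width:
            rows.append({"case_id": ids[ci], "control_id": ids[ctrl_idx[j]],
                         "distance": float(d[j])})
            ctrl_idx.pop(j)
        else:
            rows.append({"case_id": ids[ci], "control_id": np.nan,
                         "distance": np.nan})
    out = pd.DataFrame(rows, columns=["case_id", "control_id", "distance"])
    matched = out.dropna(subset=["control_id"])
    if matched.empty:
        logger.warning("no controls within caliper for any case")
    return pd.concat([matched, out[out["control_id"].isna()]], ignore_index=True)
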