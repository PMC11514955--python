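"""Synthetic cohort generator.

Emits the three linked tables the analysis consumes — clinical covariates,
per-patient panel mutation records, and per-cell spatial mIHC records —
with the group-level structure the study design assumes: a 257-patient
cohort (204 pN-negative, 53 pN-positive), a propensity-matched 92-patient
mIHC subset imaged over ~6.5 regions of interest (ROIs) each, group-specific
driver-gene mutation frequencies (e.g. TP53 55% vs 37%, PIK3CG 7.5% vs
0.5%), mutation-count/TMB and VAF-dispersion (MATH) shifts, and spatial
enrichment of macrophage and Treg metaclusters near epithelial nests in
node-positive tissue.

Everything is drawn from a single :class:`numpy.random.Generator` seeded
once, so a configuration plus seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from imgene.phenotyping import MARKERS, METACLUSTERS
from imgene.stats import InputError


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


# ---------------------------------------------------------------------------
# planted parameters
# ---------------------------------------------------------------------------

#: per-gene alteration frequency (pN-negative, pN-positive)
DRIVER_GENE_FREQS: dict[str, tuple[float, float]] = {
    "EGFR": (0.66, 0.66),
    "TP53": (0.37, 0.55),
    "KRAS": (0.12, 0.12),
    "RBM10": (0.08, 0.08),
    "PIK3CA": (0.04, 0.08),
    "ATM": (0.03, 0.12),
    "PIK3CG": (0.005, 0.075),
    "RB1": (0.06, 0.06),
    "STK11": (0.03, 0.03),
    "SETD2": (0.05, 0.05),
    "SF3B1": (0.03, 0.03),
    "PTEN": (0.04, 0.04),
    "HGF": (0.04, 0.04),
    "BRAF": (0.04, 0.08),
    "ARID1A": (0.05, 0.05),
    "KEAP1": (0.02, 0.02),
    "CTNNB1": (0.06, 0.03),
    "KMT2B": (0.02, 0.06),
    "BRD4": (0.02, 0.06),
    "NF1": (0.01, 0.01),
}

#: passenger symbols used to pad nonsynonymous counts up to the group totals
PASSENGER_GENES = [
    "LRP1B", "FAT1", "NOTCH1", "KMT2D", "ZFHX3", "SPTA1", "GRIN2A", "EPHA5",
    "TRRAP", "PREX2", "ERBB4", "NTRK3", "ROS1", "ALK", "MET", "FGFR1",
    "FGFR2", "FGFR3", "SMAD4", "APC", "MTOR", "AKT1", "NFE2L2", "CUL3",
    "CDKN2A", "CCND1", "CDK4", "MDM2", "ERBB2", "RET", "SMARCA4", "POLE",
    "MSH2", "MLH1", "BRCA1", "BRCA2", "CHEK2", "PALB2", "TSC1", "TSC2",
]

CNV_GENES = ["EGFR", "MET", "CDK4", "MDM2", "ERBB2"]
FUSION_GENES = ["ALK", "RET", "ROS1"]

#: metacluster composition targets per group (fractions of total cells);
#: immune infiltrate totals 31.1% (pN-) and 36.5% (pN+), with macrophage
#: 4.8% vs 7.1% and Treg 0.29% vs 0.85%.
COMPOSITION_TARGETS: dict[str, dict[str, float]] = {
    "pN-": {
        "Epithelial": 0.580, "PDL1pos_Epithelial": 0.039,
        "CD4_T": 0.070, "CD8_T": 0.070, "Treg": 0.0029,
        "Macrophage": 0.048, "PDL1pos_Macrophage": 0.020,
        "Other_Immune": 0.1001, "Other": 0.070,
    },
    "pN+": {
        "Epithelial": 0.530, "PDL1pos_Epithelial": 0.035,
        "CD4_T": 0.070, "CD8_T": 0.070, "Treg": 0.0085,
        "Macrophage": 0.071, "PDL1pos_Macrophage": 0.025,
        "Other_Immune": 0.1205, "Other": 0.070,
    },
}

#: raw marker intensity means per metacluster (rows) x marker (columns);
#: positives sit at 20 (secondary markers 15), negatives at 0.05 so that
#: asinh + z-scoring separates the modes cleanly.
MARKER_SIGNATURES: dict[str, list[float]] = {
    #               panck  cd4   cd8  foxp3  cd68  pdl1
    "Epithelial":          [20.0, 0.05, 0.05, 0.05, 0.05, 0.05],
    "PDL1pos_Epithelial":  [20.0, 0.05, 0.05, 0.05, 0.05, 15.0],
    "CD4_T":               [0.05, 20.0, 0.05, 0.05, 0.05, 0.05],
    "CD8_T":               [0.05, 0.05, 20.0, 0.05, 0.05, 0.05],
    "Treg":                [0.05, 20.0, 0.05, 15.0, 0.05, 0.05],
    "Macrophage":          [0.05, 0.05, 0.05, 0.05, 20.0, 0.05],
    "PDL1pos_Macrophage":  [0.05, 0.05, 0.05, 0.05, 20.0, 15.0],
    "Other_Immune":        [0.05, 0.05, 0.05, 0.05, 0.05, 15.0],
    "Other":               [0.05, 0.05, 0.05, 0.05, 0.05, 0.05],
}

#: Table-style clinical covariate rates per group
CLINICAL_RATES = {
    "pN-": {"male": 0.456, "smoking": 0.284, "solid": 0.529, "stas": 0.113,
            "vpi": 0.172, "lvi": 0.255, "mip_sol": 0.147,
            "age_mean": 61.0, "size_median": 2.3},
    "pN+": {"male": 0.434, "smoking": 0.283, "solid": 0.906, "stas": 0.170,
            "vpi": 0.566, "lvi": 0.717, "mip_sol": 0.547,
            "age_mean": 63.0, "size_median": 2.9},
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Group-specific frequencies and endpoint medians mirror the published
    cohort; purely generative quantities (cells per ROI, ROI size, Beta /
    log-normal parameters) are declared defaults chosen for desk-scale runs.
    """

    n_patients: int = 257
    n_pn_positive: int = 53
    n_mihc_patients: int = 92
    rois_per_patient: tuple[int, int] = (5, 8)   # inclusive uniform range, ~6.5 mean
    cells_per_roi: float = 250.0                 # Poisson mean
    roi_size_um: float = 400.0
    panel_mb: float = 1.21
    #: group TMB medians (mutations/Mb) scaling the Poisson mutation counts
    tmb_medians: tuple[float, float] = (3.16, 4.74)
    gene_freqs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DRIVER_GENE_FREQS))
    #: weight of the subclonal Beta(2,12) VAF component per group; the
    #: clonal component is Beta(10,15).  Calibrated so MATH medians land
    #: near 45.7 (pN-) and 53.5 (pN+).
    subclonal_weight: tuple[float, float] = (0.40, 0.43)
    metacluster_fracs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in COMPOSITION_TARGETS.items()})
    composition_concentration: float = 500.0     # Dirichlet patient-level variation
    n_batches: int = 4
    batch_sigma: float = 0.15                    # log-sd of multiplicative shifts
    marker_noise_sigma: float = 0.30             # log-normal intensity noise
    n_epithelial_nests: float = 3.0              # Poisson mean (+1) of nest parents
    nest_sd_um: float = 40.0
    macrophage_contact_prob: tuple[float, float] = (0.25, 0.60)  # (pN-, pN+)
    macrophage_contact_sd_um: float = 25.0
    treg_niche_prob: float = 0.70
    treg_niche_sd_um: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pn_positive > self.n_patients:
            raise ConfigError("n_pn_positive exceeds n_patients")
        if self.n_mihc_patients > self.n_patients:
            raise ConfigError("n_mihc_patients exceeds n_patients")
        if self.roi_size_um <= 0 or self.cells_per_roi <= 0:
            raise ConfigError("ROI dimensions and cell density must be positive")
        for g, comp in self.metacluster_fracs.items():
            vals = np.array([comp[m] for m in METACLUSTERS])
            if np.any(vals < 0) or np.any(vals > 1):
                raise ConfigError(f"composition for {g} outside [0,1]")
            if abs(vals.sum() - 1.0) > 1e-6:
                raise ConfigError(f"composition for {g} does not sum to 1")
        for gene, (f0, f1) in self.gene_freqs.items():
            if not (0 <= f0 <= 1 and 0 <= f1 <= 1):
                raise ConfigError(f"frequency for {gene} outside [0,1]")

    def null(self) -> "SimConfig":
        """A copy with all group differences removed (type-I calibration)."""
        pooled_freqs = {g: ((f0 + f1) / 2,) * 2 for g, (f0, f1) in self.gene_freqs.items()}
        comp = dict(self.metacluster_fracs["pN-"])
        tmb = (sum(self.tmb_medians) / 2,) * 2
        return replace(self, gene_freqs=pooled_freqs,
                       metacluster_fracs={"pN-": comp, "pN+": dict(comp)},
                       tmb_medians=tmb,
                       subclonal_weight=(self.subclonal_weight[0],) * 2,
                       macrophage_contact_prob=(self.macrophage_contact_prob[0],) * 2)


@dataclass
class SyntheticCohort:
    """Clinical, mutation and cell tables plus the planted ground truth."""

    clinical: pd.DataFrame
    mutations: pd.DataFrame
    cells: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

def _generate_clinical(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n, npos = config.n_patients, config.n_pn_positive
    pn = np.zeros(n, dtype=int)
    pn[rng.choice(n, size=npos, replace=False)] = 1
    rows = []
    for i in range(n):
        grp = "pN+" if pn[i] else "pN-"
        r = CLINICAL_RATES[grp]
        rows.append({
            "patient_id": f"P{i + 1:03d}",
            "pn_status": int(pn[i]),
            "age": float(np.round(rng.normal(r["age_mean"], 9.0))),
            "sex_male": int(rng.random() < r["male"]),
            "smoking": int(rng.random() < r["smoking"]),
            "nodule_solid": int(rng.random() < r["solid"]),
            "tumor_size_cm": float(np.round(
                r["size_median"] * np.exp(rng.normal(0.0, 0.35)), 1)),
            "histology_mip_sol": int(rng.random() < r["mip_sol"]),
            "path_stas": int(rng.random() < r["stas"]),
            "path_vpi": int(rng.random() < r["vpi"]),
            "path_lvi": int(rng.random() < r["lvi"]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def _draw_vafs(n: int, group_idx: int, config: SimConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Clonal/subclonal Beta mixture, sampled balanced within a patient.

    Each patient receives its expected share of subclonal variants (the
    fractional remainder randomized) rather than iid component draws; with
    only a handful of variants per tumor, iid draws make per-patient MATH
    strongly bimodal and the cohort median unstable.
    """
    w = config.subclonal_weight[group_idx]
    n_sub = int(w * n)
    if rng.random() < (w * n - n_sub):
        n_sub += 1
    sub = np.zeros(n, dtype=bool)
    sub[rng.choice(n, size=min(n_sub, n), replace=False)] = True
    v = np.where(sub, rng.beta(2.0, 12.0, n), rng.beta(10.0, 15.0, n))
    return np.clip(v, 0.01, 1.0)


def _generate_mutations(config: SimConfig, clinical: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    from imgene.genomics import DEFAULT_ACTIONABILITY  # static level table

    records = []
    lam = (config.tmb_medians[0] * config.panel_mb,
           config.tmb_medians[1] * config.panel_mb)
    mean_driver = (sum(f[0] for f in config.gene_freqs.values()),
                   sum(f[1] for f in config.gene_freqs.values()))
    for _, row in clinical.iterrows():
        g = int(row["pn_status"])
        pid = row["patient_id"]
        mutated = [gene for gene, fr in config.gene_freqs.items()
                   if rng.random() < fr[g]]
        n_extra = rng.poisson(max(0.0, lam[g] - mean_driver[g]))
        extra = list(rng.choice(PASSENGER_GENES,
                                size=min(n_extra, len(PASSENGER_GENES)),
                                replace=False))
        small_variants = mutated + extra
        vafs = _draw_vafs(len(small_variants), g, config, rng)
        for gene, vaf in zip(small_variants, vafs):
            is_driver = gene in config.gene_freqs
            klass = "indel" if rng.random() < 0.15 else "nonsynonymous_snv"
            if is_driver:
                onc = rng.choice(["oncogenic", "likely", "predicted"],
                                 p=[0.7, 0.2, 0.1])
            else:
                onc = rng.choice(["vus", "predicted"], p=[0.85, 0.15])
            level = DEFAULT_ACTIONABILITY.get(gene, "none") if onc != "vus" else "none"
            records.append({"patient_id": pid, "gene": gene,
                            "alteration_class": klass, "vaf": float(vaf),
                            "oncogenic": onc, "level": level})
        if rng.random() < 0.12:
            gene = str(rng.choice(CNV_GENES))
            records.append({"patient_id": pid, "gene": gene,
                            "alteration_class": "cnv", "vaf": np.nan,
                            "oncogenic": "oncogenic",
                            "level": DEFAULT_ACTIONABILITY.get(gene, "none")})
        if rng.random() < 0.04:
            gene = str(rng.choice(FUSION_GENES))
            records.append({"patient_id": pid, "gene": gene,
                            "alteration_class": "fusion", "vaf": np.nan,
                            "oncogenic": "oncogenic",
                            "level": DEFAULT_ACTIONABILITY.get(gene, "none")})
    return pd.DataFrame(records, columns=["patient_id", "gene",
                                          "alteration_class", "vaf",
                                          "oncogenic", "level"])


# ---------------------------------------------------------------------------
# spatial cells
# ---------------------------------------------------------------------------

def _place_uniform(n: int, size: float, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.0, size, size=(n, 2))


def _place_near(centers: np.ndarray, n: int, sd: float, size: float,
                rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, len(centers), size=n)
    pts = centers[idx] + rng.normal(0.0, sd, size=(n, 2))
    return np.clip(pts, 0.0, size)


def generate_roi(config: SimConfig, group: str, roi_id: str,
                 rng: np.random.Generator | None = None,
                 composition: Mapping[str, float] | None = None,
                 batch_multipliers: np.ndarray | None = None,
                 patient_id: str = "SIM", batch_id: str = "B1") -> pd.DataFrame:
    """Generate one ROI's cell table fragment.

    Epithelial cells form Thomas-type nests; macrophages are placed within
    a contact distance of nest centers with a group-dependent probability
    (stronger in pN+ tissue); Tregs aggregate into niches; remaining cells
    are uniform.  Marker intensities are log-normal around the metacluster
    signature, scaled by per-batch multipliers.
    """
    if group not in ("pN-", "pN+"):
        raise ConfigError(f"unknown group {group!r}")
    if config.roi_size_um <= 0:
        raise ConfigError("non-positive ROI dimension")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    comp = composition if composition is not None else config.metacluster_fracs[group]
    p = np.array([comp[m] for m in METACLUSTERS], dtype=float)
    p = p / p.sum()
    size = config.roi_size_um
    gidx = 1 if group == "pN+" else 0

    n_cells = max(int(rng.poisson(config.cells_per_roi)), 1)
    counts = rng.multinomial(n_cells, p)
    nests = _place_uniform(1 + rng.poisson(config.n_epithelial_nests), size, rng)
    niches = _place_uniform(1 + rng.poisson(1.0), size, rng)

    xs, ys, mcs = [], [], []
    for mc, cnt in zip(METACLUSTERS, counts):
        if cnt == 0:
            continue
        if mc in ("Epithelial", "PDL1pos_Epithelial"):
            pts = _place_near(nests, cnt, config.nest_sd_um, size, rng)
        elif mc in ("Macrophage", "PDL1pos_Macrophage"):
            near = rng.random(cnt) < config.macrophage_contact_prob[gidx]
            pts = _place_uniform(cnt, size, rng)
            if near.any():
                pts[near] = _place_near(nests, int(near.sum()),
                                        config.macrophage_contact_sd_um, size, rng)
        elif mc == "Treg":
            near = rng.random(cnt) < config.treg_niche_prob
            pts = _place_uniform(cnt, size, rng)
            if near.any():
                pts[near] = _place_near(niches, int(near.sum()),
                                        config.treg_niche_sd_um, size, rng)
        else:
            pts = _place_uniform(cnt, size, rng)
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        mcs.extend([mc] * cnt)

    x = np.concatenate(xs); y = np.concatenate(ys)
    sig = np.array([MARKER_SIGNATURES[m] for m in mcs])
    noise = np.exp(rng.normal(0.0, config.marker_noise_sigma, size=sig.shape))
    mult = batch_multipliers if batch_multipliers is not None else np.ones(len(MARKERS))
    intensities = sig * noise * mult[None, :]

    df = pd.DataFrame({
        "cell_id": [f"{roi_id}_c{i + 1}" for i in range(len(mcs))],
        "patient_id": patient_id,
        "roi_id": roi_id,
        "batch_id": batch_id,
        "x_um": x,
        "y_um": y,
    })
    for j, m in enumerate(MARKERS):
        df[m] = intensities[:, j]
    df["true_metacluster"] = mcs
    return df


def _select_mihc_patients(config: SimConfig, clinical: pd.DataFrame,
                          rng: np.random.Generator) -> list[str]:
    """Propensity-matched mIHC subset: pN+ cases 1:1 with pN- controls."""
    from imgene.genomics import propensity_match

    n_pairs = config.n_mihc_patients // 2
    pairs = propensity_match(clinical, case_col="pn_status",
                             covariates=["age", "sex_male", "smoking"],
                             caliper=0.2, rng=rng)
    pairs = pairs.iloc[:n_pairs]
    chosen = list(pairs["case_id"]) + list(pairs["control_id"])
    if len(chosen) < config.n_mihc_patients:  # top up if matching fell short
        rest = [p for p in clinical["patient_id"] if p not in chosen]
        extra = rng.choice(rest, size=config.n_mihc_patients - len(chosen),
                           replace=False)
        chosen.extend(extra.tolist())
    return chosen


def _generate_cells(config: SimConfig, clinical: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    mihc_patients = _select_mihc_patients(config, clinical, rng)
    pn_of = clinical.set_index("patient_id")["pn_status"]
    batch_mult = {
        f"B{b + 1}": np.exp(rng.normal(0.0, config.batch_sigma, size=len(MARKERS)))
        for b in range(config.n_batches)
    }
    lo, hi = config.rois_per_patient
    frames = []
    for i, pid in enumerate(mihc_patients):
        group = "pN+" if pn_of[pid] else "pN-"
        batch = f"B{i % config.n_batches + 1}"
        target = np.array([config.metacluster_fracs[group][m] for m in METACLUSTERS])
        comp_vec = rng.dirichlet(target * config.composition_concentration)
        comp = dict(zip(METACLUSTERS, comp_vec))
        for r in range(int(rng.integers(lo, hi + 1))):
            roi_id = f"{pid}_R{r + 1}"
            frames.append(generate_roi(config, group, roi_id, rng=rng,
                                       composition=comp,
                                       batch_multipliers=batch_mult[batch],
                                       patient_id=pid, batch_id=batch))
    cells = pd.concat(frames, ignore_index=True)
    truth = {"mihc_patients": mihc_patients,
             "batch_multipliers": {b: m.tolist() for b, m in batch_mult.items()}}
    return cells, truth


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given (config, seed)."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    clinical = _generate_clinical(config, rng)
    mutations = _generate_mutations(config, clinical, rng)
    cells, cell_truth = _generate_cells(config, clinical, rng)
    truth = {
        "gene_freqs": {g: list(f) for g, f in config.gene_freqs.items()},
        "composition_targets": {g: dict(v) for g, v in config.metacluster_fracs.items()},
        "tmb_medians": list(config.tmb_medians),
        "subclonal_weight": list(config.subclonal_weight),
        "seed": config.seed,
        **cell_truth,
    }
    return SyntheticCohort(clinical=clinical, mutations=mutations,
                           cells=cells, truth=truth)
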