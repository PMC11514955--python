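"""Single-cell phenotyping of multiplex-IHC marker intensities.

Pipeline: asinh transform + per-marker z-scoring -> PCA -> iterative
cluster-centroid batch correction in PC space -> rule-based assignment of
each cell to one of nine metaclusters -> per-patient composition statistics.

The nine-label scheme is derived from the six-marker panel (PANCK, CD4,
CD8, FOXP3, CD68, PD-L1): epithelial cells and their PD-L1+ variant,
CD4/CD8 T cells, regulatory T cells (CD4+FOXP3+), macrophages and their
PD-L1+ variant, a remaining marker-positive immune class, and a
marker-negative remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from imgene.stats import InputError, TestResult, mann_whitney

logger = logging.getLogger(__name__)

MARKERS = ["panck", "cd4", "cd8", "foxp3", "cd68", "pdl1"]

METACLUSTERS = [
    "Epithelial",
    "PDL1pos_Epithelial",
    "CD4_T",
    "CD8_T",
    "Treg",
    "Macrophage",
    "PDL1pos_Macrophage",
    "Other_Immune",
    "Other",
]

EPITHELIAL_METACLUSTERS = {"Epithelial", "PDL1pos_Epithelial"}
#: "immune" denominator: every labeled cell except epithelial and the
#: marker-negative remainder.
IMMUNE_METACLUSTERS = {
    "CD4_T", "CD8_T", "Treg", "Macrophage", "PDL1pos_Macrophage", "Other_Immune",
}


@dataclass
class Embedding:
    """Transformed marker space and (optionally corrected) PC scores."""

    transformed: pd.DataFrame          # z-scored asinh intensities, cell x marker
    pcs: np.ndarray | None = None      # cell x n_pc scores
    corrected: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None


# ---------------------------------------------------------------------------
# stage 1: marker transform
# ---------------------------------------------------------------------------

def transform_markers(cells: pd.DataFrame, cofactor: float = 1.0,
                      markers: list[str] = MARKERS) -> Embedding:
    """asinh(intensity / cofactor), then z-score each marker across cells.

    A zero-variance marker gets z-scores of 0 (logged) rather than NaN.
    """
    if cofactor <= 0:
        raise InputError("cofactor must be positive")
    missing = [m for m in markers if m not in cells.columns]
    if missing:
        raise InputError(f"missing marker columns: {missing}")
    raw = cells[markers].to_numpy(dtype=float)
    if np.any(raw < 0):
        raise InputError("marker intensities must be non-negative")
    t = np.arcsinh(raw / cofactor)
    mu = t.mean(axis=0)
    sd = t.std(axis=0)
    zero = sd <= 1e-9 * np.maximum(1.0, np.abs(mu))
    if zero.any():
        logger.warning("zero-variance markers %s; z-scores set to 0",
                       [m for m, z in zip(markers, zero) if z])
        sd = np.where(zero, 1.0, sd)
    z = (t - mu) / sd
    z[:, zero] = 0.0
    return Embedding(transformed=pd.DataFrame(z, columns=markers, index=cells.index))


# ---------------------------------------------------------------------------
# stage 2: PCA + batch correction
# ---------------------------------------------------------------------------

def _soft_assign(Z: np.ndarray, centroids: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    logr = -d2 / (2.0 * sigma ** 2)
    logr -= logr.max(axis=1, keepdims=True)
    r = np.exp(logr)
    return r / r.sum(axis=1, keepdims=True)


def _diversity_assign(Z, centroids, sigma, batches, uniq, theta=2.0,
                      tau=1.0) -> np.ndarray:
    """Soft assignment re-weighted toward batch-diverse clusters.

    Responsibilities are multiplied by (expected / observed)^theta
    batch-cluster mass so batch-pure clusters are penalized; without this
    a strong batch effect forms batch-pure clusters whose centroids the
    alignment step cannot move.
    """
    R = _soft_assign(Z, centroids, sigma)
    col = R.sum(axis=0)
    for b in uniq:
        mask = batches == b
        obs = R[mask].sum(axis=0)
        exp = col * mask.mean()
        R[mask] *= ((exp + tau) / (obs + tau)) ** theta
    return R / R.sum(axis=1, keepdims=True)


def embed_and_correct(embedding: Embedding, batches, n_pcs: int = 20,
                      n_clusters: int = 10, n_iter: int = 5,
                      theta: float = 2.0, seed: int = 0) -> Embedding:
    """PCA to the top PCs, then batch correction in PC space.

    Correction alternates diversity-penalized soft clustering (``theta``
    controls how strongly clusters are pushed to mix batches) with
    per-batch, per-cluster centroid alignment: within every cluster each
    batch's centroid is moved onto the pooled centroid, cells weighted by
    their cluster responsibility.  With a single batch the correction is
    the identity (logged).
    """
    X = embedding.transformed.to_numpy()
    batches = np.asarray(batches)
    if batches.shape[0] != X.shape[0]:
        raise InputError("batch labels not aligned with cells")
    n_comp = min(n_pcs, X.shape[1], X.shape[0] - 1)
    pca = PCA(n_components=n_comp, random_state=seed)
    Z = pca.fit_transform(X)

    uniq = np.unique(batches)
    corrected = Z.copy()
    if uniq.size < 2:
        logger.warning("single batch: correction is identity")
        return Embedding(embedding.transformed, pcs=Z, corrected=corrected,
                         explained_variance_ratio=pca.explained_variance_ratio_)

    rng = np.random.default_rng(seed)
    k = min(n_clusters, X.shape[0])
    sigma = float(np.sqrt(Z.var(axis=0).sum()) / 2.0) or 1.0
    centroids = corrected[rng.choice(X.shape[0], size=k, replace=False)]
    for _ in range(n_iter):
        for _ in range(5):
            R = _diversity_assign(corrected, centroids, sigma, batches, uniq,
                                  theta=theta)
            w = R.sum(axis=0)
            centroids = (R.T @ corrected) / np.maximum(w, 1e-12)[:, None]
        R = _diversity_assign(corrected, centroids, sigma, batches, uniq,
                              theta=theta)
        shift = np.zeros_like(corrected)
        for c in range(k):
            r = R[:, c]
            tot = r.sum()
            if tot < 1e-9:
                continue
            pooled = (r[:, None] * corrected).sum(axis=0) / tot
            for b in uniq:
                mask = batches == b
                rb = r[mask]
                wb = rb.sum()
                if wb < 1e-9:
                    continue
                mu_b = (rb[:, None] * corrected[mask]).sum(axis=0) / wb
                shift[mask] += r[mask, None] * (mu_b - pooled)[None, :]
        corrected = corrected - shift
    return Embedding(embedding.transformed, pcs=Z, corrected=corrected,
                     explained_variance_ratio=pca.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# stage 3: metacluster assignment
# ---------------------------------------------------------------------------

@dataclass
class GatingRules:
    """Threshold-based gate on z-scored transformed intensities.

    Precedence (first match wins): PANCK+ -> Epithelial (PD-L1+ subsplit);
    CD68+ -> Macrophage (PD-L1+ subsplit); CD4+FOXP3+ -> Treg; CD4+ ->
    CD4_T; CD8+ -> CD8_T; any remaining marker+ -> Other_Immune; else Other.
    """

    threshold: float = 0.5
    labels: tuple = tuple(METACLUSTERS)


def assign_metaclusters(transformed: pd.DataFrame,
                        rules: GatingRules | None = None) -> pd.Series:
    """Deterministic marker gating; returns one of the nine labels per cell."""
    rules = rules or GatingRules()
    if set(rules.labels) != set(METACLUSTERS):
        raise InputError("rule table must cover exactly the 9 metacluster labels")
    z = transformed
    thr = rules.threshold
    pos = {m: z[m].to_numpy() > thr for m in MARKERS}
    n = len(z)
    labels = np.full(n, "Other", dtype=object)
    remaining_pos = pos["foxp3"] | pos["pdl1"]
    labels[remaining_pos] = "Other_Immune"
    labels[pos["cd8"]] = "CD8_T"
    labels[pos["cd4"]] = "CD4_T"
    labels[pos["cd4"] & pos["foxp3"]] = "Treg"
    labels[pos["cd68"]] = "Macrophage"
    labels[pos["cd68"] & pos["pdl1"]] = "PDL1pos_Macrophage"
    labels[pos["panck"]] = "Epithelial"
    labels[pos["panck"] & pos["pdl1"]] = "PDL1pos_Epithelial"
    return pd.Series(labels, index=z.index, name="metacluster")


def phenotype_cells(cells: pd.DataFrame, cofactor: float = 1.0,
                    rules: GatingRules | None = None,
                    correct_batches: bool = True,
                    seed: int = 0) -> tuple[pd.DataFrame, Embedding]:
    """Full phenotyping pass: transform, embed/correct, gate.

    Returns the cell table with a ``metacluster`` column appended and the
    embedding.  Gating operates on transformed intensities; the corrected
    embedding is produced for visualization and QC.
    """
    emb = transform_markers(cells, cofactor=cofactor)
    if correct_batches and "batch_id" in cells.columns and cells["batch_id"].nunique() > 1:
        emb = embed_and_correct(emb, cells["batch_id"].to_numpy(), seed=seed)
    out = cells.copy()
    out["metacluster"] = assign_metaclusters(emb.transformed, rules)
    return out, emb


# ---------------------------------------------------------------------------
# stage 4: composition statistics
# ---------------------------------------------------------------------------

def patient_composition(cells: pd.DataFrame, denominator: str = "total") -> pd.DataFrame:
    """Per-patient metacluster fractions.

    ``denominator="total"`` uses all cells; ``"immune"`` restricts to the
    immune metaclusters.  Patients with a zero denominator get NaN rows.
    """
    if denominator not in ("total", "immune"):
        raise InputError("denominator must be 'total' or 'immune'")
    counts = (cells.groupby(["patient_id", "metacluster"], observed=False)
              .size().unstack(fill_value=0))
    counts = counts.reindex(columns=METACLUSTERS, fill_value=0)
    if denominator == "total":
        denom = counts.sum(axis=1)
    else:
        denom = counts[list(IMMUNE_METACLUSTERS)].sum(axis=1)
    frac = counts.div(denom.replace(0, np.nan), axis=0)
    if denominator == "immune":
        frac = frac[[m for m in METACLUSTERS if m in IMMUNE_METACLUSTERS]]
    return frac


def composition_compare(cells: pd.DataFrame, groups: pd.Series,
                        denominator: str = "total") -> pd.DataFrame:
    """Mann-Whitney comparison of per-patient fractions between two groups.

    ``groups`` maps patient_id -> group label (exactly two distinct values).
    Returns a frame indexed by metacluster with group means and p-values.
    """
    frac = patient_composition(cells, denominator=denominator)
    groups = pd.Series(groups)
    missing = [p for p in frac.index if p not in groups.index]
    if missing:
        raise InputError(f"patients without group assignment: {missing[:5]}")
    gvals = sorted(groups.unique())
    if len(gvals) != 2:
        raise InputError("composition_compare requires exactly two groups")
    rows = []
    for mc in frac.columns:
        a = frac.loc[groups.reindex(frac.index) == gvals[0], mc].dropna()
        b = frac.loc[groups.reindex(frac.index) == gvals[1], mc].dropna()
        if len(a) == 0 or len(b) == 0:
            continue
        res: TestResult = mann_whitney(a, b)
        rows.append({"metacluster": mc,
                     f"mean_{gvals[0]}": a.mean(), f"mean_{gvals[1]}": b.mean(),
                     "statistic": res.statistic, "p_value": res.p_value})
    return pd.DataFrame(rows).set_index("metacluster")
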