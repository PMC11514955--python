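"""Tumor immune microenvironment (TIME) subtyping by consensus NMF.

The ROI x metacluster composition matrix is factorized repeatedly
(rank 2, 50 random restarts by default); each run clusters ROIs by their
dominant basis component, the co-clustering fractions form a consensus
matrix, and the final labels come from an average-linkage hierarchical cut
of the consensus distances.  Patient labels integrate ROI labels by
majority vote, with ties broken toward the subtype with higher mean
consensus confidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score

from imgene import stats
from imgene.stats import InputError

logger = logging.getLogger(__name__)


@dataclass
class SubtypeResult:
    """Consensus clustering outcome over ROIs."""

    consensus: np.ndarray            # symmetric, unit diagonal, in [0, 1]
    roi_labels: pd.Series            # subtype per ROI, values in {1, 2, ...}
    silhouette: float                # mean silhouette on consensus distances
    rank: int
    iterations: int
    degenerate: bool = False         # all ROIs fell into one cluster


def cnmf(composition: pd.DataFrame, rank: int = 2, iterations: int = 50,
         seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> SubtypeResult:
    """Consensus non-negative matrix factorization of ROI compositions.

    Each of ``iterations`` NMF runs uses a distinct seeded random
    initialization (multiplicative updates, Frobenius objective); a run
    assigns each ROI to its argmax basis coefficient.  consensus(i, j) is
    the fraction of runs co-clustering ROIs i and j.
    """
    M = composition.to_numpy(dtype=float)
    if np.any(M < 0):
        raise InputError("composition matrix must be non-negative")
    n = M.shape[0]
    if n < rank + 1:
        raise InputError("need at least rank + 1 ROIs")
    if np.allclose(M, M[0], atol=1e-12):
        # no structure to factorize: every run's split is arbitrary
        logger.warning("all ROI compositions identical; clustering degenerate")
        return SubtypeResult(consensus=np.ones((n, n)),
                             roi_labels=pd.Series(1, index=composition.index,
                                                  name="subtype"),
                             silhouette=-1.0, rank=rank, iterations=iterations,
                             degenerate=True)
    rng = np.random.default_rng(seed)
    consensus = np.zeros((n, n))
    for _ in range(iterations):
        run_seed = int(rng.integers(0, 2 ** 31 - 1))
        nmf = NMF(n_components=rank, init="random", solver="mu",
                  beta_loss="frobenius", max_iter=max_iter, tol=tol,
                  random_state=run_seed)
        with warnings.catch_warnings():
            # run-to-run label agreement, not the factorization residual,
            # is what the consensus uses; late-iteration drift is immaterial
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = nmf.fit_transform(M)
        lab = W.argmax(axis=1)
        consensus += (lab[:, None] == lab[None, :]).astype(float)
    consensus /= iterations
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=rank, criterion="maxclust")
    degenerate = len(np.unique(labels)) < 2
    if degenerate:
        logger.warning("degenerate consensus clustering: single cluster")
        sil = -1.0
    else:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    return SubtypeResult(consensus=consensus,
                         roi_labels=pd.Series(labels, index=composition.index,
                                              name="subtype"),
                         silhouette=sil, rank=rank, iterations=iterations,
                         degenerate=degenerate)


def roi_composition(cells: pd.DataFrame, label_col: str = "metacluster"
                    ) -> pd.DataFrame:
    """Per-ROI metacluster fraction matrix (rows sum to 1)."""
    from imgene.phenotyping import METACLUSTERS

    counts = (cells.groupby(["roi_id", label_col], observed=False).size()
              .unstack(fill_value=0).reindex(columns=METACLUSTERS, fill_value=0))
    return counts.div(counts.sum(axis=1), axis=0)


def integrate_roi_labels(result: SubtypeResult,
                         roi_to_patient: pd.Series) -> pd.Series:
    """Majority vote of ROI subtype labels per patient.

    Ties break toward the subtype whose ROIs show the higher mean
    within-subtype consensus (cohort-wide confidence).
    """
    roi_to_patient = pd.Series(roi_to_patient)
    unmapped = [r for r in result.roi_labels.index if r not in roi_to_patient.index]
    if unmapped:
        raise InputError(f"ROIs without patient mapping: {unmapped[:5]}")
    labels = result.roi_labels
    rois = list(labels.index)
    roi_pos = {r: i for i, r in enumerate(rois)}
    # cohort-wide confidence per subtype: mean consensus among its ROIs
    conf = {}
    for s in np.unique(labels):
        idx = [roi_pos[r] for r in labels.index[labels == s]]
        block = result.consensus[np.ix_(idx, idx)]
        conf[s] = float(block.mean()) if len(idx) > 1 else 1.0
    out = {}
    for pid, rois_of in labels.groupby(roi_to_patient.reindex(labels.index)):
        counts = rois_of.value_counts()
        top = counts[counts == counts.max()].index.tolist()
        out[pid] = max(top, key=lambda s: conf[s]) if len(top) > 1 else top[0]
    return pd.Series(out, name="subtype")


def subtype_associations(patient_labels: pd.Series, pn: pd.Series,
                         composition: pd.DataFrame | None = None,
                         muts: pd.DataFrame | None = None,
                         genes: list[str] | None = None) -> dict:
    """Associations of patient subtypes with nodal status, composition and
    gene mutations.

    Returns ``pn_test`` (subtype x pN Fisher), ``composition_tests``
    (per-metacluster Mann-Whitney across subtypes) and ``gene_tests``
    (per-gene Fisher across subtypes, BH-adjusted).  Subtypes with fewer
    than 2 patients are skipped with a warning.
    """
    labels = pd.Series(patient_labels).dropna()
    subtypes = sorted(labels.unique())
    if len(subtypes) != 2:
        raise InputError("subtype_associations expects exactly two subtypes")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        logger.warning("a subtype has < 2 patients; associations skipped")
        return {"pn_test": None, "composition_tests": None, "gene_tests": None}
    pn = pd.Series(pn).reindex(labels.index)
    tab = [[int(((labels == s) & (pn == v)).sum()) for v in (0, 1)]
           for s in subtypes]
    pn_test = stats.fisher_exact(tab)

    comp_tests = None
    if composition is not None:
        rows = []
        for mc in composition.columns:
            a = composition.loc[labels.index[labels == subtypes[0]], mc].dropna()
            b = composition.loc[labels.index[labels == subtypes[1]], mc].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            res = stats.mann_whitney(a, b)
            rows.append({"metacluster": mc, "mean_subtype1": a.mean(),
                         "mean_subtype2": b.mean(), "p_value": res.p_value})
        comp_tests = pd.DataFrame(rows).set_index("metacluster")

    gene_tests = None
    if muts is not None:
        genes = genes or sorted(muts["gene"].unique())
        rows = []
        for g in genes:
            mutated = set(muts.loc[muts["gene"] == g, "patient_id"])
            cells_ = [[int(((labels == s) & labels.index.isin(mutated)).sum()),
                       int(((labels == s) & ~labels.index.isin(mutated)).sum())]
                      for s in subtypes]
            if sum(c[0] for c in cells_) == 0:
                continue
            res = stats.fisher_exact(cells_)
            rows.append({"gene": g, "p_value": res.p_value,
                         "freq_subtype1": cells_[0][0] / max(1, sum(cells_[0])),
                         "freq_subtype2": cells_[1][0] / max(1, sum(cells_[1]))})
        gene_tests = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
        if len(gene_tests):
            gene_tests["q_value"] = stats.bh_fdr(
                gene_tests["p_value"].to_numpy()).q_values
    return {"pn_test": pn_test, "composition_tests": comp_tests,
            "gene_tests": gene_tests}
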