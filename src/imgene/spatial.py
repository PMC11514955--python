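"""Spatial graphs, cellular neighbourhoods (CNs) and interaction testing.

Per region of interest (ROI): Delaunay triangulation defines cell-cell
adjacency; the composition of each cell's 20 nearest neighbours defines its
window; K-means over windows (k = 10 by default) defines CNs, which are
annotated by their dominant metacluster.  Pairwise interaction/avoidance is
scored against a within-ROI label-permutation null.  Voronoi tessellations
clipped to the ROI box provide topology maps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, Voronoi, cKDTree, QhullError
from shapely.geometry import Polygon, box

from imgene import stats
from imgene.phenotyping import METACLUSTERS
from imgene.stats import InputError

logger = logging.getLogger(__name__)

FUNCTIONAL_GROUPS = ["Epithelial-CN", "MF_and_T-CN", "Immune-suppressed-CN", "T-CN"]

_GROUP_OF = {
    "Epithelial": "Epithelial-CN",
    "PDL1pos_Epithelial": "Epithelial-CN",
    "Macrophage": "MF_and_T-CN",
    "PDL1pos_Macrophage": "MF_and_T-CN",
    "Treg": "Immune-suppressed-CN",
    "CD4_T": "T-CN",
    "CD8_T": "T-CN",
}


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

def build_graph(coords: np.ndarray, prune_um: float | None = None) -> np.ndarray:
    """Delaunay adjacency for one ROI: array of undirected edges (i < j).

    Duplicate coordinates are jittered by 1e-6 um (logged).  Fewer than 3
    points, or a degenerate (collinear) configuration, falls back to
    nearest-neighbour edges.  Edges longer than ``prune_um`` are dropped.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("coords must be an (n, 2) array")
    n = pts.shape[0]
    if n >= 2:
        _, inv, counts = np.unique(pts, axis=0, return_inverse=True,
                                   return_counts=True)
        if np.any(counts > 1):
            logger.info("duplicate coordinates jittered by 1e-6 um")
            rng = np.random.default_rng(0)
            dup = counts[inv] > 1
            pts = pts.copy()
            pts[dup] += rng.uniform(-1e-6, 1e-6, size=(int(dup.sum()), 2))
    edges: set[tuple[int, int]] = set()
    if n < 3:
        if n == 2:
            edges.add((0, 1))
    else:
        try:
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for a, b in itertools.combinations(simplex, 2):
                    edges.add((min(a, b), max(a, b)))
        except QhullError:
            # collinear: connect each point to its nearest neighbour
            tree = cKDTree(pts)
            _, idx = tree.query(pts, k=2)
            for i, j in enumerate(idx[:, 1]):
                edges.add((min(i, int(j)), max(i, int(j))))
    edge_arr = np.array(sorted(edges), dtype=int).reshape(-1, 2)
    if prune_um is not None:
        edge_arr = interaction_partners(edge_arr, pts, prune_um)
    return edge_arr


def interaction_partners(edges: np.ndarray, coords: np.ndarray,
                         radius: float = 4.0) -> np.ndarray:
    """Retain graph edges whose centroid distance is <= ``radius`` um."""
    if radius <= 0:
        raise InputError("radius must be positive")
    if len(edges) == 0:
        return edges
    pts = np.asarray(coords, dtype=float)
    d = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    return edges[d <= radius]


def build_graphs(cells: pd.DataFrame, prune_um: float | None = None
                 ) -> dict[str, np.ndarray]:
    """Per-ROI Delaunay graphs; edge indices are positions within the ROI
    frame sorted by cell_id."""
    out = {}
    for roi, sub in cells.groupby("roi_id"):
        sub = sub.sort_values("cell_id")
        out[str(roi)] = build_graph(sub[["x_um", "y_um"]].to_numpy(), prune_um)
    return out


# ---------------------------------------------------------------------------
# neighbourhood windows and CN clustering
# ---------------------------------------------------------------------------

def neighborhood_windows(cells: pd.DataFrame, labels: pd.Series, k: int = 20,
                         include_self: bool = True, mode: str = "knn",
                         radius: float = 4.0) -> pd.DataFrame:
    """Metacluster composition of each cell's local window.

    ``mode="knn"`` (default): the k nearest cells; distance ties resolve by
    cell id (the ROI frame is sorted by cell_id before the k-d tree query);
    ROIs with fewer than k cells use every cell (logged).  ``mode="radius"``:
    the centre cell, its primary neighbours within ``radius`` um, and those
    neighbours' own within-radius (secondary) neighbours.  Rows sum to 1.
    """
    if mode not in ("knn", "radius"):
        raise InputError(f"unknown window mode {mode!r}")
    labels = pd.Series(labels)
    mc_index = {m: i for i, m in enumerate(METACLUSTERS)}
    comp = np.zeros((len(cells), len(METACLUSTERS)))
    order = np.empty(len(cells), dtype=int)
    pos = 0
    for roi, sub in cells.groupby("roi_id"):
        sub = sub.sort_values("cell_id")
        idx = sub.index.to_numpy()
        pts = sub[["x_um", "y_um"]].to_numpy()
        codes = labels.loc[idx].map(mc_index).to_numpy()
        n = len(sub)
        tree = cKDTree(pts)
        counts = np.zeros((n, len(METACLUSTERS)))
        if mode == "knn":
            kk = min(k, n) if include_self else min(k, n - 1)
            if kk < k:
                logger.info("ROI %s has %d cells (< window size %d)", roi, n, k)
            _, nbr = tree.query(pts, k=max(kk + (0 if include_self else 1), 1))
            nbr = np.atleast_2d(nbr)
            if not include_self:
                nbr = nbr[:, 1:]
            for c in range(nbr.shape[1]):
                np.add.at(counts, (np.arange(n), codes[nbr[:, c]]), 1.0)
        else:
            primary = tree.query_ball_point(pts, r=radius)
            for i in range(n):
                members = set(primary[i]) | {i}
                for j in primary[i]:
                    members.update(primary[j])
                for j in members:
                    counts[i, codes[j]] += 1.0
        comp[pos:pos + n] = counts / counts.sum(axis=1, keepdims=True)
        order[pos:pos + n] = idx
        pos += n
    return pd.DataFrame(comp, index=order, columns=METACLUSTERS).loc[cells.index]


@dataclass
class CnAssignment:
    """Per-cell CN labels (1..k) with the window compositions behind them."""

    windows: pd.DataFrame
    labels: pd.Series           # CN label per cell, 1-based
    k: int
    centroids: np.ndarray = field(repr=False, default=None)


def cluster_cns(windows: pd.DataFrame, k_cn: int = 10, seed: int = 0,
                n_init: int = 10) -> CnAssignment:
    """K-means over window composition vectors across all ROIs jointly."""
    from sklearn.cluster import KMeans

    X = windows.to_numpy()
    n_distinct = len(np.unique(X, axis=0))
    k = k_cn
    if n_distinct < k_cn:
        logger.warning("only %d distinct windows; reducing k from %d",
                       n_distinct, k_cn)
        k = max(1, n_distinct)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    lab = km.fit_predict(X) + 1
    return CnAssignment(windows=windows,
                        labels=pd.Series(lab, index=windows.index, name="cn"),
                        k=k, centroids=km.cluster_centers_)


def annotate_cns(assignment: CnAssignment,
                 cell_labels: pd.Series | None = None) -> pd.DataFrame:
    """Annotate each CN by its highest-mean-composition metacluster.

    Functional groups: dominant epithelial -> Epithelial-CN; dominant
    macrophage -> MF_and_T-CN; dominant Treg -> Immune-suppressed-CN;
    dominant CD4/CD8 T -> T-CN.  A CN dominated by the residual classes
    (Other / Other_Immune) falls back to the largest of the four grouped
    fractions.  Ties break toward the cohort-wide rarer metacluster.
    """
    mean_comp = assignment.windows.groupby(assignment.labels).mean()
    overall = assignment.windows.mean()
    rows = []
    for cn, comp in mean_comp.iterrows():
        top = comp.max()
        candidates = [m for m in METACLUSTERS if comp[m] == top]
        dominant = min(candidates, key=lambda m: overall[m])  # rarer wins ties
        group = _GROUP_OF.get(dominant)
        if group is None:
            grouped = {
                "Epithelial-CN": comp["Epithelial"] + comp["PDL1pos_Epithelial"],
                "MF_and_T-CN": comp["Macrophage"] + comp["PDL1pos_Macrophage"],
                "Immune-suppressed-CN": comp["Treg"],
                "T-CN": comp["CD4_T"] + comp["CD8_T"],
            }
            group = max(grouped, key=grouped.get)
        rows.append({"cn": cn, "dominant_metacluster": dominant,
                     "functional_group": group,
                     **{f"mean_{m}": comp[m] for m in METACLUSTERS}})
    return pd.DataFrame(rows).set_index("cn")


def cn_frequencies(cells: pd.DataFrame, assignment: CnAssignment) -> pd.DataFrame:
    """Per-patient fraction of cells in each CN."""
    df = pd.DataFrame({"patient_id": cells["patient_id"],
                       "cn": assignment.labels})
    counts = df.pivot_table(index="patient_id", columns="cn", aggfunc="size",
                            fill_value=0)
    counts = counts.reindex(columns=range(1, assignment.k + 1), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# interaction / avoidance testing
# ---------------------------------------------------------------------------

def _pair_counts(codes: np.ndarray, edges: np.ndarray, n_classes: int) -> np.ndarray:
    a = codes[edges[:, 0]]
    b = codes[edges[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    return np.bincount(lo * n_classes + hi, minlength=n_classes * n_classes)


def interaction_test_roi(codes: np.ndarray, edges: np.ndarray,
                         n_classes: int, n_perm: int = 1000,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Permutation interaction test for one ROI.

    Labels are shuffled within the ROI (geometry fixed); per metacluster
    pair: z = (obs - null mean) / null SD and empirical two-sided
    p = (1 + #{|null - mean| >= |obs - mean|}) / (1 + n_perm).  Pairs whose
    metaclusters are absent from the ROI are excluded.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(edges) == 0 or len(np.unique(codes)) < 2:
        return pd.DataFrame(columns=["a", "b", "observed", "z", "p"])
    obs = _pair_counts(codes, edges, n_classes)
    perm_labels = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    a = perm_labels[:, edges[:, 0]]
    b = perm_labels[:, edges[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    idx = lo * n_classes + hi + np.arange(n_perm)[:, None] * (n_classes ** 2)
    null = np.bincount(idx.ravel(), minlength=n_perm * n_classes ** 2)
    null = null.reshape(n_perm, n_classes ** 2)
    mean = null.mean(axis=0)
    sd = null.std(axis=0)
    present = np.unique(codes)
    rows = []
    for i in present:
        for j in present[present >= i]:
            flat = i * n_classes + j
            if sd[flat] == 0 and obs[flat] == mean[flat]:
                z = 0.0
            else:
                z = float((obs[flat] - mean[flat]) / sd[flat]) if sd[flat] > 0 else np.inf
            dev = np.abs(null[:, flat] - mean[flat])
            p = float((1 + np.sum(dev >= abs(obs[flat] - mean[flat]))) / (1 + n_perm))
            rows.append({"a": int(i), "b": int(j),
                         "observed": int(obs[flat]), "z": z, "p": p})
    return pd.DataFrame(rows)


@dataclass
class InteractionResult:
    """Cohort-level interaction/avoidance summary over metacluster pairs."""

    table: pd.DataFrame  # per-pair: mean_z, n_rois, sig fractions, direction
    alpha: float = 0.05


def interaction_test(cells: pd.DataFrame, labels: pd.Series,
                     graphs: dict[str, np.ndarray], n_perm: int = 1000,
                     seed: int = 0, alpha: float = 0.05) -> InteractionResult:
    """Permutation interaction/avoidance test pooled over ROIs.

    Each ROI is tested separately; the cohort-level direction for a pair is
    the majority direction among ROIs significant at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    mc_index = {m: i for i, m in enumerate(METACLUSTERS)}
    n_classes = len(METACLUSTERS)
    acc: dict[tuple[int, int], list] = {}
    for roi, sub in cells.groupby("roi_id"):
        sub = sub.sort_values("cell_id")
        edges = graphs.get(str(roi))
        if edges is None or len(edges) == 0:
            continue
        codes = labels.loc[sub.index].map(mc_index).to_numpy()
        res = interaction_test_roi(codes, edges, n_classes, n_perm, rng)
        for _, r in res.iterrows():
            acc.setdefault((int(r["a"]), int(r["b"])), []).append(
                (r["z"], r["p"]))
    rows = []
    for (i, j), vals in sorted(acc.items()):
        zs = np.array([v[0] for v in vals])
        ps = np.array([v[1] for v in vals])
        finite = np.isfinite(zs)
        sig = ps < alpha
        n_pos = int(np.sum(sig & (zs > 0)))
        n_neg = int(np.sum(sig & (zs < 0)))
        if n_pos > n_neg and n_pos > 0:
            direction = "interaction"
        elif n_neg > n_pos and n_neg > 0:
            direction = "avoidance"
        else:
            direction = "none"
        rows.append({"metacluster_a": METACLUSTERS[i],
                     "metacluster_b": METACLUSTERS[j],
                     "n_rois": len(vals),
                     "mean_z": float(zs[finite].mean()) if finite.any() else np.nan,
                     "n_sig_attraction": n_pos, "n_sig_avoidance": n_neg,
                     "sig_fraction": float(np.mean(sig)),
                     "direction": direction})
    return InteractionResult(table=pd.DataFrame(rows), alpha=alpha)


# ---------------------------------------------------------------------------
# CN group analyses
# ---------------------------------------------------------------------------

def cn_group_analysis(cn_freq: pd.DataFrame, groups: pd.Series,
                      annotation: pd.DataFrame,
                      composition: pd.DataFrame | None = None,
                      muts: pd.DataFrame | None = None,
                      genes: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """CN abundance vs group, dominant-metacluster coupling, and mutations.

    Returns a dict with ``group_tests`` (per-CN Mann-Whitney across the two
    groups), ``metacluster_correlation`` (Spearman rho between each CN's
    abundance and its dominant metacluster's per-patient proportion), and
    ``gene_associations`` (per CN x gene Mann-Whitney of CN abundance by
    mutation status, BH-adjusted) when mutation data are supplied.
    """
    groups = pd.Series(groups).reindex(cn_freq.index)
    gvals = sorted(groups.dropna().unique())
    if len(gvals) != 2:
        raise InputError("cn_group_analysis requires exactly two groups")
    rows = []
    for cn in cn_freq.columns:
        a = cn_freq.loc[groups == gvals[0], cn]
        b = cn_freq.loc[groups == gvals[1], cn]
        res = stats.mann_whitney(a, b)
        rows.append({"cn": cn, f"mean_{gvals[0]}": a.mean(),
                     f"mean_{gvals[1]}": b.mean(), "p_value": res.p_value})
    group_tests = pd.DataFrame(rows).set_index("cn")

    corr = None
    if composition is not None:
        crows = []
        for cn in cn_freq.columns:
            dom = annotation.loc[cn, "dominant_metacluster"]
            if dom not in composition.columns:
                continue
            joined = pd.concat([cn_freq[cn], composition[dom]], axis=1).dropna()
            if len(joined) < 3 or joined.iloc[:, 0].nunique() < 2:
                continue
            res = stats.spearman(joined.iloc[:, 0], joined.iloc[:, 1])
            crows.append({"cn": cn, "dominant_metacluster": dom,
                          "rho": res.estimate, "p_value": res.p_value})
        corr = pd.DataFrame(crows).set_index("cn") if crows else pd.DataFrame()

    gene_assoc = None
    if muts is not None:
        genes = genes or sorted(muts["gene"].unique())
        mutated = {g: set(muts.loc[muts["gene"] == g, "patient_id"]) for g in genes}
        arows = []
        for cn in cn_freq.columns:
            for g in genes:
                has = cn_freq.index.isin(mutated[g])
                if has.sum() < 2 or (~has).sum() < 2:
                    continue
                res = stats.mann_whitney(cn_freq.loc[has, cn],
                                         cn_freq.loc[~has, cn])
                arows.append({"cn": cn, "gene": g,
                              "mean_mutated": cn_freq.loc[has, cn].mean(),
                              "mean_wildtype": cn_freq.loc[~has, cn].mean(),
                              "p_value": res.p_value})
        gene_assoc = pd.DataFrame(arows)
        if len(gene_assoc):
            gene_assoc["q_value"] = stats.bh_fdr(
                gene_assoc["p_value"].to_numpy()).q_values
    return {"group_tests": group_tests, "metacluster_correlation": corr,
            "gene_associations": gene_assoc}


# ---------------------------------------------------------------------------
# Voronoi topology maps
# ---------------------------------------------------------------------------

def voronoi_map(coords: np.ndarray, bounds: tuple[float, float, float, float]
                ) -> list[Polygon]:
    """Voronoi tessellation clipped to a rectangular ROI.

    Implemented by mirroring the points across the four box edges so every
    cell of an original point is bounded; the returned polygons tile the
    box exactly (areas sum to the box area) and each contains its
    generating point.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.shape[0] < 4:
        raise InputError("voronoi_map needs >= 4 cells")
    xmin, ymin, xmax, ymax = bounds
    mirrored = [pts]
    for axis, lo, hi in ((0, xmin, xmax), (1, ymin, ymax)):
        for bound in (lo, hi):
            m = pts.copy()
            m[:, axis] = 2 * bound - m[:, axis]
            mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    clip = box(xmin, ymin, xmax, ymax)
    polys = []
    for i in range(len(pts)):
        region = [v for v in vor.regions[vor.point_region[i]] if v != -1]
        verts = vor.vertices[region]
        # regions are convex: angular sort around the generator is exact
        ang = np.arctan2(verts[:, 1] - pts[i, 1], verts[:, 0] - pts[i, 0])
        poly = Polygon(verts[np.argsort(ang)])
        polys.append(poly.intersection(clip))
    return polys


def plot_voronoi(coords: np.ndarray, cn_labels, bounds, path=None, cmap="tab10"):
    """Render a CN-colored Voronoi topology map (SVG/PNG via matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    polys = voronoi_map(coords, bounds)
    labels = np.asarray(cn_labels)
    colors = colormaps[cmap]
    fig, ax = plt.subplots(figsize=(5, 5))
    for poly, lab in zip(polys, labels):
        if poly.is_empty:
            continue
        xs, ys = poly.exterior.xy
        ax.fill(xs, ys, color=colors((int(lab) - 1) % colors.N),
                edgecolor="white", linewidth=0.3)
    ax.set_xlim(bounds[0], bounds[2])
    ax.set_ylim(bounds[3], bounds[1])  # image convention: y down
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
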