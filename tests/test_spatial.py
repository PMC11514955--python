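"""Spatial graphs, windows, CN clustering/annotation, interaction testing,
and Voronoi topology maps."""

import numpy as np
import pandas as pd
import pytest

from helpers import interaction_exhaustive_oracle
from imgene import spatial
from imgene.phenotyping import METACLUSTERS
from imgene.stats import InputError

MC = {m: i for i, m in enumerate(METACLUSTERS)}


def _cells(xy, labels, roi="R1", patient="p0"):
    df = pd.DataFrame(xy, columns=["x_um", "y_um"])
    df["cell_id"] = [f"c{i:03d}" for i in range(len(df))]
    df["roi_id"] = roi
    df["patient_id"] = patient
    df["metacluster"] = labels
    return df


class TestGraph:
    def test_triangle(self):
        edges = spatial.build_graph([[0, 0], [1, 0], [0, 1]])
        assert len(edges) == 3
        deg = np.bincount(edges.ravel())
        assert (deg == 2).all()

    def test_unit_square_has_five_edges(self):
        edges = spatial.build_graph([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert len(edges) == 5  # 4 sides + 1 diagonal

    def test_no_self_edges_and_unique(self, rng):
        pts = rng.uniform(0, 100, size=(40, 2))
        edges = spatial.build_graph(pts)
        assert (edges[:, 0] < edges[:, 1]).all()
        assert len(np.unique(edges, axis=0)) == len(edges)

    def test_duplicate_coordinates_handled(self):
        pts = [[0, 0], [0, 0], [1, 0], [0, 1], [1, 1]]
        edges = spatial.build_graph(pts)
        assert len(edges) > 0

    def test_collinear_fallback(self):
        edges = spatial.build_graph([[0, 0], [1, 0], [2, 0], [3, 0]])
        assert len(edges) >= 3

    def test_two_points(self):
        assert len(spatial.build_graph([[0, 0], [5, 5]])) == 1


class TestInteractionPartners:
    def test_radius_pruning(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [13.0, 0.0]])
        edges = spatial.build_graph(pts)
        kept = spatial.interaction_partners(edges, pts, radius=4.0)
        dists = np.linalg.norm(pts[kept[:, 0]] - pts[kept[:, 1]], axis=1)
        assert (dists <= 4.0).all()
        assert [0, 1] in kept.tolist()

    def test_infinite_radius_identity(self, rng):
        pts = rng.uniform(0, 50, size=(20, 2))
        edges = spatial.build_graph(pts)
        kept = spatial.interaction_partners(edges, pts, radius=np.inf)
        assert np.array_equal(kept, edges)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(InputError):
            spatial.interaction_partners(np.empty((0, 2), int), np.empty((0, 2)), 0)


class TestWindows:
    def test_homogeneous_roi_one_hot(self, rng):
        cells = _cells(rng.uniform(0, 100, (30, 2)), ["Macrophage"] * 30)
        win = spatial.neighborhood_windows(cells, cells["metacluster"], k=20)
        assert (win["Macrophage"] == 1.0).all()
        assert np.allclose(win.sum(axis=1), 1.0)

    def test_balanced_equidistant_neighbours(self):
        # 10 epithelial and 10 macrophages on a ring around a central cell
        ang = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        ring = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang)])
        labels = ["Epithelial"] * 10 + ["Macrophage"] * 10
        xy = np.vstack([[0.0, 0.0], ring + 50.0]) + 50.0
        xy[0] = [50.0, 50.0]
        cells = _cells(xy, ["Other"] + labels)
        win = spatial.neighborhood_windows(cells, cells["metacluster"], k=21)
        center = win.iloc[0]
        assert center["Epithelial"] == pytest.approx(10 / 21)
        assert center["Macrophage"] == pytest.approx(10 / 21)
        assert center["Other"] == pytest.approx(1 / 21)

    def test_small_roi_uses_all_cells(self, rng):
        cells = _cells(rng.uniform(0, 10, (5, 2)),
                       ["Epithelial", "Epithelial", "Treg", "Treg", "Other"])
        win = spatial.neighborhood_windows(cells, cells["metacluster"], k=20)
        assert np.allclose(win["Epithelial"], 0.4)

    def test_rigid_motion_invariance(self, rng):
        xy = rng.uniform(0, 100, (40, 2))
        labels = list(rng.choice(["Epithelial", "Macrophage", "CD8_T"], 40))
        cells = _cells(xy, labels)
        win = spatial.neighborhood_windows(cells, cells["metacluster"], k=10)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        cells2 = cells.copy()
        cells2[["x_um", "y_um"]] = xy @ rot.T + np.array([37.0, -11.0])
        win2 = spatial.neighborhood_windows(cells2, cells2["metacluster"], k=10)
        assert np.allclose(win.to_numpy(), win2.to_numpy())


class TestCnClustering:
    def test_segregated_regions_recovered(self, rng):
        left = _cells(rng.uniform(0, 40, (40, 2)), ["Epithelial"] * 40)
        right_xy = rng.uniform(0, 40, (40, 2)) + np.array([200.0, 0.0])
        right = _cells(right_xy, ["CD8_T"] * 40)
        right["cell_id"] = [f"d{i:03d}" for i in range(40)]
        cells = pd.concat([left, right], ignore_index=True)
        win = spatial.neighborhood_windows(cells, cells["metacluster"], k=10)
        assignment = spatial.cluster_cns(win, k_cn=2, seed=0)
        lab = assignment.labels.to_numpy()
        assert len(set(lab[:40])) == 1
        assert len(set(lab[40:])) == 1
        assert lab[0] != lab[-1]

    def test_cell_order_invariance_up_to_renaming(self, rng):
        xy = rng.uniform(0, 100, (60, 2))
        labels = list(rng.choice(["Epithelial", "Treg", "Macrophage"], 60))
        cells = _cells(xy, labels)
        win = spatial.neighborhood_windows(cells, cells["metacluster"], k=10)
        a = spatial.cluster_cns(win, k_cn=3, seed=1).labels
        perm = rng.permutation(60)
        b = spatial.cluster_cns(win.iloc[perm], k_cn=3, seed=1).labels
        b = b.loc[a.index]
        # same partition: co-membership matrices agree
        am = a.to_numpy()[:, None] == a.to_numpy()[None, :]
        bm = b.to_numpy()[:, None] == b.to_numpy()[None, :]
        assert (am == bm).all()

    def test_single_cluster(self, rng):
        cells = _cells(rng.uniform(0, 50, (20, 2)), ["Other"] * 20)
        win = spatial.neighborhood_windows(cells, cells["metacluster"], k=5)
        assignment = spatial.cluster_cns(win, k_cn=1, seed=0)
        assert assignment.labels.nunique() == 1

    def test_k_reduced_when_windows_degenerate(self, rng):
        cells = _cells(rng.uniform(0, 50, (30, 2)), ["Other"] * 30)
        win = spatial.neighborhood_windows(cells, cells["metacluster"], k=10)
        assignment = spatial.cluster_cns(win, k_cn=10, seed=0)
        assert assignment.k == 1


class TestAnnotation:
    def _assignment(self, comps, labels):
        win = pd.DataFrame(comps, columns=METACLUSTERS)
        return spatial.CnAssignment(windows=win,
                                    labels=pd.Series(labels, index=win.index),
                                    k=len(set(labels)))

    def test_dominant_rules(self):
        epi = np.zeros(9); epi[MC["Epithelial"]] = 0.8; epi[MC["Other"]] = 0.2
        treg = np.zeros(9); treg[MC["Treg"]] = 0.5; treg[MC["Macrophage"]] = 0.2
        treg[MC["Other"]] = 0.3
        mac = np.zeros(9); mac[MC["Macrophage"]] = 0.5; mac[MC["CD8_T"]] = 0.5 - 1e-9
        t = np.zeros(9); t[MC["CD4_T"]] = 0.6; t[MC["Other"]] = 0.4
        a = self._assignment([epi, treg, mac, t], [1, 2, 3, 4])
        ann = spatial.annotate_cns(a)
        assert ann.loc[1, "functional_group"] == "Epithelial-CN"
        assert ann.loc[2, "functional_group"] == "Immune-suppressed-CN"
        assert ann.loc[3, "functional_group"] == "MF_and_T-CN"
        assert ann.loc[4, "functional_group"] == "T-CN"

    def test_planted_treg_niche_maps_to_immune_suppressed(self, rng):
        niche = rng.normal([50.0, 50.0], 8.0, size=(20, 2))
        nests = rng.uniform(150, 350, size=(60, 2))
        cells = _cells(np.vstack([niche, nests]),
                       ["Treg"] * 20 + ["Epithelial"] * 60)
        win = spatial.neighborhood_windows(cells, cells["metacluster"], k=10)
        assignment = spatial.cluster_cns(win, k_cn=2, seed=0)
        ann = spatial.annotate_cns(assignment)
        treg_cn = ann["mean_Treg"].idxmax()
        assert ann.loc[treg_cn, "functional_group"] == "Immune-suppressed-CN"
        assert ann.loc[treg_cn, "dominant_metacluster"] == "Treg"


class TestInteractionTest:
    def _toy(self):
        # two tight mixed pairs: macrophages adjacent to epithelial cells
        xy = np.array([[0, 0], [1, 0], [20, 0], [21, 0], [10, 30], [11, 30],
                       [0, 60], [20, 60]], dtype=float)
        labels = ["Epithelial", "Macrophage", "Epithelial", "Macrophage",
                  "Epithelial", "Macrophage", "Other", "Other"]
        return xy, labels

    def test_matches_exhaustive_oracle_on_toy_roi(self):
        xy, labels = self._toy()
        edges = spatial.build_graph(xy)
        codes = np.array([MC[m] for m in labels])
        oracle = interaction_exhaustive_oracle(codes, edges, len(METACLUSTERS))
        res = spatial.interaction_test_roi(codes, edges, len(METACLUSTERS),
                                           n_perm=20000,
                                           rng=np.random.default_rng(0))
        for _, row in res.iterrows():
            obs, z_exact, p_exact = oracle[(row["a"], row["b"])]
            assert row["observed"] == obs
            if np.isfinite(row["z"]) and abs(z_exact) < 10:
                assert row["z"] == pytest.approx(z_exact, abs=0.15)
            assert row["p"] == pytest.approx(p_exact, abs=0.03)

    def test_planted_attraction_detected(self, rng):
        # epithelial and macrophages co-located; Others in a distant blob
        blob = rng.uniform(0, 30, size=(10, 2))
        far = rng.uniform(200, 260, size=(10, 2))
        xy = np.vstack([blob, far])
        labels = (["Epithelial", "Macrophage"] * 5) + ["Other"] * 10
        edges = spatial.build_graph(xy)
        codes = np.array([MC[m] for m in labels])
        res = spatial.interaction_test_roi(codes, edges, len(METACLUSTERS),
                                           n_perm=5000,
                                           rng=np.random.default_rng(1))
        row = res[(res["a"] == MC["Epithelial"])
                  & (res["b"] == MC["Macrophage"])].iloc[0]
        assert row["z"] > 0
        assert row["p"] < 0.05

    def test_single_metacluster_roi_empty(self, rng):
        xy = rng.uniform(0, 50, (10, 2))
        edges = spatial.build_graph(xy)
        res = spatial.interaction_test_roi(np.zeros(10, dtype=int), edges, 9)
        assert res.empty

    def test_cohort_level_direction(self, rng):
        frames, graphs = [], {}
        for r in range(6):
            blob = rng.uniform(0, 30, size=(10, 2))
            far = rng.uniform(200, 260, size=(10, 2))
            xy = np.vstack([blob, far])
            labels = (["Epithelial", "Macrophage"] * 5) + ["Other"] * 10
            cells = _cells(xy, labels, roi=f"R{r}")
            frames.append(cells)
            sub = cells.sort_values("cell_id")
            graphs[f"R{r}"] = spatial.build_graph(sub[["x_um", "y_um"]].to_numpy())
        cells = pd.concat(frames, ignore_index=True)
        out = spatial.interaction_test(cells, cells["metacluster"], graphs,
                                       n_perm=800, seed=0)
        row = out.table[(out.table["metacluster_a"] == "Epithelial")
                        & (out.table["metacluster_b"] == "Macrophage")].iloc[0]
        assert row["direction"] == "interaction"


class TestCnGroupAnalysis:
    def test_identical_frequencies_nonsignificant(self):
        freq = pd.DataFrame({1: [0.5] * 10, 2: [0.5] * 10},
                            index=[f"p{i}" for i in range(10)])
        groups = pd.Series({f"p{i}": i % 2 for i in range(10)})
        ann = pd.DataFrame({"dominant_metacluster": ["Treg", "Epithelial"]},
                           index=[1, 2])
        out = spatial.cn_group_analysis(freq, groups, ann)
        assert (out["group_tests"]["p_value"] > 0.9).all()

    def test_monotone_abundance_gives_rho_one(self, rng):
        n = 12
        treg = np.linspace(0.01, 0.2, n)
        freq = pd.DataFrame({1: treg ** 2}, index=[f"p{i}" for i in range(n)])
        comp = pd.DataFrame({"Treg": treg}, index=freq.index)
        groups = pd.Series({f"p{i}": i % 2 for i in range(n)})
        ann = pd.DataFrame({"dominant_metacluster": ["Treg"]}, index=[1])
        out = spatial.cn_group_analysis(freq, groups, ann, composition=comp)
        assert out["metacluster_correlation"].loc[1, "rho"] == pytest.approx(1.0)


class TestVoronoi:
    def test_unit_square_corners_quadrants(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        polys = spatial.voronoi_map(pts, (0, 0, 1, 1))
        for p in polys:
            assert p.area == pytest.approx(0.25, rel=1e-9)

    def test_area_conservation_and_containment(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        polys = spatial.voronoi_map(pts, (0, 0, 100, 100))
        total = sum(p.area for p in polys)
        assert total == pytest.approx(100 * 100, rel=1e-6)
        from shapely.geometry import Point
        for i, poly in enumerate(polys):
            assert poly.buffer(1e-9).contains(Point(pts[i]))

    def test_too_few_cells_rejected(self):
        with pytest.raises(InputError):
            spatial.voronoi_map(np.zeros((3, 2)), (0, 0, 1, 1))
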