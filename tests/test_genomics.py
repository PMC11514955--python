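"""Panel-NGS statistics: TMB, MATH, frequency/co-occurrence/pathway tests,
actionability tallies, propensity matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import median_abs_deviation

from imgene import genomics
from imgene.genomics import PanelConfig, compute_math, compute_tmb
from imgene.stats import InputError


def _mut(pid, gene, klass="nonsynonymous_snv", vaf=0.3, onc="oncogenic",
         level="none"):
    return {"patient_id": pid, "gene": gene, "alteration_class": klass,
            "vaf": vaf, "oncogenic": onc, "level": level}


@pytest.fixture(scope="module")
def panel():
    return PanelConfig()


class TestTmb:
    def test_counts_per_megabase(self, panel):
        muts = pd.DataFrame([_mut("p1", f"G{i}") for i in range(6)])
        assert compute_tmb(muts, panel, "p1") == pytest.approx(6 / 1.21)

    def test_linearity(self, panel):
        muts = pd.DataFrame([_mut("p1", f"G{i}") for i in range(4)])
        doubled = pd.concat([muts, muts.assign(gene=lambda d: d.gene + "b")])
        assert compute_tmb(doubled, panel, "p1") == pytest.approx(
            2 * compute_tmb(muts, panel, "p1"))

    def test_cnv_and_fusion_excluded(self, panel):
        muts = pd.DataFrame([_mut("p1", "EGFR"),
                             _mut("p1", "MET", klass="cnv", vaf=np.nan),
                             _mut("p1", "ALK", klass="fusion", vaf=np.nan)])
        assert compute_tmb(muts, panel, "p1") == pytest.approx(1 / 1.21)
        summ = genomics.genomic_summary(muts, panel)
        assert summ.loc["p1", "mutation_count"] == 3

    def test_unknown_patient(self, panel):
        muts = pd.DataFrame([_mut("p1", "EGFR")])
        with pytest.raises(InputError):
            compute_tmb(muts, panel, "nobody")


class TestMath:
    def test_reference_value(self):
        assert compute_math([0.1, 0.2, 0.3, 0.4, 0.5]) == pytest.approx(49.42)

    def test_no_dispersion(self):
        assert compute_math([0.3, 0.3, 0.3]) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=20),
           st.floats(0.1, 0.9))
    def test_scale_invariance(self, vafs, scale):
        base = compute_math(vafs)
        scaled = compute_math([v * scale for v in vafs])
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_matches_mad_oracle(self, rng):
        v = rng.beta(3, 6, size=25)
        expected = 100 * median_abs_deviation(v, scale="normal") / np.median(v)
        assert compute_math(v) == pytest.approx(expected, rel=1e-3)

    def test_undefined_cases(self):
        assert compute_math([0.2, 0.3]) is None
        assert compute_math([0.0, 0.0, 0.0]) is None


class TestGeneFrequencies:
    def test_published_pik3cg_counts_significant(self):
        # 4 of 53 node-positive vs 1 of 204 node-negative carriers
        rows = ([_mut(f"pos{i}", "PIK3CG") for i in range(4)]
                + [_mut("neg0", "PIK3CG")])
        muts = pd.DataFrame(rows)
        groups = pd.Series({f"pos{i}": 1 for i in range(53)}
                           | {f"neg{i}": 0 for i in range(204)})
        out = genomics.compare_gene_frequencies(muts, groups)
        assert out.loc["PIK3CG", "p_value"] < 0.05

    def test_absent_gene_skipped(self):
        muts = pd.DataFrame([_mut("a", "TP53")])
        groups = pd.Series({"a": 1, "b": 0})
        out = genomics.compare_gene_frequencies(muts, groups,
                                                genes=["TP53", "KRAS"])
        assert "KRAS" not in out.index


class TestCooccurrence:
    def test_perfectly_exclusive_pair(self):
        rows = [_mut(f"p{i}", "EGFR") for i in range(10)] + \
               [_mut(f"p{i}", "KRAS") for i in range(10, 20)]
        out = genomics.cooccurrence_analysis(pd.DataFrame(rows),
                                             [f"p{i}" for i in range(20)],
                                             ["EGFR", "KRAS"])
        assert out.iloc[0]["odds_ratio"] == 0.0
        assert out.iloc[0]["direction"] == "exclusivity"

    def test_planted_cooccurrence_detected(self, rng):
        patients = [f"p{i}" for i in range(120)]
        rows = []
        for p in patients:
            a = rng.random() < 0.4
            b = a if rng.random() < 0.8 else (rng.random() < 0.4)
            if a:
                rows.append(_mut(p, "KEAP1"))
            if b:
                rows.append(_mut(p, "STK11"))
        out = genomics.cooccurrence_analysis(pd.DataFrame(rows), patients,
                                             ["KEAP1", "STK11"])
        assert out.iloc[0]["log_odds"] > 0
        assert out.iloc[0]["p_value"] < 0.05

    def test_monomorphic_gene_skipped(self):
        rows = [_mut("p0", "EGFR"), _mut("p1", "EGFR"), _mut("p0", "TP53")]
        out = genomics.cooccurrence_analysis(pd.DataFrame(rows), ["p0", "p1"],
                                             ["EGFR", "TP53"])
        assert len(out) == 0  # EGFR mutated in all, TP53 is its only partner


class TestPathways:
    def test_universal_tp53_gives_full_p53_frequency(self, panel):
        muts = pd.DataFrame([_mut(f"p{i}", "TP53") for i in range(10)])
        groups = pd.Series({f"p{i}": i % 2 for i in range(10)})
        out = genomics.pathway_alteration_frequency(muts, panel, groups)
        assert out.loc["p53", "freq_0"] == 1.0
        assert out.loc["p53", "freq_1"] == 1.0

    def test_vus_only_patient_not_counted(self, panel):
        muts = pd.DataFrame([_mut("p0", "TP53", onc="vus"),
                             _mut("p1", "TP53")])
        groups = pd.Series({"p0": 0, "p1": 1})
        out = genomics.pathway_alteration_frequency(muts, panel, groups,
                                                    oncogenic_only=True)
        assert out.loc["p53", "freq_0"] == 0.0
        assert out.loc["p53", "freq_1"] == 1.0


def published_actionability_table():
    """Mutation table realizing the printed actionability tallies:
    260 actionable alterations (184 L1, 7 L3A, 23 L3B, 46 L4) over 257
    samples, 216 of them actionable, 180 with L1 as highest level."""
    rows = []
    # 180 samples whose best evidence is L1; 184 L1 alterations in total
    for i in range(180):
        rows.append(_mut(f"s{i:03d}", "EGFR", level="L1"))
    for i in range(4):
        rows.append(_mut(f"s{i:03d}", "BRAF", level="L1"))
    for i in range(180, 187):      # 7 samples topping out at L3A
        rows.append(_mut(f"s{i:03d}", "ERBB2", level="L3A"))
    for i in range(187, 210):      # 23 samples topping out at L3B
        rows.append(_mut(f"s{i:03d}", "PIK3CA", level="L3B"))
    for i in range(210, 216):      # 6 samples topping out at L4
        rows.append(_mut(f"s{i:03d}", "ATM", level="L4"))
    for i in range(40):            # 40 more L4 alterations in L1 samples
        rows.append(_mut(f"s{i:03d}", "PTEN", level="L4"))
    # non-actionable alterations in otherwise empty samples
    for i in range(216, 257):
        rows.append(_mut(f"s{i:03d}", "LRP1B", onc="vus", level="none"))
    return pd.DataFrame(rows), [f"s{i:03d}" for i in range(257)]


class TestActionability:
    def test_published_tallies(self, panel):
        muts, patients = published_actionability_table()
        out = genomics.actionability_summary(muts, panel, patients)
        assert out["total_actionable_alterations"] == 260
        assert out["alterations_by_level"] == {"L1": 184, "L3A": 7,
                                               "L3B": 23, "L4": 46}
        assert out["n_actionable_samples"] == 216
        assert out["samples_by_level"]["L1"] == 180
        assert out["pct_level1_alterations"] == pytest.approx(100 * 184 / 260)
        assert out["pct_actionable_samples"] == pytest.approx(100 * 216 / 257)
        assert out["pct_level1_samples"] == pytest.approx(100 * 180 / 216)

    def test_highest_level_rule(self, panel):
        muts = pd.DataFrame([_mut("p0", "PIK3CA", level="L3B"),
                             _mut("p0", "EGFR", level="L1")])
        out = genomics.actionability_summary(muts, panel, ["p0"])
        assert out["sample_highest_level"]["p0"] == "L1"

    def test_counts_partition_alterations(self, panel):
        muts, patients = published_actionability_table()
        out = genomics.actionability_summary(muts, panel, patients)
        assert sum(out["alterations_by_level"].values()) == \
            out["total_actionable_alterations"]
        assert sum(out["samples_by_level"].values()) == out["n_actionable_samples"]

    def test_unknown_level_rejected(self, panel):
        muts = pd.DataFrame([_mut("p0", "EGFR", level="L2")])
        with pytest.raises(InputError):
            genomics.actionability_summary(muts, panel, ["p0"])


class TestPropensityMatch:
    def _table(self, n_case, n_ctrl, case_shift=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for i in range(n_case):
            rows.append({"patient_id": f"c{i}", "case": 1,
                         "age": 60 + case_shift + rng.normal(0, 5),
                         "male": int(rng.random() < 0.5)})
        for i in range(n_ctrl):
            rows.append({"patient_id": f"k{i}", "case": 0,
                         "age": 60 + rng.normal(0, 5),
                         "male": int(rng.random() < 0.5)})
        return pd.DataFrame(rows)

    def test_identical_covariates_all_matched(self):
        t = self._table(5, 5)
        t["age"] = 60.0
        t["male"] = 1
        out = genomics.propensity_match(t, "case", ["age", "male"])
        assert out["control_id"].notna().sum() == 5

    def test_extreme_case_unmatched(self, rng):
        t = self._table(4, 20, rng=rng)
        t.loc[t["patient_id"] == "c0", "age"] = 200.0  # far outside caliper
        out = genomics.propensity_match(t, "case", ["age"], rng=rng)
        row = out[out["case_id"] == "c0"].iloc[0]
        assert pd.isna(row["control_id"])

    def test_matching_reduces_imbalance(self, rng):
        t = self._table(30, 120, case_shift=4.0, rng=rng)
        out = genomics.propensity_match(t, "case", ["age", "male"], rng=rng)
        matched = out.dropna(subset=["control_id"])
        tt = t.set_index("patient_id")
        for cov in ("age",):
            pre = genomics.standardized_mean_difference(
                tt.loc[tt["case"] == 1, cov], tt.loc[tt["case"] == 0, cov])
            post = genomics.standardized_mean_difference(
                tt.loc[matched["case_id"], cov], tt.loc[matched["control_id"], cov])
            assert abs(post) < abs(pre)
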