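import numpy as np
import pandas as pd
import pytest

from cistroshift.cistrome import (SignificanceThresholds, call_significant,
                                  classify_mono_vs_co, classify_trend,
                                  factor_coupling_stats, overlap_partition,
                                  status_counts)
from conftest import tiny_matrix


class TestCallSignificant:
    @pytest.mark.parametrize("intensity,log2fc,fdr,expected", [
        (4.0, 1.0, 0.05, True),    # all bounds inclusive
        (3.99, 2.0, 0.001, False),  # intensity below floor
        (6.0, 0.99, 0.001, False),
        (6.0, 2.0, 0.051, False),
    ])
    def test_inclusive_boundaries(self, intensity, log2fc, fdr, expected):
        mat = tiny_matrix([("w1", {("GR", "bud"): {
            "intensity": intensity, "log2fc": log2fc, "fdr": fdr}})])
        got = call_significant(mat, "GR", "bud")
        assert ("w1" in got) is expected

    def test_missing_column_raises(self):
        mat = tiny_matrix([("w1", {("GR", "bud"): {}})])
        with pytest.raises(KeyError):
            call_significant(mat, "RELA", "il1b")

    def test_equals_brute_force_filter(self, small_matrix):
        thr = SignificanceThresholds()
        got = call_significant(small_matrix, "GR", "co", thr)
        expected = set()
        for r in small_matrix.df.itertuples(index=False):
            if (r.GR_co_intensity >= thr.min_intensity
                    and r.GR_co_log2fc >= thr.min_log2fc
                    and r.GR_co_fdr <= thr.max_fdr):
                expected.add(r.window_id)
        assert got == expected
        assert len(got) > 0


class TestClassifyMonoVsCo:
    def test_set_algebra(self):
        cls = classify_mono_vs_co({"a", "b"}, {"b", "c"})
        got = cls.set_index("window_id")["status"].to_dict()
        assert got == {"a": "lost", "b": "maintained", "c": "gained"}

    def test_identical_sets_all_maintained(self):
        cls = classify_mono_vs_co({"a", "b"}, {"a", "b"})
        assert (cls["status"] == "maintained").all()

    def test_published_counts(self, published_matrix):
        """The worked-example fixture reproduces the published GBR
        arithmetic: 6,479 mono, 7,005 co, 1,216 lost => 5,263 maintained,
        1,742 gained, union 8,221."""
        g = classify_mono_vs_co(
            call_significant(published_matrix, "GR", "bud"),
            call_significant(published_matrix, "GR", "co"))
        assert status_counts(g) == {
            "mono": 6479, "co": 7005, "lost": 1216, "maintained": 5263,
            "gained": 1742, "union": 8221}

    def test_count_identities(self, small_matrix):
        g = classify_mono_vs_co(call_significant(small_matrix, "GR", "bud"),
                                call_significant(small_matrix, "GR", "co"))
        c = status_counts(g)
        assert c["lost"] + c["maintained"] == c["mono"]
        assert c["gained"] + c["maintained"] == c["co"]
        assert c["union"] == c["lost"] + c["maintained"] + c["gained"]


class TestClassifyTrend:
    def _mat(self, mono_i, co_i):
        return tiny_matrix([("w1", {
            ("GR", "bud"): {"intensity": mono_i, "log2fc": 2, "fdr": 0.01},
            ("GR", "co"): {"intensity": co_i, "log2fc": 2, "fdr": 0.01}})])

    @pytest.mark.parametrize("delta,expected", [
        (-0.5, "decreasing"),   # inclusive lower bound
        (-0.49, "unchanged"),
        (0.49, "unchanged"),
        (0.5, "increasing"),    # inclusive upper bound
    ])
    def test_boundaries(self, delta, expected):
        tr = classify_trend(self._mat(6.0, 6.0 + delta), "GR", "bud", "co")
        assert tr.loc[0, "trend"] == expected
        assert tr.loc[0, "delta"] == pytest.approx(delta)

    def test_trend_partitions_union(self, small_matrix):
        tr = classify_trend(small_matrix, "GR", "bud", "co")
        union = (call_significant(small_matrix, "GR", "bud")
                 | call_significant(small_matrix, "GR", "co"))
        assert set(tr["window_id"]) == union
        assert set(tr["trend"]) <= {"decreasing", "unchanged", "increasing"}


class TestOverlapPartition:
    def test_published_partition(self, published_matrix):
        """Reproduces the published loss/gain splits: GR loss 22.3% at
        non-overlapping vs 2.6% at overlapping mono windows, RELA loss
        24.4%, gains 11.5% / 41.7% and 33.8%, co-overlap shares
        63.8% (RELA) and 44.3% (GR, printed as 44.4)."""
        g = classify_mono_vs_co(
            call_significant(published_matrix, "GR", "bud"),
            call_significant(published_matrix, "GR", "co"))
        r = classify_mono_vs_co(
            call_significant(published_matrix, "RELA", "il1b"),
            call_significant(published_matrix, "RELA", "co"))
        part = overlap_partition(g, r)
        assert part["mono_overlap"] == 1163
        assert part["co_overlap"] == 3106
        gl = part["G"]["loss"]
        assert (gl["non_overlapping"], gl["event_non_overlapping"]) == (5316, 1186)
        assert gl["pct_non_overlapping"] == 22.3
        assert (gl["overlapping"], gl["event_overlapping"]) == (1163, 30)
        assert gl["pct_overlapping"] == 2.6
        rl = part["R"]["loss"]
        assert rl["pct_non_overlapping"] == 24.4
        assert rl["event_overlapping"] == 141
        # both candidate denominators for the ambiguous published 4.5%
        assert rl["pct_overlapping"] == 12.1
        assert rl["pct_overlapping_alt_co_denominator"] == 4.5
        gg = part["G"]["gain"]
        assert (gg["pct_non_overlapping"], gg["pct_overlapping"]) == (11.5, 41.7)
        assert part["R"]["gain"]["pct_overlapping"] == 33.8
        assert part["co_overlap_share_of_R"] == 63.8
        assert part["co_overlap_share_of_G"] == 44.3
        assert abs(part["co_overlap_share_of_G"] - 44.4) <= 0.1 + 1e-9

    def test_disjoint_cistromes_undefined_percentages(self):
        g = classify_mono_vs_co({"a", "b"}, {"a"})
        r = classify_mono_vs_co({"x"}, {"x", "y"})
        part = overlap_partition(g, r)
        assert part["mono_overlap"] == 0 and part["co_overlap"] == 0
        assert part["G"]["loss"]["pct_overlapping"] is None

    def test_symmetry_of_overlap(self, small_matrix):
        g = classify_mono_vs_co(call_significant(small_matrix, "GR", "bud"),
                                call_significant(small_matrix, "GR", "co"))
        r = classify_mono_vs_co(
            call_significant(small_matrix, "RELA", "il1b"),
            call_significant(small_matrix, "RELA", "co"))
        assert (overlap_partition(g, r)["mono_overlap"]
                == overlap_partition(r, g)["mono_overlap"])


class TestFactorCoupling:
    def test_planted_coupling_recovered(self):
        from dataclasses import replace

        from cistroshift.simulate import SimConfig, simulate_cistromes

        cfg = SimConfig(seed=9, n_windows=5000, coupling_slope_gr=0.4,
                        coupling_slope_rela=0.0)
        mat = simulate_cistromes(cfg)
        tr = classify_trend(mat, "GR", "bud", "co")
        rep = factor_coupling_stats(mat, tr, "GR", "RELA")
        assert rep["correlation"]["spearman_rho"] > 0
        assert rep["correlation"]["p"] < 0.01
        assert {"group_tests", "correlation", "rnap2"} <= set(rep)

    def test_shuffled_other_factor_kills_correlation(self):
        from cistroshift.io import CistromeMatrix
        from cistroshift.simulate import SimConfig, simulate_cistromes

        cfg = SimConfig(seed=10, n_windows=5000, coupling_slope_gr=0.4,
                        coupling_slope_rela=0.0)
        mat = simulate_cistromes(cfg)
        rng = np.random.default_rng(0)
        df = mat.df.copy()
        col = CistromeMatrix.col("RELA", "co", "intensity")
        df[col] = rng.permutation(df[col].to_numpy())
        shuffled = CistromeMatrix(df, width=mat.width)
        tr = classify_trend(shuffled, "GR", "bud", "co")
        rep = factor_coupling_stats(shuffled, tr, "GR", "RELA")
        assert abs(rep["correlation"]["spearman_rho"]) < 0.05

    def test_rnap2_table_emitted(self, small_matrix):
        tr = classify_trend(small_matrix, "GR", "bud", "co")
        rep = factor_coupling_stats(small_matrix, tr, "GR", "RELA",
                                    rnap2_factor="RNAP2")
        tab = rep["rnap2"]
        assert tab is not None
        assert (tab["test"] == "kruskal").any()
        assert (tab["test"] == "pairwise").any()
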