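import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cistroshift.proximity import (DistanceProfile, distance_profile_compare,
                                   distance_trend, generate_random_regions,
                                   nearest_region_distance, protection_test)


def tss_frame(positions):
    return pd.DataFrame([(f"g{i}", c, p) for i, (c, p) in enumerate(positions)],
                        columns=["gene_id", "chrom", "pos"])


def region_frame(intervals):
    return pd.DataFrame([(f"r{i}", c, s, e)
                         for i, (c, s, e) in enumerate(intervals)],
                        columns=["window_id", "chrom", "start", "end"])


def brute_force_distance(tss, regions):
    out = {}
    for t in tss.itertuples(index=False):
        best = None
        for r in regions.itertuples(index=False):
            if r.chrom != t.chrom:
                continue
            if r.start <= t.pos < r.end:
                d = 0
            elif r.start > t.pos:
                d = r.start - t.pos
            else:
                d = t.pos - r.end + 1
            best = d if best is None else min(best, d)
        out[t.gene_id] = np.nan if best is None else best
    return out


class TestNearestRegionDistance:
    def test_reference_conventions(self):
        tss = tss_frame([("chr1", 1000), ("chr1", 1550), ("chr1", 2000),
                         ("chr1", 1600), ("chr2", 5)])
        regions = region_frame([("chr1", 1500, 1600)])
        prof = nearest_region_distance(tss, regions)
        d = prof.df.set_index("gene_id")["distance"]
        assert d["g0"] == 500     # downstream: start - pos
        assert d["g1"] == 0       # inside
        assert d["g2"] == 401     # upstream: pos - end + 1
        assert d["g3"] == 1       # bookended
        assert np.isnan(d["g4"])  # no region on chromosome

    def test_matches_bedtools_closest(self, tmp_path):
        rng = np.random.default_rng(4)
        tss = tss_frame([("chr1", int(p)) for p in
                         np.sort(rng.integers(0, 10**6, 60))])
        regions = region_frame(sorted(
            ("chr1", int(s), int(s) + 400)
            for s in rng.integers(0, 10**6, 25)))
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        a.write_text("".join(f"{r.chrom}\t{r.pos}\t{r.pos+1}\t{r.gene_id}\n"
                             for r in tss.itertuples(index=False)))
        b.write_text("".join(f"{r.chrom}\t{r.start}\t{r.end}\t{r.window_id}\n"
                             for r in regions.itertuples(index=False)))
        out = subprocess.run(["bedtools", "closest", "-a", a, "-b", b, "-d"],
                             capture_output=True, text=True, check=True)
        expected = {}
        for line in out.stdout.splitlines():
            f = line.split("\t")
            expected.setdefault(f[3], int(f[-1]))
        prof = nearest_region_distance(tss, regions)
        got = prof.df.set_index("gene_id")["distance"].astype(int).to_dict()
        assert got == expected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_with_overlapping_regions(self, seed):
        rng = np.random.default_rng(seed)
        chroms = ["chr1", "chr2"]
        tss = tss_frame([(rng.choice(chroms), int(rng.integers(0, 10**5)))
                         for _ in range(300)])
        regions = region_frame([
            (rng.choice(chroms), int(s), int(s) + int(rng.integers(50, 5000)))
            for s in rng.integers(0, 10**5, 80)])
        prof = nearest_region_distance(tss, regions)
        got = prof.df.set_index("gene_id")["distance"].to_dict()
        bf = brute_force_distance(tss, regions)
        for g, v in bf.items():
            assert (np.isnan(v) and np.isnan(got[g])) or got[g] == v

    def test_empty_region_set_warns(self):
        with pytest.warns(UserWarning):
            prof = nearest_region_distance(tss_frame([("chr1", 5)]),
                                           region_frame([]))
        assert prof.df["distance"].isna().all()


class TestRandomRegions:
    def test_deterministic_under_seed(self):
        sizes = {"chr1": 10**6, "chr2": 5 * 10**5}
        a = generate_random_regions(100, sizes, 400, seed=5)
        b = generate_random_regions(100, sizes, 400, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = generate_random_regions(100, sizes, 400, seed=6)
        assert not a.equals(c)

    def test_count_width_and_exclusion(self):
        regs = generate_random_regions(50, {"chr1": 10**6, "tiny": 100},
                                       400, seed=0)
        assert len(regs) == 50
        assert ((regs["end"] - regs["start"]) == 400).all()
        assert set(regs["chrom"]) == {"chr1"}

    def test_mean_nearest_distance_matches_uniform_spacing(self):
        # a uniform query point lands in a size-biased gap between the n
        # uniform regions; the mean distance to the nearer flank is of order
        # L/(2(n+1)) (E[g^2]/(4 E[g]) with near-exponential gaps)
        L, n, w = 10**8, 10**4, 400
        regs = generate_random_regions(n, {"chr1": L}, w, seed=1)
        rng = np.random.default_rng(2)
        tss = tss_frame([("chr1", int(p)) for p in rng.integers(0, L, 3000)])
        prof = nearest_region_distance(tss, regs)
        got = prof.df["distance"].mean()
        expected = L / (2 * (n + 1))
        assert abs(got - expected) / expected < 0.05


class TestDistanceProfileCompare:
    def test_planted_proximity_detected(self):
        rng = np.random.default_rng(7)
        regions = region_frame([("chr1", int(s), int(s) + 400)
                                for s in rng.integers(0, 10**8, 200)])
        near_pos = [("chr1", int(regions.loc[i % 200, "end"]
                                 + rng.integers(0, 10_000)))
                    for i in range(150)]
        rnd_pos = [("chr1", int(p)) for p in rng.integers(0, 10**8, 150)]
        prof_near = nearest_region_distance(tss_frame(near_pos), regions, "up")
        prof_rand = nearest_region_distance(tss_frame(rnd_pos), regions,
                                            "random")
        rep = distance_profile_compare({"up": prof_near}, prof_rand)
        row = rep.iloc[0]
        assert row["mean"] < row["random_mean"] / 5
        assert row["ks_p"] < 0.01

    def test_identical_profiles_ks_zero(self):
        regions = region_frame([("chr1", 1000, 1400)])
        prof = nearest_region_distance(tss_frame([("chr1", 100)] * 5), regions)
        rep = distance_profile_compare({"x": prof}, prof)
        assert rep.iloc[0]["ks_stat"] == 0

    def test_empty_class_noted(self):
        regions = region_frame([("chr1", 1000, 1400)])
        prof = nearest_region_distance(tss_frame([]), regions)
        rep = distance_profile_compare({"x": prof}, prof)
        assert rep.iloc[0]["note"] == "no genes"


def planted_protection(rng, n_per_group=300, delta=1.0, sd=0.5):
    """Near-group deltas N(-1.5 + delta, sd), far N(-1.5, sd)."""
    genes = [f"g{i}" for i in range(2 * n_per_group)]
    deltas = pd.DataFrame({
        "gene_id": genes,
        "delta": np.concatenate([
            rng.normal(-1.5 + delta, sd, n_per_group),
            rng.normal(-1.5, sd, n_per_group)])})
    dist = np.concatenate([rng.uniform(0, 30_000, n_per_group),
                           rng.uniform(45_000, 150_000, n_per_group)])
    prof = DistanceProfile(pd.DataFrame({
        "gene_id": genes, "chrom": "chr1", "pos": 0, "distance": dist}))
    return deltas, prof


class TestProtectionTest:
    def test_planted_effect_detected(self):
        deltas, prof = planted_protection(np.random.default_rng(11))
        res = protection_test(deltas, prof)
        assert res.p_value < 1e-10
        assert res.median_difference == pytest.approx(1.0, abs=0.1)
        assert res.n_near == res.n_far == 300

    def test_null_p_uniform_over_seeds(self):
        ps = []
        for seed in range(60):
            deltas, prof = planted_protection(np.random.default_rng(seed),
                                              n_per_group=100, delta=0.0)
            ps.append(protection_test(deltas, prof).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_undefined_distance_joins_far_group(self):
        deltas = pd.DataFrame({"gene_id": ["a", "b"], "delta": [0.0, -1.0]})
        prof = DistanceProfile(pd.DataFrame({
            "gene_id": ["a", "b"], "chrom": "chr1", "pos": 0,
            "distance": [1000.0, np.nan]}))
        res = protection_test(deltas, prof)
        assert (res.n_near, res.n_far) == (1, 1)

    def test_all_near_gives_undefined_test(self):
        deltas = pd.DataFrame({"gene_id": ["a", "b"], "delta": [0.0, -1.0]})
        prof = DistanceProfile(pd.DataFrame({
            "gene_id": ["a", "b"], "chrom": "chr1", "pos": 0,
            "distance": [100.0, 200.0]}))
        res = protection_test(deltas, prof)
        assert res.p_value is None and res.n_far == 0 and res.n_near == 2

    def test_exclusion_and_nesting_filters(self):
        deltas, prof = planted_protection(np.random.default_rng(12))
        res = protection_test(deltas, prof, exclude={"g0", "g1", "g599"})
        assert res.n_excluded == 3
        assert res.n_near + res.n_far == 597
        nest = DistanceProfile(prof.df.assign(
            distance=np.where(prof.df["gene_id"].str[1:].astype(int) < 450,
                              1000.0, 10**6)))
        res2 = protection_test(deltas, prof, nest_within=(nest, 30_000))
        assert res2.n_outside_nest == 150
        assert res2.n_near + res2.n_far == 450

    def test_groups_partition_filtered_set(self):
        deltas, prof = planted_protection(np.random.default_rng(13))
        res = protection_test(deltas, prof, exclude={"g5"})
        assert res.n_near + res.n_far + res.n_excluded == len(deltas)


class TestDistanceTrend:
    def test_planted_monotone_decay(self):
        rng = np.random.default_rng(14)
        n = 500
        genes = [f"g{i}" for i in range(n)]
        dist = rng.uniform(0, 100_000, n)
        delta = -1.5 - dist / 100_000 + rng.normal(0, 0.3, n)
        deltas = pd.DataFrame({"gene_id": genes, "delta": delta})
        prof = DistanceProfile(pd.DataFrame({
            "gene_id": genes, "chrom": "chr1", "pos": 0, "distance": dist}))
        per_bin, corr = distance_trend(deltas, prof,
                                       bins=[0, 25_000, 50_000, 75_000, 1e6])
        assert corr["spearman_rho"] < 0
        assert corr["p"] < 0.01
        assert (per_bin["median"].diff().dropna() < 0.2).all()

    def test_constant_deltas_rho_zero(self):
        genes = ["a", "b", "c", "d"]
        deltas = pd.DataFrame({"gene_id": genes, "delta": [1.0] * 4})
        prof = DistanceProfile(pd.DataFrame({
            "gene_id": genes, "chrom": "chr1", "pos": 0,
            "distance": [1.0, 2.0, 3.0, 4.0]}))
        _, corr = distance_trend(deltas, prof, bins=[0, 2.5, 5])
        assert corr["spearman_rho"] == 0.0

    def test_hand_computed_bin_medians(self):
        genes = [f"g{i}" for i in range(10)]
        dist = [100, 200, 300, 11_000, 12_000, 13_000, 40_000, 50_000,
                60_000, 70_000]
        delta = [0.1, 0.2, 0.3, -0.5, -0.6, -0.7, -1.0, -1.1, -1.3, -1.5]
        deltas = pd.DataFrame({"gene_id": genes, "delta": delta})
        prof = DistanceProfile(pd.DataFrame({
            "gene_id": genes, "chrom": "chr1", "pos": 0, "distance": dist}))
        per_bin, _ = distance_trend(deltas, prof, bins=[0, 10_000, 30_000, 1e6])
        assert per_bin["median"].tolist() == [0.2, -0.6, pytest.approx(-1.2)]
        assert per_bin["n"].tolist() == [3, 3, 4]
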