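"""Binned track arithmetic, window assignment and the signed-rank test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dsbquant import enrichment as enr
from dsbquant.errors import AlignmentError, ParameterError


def make_track(values, bin_width=50, chrom="chr1", start0=0):
    values = np.asarray(values, float)
    starts = start0 + np.arange(len(values)) * bin_width
    return enr.BinTrack(
        pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + bin_width,
                      "value": values}),
        bin_width,
    )


def make_sites(positions, chrom="chr1", genic=None, scores=None):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "position": list(positions),
            "cleavage_score": scores if scores is not None else np.arange(n, dtype=float),
            "genic": genic if genic is not None else [True] * n,
            "site_id": [f"s{i}" for i in range(n)],
        }
    )


class TestTrackArithmetic:
    def test_rpkm_formula(self):
        t = enr.normalize_track(make_track([5.0]), total_reads=1_000_000)
        assert t.df["value"].iloc[0] == pytest.approx(100.0)

    def test_rpkm_zero_count(self):
        t = enr.normalize_track(make_track([0.0, 3.0]), total_reads=2_000_000)
        assert t.df["value"].iloc[0] == 0.0

    def test_rpkm_matches_direct_formula(self, rng):
        vals = rng.integers(0, 500, 200).astype(float)
        total = 3_456_789
        t = enr.normalize_track(make_track(vals), total)
        expected = vals / ((50 / 1000) * (total / 1e6))
        np.testing.assert_allclose(t.df["value"], expected, rtol=1e-12)

    def test_rpkm_rejects_bad_total(self):
        with pytest.raises(ParameterError):
            enr.normalize_track(make_track([1.0]), 0)

    def test_log2_identical_tracks_all_zero(self, rng):
        vals = rng.uniform(0, 100, 100)
        t = make_track(vals)
        out = enr.log2_ratio_track(t, make_track(vals))
        assert (out.df["value"] == 0.0).all()

    def test_log2_arithmetic(self):
        out = enr.log2_ratio_track(make_track([3.0]), make_track([1.0]), pseudocount=1.0)
        assert out.df["value"].iloc[0] == pytest.approx(1.0)

    def test_log2_antisymmetry_exact(self, rng):
        a, b = make_track(rng.uniform(0, 50, 300)), make_track(rng.uniform(0, 50, 300))
        fwd = enr.log2_ratio_track(a, b).df["value"].to_numpy()
        rev = enr.log2_ratio_track(b, a).df["value"].to_numpy()
        np.testing.assert_array_equal(fwd, -rev)

    def test_log2_matches_per_bin_oracle(self, rng):
        av, bv = rng.uniform(0, 50, 64), rng.uniform(0, 50, 64)
        out = enr.log2_ratio_track(make_track(av), make_track(bv), pseudocount=0.5)
        np.testing.assert_allclose(out.df["value"],
                                   [np.log2((x + 0.5) / (y + 0.5)) for x, y in zip(av, bv)])

    def test_mismatched_grids_raise_alignment_error(self):
        with pytest.raises(AlignmentError, match="mismatch"):
            enr.log2_ratio_track(make_track([1, 2]), make_track([1, 2], start0=25))


class TestSelectTopSites:
    def test_k_equal_table_size_is_identity(self):
        s = make_sites([100, 200, 300])
        out = enr.select_top_sites(s, 3)
        assert set(out["site_id"]) == set(s["site_id"])

    def test_scores_1_to_100_top_50(self):
        s = make_sites(range(1000, 101_000, 1000), scores=np.arange(1.0, 101.0))
        out = enr.select_top_sites(s, 50)
        assert sorted(out["cleavage_score"]) == list(np.arange(51.0, 101.0))

    def test_ties_broken_by_position_matches_sort_oracle(self, rng):
        n = 40
        scores = rng.integers(0, 5, n).astype(float)  # heavy ties
        pos = rng.permutation(n) * 100
        s = make_sites(pos, scores=scores)
        k = 15
        out = enr.select_top_sites(s, k)
        oracle = sorted(
            s.itertuples(index=False),
            key=lambda r: (-r.cleavage_score, r.chrom, r.position),
        )[:k]
        assert out["site_id"].tolist() == [r.site_id for r in oracle]

    def test_k_larger_than_table_returns_all(self):
        s = make_sites([100, 200])
        assert len(enr.select_top_sites(s, 10)) == 2


def brute_force_assign(track, sites, intervals, frac):
    """Quadratic interval-intersection oracle."""
    rows = []
    for site in sites.itertuples(index=False):
        for iv in intervals:
            segs = [(site.position - iv.upper, site.position - iv.lower),
                    (site.position + iv.lower, site.position + iv.upper)]
            for b in track.df.itertuples(index=False):
                if b.chrom != site.chrom:
                    continue
                ov = sum(max(0, min(b.end, hi) - max(b.start, lo)) for lo, hi in segs)
                if ov >= frac * track.bin_width - 1e-9:
                    rows.append((site.site_id, iv.label, b.start))
    return sorted(rows)


class TestAssignBins:
    def test_fully_contained_bin_assigned_to_its_window(self):
        track = make_track(np.ones(200))
        sites = make_sites([5000])
        out = enr.assign_bins(track, sites)
        row = out[(out["start"] == 5700)]
        assert row["interval"].tolist() == ["0.5-1"]

    def test_90_percent_boundary_exact(self):
        # one 50-bp bin overlapping the footprint by exactly 45 bp vs 44 bp
        track = make_track([1.0], start0=955)  # bin [955, 1005)
        iv = [enr.DistanceInterval("0-0.5", 0, 500)]
        assert len(enr.assign_bins(track, make_sites([500]), iv)) == 1  # ov 45
        track44 = make_track([1.0], start0=956)  # bin [956, 1006) -> ov 44
        assert len(enr.assign_bins(track44, make_sites([500]), iv)) == 0

    def test_88_percent_rejected(self):
        track = make_track([1.0], start0=956)
        iv = [enr.DistanceInterval("0-0.5", 0, 500)]
        assert len(enr.assign_bins(track, make_sites([500]), iv, min_overlap_frac=0.88)) == 1
        assert len(enr.assign_bins(track, make_sites([500]), iv, min_overlap_frac=0.9)) == 0

    def test_matches_quadratic_oracle_on_random_configurations(self, rng):
        intervals = enr.default_intervals()
        track = make_track(rng.uniform(-2, 2, 2000),
                           start0=int(rng.integers(0, 49)))
        sites = make_sites(sorted(rng.integers(0, 100_000, 20)))
        out = enr.assign_bins(track, sites, intervals)
        got = sorted(zip(out["site_id"], out["interval"], out["start"]))
        assert got == brute_force_assign(track, sites, intervals, 0.9)

    def test_bin_serves_multiple_sites_but_one_window_each(self):
        track = make_track(np.ones(100))
        sites = make_sites([2000, 3000])
        out = enr.assign_bins(track, sites)
        per_site = out.groupby(["site_id", "start"])["interval"].nunique()
        assert (per_site == 1).all()
        shared = out.groupby("start")["site_id"].nunique()
        assert (shared > 1).any()


class TestSiteIntervalMeans:
    def test_single_and_mean_values(self):
        df = pd.DataFrame({
            "site_id": ["s0", "s1", "s1"],
            "interval": ["0-0.5", "0-0.5", "0-0.5"],
            "value": [2.0, 1.0, 3.0],
        })
        out = enr.site_interval_means(df)
        assert out.set_index("site_id").loc["s0", "mean_log2"] == 2.0
        assert out.set_index("site_id").loc["s1", "mean_log2"] == 2.0
        assert out.set_index("site_id").loc["s1", "n_bins"] == 2

    def test_matches_groupby_oracle(self, rng):
        df = pd.DataFrame({
            "site_id": rng.choice(["a", "b", "c"], 100),
            "interval": rng.choice(["0-0.5", "1-1.5"], 100),
            "value": rng.normal(size=100),
        })
        out = enr.site_interval_means(df).set_index(["site_id", "interval"])
        for (sid, iv), grp in df.groupby(["site_id", "interval"]):
            assert out.loc[(sid, iv), "mean_log2"] == pytest.approx(grp["value"].mean())
            assert out.loc[(sid, iv), "n_bins"] == len(grp)


def enumerate_signed_rank_p(values, alternative="two-sided"):
    """Full 2^n enumeration of the signed-rank null (no ties, no zeros)."""
    from scipy.stats import rankdata

    d = np.asarray(values, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, float)
    if alternative == "greater":
        return float((ws >= w_obs).mean())
    if alternative == "less":
        return float((ws <= w_obs).mean())
    p = 2 * min((ws >= w_obs).mean(), (ws <= w_obs).mean())
    return float(min(1.0, p))


class TestSignedRank:
    def test_all_zero_differences_withheld(self):
        res = enr.signed_rank_test([0.0, 0.0, 0.0])
        assert np.isnan(res.p_value) and res.n_used == 0

    def test_five_positive_values_extreme_ranking(self):
        one_sided = enr.signed_rank_test([0.3, 1.0, 2.0, 0.1, 5.0], alternative="greater")
        assert one_sided.p_value == pytest.approx(1 / 32)
        two_sided = enr.signed_rank_test([0.3, 1.0, 2.0, 0.1, 5.0])
        assert two_sided.p_value == pytest.approx(2 / 32)
        assert two_sided.method == "exact"

    @pytest.mark.parametrize("n", range(4, 11))
    def test_exact_branch_equals_full_enumeration(self, n, rng):
        for _ in range(10):
            vals = rng.normal(0.3, 1.0, n)
            res = enr.signed_rank_test(vals)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(enumerate_signed_rank_p(vals), abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        res = enr.signed_rank_test(rng.normal(0.2, 1.0, 60))
        assert res.method == "normal-approx"
        assert 0 <= res.p_value <= 1


class TestStratifyAndTest:
    def test_small_windows_withheld_and_strata_split(self):
        enrich = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(6)] + ["s0", "s1"],
            "interval": ["0-0.5"] * 6 + ["1-1.5"] * 2,
            "mean_log2": [0.5, 0.7, 0.6, 0.9, 0.8, 0.4, 1.0, 1.2],
            "n_bins": 10,
        })
        sites = make_sites(range(0, 6000, 1000),
                           genic=[True, True, True, False, False, False])
        out = enr.stratify_and_test(enrich, sites)
        allrow = out[(out.stratum == "all") & (out.interval == "0-0.5")].iloc[0]
        assert allrow["tested"] and allrow["n_sites"] == 6
        # genic stratum has only 3 sites in that window -> withheld
        grow = out[(out.stratum == "genic") & (out.interval == "0-0.5")].iloc[0]
        assert not grow["tested"] and np.isnan(grow["p_value"])
        sparse = out[(out.stratum == "all") & (out.interval == "1-1.5")].iloc[0]
        assert not sparse["tested"]

    def test_bonferroni_caps_at_one(self):
        enrich = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(6)],
            "interval": ["0-0.5"] * 6,
            "mean_log2": [0.5, -0.4, 0.3, -0.2, 0.1, 0.6],
            "n_bins": 10,
        })
        sites = make_sites(range(0, 6000, 1000))
        out = enr.stratify_and_test(enrich, sites, bonferroni=True)
        tested = out[out["tested"]]
        assert (tested["p_adjusted"] <= 1.0).all()
        assert (tested["p_adjusted"] >= tested["p_value"]).all()


class TestIO:
    def test_bedgraph_round_trip(self, tmp_path, rng):
        t = make_track(rng.uniform(0, 10, 30))
        p = tmp_path / "t.bedgraph"
        enr.write_bedgraph(t, p)
        back = enr.read_bedgraph(p)
        assert back.bin_width == 50
        np.testing.assert_allclose(back.df["value"], t.df["value"], rtol=1e-9)

    def test_sites_bed_round_trip(self, tmp_path):
        s = make_sites([1000, 2000], genic=[True, False], scores=[7.0, 3.0])
        p = tmp_path / "s.bed"
        enr.write_sites_bed(s, p)
        back = enr.read_sites_bed(p)
        assert back["position"].tolist() == [1000, 2000]
        assert back["genic"].tolist() == [True, False]
        assert back["cleavage_score"].tolist() == [7.0, 3.0]
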