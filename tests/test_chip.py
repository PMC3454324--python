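"""Tiling-array normalization, probe statistics, smoothing and region calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hrescan.chip import (EnrichedRegion, ProbeTrack, benjamini_hochberg,
                          call_regions, normalize_track, null_threshold,
                          probe_statistics, smooth_signal)

from conftest import brute_force_bh


def make_track(values, spacing=80, chrom="chr1", replicates=None):
    """Track with given replicate-mean values (split into 2 replicates)."""
    n = len(values) if values is not None else len(replicates[0])
    starts = np.arange(n) * spacing
    df = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "chrom": chrom, "start": starts, "end": starts + 50,
    })
    if replicates is None:
        df["r1"] = np.asarray(values, dtype=float)
        df["r2"] = np.asarray(values, dtype=float)
    else:
        for j, rep in enumerate(replicates):
            df[f"r{j + 1}"] = rep
    return ProbeTrack(df)


class TestNormalize:
    def test_none_is_identity(self):
        track = make_track([1.0, 2.0, 3.0])
        assert normalize_track(track, "none") is track

    def test_glog_centers_each_replicate(self):
        rng = np.random.default_rng(0)
        track = make_track(rng.normal(2, 1, 200))
        out = normalize_track(track, "glog")
        for col in out.replicate_columns:
            assert abs(np.median(out.probes[col])) < 1e-9

    def test_quantile_makes_scaled_copies_identical(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 100)
        track = make_track(None, replicates=[base, 3.0 * base])
        out = normalize_track(track, "quantile")
        X = out.probes[["r1", "r2"]].to_numpy()
        assert np.allclose(X[:, 0], X[:, 1])
        # and rank order preserved
        assert np.all(np.argsort(X[:, 0]) == np.argsort(base))

    def test_single_replicate_rejected(self):
        df = make_track([1.0, 2.0]).probes.drop(columns=["r2"])
        with pytest.raises(ValueError):
            normalize_track(ProbeTrack(df), "glog")


class TestProbeStatistics:
    def test_all_zero_probe_p_one(self):
        rng = np.random.default_rng(2)
        reps = [rng.normal(0.5, 0.2, 50) for _ in range(4)]
        for r in reps:
            r[0] = 0.0
        track = make_track(None, replicates=reps)
        out = probe_statistics(track, shrink=False)
        assert out.probes["pvalue"].iloc[0] == 1.0

    def test_too_few_replicates_flagged(self):
        reps = [np.array([1.0, 2.0]), np.array([np.nan, 2.1]),
                np.array([np.nan, 1.9])]
        track = make_track(None, replicates=reps)
        out = probe_statistics(track, shrink=False)
        assert bool(out.probes["flagged"].iloc[0])
        assert out.probes["pvalue"].iloc[0] == 1.0

    def test_bh_hand_example(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=60))
    def test_bh_matches_brute_force_oracle(self, pvals):
        assert np.allclose(benjamini_hochberg(np.array(pvals)),
                           brute_force_bh(pvals), atol=1e-12)

    def test_equal_variance_limit_constant_posterior(self):
        # identical sample variances: full shrinkage, posterior variance
        # constant, ranking identical to the plain t statistic
        rng = np.random.default_rng(3)
        means = rng.normal(0, 1, 40)
        devs = np.array([-1.0, 0.0, 1.0]) * 0.3
        reps = [means + devs[j] for j in range(3)]
        track = make_track(None, replicates=reps)
        shrunk = probe_statistics(track, shrink=True).probes["pvalue"]
        plain = probe_statistics(track, shrink=False).probes["pvalue"]
        assert np.all(np.argsort(shrunk.to_numpy(), kind="stable")
                      == np.argsort(plain.to_numpy(), kind="stable"))

    def test_shrinkage_tames_small_variance_outliers(self):
        rng = np.random.default_rng(4)
        reps = [rng.normal(0, 1, 500) for _ in range(4)]
        # one probe with tiny variance and tiny mean
        for j, r in enumerate(reps):
            r[0] = 0.01 + 1e-6 * j
        track = make_track(None, replicates=reps)
        p_shrunk = probe_statistics(track, shrink=True).probes["pvalue"].iloc[0]
        p_plain = probe_statistics(track, shrink=False).probes["pvalue"].iloc[0]
        assert p_shrunk > p_plain


class TestSmoothing:
    def test_isolated_probe_keeps_own_value(self):
        track = make_track([1.0, 5.0], spacing=10_000)
        out = smooth_signal(track)
        assert out.probes["smoothed"].tolist() == [1.0, 5.0]

    def test_three_probe_window_quantile(self):
        track = make_track([1.0, 2.0, 3.0], spacing=80)
        out = smooth_signal(track, winHalfSize=100, quant=0.75)
        # middle probe sees (1, 2, 3): 0.75-quantile = 2.5 (linear interp.)
        assert out.probes["smoothed"].iloc[1] == 2.5
        # edge probes see two neighbors each
        assert out.probes["smoothed"].iloc[0] == np.quantile([1.0, 2.0], 0.75)

    def test_constant_track_invariant(self):
        track = make_track([2.0] * 30)
        out = smooth_signal(track)
        assert np.allclose(out.probes["smoothed"], 2.0)

    def test_windows_respect_chromosomes(self):
        df1 = make_track([0.0] * 5).probes
        df2 = make_track([10.0] * 5).probes
        df2["chrom"] = "chr2"
        df2["probe_id"] = [f"q{i}" for i in range(5)]
        out = smooth_signal(ProbeTrack(pd.concat([df1, df2])))
        assert set(out.probes.groupby("chrom")["smoothed"].mean()) == {0.0, 10.0}


class TestNullThreshold:
    def test_symmetric_matches_empirical_quantile(self):
        rng = np.random.default_rng(5)
        track = make_track(rng.normal(0, 1, 5000))
        track.probes["smoothed"] = track.probes["r1"]
        t_mode = null_threshold(track, q=0.99)
        t_emp = float(np.quantile(track.probes["smoothed"], 0.99))
        # mode-reflection reproduces the empirical bound up to roughly
        # twice the intrinsic mode-estimation noise (~0.2 SD at n=5000)
        assert abs(t_mode - t_emp) < 0.5
        assert t_mode > 2.0

    def test_planted_positives_barely_move_threshold(self):
        rng = np.random.default_rng(6)
        clean = rng.normal(0, 1, 5000)
        spiked = clean.copy()
        spiked[:250] += 6.0  # 5% strongly bound probes
        t0 = null_threshold(_smoothed_track(clean))
        t1 = null_threshold(_smoothed_track(spiked))
        assert abs(t1 - t0) < 0.35  # far less than the +6 shift

    def test_median_of_null_near_mode(self):
        rng = np.random.default_rng(7)
        track = _smoothed_track(rng.normal(3.0, 0.5, 4000))
        t = null_threshold(track, q=0.5)
        assert abs(t - 3.0) < 0.15

    def test_constant_values_warn(self):
        track = _smoothed_track(np.full(10, 1.5))
        with pytest.warns(UserWarning):
            assert null_threshold(track) == 1.5


def _smoothed_track(values):
    track = make_track(values)
    track.probes["smoothed"] = np.asarray(values, dtype=float)
    return track


class TestCallRegions:
    def track_with(self, smoothed, adj_p=None, spacing=80):
        track = make_track(smoothed, spacing=spacing)
        track.probes["smoothed"] = np.asarray(smoothed, dtype=float)
        track.probes["adj_pvalue"] = (np.ones(len(smoothed)) if adj_p is None
                                      else np.asarray(adj_p, dtype=float))
        return track

    def test_four_probes_with_gated_p_make_one_region(self):
        smoothed = [0, 0, 1, 1, 1, 1, 0, 0]
        adj_p = [1, 1, 1, 0.001, 1, 1, 1, 1]
        regions = call_regions(self.track_with(smoothed, adj_p), threshold=0.5)
        assert len(regions) == 1
        assert regions[0].n_probes == 4 and regions[0].best_adj_p == 0.001

    def test_three_probes_insufficient(self):
        smoothed = [0, 0, 1, 1, 1, 0, 0, 0]
        adj_p = [1, 1, 0.001, 0.001, 0.001, 1, 1, 1]
        assert call_regions(self.track_with(smoothed, adj_p), 0.5) == []

    def test_gap_over_cutoff_splits_runs(self):
        # 8 above-threshold probes, fifth displaced so the center gap > 200
        starts = [0, 80, 160, 240, 500, 580, 660, 740]
        df = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(8)], "chrom": "chr1",
            "start": starts, "end": [s + 50 for s in starts],
            "r1": 1.0, "r2": 1.0,
            "smoothed": 1.0, "adj_pvalue": 0.001,
        })
        regions = call_regions(ProbeTrack(df), 0.5, min_total_probes=4)
        assert len(regions) == 2
        assert all(r.n_probes == 4 for r in regions)

    def test_p_gate_required(self):
        smoothed = [0, 1, 1, 1, 1, 0]
        regions = call_regions(self.track_with(smoothed), 0.5)  # all adj_p = 1
        assert regions == []

    def test_total_probe_coverage_filter(self):
        # isolated cluster of 4 probes with nothing nearby: total = 4 < 8
        starts = [0, 80, 160, 240]
        df = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(4)], "chrom": "chr1",
            "start": starts, "end": [s + 50 for s in starts],
            "r1": 1.0, "r2": 1.0, "smoothed": 1.0, "adj_pvalue": 0.001,
        })
        assert call_regions(ProbeTrack(df), 0.5) == []
        assert len(call_regions(ProbeTrack(df), 0.5, min_total_probes=4)) == 1

    def test_regions_disjoint_sorted_and_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        smoothed = rng.normal(0, 1, 400)
        smoothed[100:110] += 4
        smoothed[200:212] += 4
        adj_p = np.where(smoothed > 2, 0.001, 1.0)
        track = self.track_with(smoothed.tolist(), adj_p.tolist())
        hi = call_regions(track, 2.0)
        lo = call_regions(track, 1.0)
        for regs in (hi, lo):
            ordered = sorted(regs, key=lambda r: r.start)
            for a, b in zip(ordered, ordered[1:]):
                assert a.end <= b.start
        # every probe covered at the high threshold stays covered at the low
        def covered(regs):
            return set().union(*[set(range(r.start, r.end)) for r in regs]) \
                if regs else set()
        assert covered(hi) <= covered(lo)

    def test_ranking_by_best_p_then_signal(self):
        smoothed = [1, 1, 1, 1, 0, 0, 2, 2, 2, 2]
        adj_p = [0.01, 1, 1, 1, 1, 1, 0.001, 1, 1, 1]
        regions = call_regions(self.track_with(smoothed, adj_p), 0.5,
                               min_total_probes=4)
        assert [r.rank for r in regions] == [1, 2]
        assert regions[0].best_adj_p == 0.001
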