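"""Positioning statistics, occupancy, filters, and the genome partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nucmut import nucstats
from nucmut.io import GenomicInterval, ValidationError
from nucmut.nucstats import FragmentMidpointSet


def mids(*positions, chrom="c"):
    return FragmentMidpointSet({chrom: np.array(sorted(positions))})


def brute_force_stats(site, midpoint_array, window=95):
    """Independent oracle: scan every midpoint, no sorted-array shortcuts."""
    d = []
    for m in midpoint_array:
        if abs(int(m) - site) <= window:
            d.append(abs(int(m) - site))
    d = np.array(d, dtype=float)
    if len(d) == 0:
        return 0, np.nan, np.nan
    d_var = float(np.var(d, ddof=1)) if len(d) >= 2 else np.nan
    return len(d), float(np.mean(d)), d_var


class TestSitePositioningStats:
    def test_worked_example(self):
        st_ = nucstats.site_positioning_stats("c", 100, mids(90, 100, 120))
        assert (st_.n, st_.d_mean, st_.d_var) == (3, 10.0, 100.0)

    def test_zero_variance_when_all_distances_equal(self):
        st_ = nucstats.site_positioning_stats("c", 100, mids(70, 70, 130, 130))
        assert st_.d_var == 0.0 and st_.d_mean == 30.0

    def test_window_bound_is_closed_at_95(self):
        st_ = nucstats.site_positioning_stats("c", 100, mids(5, 195, 4, 196))
        assert st_.n == 2 and st_.d_mean == 95.0

    def test_too_few_midpoints_not_usable(self):
        st_ = nucstats.site_positioning_stats("c", 100, mids(*range(90, 99)))
        assert st_.n == 9 and not st_.usable
        st_ = nucstats.site_positioning_stats("c", 100, mids(*range(90, 100)))
        assert st_.n == 10 and st_.usable

    def test_empty_and_single_windows_are_missing_not_zero(self):
        st_ = nucstats.site_positioning_stats("c", 100, mids(500))
        assert st_.n == 0 and np.isnan(st_.d_mean) and np.isnan(st_.d_var)
        st_ = nucstats.site_positioning_stats("c", 100, mids(110))
        assert st_.n == 1 and st_.d_mean == 10.0 and np.isnan(st_.d_var)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(42)
        midpoint_array = np.sort(rng.integers(0, 50_000, 20_000))
        mset = FragmentMidpointSet({"c": midpoint_array})
        for site in rng.integers(0, 50_000, 300):
            got = nucstats.site_positioning_stats("c", int(site), mset)
            n, dm, dv = brute_force_stats(int(site), midpoint_array)
            assert got.n == n
            assert got.d_mean == dm or (np.isnan(got.d_mean) and np.isnan(dm))
            assert got.d_var == dv or (np.isnan(got.d_var) and np.isnan(dv))

    def test_batch_agrees_with_single_site(self):
        rng = np.random.default_rng(1)
        m = np.sort(rng.integers(0, 10_000, 3_000))
        mset = FragmentMidpointSet({"c": m})
        sites = rng.integers(0, 10_000, 200)
        batch = nucstats.batch_positioning_stats(sites, m)
        for row in batch.itertuples(index=False):
            single = nucstats.site_positioning_stats("c", int(row.pos0), mset)
            assert row.n == single.n
            if single.n:
                assert row.d_mean == pytest.approx(single.d_mean, abs=1e-9)
            if single.n >= 2:
                assert row.d_var == pytest.approx(single.d_var, abs=1e-8)

    def test_dvar_monotone_in_generator_jitter(self, landscape, site_stats):
        """d_var at true dyads tracks the generator's per-dyad jitter SD."""
        from scipy.stats import spearmanr

        dyads = landscape["dyads"]
        merged = dyads.merge(site_stats, on="pos0", how="inner")
        assert len(merged) > 100
        rho = spearmanr(merged["sigma"], merged["d_var"]).statistic
        assert rho > 0.9


class TestBinDmean:
    @pytest.mark.parametrize("d_mean, expected", [
        (0, 1), (18, 1), (19, 2), (36, 2), (37, 3), (54, 3), (55, 4),
        (73, 4), (74, 5), (95, 5), (18.5, 2), (73.5, 5),
    ])
    def test_printed_bins(self, d_mean, expected):
        assert nucstats.bin_dmean(d_mean) == expected

    @pytest.mark.parametrize("bad", [-1, 95.1, 1000])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            nucstats.bin_dmean(bad)


class TestOccupancy:
    def test_identity_doubling_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        cov = rng.integers(0, 20, 1000).astype(float)
        same = nucstats.compute_occupancy({"c": cov}, {"c": cov})
        assert np.allclose(same.data["c"][2], 1.0)
        double = nucstats.compute_occupancy({"c": 2 * cov}, {"c": cov})
        assert np.allclose(double.data["c"][2], 2.0)
        scaled = nucstats.compute_occupancy({"c": 7 * cov}, {"c": 7 * cov})
        assert np.allclose(scaled.data["c"][2], same.data["c"][2])

    def test_zero_control_bin_is_missing(self):
        obs = np.ones(30)
        ctl = np.ones(30)
        ctl[10:20] = 0
        track = nucstats.compute_occupancy({"c": obs}, {"c": ctl})
        assert np.isnan(track.value_at("c", 15))
        assert track.value_at("c", 5) == 1.0

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValidationError):
            nucstats.compute_occupancy({"c": np.array([-1.0])},
                                       {"c": np.array([1.0])})


class TestControlFragments:
    def test_uniform_counts_are_poisson_like(self):
        from scipy.stats import chisquare

        n = 50_000
        ctl = nucstats.simulate_control_fragments({"c": 100_000}, n, seed=3)
        cov = nucstats.midpoint_coverage(ctl, "c", 100_000)
        bins = cov[:99_000].reshape(-1, 1000).sum(axis=1)
        stat, p = chisquare(bins)
        assert p > 0.001

    def test_empty_and_deterministic(self):
        assert nucstats.simulate_control_fragments({"c": 1000}, 0, seed=1).total == 0
        a = nucstats.simulate_control_fragments({"c": 1000}, 50, seed=9)
        b = nucstats.simulate_control_fragments({"c": 1000}, 50, seed=9)
        assert all(np.array_equal(a.positions[c], b.positions[c])
                   for c in a.positions)

    def test_gc_weighted_runs(self, genome, landscape):
        sub = {"chrT": 5_000}
        ctl = nucstats.simulate_control_fragments(
            sub, 200, mode="gc_weighted", genome={"chrT": genome["chrT"][:5000]},
            observed=landscape["midpoints"], seed=4)
        assert ctl.total == 200


class TestUsableFilter:
    def make_track(self, value):
        from nucmut.io import SignalTrack
        return SignalTrack({"c": (np.array([0]), np.array([100]),
                                  np.array([float(value)]))})

    def test_mappability_threshold_inclusive(self):
        sites = [("c", 50)]
        stats = pd.DataFrame({"n": [10]})
        assert not nucstats.usable_sites_filter(sites, stats, self.make_track(89))[0]
        assert nucstats.usable_sites_filter(sites, stats, self.make_track(90))[0]

    def test_missing_mappability_excludes(self):
        sites = [("c", 500)]  # outside track coverage
        stats = pd.DataFrame({"n": [10]})
        assert not nucstats.usable_sites_filter(sites, stats, self.make_track(100))[0]


class TestStabilityTerciles:
    def frame(self, scores):
        return pd.DataFrame({"chrom": "c", "pos0": range(len(scores)),
                             "stability_score": scores})

    def test_equal_split(self):
        labels = nucstats.classify_stability_terciles(self.frame(range(9)))
        assert labels.value_counts().to_dict() == {"low": 3, "middle": 3, "high": 3}

    def test_remainder_goes_to_lower_groups(self):
        labels = nucstats.classify_stability_terciles(self.frame(range(10)))
        counts = labels.value_counts().to_dict()
        assert counts == {"low": 4, "middle": 3, "high": 3}

    def test_order_invariance(self):
        df = self.frame([5, 1, 9, 3, 7, 2, 8, 4, 6])
        shuffled = df.sample(frac=1, random_state=0)
        a = nucstats.classify_stability_terciles(df).sort_index()
        b = nucstats.classify_stability_terciles(shuffled).sort_index()
        assert (a == b).all()

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValidationError, match="ordering"):
            nucstats.classify_stability_terciles(self.frame([1.0] * 5))


class TestPartition:
    def test_precedence_example(self):
        part = nucstats.partition_genome_context(
            [GenomicInterval("c", 0, 100)], [GenomicInterval("c", 50, 150)],
            [GenomicInterval("c", 0, 200)])
        assert part.strong == (GenomicInterval("c", 0, 100),)
        assert part.rotational_only == (GenomicInterval("c", 100, 150),)
        assert part.other == (GenomicInterval("c", 150, 200),)

    def test_empty_inputs_leave_everything_other(self):
        ws = [GenomicInterval("c", 0, 50)]
        part = nucstats.partition_genome_context([], [], ws)
        assert part.other == tuple(ws) and not part.strong

    def test_outside_workspace_rejected(self):
        with pytest.raises(ValidationError, match="workspace"):
            nucstats.partition_genome_context(
                [GenomicInterval("c", 90, 120)], [], [GenomicInterval("c", 0, 100)])

    @given(st.lists(st.tuples(st.integers(0, 180), st.integers(1, 40)),
                    max_size=8),
           st.lists(st.tuples(st.integers(0, 180), st.integers(1, 40)),
                    max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_classes_tile_workspace(self, a, b):
        from nucmut.io import intersect_intervals, total_length

        ws = [GenomicInterval("c", 0, 250)]
        strong = [GenomicInterval("c", s, s + l) for s, l in a]
        rot = [GenomicInterval("c", s, s + l) for s, l in b]
        part = nucstats.partition_genome_context(strong, rot, ws)
        parts = [part.strong, part.rotational_only, part.other]
        assert sum(total_length(p) for p in parts) == 250
        for i in range(3):
            for j in range(i + 1, 3):
                assert total_length(intersect_intervals(parts[i], parts[j])) == 0
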