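"""Randomization enrichment, meta-profiles, and escape ratios."""

import numpy as np
import pandas as pd
import pytest

from nucmut import profiles, simulate
from nucmut.io import GenomicInterval, SignalTrack, ValidationError
from nucmut.profiles import (escape_ratio, escape_ratio_profile,
                             fisher_escape_region, meta_profile,
                             randomized_enrichment)

WS = [GenomicInterval("c", 0, 100_000)]


class TestRandomizedEnrichment:
    def test_annotation_equals_workspace(self):
        events = [("c", int(p)) for p in range(0, 100_000, 1000)]
        res = randomized_enrichment(events, WS, WS, n_samples=200, seed=1)
        assert res.fold == 1.0 and res.p == 1.0 and res.expected == len(events)

    def test_all_events_in_small_annotation(self):
        ann = [GenomicInterval("c", 0, 10_000)]  # 10% of workspace
        events = [("c", int(p)) for p in range(0, 10_000, 50)]
        n_samples = 1000
        res = randomized_enrichment(events, ann, WS, n_samples=n_samples,
                                    seed=2)
        assert res.fold == pytest.approx(10.0, rel=0.1)
        assert res.p == pytest.approx(2.0 / (n_samples + 1))

    def test_expected_converges_to_length_fraction(self):
        ann = [GenomicInterval("c", 20_000, 45_000)]  # 25% of workspace
        rng = np.random.default_rng(3)
        events = [("c", int(p)) for p in rng.integers(0, 100_000, 400)]
        res = randomized_enrichment(events, ann, WS, n_samples=10_000, seed=4)
        assert res.expected == pytest.approx(0.25 * 400, rel=0.02)

    def test_interval_events_longer_than_workspace_segment_rejected(self):
        ws = [GenomicInterval("c", 0, 100)]
        events = [GenomicInterval("c", 0, 100)]
        with pytest.raises(ValidationError, match="exceeds"):
            randomized_enrichment([GenomicInterval("c", 0, 500)], events, ws,
                                  n_samples=10, seed=1)

    def test_event_outside_workspace_chrom_rejected(self):
        with pytest.raises(ValidationError, match="workspace"):
            randomized_enrichment([("other", 5)], WS, WS, n_samples=10, seed=1)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        events = [("c", int(p)) for p in rng.integers(0, 100_000, 100)]
        ann = [GenomicInterval("c", 0, 30_000)]
        a = randomized_enrichment(events, ann, WS, n_samples=500, seed=6)
        b = randomized_enrichment(events, ann, WS, n_samples=500, seed=6)
        assert (a.expected, a.p, a.fold_ci) == (b.expected, b.p, b.fold_ci)


class TestMetaProfile:
    def test_two_event_worked_example(self):
        prof = meta_profile([("c", 1000)], events=[("c", 995), ("c", 1004)],
                            window=10, bin_size=10)
        assert list(prof.bin_starts) == [-10, 0]
        assert np.allclose(prof.values, [0.1, 0.1])

    def test_uniform_events_make_flat_profile(self):
        rng = np.random.default_rng(7)
        anchors = [("c", int(p)) for p in rng.integers(2000, 98_000, 1000)]
        events = [("c", int(p)) for p in rng.integers(0, 100_000, 100_000)]
        prof = meta_profile(anchors, events=events, window=1000, bin_size=100)
        assert prof.values.max() / prof.values.min() < 1.3

    def test_conservation_invariant(self):
        rng = np.random.default_rng(8)
        anchors = [("c", int(p)) for p in rng.integers(2000, 8000, 20)]
        events = [("c", int(p)) for p in rng.integers(0, 10_000, 500)]
        prof = meta_profile(anchors, events=events, window=500, bin_size=10)
        total = sum(
            1 for _, a in anchors for _, e in events if -500 <= e - a < 500)
        assert prof.values.sum() * prof.bin_size * prof.n_anchors == \
            pytest.approx(total)

    def test_constant_signal_mean(self):
        track = SignalTrack({"c": (np.array([0]), np.array([10_000]),
                                   np.array([4.5]))})
        prof = meta_profile([("c", 3000), ("c", 7000)], signal=track,
                            chrom_lengths={"c": 10_000}, window=500,
                            bin_size=50, mode="signal_mean")
        assert np.allclose(prof.values, 4.5)

    def test_edge_anchors_dropped_and_counted(self):
        prof = meta_profile([("c", 100), ("c", 5000)], events=[("c", 5005)],
                            chrom_lengths={"c": 10_000}, window=1000,
                            bin_size=100)
        assert prof.n_anchors == 1 and prof.n_dropped_anchors == 1

    def test_no_anchors_rejected(self):
        with pytest.raises(ValidationError):
            meta_profile([], events=[("c", 1)])


class TestEscapeRatio:
    def test_arithmetic(self):
        assert escape_ratio(4.0, 2.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_scale_invariance(self):
        base = escape_ratio(4.0, 2.0, 1.0, 0.5)
        scaled = escape_ratio(4.0 * 7, 2.0 * 7, 1.0 * 7, 0.5 * 7)
        assert base == pytest.approx(scaled)

    def test_undefined_when_denominator_zero(self):
        assert np.isnan(escape_ratio(4.0, 0.0, 1.0, 1.0))

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValidationError):
            escape_ratio(1.0, 1.0, 0.0, 1.0)


@pytest.fixture(scope="module")
def cohort_setup(genome):
    dyads = pd.DataFrame({"chrom": "chrT",
                          "pos0": np.arange(2000, 198_000, 2500)})
    b = 5e-3
    step = lambda o: np.where(np.abs(o) <= 95, 2 * b, b)
    flat = lambda o: np.full(np.shape(o), b)
    return genome, dyads, b, step, flat


class TestEscapeProfile:
    def test_step_profile_recovered(self, cohort_setup):
        genome, dyads, b, step, flat = cohort_setup
        ca, cb, truth = simulate.gen_paired_cohorts(genome, dyads, step, flat,
                                                    b, b, seed=50)
        prof = escape_ratio_profile(ca, cb, dyads, {"chrT": 200_000}, seed=51)
        inside = prof[(prof["bin_start"] >= -90) & (prof["bin_start"] < 90)]
        outside = prof[np.abs(prof["bin_start"]) >= 300]
        # per-bin Poisson-ratio CIs around the estimates must cover truth
        def covered(rows, target):
            ok = 0
            for r in rows.itertuples(index=False):
                if r.count_b == 0 or r.count_a == 0:
                    continue
                lo, hi = poisson_ratio_ci(r.count_a, r.count_b)
                norm = (r.mbar_a / r.mbar_b)
                ok += lo / norm <= target <= hi / norm
            return ok / len(rows)

        assert covered(inside, 2.0) >= 0.9
        assert covered(outside, 1.0) >= 0.9

    def test_null_profile_near_one(self, cohort_setup):
        genome, dyads, b, step, flat = cohort_setup
        ca, cb, _ = simulate.gen_paired_cohorts(genome, dyads, flat, flat,
                                                b, b, seed=52)
        prof = escape_ratio_profile(ca, cb, dyads, {"chrT": 200_000}, seed=53)
        # aggregate over bins before taking the ratio: the per-bin ratio of
        # small Poisson counts is upward-biased even under the null
        agg = escape_ratio(prof["count_a"].sum(), prof["count_b"].sum(),
                           prof["mbar_a"].iloc[0], prof["mbar_b"].iloc[0])
        assert agg == pytest.approx(1.0, abs=0.1)

    def test_mappability_filter_restricts_dyads(self, cohort_setup):
        genome, dyads, b, step, flat = cohort_setup
        ca, cb, _ = simulate.gen_paired_cohorts(genome, dyads, flat, flat,
                                                b, b, seed=54)
        # only the first half of the chromosome is perfectly mappable
        track = SignalTrack({"chrT": (np.array([0]), np.array([100_000]),
                                      np.array([100.0]))})
        prof = escape_ratio_profile(ca, cb, dyads, {"chrT": 200_000},
                                    mappability=track, seed=55)
        n_expected = (dyads["pos0"] + 800 <= 100_000).sum()
        assert prof["n_dyads"].iloc[0] == n_expected

    def test_empty_cohort_rejected(self, cohort_setup):
        genome, dyads, *_ = cohort_setup
        with pytest.raises(ValidationError):
            escape_ratio_profile([], [], dyads, {"chrT": 200_000}, seed=1)


def poisson_ratio_ci(a, b, level=0.95):
    """95% CI for the rate ratio of two Poisson counts (conditional binomial)."""
    from scipy.stats import beta as beta_dist

    alpha = 1 - level
    lo_p = beta_dist.ppf(alpha / 2, a, b + 1) if a > 0 else 0.0
    hi_p = beta_dist.ppf(1 - alpha / 2, a + 1, b) if b > 0 else 1.0
    lo = lo_p / (1 - lo_p) if lo_p < 1 else np.inf
    hi = hi_p / (1 - hi_p) if hi_p < 1 else np.inf
    return lo, hi


class TestFisherEscape:
    @staticmethod
    def enumeration_fisher(a, b, c, d):
        from scipy.stats import hypergeom

        M, n1, K = a + b + c + d, a + b, a + c
        ks = np.arange(max(0, n1 + K - M), min(n1, K) + 1)
        pmf = hypergeom.pmf(ks, M, K, n1)
        pobs = hypergeom.pmf(a, M, K, n1)
        return float(pmf[pmf <= pobs * (1 + 1e-12)].sum())

    def test_table_against_enumeration(self):
        enumeration_fisher = self.enumeration_fisher
        # known counts around one dyad: "strong" = |offset| <= 95, the rest
        # inside the all-considered window |offset| <= 800
        dyads = pd.DataFrame({"chrom": "c", "pos0": [10_000]})
        outer_a = list(range(100, 585)) + list(range(-584, -99))       # 970
        outer_b = list(range(100, 595)) + list(range(-594, -99))       # 990
        ca = [_variant("c", 10_000 + o) for o in range(-30, 0)]        # 30
        ca += [_variant("c", 10_000 + o) for o in outer_a]
        cb = [_variant("c", 10_000 + o) for o in range(10)]
        cb += [_variant("c", 10_000 + o) for o in outer_b]
        odds, p = fisher_escape_region(ca, cb, dyads)
        assert p == pytest.approx(enumeration_fisher(30, 970, 10, 990),
                                  abs=1e-12)

    def test_zero_margin_p_one(self):
        dyads = pd.DataFrame({"chrom": "c", "pos0": [1000]})
        ca = [_variant("c", 5000)]
        cb = [_variant("c", 6000)]
        _, p = fisher_escape_region(ca, cb, dyads, all_halfwidth=10_000)
        assert p == 1.0


def _variant(chrom, pos):
    from nucmut.io import Variant

    return Variant(chrom, pos, "A", "C")
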