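"""Extrema detection, nucleosome calling, spacing/density statistics,
occupancy states, and the genic/non-genic partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetramap import calling
from tetramap.core import NucleosomeCall, Replicon, SmoothedTrack, TranscriptUnit


def track_of(values, circular=True):
    values = np.asarray(values, dtype=float)
    rep = Replicon("chr", len(values), circular=circular)
    return SmoothedTrack(rep, values, "test")


class TestFindExtrema:
    def test_simple_alternation_with_wrap(self):
        ext = calling.find_extrema(track_of([0, 1, 0, 1, 0]))
        assert ext.maxima.tolist() == [1, 3]
        assert 2 in ext.minima  # plus the origin-spanning boundary minimum

    def test_sine_period_70_circular(self):
        n = 7000
        x = np.cos(2 * np.pi * np.arange(n) / 70)  # peaks at exact multiples of 70
        ext = calling.find_extrema(track_of(x + 2))
        assert len(ext.maxima) == 100
        gaps = np.diff(np.sort(ext.maxima))
        assert set(gaps.tolist()) == {70}

    def test_plateau_collapses_to_center(self):
        ext = calling.find_extrema(track_of([0, 1, 1, 1, 0]))
        assert ext.maxima.tolist() == [2]

    def test_even_plateau_takes_left_of_center(self):
        ext = calling.find_extrema(track_of([0, 0, 1, 1, 0, 0]))
        assert ext.maxima.tolist() == [2]

    def test_constant_track_empty_with_warning(self, caplog):
        ext = calling.find_extrema(track_of([2, 2, 2, 2]))
        assert len(ext.maxima) == 0 and len(ext.minima) == 0

    @given(st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_maxima_and_minima_strictly_alternate(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60).cumsum()  # rough but non-trivial signal
        ext = calling.find_extrema(track_of(x))
        seq = ext.ordered()
        if len(seq) >= 2:
            kinds = [k for _, k in seq] + [seq[0][1]]  # circular closure
            assert all(a != b for a, b in zip(kinds, kinds[1:]))
            assert len(ext.maxima) == len(ext.minima)


class TestCallNucleosomes:
    def test_zero_prominence_keeps_every_maximum(self):
        x = [0, 5, 0, 1, 0.5, 1, 0, 5, 0, 2]
        calls = calling.call_nucleosomes(track_of(x), min_prominence=0.0)
        ext = calling.find_extrema(track_of(x))
        assert len(calls) == len(ext.maxima)

    def test_shallow_peak_merged_into_neighbor(self):
        # two peaks with an equal-height trough: one has zero prominence side
        x = [0, 5, 3, 5, 0, 0, 0, 0]
        keep_all = calling.call_nucleosomes(track_of(x), min_prominence=0.0)
        merged = calling.call_nucleosomes(track_of(x), min_prominence=2.5)
        assert len(keep_all) == 2
        assert len(merged) == 1

    def test_flanking_troughs_bracket_midpoint(self, calls):
        for c in calls[:200]:
            assert c.prominence >= 0
            assert c.peak_value >= 0

    def test_calls_reproducible(self, smoothed):
        a = calling.call_nucleosomes(smoothed)
        b = calling.call_nucleosomes(smoothed)
        assert [(c.midpoint, c.prominence) for c in a] == [
            (c.midpoint, c.prominence) for c in b
        ]


def mkcalls(positions, name="chr"):
    return [NucleosomeCall(name, p, 1.0, p - 30, p + 30, 1.0) for p in positions]


class TestPeakSpacing:
    def test_all_genic_mean(self):
        rep = Replicon("chr", 1000, circular=False)
        regions = calling.RegionSet(rep, np.ones(1000, dtype=bool))
        stats = calling.peak_spacing(mkcalls([10, 80, 150]), regions)
        assert stats["genic"]["mean"] == pytest.approx(70.0)
        assert stats["non_genic"] is None

    def test_cross_class_pairs_excluded(self):
        rep = Replicon("chr", 300, circular=False)
        mask = np.zeros(300, dtype=bool)
        mask[:100] = True  # genic block then non-genic block
        regions = calling.RegionSet(rep, mask)
        stats = calling.peak_spacing(mkcalls([10, 80, 150, 220]), regions)
        # (10,80) genic, (150,220) non-genic; the boundary pair (80,150) drops
        assert stats["genic"]["n"] == 1 and stats["genic"]["mean"] == pytest.approx(70.0)
        assert stats["non_genic"]["n"] == 1
        assert stats["all"]["n"] == 3

    def test_single_call_no_crash(self):
        rep = Replicon("chr", 100, circular=False)
        regions = calling.RegionSet(rep, np.ones(100, dtype=bool))
        stats = calling.peak_spacing(mkcalls([50]), regions)
        assert stats["all"] is None

    def test_wrap_pair_included_on_circular(self):
        rep = Replicon("chr", 200, circular=True)
        regions = calling.RegionSet(rep, np.ones(200, dtype=bool))
        stats = calling.peak_spacing(mkcalls([20, 120]), regions)
        assert stats["all"]["n"] == 2  # 100 forward + 100 around the origin
        assert stats["all"]["mean"] == pytest.approx(100.0)


class TestDensity:
    def test_calls_per_kilobase(self):
        rep = Replicon("chr", 10_000)
        assert calling.nucleosome_density(mkcalls(range(142)), rep) == pytest.approx(14.2)

    def test_no_calls_zero(self):
        assert calling.nucleosome_density([], Replicon("chr", 5000)) == 0.0


class TestOccupancyStates:
    def test_triangle_wave_thirds(self):
        # 0 -> 1 -> 0 triangle: rescaled value equals the ramp itself
        up = np.linspace(0, 1, 31)
        x = np.concatenate([up, up[::-1][1:]])
        st_track = calling.occupancy_states(track_of(x, circular=False))
        states = st_track.states
        assert states[30] == 1.0  # peak occupied
        assert states[0] == 0.0 and states[-1] == 0.0  # troughs depleted
        inner = states[1:-1]
        assert set(np.unique(inner)) <= {0.0, 0.5, 1.0}

    def test_midpoints_occupied_troughs_depleted(self, smoothed, calls):
        st_track = calling.occupancy_states(smoothed)
        for c in calls[:100]:
            assert st_track.states[c.midpoint] == 1.0
            assert st_track.states[c.left_trough] == 0.0

    def test_occupied_fraction_monotone_in_threshold(self, smoothed):
        fracs = []
        for theta in (0.5, 2 / 3, 0.8, 0.9):
            st_track = calling.occupancy_states(smoothed, theta_occ=theta)
            fracs.append((st_track.states == 1.0).mean())
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_invalid_thresholds_rejected(self, smoothed):
        with pytest.raises(ValueError):
            calling.occupancy_states(smoothed, theta_occ=0.2, theta_dep=0.4)


class TestBuildRegions:
    def test_plus_strand_extends_upstream(self):
        rep = Replicon("chr", 1000, circular=False)
        u = TranscriptUnit("chr", 100, 400, "+", "confirmed", ("a",))
        regions = calling.build_regions([u], rep)
        assert regions.intervals("genic") == [(60, 400)]

    def test_minus_strand_mirrors(self):
        rep = Replicon("chr", 1000, circular=False)
        u = TranscriptUnit("chr", 100, 400, "-", "confirmed", ("a",))
        regions = calling.build_regions([u], rep)
        assert regions.intervals("genic") == [(100, 440)]

    def test_overlapping_extensions_merge_and_partition(self):
        rep = Replicon("chr", 1000, circular=False)
        us = [
            TranscriptUnit("chr", 100, 400, "+", "confirmed", ("a",)),
            TranscriptUnit("chr", 420, 600, "+", "confirmed", ("b",)),
        ]
        regions = calling.build_regions(us, rep)
        genic = regions.intervals("genic")
        non = regions.intervals("non_genic")
        assert genic == [(60, 600)]  # 420-40=380 < 400: extensions merge
        covered = sorted(genic + non)
        assert covered[0][0] == 0 and covered[-1][1] == 1000
        total = sum(e - s for s, e in covered)
        assert total == 1000  # exact partition

    def test_strandless_unit_excluded(self):
        rep = Replicon("chr", 500, circular=False)
        u = TranscriptUnit("chr", 100, 200, ".", "novel", ())
        regions = calling.build_regions([u], rep)
        assert regions.intervals("genic") == []
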