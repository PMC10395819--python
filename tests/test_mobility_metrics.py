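"""Radius of gyration, rank/growth curves, and exponent fitting."""

import numpy as np
import pytest

from trajscale.mobility_metrics import (
    distinct_over_time,
    fit_exponent,
    population_curve,
    radius_of_gyration,
    sequence_radius_of_gyration,
    visitation_frequency,
)
from trajscale.stay_regions import StayRegion
from trajscale.temporal_aggregation import GAP, SymbolSequence

M_PER_DEG_LAT = 6_371_008.8 * np.pi / 180.0


def ntb(symbols, ind="bird-1"):
    return SymbolSequence(ind, "ntb", symbols)


class TestRadiusOfGyration:
    def test_identical_points(self):
        pts = np.array([[2.9, 51.2]] * 5)
        assert radius_of_gyration(pts) == pytest.approx(0.0, abs=1e-9)

    def test_two_points_km_apart(self):
        d_deg = 1000.0 / M_PER_DEG_LAT
        pts = np.array([[2.9, 51.2], [2.9, 51.2 + d_deg]])
        assert radius_of_gyration(pts) == pytest.approx(500.0, rel=1e-6)

    def test_three_point_case_matches_planar_computation(self):
        # small extent: compare against an independent flat-earth computation
        lat0 = 51.2
        m_per_deg_lon = M_PER_DEG_LAT * np.cos(np.radians(lat0))
        pts = np.array(
            [[2.9, lat0], [2.9 + 500 / m_per_deg_lon, lat0], [2.9, lat0 + 800 / M_PER_DEG_LAT]]
        )
        xy = np.column_stack(
            [(pts[:, 0] - 2.9) * m_per_deg_lon, (pts[:, 1] - lat0) * M_PER_DEG_LAT]
        )
        centroid = xy.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((xy - centroid) ** 2, axis=1)))
        assert radius_of_gyration(pts) == pytest.approx(expected, rel=1e-3)

    def test_weights_shift_the_centroid(self):
        d_deg = 1000.0 / M_PER_DEG_LAT
        pts = np.array([[2.9, 51.2], [2.9, 51.2 + d_deg]])
        # weights 3:1 -> centroid at 250 m, rms = sqrt((3*250^2 + 750^2)/4)
        expected = np.sqrt((3 * 250.0**2 + 750.0**2) / 4.0)
        assert radius_of_gyration(pts, np.array([3.0, 1.0])) == pytest.approx(
            expected, rel=1e-6
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 2)))

    def test_sequence_weighting_counts_symbols(self):
        regions = [StayRegion(0, 2.9, 51.2, 3), StayRegion(1, 2.9, 51.2 + 1000 / M_PER_DEG_LAT, 2)]
        seq = ntb([0, 0, 0, GAP, 1])
        got = sequence_radius_of_gyration(seq, regions)
        pts = np.array([[r.centroid_lon, r.centroid_lat] for r in regions])
        assert got == pytest.approx(radius_of_gyration(pts, np.array([3.0, 1.0])), rel=1e-9)


class TestVisitationFrequency:
    def test_simple_counts(self):
        curve = visitation_frequency(ntb([0, 0, 0, 1]))
        np.testing.assert_allclose(curve.frequencies, [0.75, 0.25])
        assert curve.region_ids.tolist() == [0, 1]

    def test_single_symbol(self):
        curve = visitation_frequency(ntb([4]))
        np.testing.assert_allclose(curve.frequencies, [1.0])

    def test_gaps_excluded(self):
        curve = visitation_frequency(ntb([0, GAP, GAP, 1]))
        np.testing.assert_allclose(curve.frequencies, [0.5, 0.5])

    def test_all_gap_rejected(self):
        with pytest.raises(ValueError):
            visitation_frequency(ntb([GAP, GAP]))

    def test_matches_counting_oracle(self, rng):
        for _ in range(30):
            symbols = [int(s) for s in rng.integers(0, 6, size=60)]
            curve = visitation_frequency(ntb(symbols))
            assert curve.frequencies.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(curve.frequencies) <= 1e-15)
            from collections import Counter

            counts = Counter(symbols)
            got = dict(zip(curve.region_ids.tolist(), curve.frequencies))
            for region, c in counts.items():
                assert got[region] == pytest.approx(c / len(symbols))


class TestDistinctOverTime:
    def test_all_new(self):
        assert distinct_over_time(ntb([0, 1, 2])).counts.tolist() == [1, 2, 3]

    def test_all_same(self):
        assert distinct_over_time(ntb([0, 0, 0])).counts.tolist() == [1, 1, 1]

    def test_gap_advances_time_not_count(self):
        curve = distinct_over_time(ntb([0, GAP, 1]))
        assert curve.times.tolist() == [1, 2, 3]
        assert curve.counts.tolist() == [1, 1, 2]

    def test_unit_increments_and_terminal_cardinality(self, rng):
        for _ in range(30):
            symbols = [int(s) for s in rng.integers(0, 8, size=50)]
            curve = distinct_over_time(ntb(symbols))
            steps = np.diff(curve.counts)
            assert set(steps.tolist()) <= {0, 1}
            assert curve.counts[-1] == len(set(symbols))
            assert curve.counts[0] == 1


class TestFitExponent:
    def test_exact_decay_recovered(self):
        x = np.arange(1, 21, dtype=float)
        fit = fit_exponent(x, x**-2)
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)
        assert fit.slope == pytest.approx(-2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_is_zero_exponent(self):
        fit = fit_exponent(np.arange(1, 10), np.full(9, 7.0))
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_noisy_growth_recovered(self):
        rng = np.random.default_rng(42)
        x = np.arange(1, 101, dtype=float)
        y = 3.0 * x**1.5 * 10 ** rng.normal(0.0, 0.01, size=100)
        fit = fit_exponent(x, y)
        assert fit.exponent == pytest.approx(1.5, abs=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponent([1.0, 2.0], [1.0, 0.5])
        with pytest.raises(ValueError):  # zeros do not count as points
            fit_exponent([1.0, 2.0, 0.0], [1.0, 0.5, 0.0])


class TestPopulationCurve:
    def test_single_curve_is_identity(self):
        c = distinct_over_time(ntb([0, 1, 1]))
        avg = population_curve([c])
        np.testing.assert_allclose(avg.mean_y, c.counts)

    def test_identical_curves_average_to_themselves(self):
        c = visitation_frequency(ntb([0, 0, 1]))
        avg = population_curve([c, c])
        np.testing.assert_allclose(avg.mean_y, c.frequencies)

    def test_unequal_lengths_average_covering_subset(self):
        avg = population_curve([np.array([1.0, 2.0]), np.array([3.0, 4.0, 5.0])])
        np.testing.assert_allclose(avg.mean_y, [2.0, 3.0, 5.0])
        assert avg.n_curves.tolist() == [2, 2, 1]


class TestArchetypeOrdering:
    def test_stationary_profile_has_steeper_zipf_decay(self):
        from trajscale.synthetic_data import make_archetypes

        stationary, roamer = make_archetypes(seed=1)
        fit_s = visitation_frequency(stationary)
        fit_r = visitation_frequency(roamer)
        zeta_s = fit_exponent(fit_s.ranks, fit_s.frequencies).exponent
        zeta_r = fit_exponent(fit_r.ranks, fit_r.frequencies).exponent
        assert zeta_s > zeta_r
        assert fit_s.frequencies[0] >= 0.8
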