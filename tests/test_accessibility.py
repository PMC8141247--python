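import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twostepfca import (
    DEFAULT_DECAY,
    METHODS,
    DecayScheme,
    Facility,
    Region,
    SeverityWeights,
    access_score,
    effective_demand,
    run_configuration,
    supply_ratio,
    zone_of,
)
from tests.conftest import random_instance
from tests.oracles import naive_scores


def region(counts, rid="R0", xy=(0.0, 0.0)):
    return Region(id=rid, centroid=xy, severity_counts=counts)


class TestEffectiveDemand:
    @pytest.mark.parametrize(
        "counts,weights,expected",
        [
            ((10, 10, 10, 10), None, 40.0),
            ((10, 10, 10, 10), (1, 2, 3, 4), 100.0),
            ((0, 0, 0, 0), (1, 2, 3, 4), 0.0),
            ((5, 0, 0, 1), (1, 2, 3, 4), 9.0),
        ],
    )
    def test_weighted_headcount(self, counts, weights, expected):
        sev = None if weights is None else SeverityWeights(weights)
        assert effective_demand(region(counts), sev) == expected

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            SeverityWeights((1, 2, 3, -1))


class TestZoneOf:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (0.0, 1),  # co-located demand belongs to the innermost zone
            (5.0, 1),  # upper edges are inclusive
            (5.0001, 2),
            (10.0, 2),
            (15.0, 3),
            (16.0, None),
            (np.inf, None),
        ],
    )
    def test_half_open_zones(self, t, expected):
        assert zone_of(t, DEFAULT_DECAY) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            zone_of(-1.0, DEFAULT_DECAY)

    @given(st.floats(min_value=0, max_value=30, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_weight_matches_zone(self, t):
        z = zone_of(t, DEFAULT_DECAY)
        w = DEFAULT_DECAY.weight_of(t)
        if z is None:
            assert w == 0.0
        else:
            assert w == DEFAULT_DECAY.zone_weights[z - 1]


class TestDecaySchemeValidation:
    def test_weights_must_decrease(self):
        with pytest.raises(ValueError):
            DecayScheme((5, 10), (0.5, 0.5))

    def test_first_weight_at_most_one(self):
        with pytest.raises(ValueError):
            DecayScheme((5, 10), (1.2, 0.5))

    def test_breaks_must_increase(self):
        with pytest.raises(ValueError):
            DecayScheme((10, 5), (1.0, 0.5))


class TestSupplyRatio:
    def test_single_region_plain_threshold(self):
        fac = Facility(id="H", location=(0, 0), beds=100)
        r = region((50, 0, 0, 0))
        assert supply_ratio(fac, [r], [3.0], 5.0) == pytest.approx(2.0)

    def test_zone_weighted_denominator(self):
        # demand 10 in each zone, weights 1.00/0.68/0.22 -> R = 10/19
        fac = Facility(id="H", location=(0, 0), beds=10)
        regions = [region((10, 0, 0, 0), rid=f"R{i}") for i in range(3)]
        r_j = supply_ratio(fac, regions, [3.0, 8.0, 12.0], DEFAULT_DECAY)
        assert r_j == pytest.approx(10.0 / 19.0)

    def test_zero_demand_gives_zero_with_warning(self, caplog):
        fac = Facility(id="H", location=(0, 0), beds=10)
        with caplog.at_level("WARNING", logger="twostepfca.accessibility"):
            r_j = supply_ratio(fac, [region((5, 5, 5, 5))], [99.0], 5.0)
        assert r_j == 0.0
        assert any("zero (weighted) demand" in m for m in caplog.messages)


class TestAccessScore:
    def test_single_facility_in_range(self):
        assert access_score([3.0], [2.0], 5.0) == pytest.approx(2.0)

    def test_zone_weighted_sum(self):
        a = access_score([3.0, 8.0, 12.0], [0.5, 0.5, 0.5], DEFAULT_DECAY)
        assert a == pytest.approx(0.5 * 1.90)

    def test_isolated_region_scores_zero(self):
        assert access_score([16.0, np.inf], [1.0, 2.0], DEFAULT_DECAY) == 0.0


class TestRunConfiguration:
    @pytest.mark.parametrize("method", METHODS)
    def test_single_pair_closed_form(self, method):
        r = region((10, 10, 10, 10))
        fac = Facility(id="H", location=(1, 1), beds=200)
        sev = SeverityWeights((1, 2, 3, 4)) if method.startswith("sev_") else None
        res = run_configuration(
            [r], [fac], np.array([[2.0]]), method, severity=sev
        )
        expected = 200.0 / effective_demand(r, sev)
        assert res.scores[0] == pytest.approx(expected)
        assert res.method == method
        assert res.region_ids == ("R0",)

    def test_unit_severity_weights_are_noop(self, rng):
        regions, facilities, times = random_instance(rng)
        plain = run_configuration(regions, facilities, times, "2sfca")
        unit = run_configuration(
            regions, facilities, times, "sev_2sfca",
            severity=SeverityWeights((1, 1, 1, 1)),
        )
        np.testing.assert_allclose(unit.scores, plain.scores, rtol=0, atol=1e-12)

    def test_unknown_method_rejected(self, rng):
        regions, facilities, times = random_instance(rng)
        with pytest.raises(ValueError, match="unknown method"):
            run_configuration(regions, facilities, times, "3sfca")

    def test_severity_weights_rejected_for_plain_method(self, rng):
        regions, facilities, times = random_instance(rng)
        with pytest.raises(ValueError, match="severity"):
            run_configuration(
                regions, facilities, times, "2sfca",
                severity=SeverityWeights((1, 2, 3, 4)),
            )

    def test_scheme_rejected_for_plain_method(self, rng):
        regions, facilities, times = random_instance(rng)
        with pytest.raises(ValueError, match="scheme"):
            run_configuration(
                regions, facilities, times, "2sfca", scheme=DEFAULT_DECAY
            )

    def test_shape_mismatch_rejected(self, rng):
        regions, facilities, _ = random_instance(rng)
        with pytest.raises(ValueError, match="shape"):
            run_configuration(
                regions, facilities, np.zeros((1, 1)), "2sfca"
            )

    def test_deterministic(self, rng):
        regions, facilities, times = random_instance(rng)
        a = run_configuration(regions, facilities, times, "e2sfca")
        b = run_configuration(regions, facilities, times, "e2sfca")
        np.testing.assert_array_equal(a.scores, b.scores)


class TestEngineProperties:
    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            regions, facilities, times = random_instance(rng)
            counts = [r.severity_counts for r in regions]
            beds = [f.beds for f in facilities]
            for method in METHODS:
                sev = (1, 2, 3, 4) if method.startswith("sev_") else None
                if method.endswith("e2sfca"):
                    breaks, zw = (5, 10, 15), (1.0, 0.68, 0.22)
                    res = run_configuration(
                        regions, facilities, times, method,
                        severity=SeverityWeights(sev) if sev else None,
                    )
                else:
                    breaks, zw = (5.0,), (1.0,)
                    res = run_configuration(
                        regions, facilities, times, method,
                        severity=SeverityWeights(sev) if sev else None,
                    )
                expected = naive_scores(counts, beds, times.tolist(), breaks, zw, sev)
                np.testing.assert_allclose(res.scores, expected, atol=1e-12)

    def test_conservation_of_supply(self, rng):
        # with every pair in the innermost reachability and no empty
        # catchment, total (weighted) demand x score returns total beds
        for _ in range(20):
            regions, facilities, times = random_instance(rng, max_time=15.0)
            times = np.minimum(times, 14.0)  # all pairs inside the last zone
            for method in ("e2sfca", "sev_e2sfca"):
                sev = SeverityWeights() if method.startswith("sev_") else None
                res = run_configuration(
                    regions, facilities, times, method, severity=sev
                )
                demand = np.array([effective_demand(r, sev) for r in regions])
                total_beds = sum(f.beds for f in facilities)
                if demand.sum() == 0:
                    continue
                assert demand @ res.scores == pytest.approx(
                    total_beds, rel=1e-9
                )

    def test_severity_domination(self, rng):
        # weights >= 1 inflate denominators, so scores can only shrink
        for _ in range(20):
            regions, facilities, times = random_instance(rng)
            plain = run_configuration(regions, facilities, times, "2sfca")
            sev = run_configuration(
                regions, facilities, times, "sev_2sfca",
                severity=SeverityWeights((1, 2, 3, 4)),
            )
            assert np.all(sev.scores <= plain.scores + 1e-12)

    def test_supply_monotonicity(self, rng):
        regions, facilities, times = random_instance(rng, n_facilities=4)
        base = run_configuration(regions, facilities, times, "e2sfca")
        bigger = list(facilities)
        bigger[0] = Facility(
            id=facilities[0].id,
            location=facilities[0].location,
            beds=facilities[0].beds + 100,
        )
        boosted = run_configuration(regions, bigger, times, "e2sfca")
        assert np.all(boosted.scores >= base.scores - 1e-12)

    def test_decay_sanity_moving_facility_outward(self, rng):
        # pushing a facility from a region's zone 1 to zone 3 cannot raise
        # that region's score
        regions, facilities, times = random_instance(rng, n_facilities=3)
        times = times.copy()
        times[0, 0] = 2.0
        near = run_configuration(regions, facilities, times, "e2sfca")
        times_far = times.copy()
        times_far[0, 0] = 14.0
        far = run_configuration(regions, facilities, times_far, "e2sfca")
        assert far.scores[0] <= near.scores[0] + 1e-12
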