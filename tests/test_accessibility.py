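import numpy as np
import pytest

from conftest import small_landscape, tiny_random_instance
from oracle import accessibility_oracle, choice_weights_oracle, service_ratio_oracle

from fca_equity import (
    EXTENDED_EXPECTED,
    DemandPoint,
    Facility,
    TravelCosts,
    accessibility_scores,
    extended_example_fixture,
    facility_service_ratio,
    regional_average,
    run_all_methods,
    selection_weights,
    worked_example_fixture,
)


class TestRegionalAverage:
    def test_national_provider_density(self):
        """One region holding the national totals gives 3.15 per 10,000."""
        demand = [DemandPoint("t", "R", "C", 3_618_878)]
        facilities = [Facility("f", "R", "C", 1140.0, 3.7)]
        res = regional_average(demand, facilities)
        assert res.scores["t"] == pytest.approx(3.15, abs=0.005)

    def test_region_without_facility_scores_zero(self):
        demand = [DemandPoint("a", "RA", "C", 10_000),
                  DemandPoint("b", "RB", "C", 5_000)]
        facilities = [Facility("f", "RA", "C", 2.0, 4.0)]
        res = regional_average(demand, facilities)
        assert res.scores["a"] == pytest.approx(2.0)
        assert res.scores["b"] == 0.0

    def test_zero_population_with_facilities_warns_and_scores_zero(self, caplog):
        demand = [DemandPoint("a", "RA", "C", 0)]
        facilities = [Facility("f", "RA", "C", 2.0, 4.0)]
        with caplog.at_level("WARNING"):
            res = regional_average(demand, facilities)
        assert res.scores["a"] == 0.0
        assert any("zero population" in r.message for r in caplog.records)

    def test_orphan_facility_logged_and_excluded(self, caplog):
        demand = [DemandPoint("a", "RA", "C", 1000)]
        facilities = [Facility("f", "NOWHERE", "C", 2.0, 4.0)]
        with caplog.at_level("WARNING"):
            res = regional_average(demand, facilities)
        assert res.scores["a"] == 0.0
        assert any("no demand region" in r.message for r in caplog.records)


class TestSelectionWeights:
    def _pair(self, s, v):
        demand = [DemandPoint("i", "i", "C", 1000)]
        facilities = [Facility("j1", "i", "C", s[0], v[0]),
                      Facility("j2", "i", "C", s[1], v[1])]
        costs = TravelCosts({("i", "j1"): 1.0, ("i", "j2"): 2.0})
        return demand, facilities, costs

    @pytest.mark.parametrize(
        "mode, s, v, expected",
        [
            ("capacity", (1.0, 3.0), (3.0, 3.0), (0.25, 0.75)),
            ("rating", (1.0, 1.0), (5.0, 2.5), (2 / 3, 1 / 3)),
            ("capacity_rating", (1.0, 3.0), (5.0, 2.5), (0.4, 0.6)),
        ],
    )
    def test_both_in_first_band_normalizes_mass(self, mode, s, v, expected):
        demand, facilities, costs = self._pair(s, v)
        w = selection_weights(demand, facilities, costs, mode=mode)
        assert w.entries[("i", "j1")] == pytest.approx(expected[0])
        assert w.entries[("i", "j2")] == pytest.approx(expected[1])

    def test_single_facility_gets_weight_one(self):
        demand = [DemandPoint("i", "i", "C", 10)]
        facilities = [Facility("j", "i", "C", 4.0, 2.0)]
        costs = TravelCosts({("i", "j"): 25.0})
        for mode in ("capacity", "rating", "capacity_rating"):
            w = selection_weights(demand, facilities, costs, mode=mode)
            assert w.entries[("i", "j")] == pytest.approx(1.0)

    def test_empty_catchment_has_no_entries(self):
        demand = [DemandPoint("i", "i", "C", 10)]
        facilities = [Facility("j", "i", "C", 4.0, 2.0)]
        costs = TravelCosts({("i", "j"): 40.0})
        w = selection_weights(demand, facilities, costs, mode="capacity")
        assert w.entries == {}

    def test_invalid_mode_rejected(self):
        demand, facilities, costs = self._pair((1.0, 1.0), (3.0, 3.0))
        with pytest.raises(ValueError):
            selection_weights(demand, facilities, costs, mode="nope")

    @pytest.mark.parametrize("mode", ["capacity", "rating", "capacity_rating"])
    @pytest.mark.parametrize("seed", range(1, 11))
    def test_weights_sum_to_one_per_catchment(self, seed, mode):
        demand, facilities, costs = small_landscape(seed)
        w = selection_weights(demand, facilities, costs, mode=mode)
        sums: dict[str, float] = {}
        for (i, _j), val in w.entries.items():
            assert 0.0 <= val <= 1.0
            sums[i] = sums.get(i, 0.0) + val
        for i, s in sums.items():
            assert s == pytest.approx(1.0, abs=1e-9), i

    def test_matches_oracle(self, rng):
        demand, facilities, costs = tiny_random_instance(rng)
        for mode in ("capacity", "rating", "capacity_rating"):
            got = selection_weights(demand, facilities, costs, mode=mode).entries
            exp = choice_weights_oracle(demand, facilities, costs, mode)
            assert set(got) == set(exp)
            for k in exp:
                assert got[k] == pytest.approx(exp[k], abs=1e-12)


class TestServiceRatio:
    def test_worked_example_ratio(self):
        demand, facilities, costs = worked_example_fixture()
        sr = facility_service_ratio(demand, facilities, costs)
        assert sr.ratios["j1"] == pytest.approx(8e-4, abs=1e-12)
        assert not sr.flagged

    def test_facility_without_reachable_demand_flagged(self, caplog):
        demand = [DemandPoint("i", "i", "C", 100)]
        facilities = [Facility("near", "i", "C", 1.0, 3.0),
                      Facility("far", "i", "C", 1.0, 3.0)]
        costs = TravelCosts({("i", "near"): 5.0, ("i", "far"): 50.0})
        with caplog.at_level("WARNING"):
            sr = facility_service_ratio(demand, facilities, costs)
        assert sr.flagged == {"far"}
        assert "far" not in sr.ratios

    def test_ratio_linear_in_capacity(self):
        demand, facilities, costs = worked_example_fixture()
        doubled = [Facility("j1", "i1", "C1", 4.0, 4.0)]
        a = facility_service_ratio(demand, facilities, costs).ratios["j1"]
        b = facility_service_ratio(demand, doubled, costs).ratios["j1"]
        assert b == pytest.approx(2 * a)

    def test_matches_oracle_with_weights(self, rng):
        demand, facilities, costs = tiny_random_instance(rng)
        w = selection_weights(demand, facilities, costs, mode="capacity_rating")
        got = facility_service_ratio(demand, facilities, costs, weights=w)
        exp = service_ratio_oracle(demand, facilities, costs, "capacity_rating")
        for j, r in exp.items():
            if r is None:
                assert j in got.flagged
            else:
                assert got.ratios[j] == pytest.approx(r, abs=1e-12)


class TestAccessibilityScores:
    def test_worked_example_a1(self):
        demand, facilities, costs = worked_example_fixture()
        res = accessibility_scores("A1", demand, facilities, costs)
        assert res.scores["i1"] == pytest.approx(8.0)
        assert res.scores["i2"] == pytest.approx(4.0)
        # conservation: (1000*8 + 3000*4)/10000 == S == 2
        assert (1000 * 8.0 + 3000 * 4.0) / 10_000 == pytest.approx(2.0)

    @pytest.mark.parametrize("method", ["A1", "A2", "A3", "A4"])
    def test_extended_fixture_frozen_scores(self, method):
        demand, facilities, costs = extended_example_fixture()
        res = accessibility_scores(method, demand, facilities, costs)
        for uid, expected in EXTENDED_EXPECTED[method].items():
            assert res.scores[uid] == pytest.approx(expected, abs=1e-9)

    def test_single_pair_makes_all_methods_agree(self):
        demand = [DemandPoint("i", "i", "C", 500)]
        facilities = [Facility("j", "i", "C", 3.0, 4.4)]
        costs = TravelCosts({("i", "j"): 12.0})
        scores = [
            accessibility_scores(m, demand, facilities, costs).scores["i"]
            for m in ("A1", "A2", "A3", "A4")
        ]
        assert all(s == pytest.approx(scores[0]) for s in scores)
        assert scores[0] == pytest.approx(10_000 * 3.0 / 500)

    @pytest.mark.parametrize("method", ["A1", "A2", "A3", "A4"])
    def test_out_of_range_demand_scores_zero(self, method):
        demand = [DemandPoint("near", "near", "C", 100),
                  DemandPoint("far", "far", "C", 100)]
        facilities = [Facility("j", "near", "C", 1.0, 3.0)]
        costs = TravelCosts({("near", "j"): 10.0, ("far", "j"): 40.0})
        res = accessibility_scores(method, demand, facilities, costs)
        assert res.scores["far"] == 0.0
        assert res.scores["near"] > 0.0

    def test_unknown_method_rejected(self):
        demand, facilities, costs = worked_example_fixture()
        with pytest.raises(ValueError):
            accessibility_scores("A9", demand, facilities, costs)

    @pytest.mark.parametrize("method", ["A1", "A2", "A3", "A4"])
    def test_matches_brute_force_oracle(self, method, rng):
        for _ in range(5):
            demand, facilities, costs = tiny_random_instance(rng)
            res = accessibility_scores(method, demand, facilities, costs)
            exp = accessibility_oracle(method, demand, facilities, costs)
            for uid in exp:
                assert res.scores[uid] == pytest.approx(exp[uid], abs=1e-9)

    def test_increasing_capacity_never_decreases_a1(self, rng):
        demand, facilities, costs = tiny_random_instance(rng, n_demand=10,
                                                         n_facility=5)
        base = accessibility_scores("A1", demand, facilities, costs).scores
        bigger = [
            Facility(f.id, f.region_id, f.county_id, f.capacity + 2.0, f.rating)
            if f.id == "f0" else f
            for f in facilities
        ]
        boosted = accessibility_scores("A1", demand, bigger, costs).scores
        for uid in base:
            assert boosted[uid] >= base[uid] - 1e-12


class TestDegenerateEquivalence:
    @staticmethod
    def _with(facilities, rating=None, capacity=None):
        return [
            Facility(f.id, f.region_id, f.county_id,
                     capacity if capacity is not None else f.capacity,
                     rating if rating is not None else f.rating)
            for f in facilities
        ]

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_equal_ratings_make_a4_equal_a2(self, seed):
        demand, facilities, costs = small_landscape(seed)
        flat = self._with(facilities, rating=3.7)
        a2 = accessibility_scores("A2", demand, flat, costs).scores
        a4 = accessibility_scores("A4", demand, flat, costs).scores
        for uid in a2:
            assert a4[uid] == pytest.approx(a2[uid], abs=1e-9)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_equal_capacities_make_a4_equal_a3(self, seed):
        demand, facilities, costs = small_landscape(seed)
        flat = self._with(facilities, capacity=2.0)
        a3 = accessibility_scores("A3", demand, flat, costs).scores
        a4 = accessibility_scores("A4", demand, flat, costs).scores
        for uid in a3:
            assert a4[uid] == pytest.approx(a3[uid], abs=1e-9)

    def test_equal_ratings_a3_uses_pure_distance_weights(self, rng):
        # with flat ratings A3's weights reduce to f(d)/sum f(d)
        demand, facilities, costs = tiny_random_instance(rng)
        flat = self._with(facilities, rating=4.0)
        w = selection_weights(demand, facilities, costs, mode="rating")
        wf = selection_weights(demand, flat, costs, mode="rating")
        # flat-rating weights match capacity-mode weights on flat capacities
        flat_cap = self._with(facilities, capacity=1.0)
        wc = selection_weights(demand, flat_cap, costs, mode="capacity")
        for k in wf.entries:
            assert wf.entries[k] == pytest.approx(wc.entries[k], abs=1e-12)


class TestConservationAndRunAll:
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_total_scored_resource_equals_supplied_capacity(self, seed):
        demand, facilities, costs = small_landscape(seed)
        pop = {d.id: d.population for d in demand}
        for method in ("A1", "A2", "A3", "A4"):
            res = accessibility_scores(method, demand, facilities, costs)
            mode = {"A1": "none", "A2": "capacity", "A3": "rating",
                    "A4": "capacity_rating"}[method]
            sr = facility_service_ratio(
                demand, facilities, costs,
                weights=None if mode == "none" else selection_weights(
                    demand, facilities, costs, mode=mode),
            )
            supplied = sum(f.capacity for f in facilities
                           if f.id not in sr.flagged)
            total = sum(pop[i] * s for i, s in res.scores.items()) / res.scale_factor
            assert total == pytest.approx(supplied, rel=1e-9)

    def test_run_all_methods_keys_and_determinism(self):
        demand, facilities, costs = extended_example_fixture()
        r1 = run_all_methods(demand, facilities, costs)
        r2 = run_all_methods(demand, facilities, costs)
        assert set(r1) == {"A0", "A1", "A2", "A3", "A4"}
        for m in r1:
            assert r1[m].scores == r2[m].scores

    def test_empty_facility_set_gives_all_zero(self):
        demand, _f, costs = worked_example_fixture()
        res = run_all_methods(demand, [], TravelCosts())
        for m, r in res.items():
            assert all(v == 0.0 for v in r.scores.values()), m

    def test_duplicate_ids_rejected(self):
        demand = [DemandPoint("i", "i", "C", 1), DemandPoint("i", "i", "C", 2)]
        with pytest.raises(ValueError, match="duplicate"):
            accessibility_scores("A1", demand, [], TravelCosts())
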