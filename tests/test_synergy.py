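import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rotoscreen import combinatorics as cb
from rotoscreen import synergy as sy

from .conftest import dilution_layout


class TestHillCurve:
    def test_zero_dose_zero_effect_and_monotonicity(self):
        c = sy.HillCurve(emax=0.8, ec50=2.0, hill=1.5)
        assert c.effect(0) == 0.0
        doses = [0.1 * i for i in range(1, 100)]
        effects = [c.effect(d) for d in doses]
        assert all(a <= b for a, b in zip(effects, effects[1:]))
        assert all(e < c.emax for e in effects)

    def test_inverse_round_trip(self):
        c = sy.HillCurve(emax=0.9, ec50=1.3, hill=2.0)
        for d in (0.01, 0.5, 1.3, 10.0):
            assert c.inverse_dose(c.effect(d)) == pytest.approx(d, rel=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sy.HillCurve(emax=0.0, ec50=1.0)
        with pytest.raises(ValueError):
            sy.HillCurve(emax=0.5, ec50=-1.0)


class TestBliss:
    def test_two_half_effects(self):
        assert sy.bliss_expected([0.5, 0.5]) == pytest.approx(0.75)

    def test_null_agent_is_identity(self):
        assert sy.bliss_expected([0.37, 0.0]) == pytest.approx(0.37)

    def test_three_way(self):
        # 1 - 0.8 * 0.7 * 0.4
        assert sy.bliss_expected([0.2, 0.3, 0.6]) == pytest.approx(0.776)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sy.bliss_expected([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=5),
           st.floats(0, 1))
    def test_monotone_in_each_argument(self, effects, bump):
        base = sy.bliss_expected(effects)
        bumped = effects[:]
        bumped[0] = min(1.0, bumped[0] + bump)
        assert sy.bliss_expected(bumped) >= base - 1e-12


class TestLoewe:
    def test_single_drug_reduces_to_hill_effect(self):
        c = sy.HillCurve(emax=0.7, ec50=1.0, hill=1.2)
        assert sy.loewe_expected([2.0], [c]) == pytest.approx(c.effect(2.0))
        assert sy.loewe_expected([0.0, 2.0], [c, c]) == pytest.approx(c.effect(2.0))

    def test_identical_curves_unit_doses_give_two_thirds(self):
        c = sy.HillCurve(emax=1.0, ec50=1.0, hill=1.0)
        assert sy.loewe_expected([1.0, 1.0], [c, c]) == pytest.approx(2 / 3, abs=1e-8)

    def test_all_zero_doses(self):
        c = sy.HillCurve(emax=1.0, ec50=1.0)
        assert sy.loewe_expected([0.0, 0.0], [c, c]) == 0.0

    @given(
        st.floats(0.2, 1.0),
        st.floats(0.1, 10.0),
        st.floats(0.5, 3.0),
        st.floats(0.01, 20.0),
        st.floats(0.01, 0.99),
    )
    def test_sham_combination_invariance(self, emax, ec50, hill, dose, split):
        """Splitting one drug's dose across two slots of the same curve
        must reproduce the undivided effect (Loewe sham principle)."""
        c = sy.HillCurve(emax=emax, ec50=ec50, hill=hill)
        whole = c.effect(dose)
        shammed = sy.loewe_expected([dose * split, dose * (1 - split)], [c, c])
        assert shammed == pytest.approx(whole, abs=1e-6)

    def test_agrees_with_bliss_for_single_drug(self):
        c = sy.HillCurve(emax=0.6, ec50=2.0, hill=1.0)
        e = c.effect(1.5)
        assert sy.loewe_expected([1.5], [c]) == pytest.approx(
            sy.bliss_expected([e])
        )


class TestScoring:
    @pytest.mark.parametrize("observed,expected,tau,value", [
        (0.5, 0.5, 0.1, 1),      # additive
        (0.7, 0.5, 0.1, 2),      # synergistic: excess 2*tau
        (0.3, 0.5, 0.1, 0),      # antagonistic
        (0.59, 0.5, 0.1, 1),     # within threshold
    ])
    def test_three_level_scale(self, observed, expected, tau, value):
        assert sy.score_interaction(observed, expected, tau).value == value

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            sy.score_interaction(0.5, 0.5, 0.0)


class TestSurface:
    def test_reproducible_and_order_independent(self):
        s1 = sy.generate_surface(4, 3, seed=7, noise_sd=0.05)
        s2 = sy.generate_surface(4, 3, seed=7, noise_sd=0.05)
        members = [(0, 0), (2, 1), (3, 2)]
        assert s1.observed_effect(members) == s2.observed_effect(reversed(members))

    def test_noiseless_surface_without_interactions_is_exactly_reference(self):
        s = sy.generate_surface(5, 3, seed=3, noise_sd=0.0)
        for pair in itertools.combinations(range(5), 2):
            members = [(d, 0) for d in pair]
            assert s.observed_effect(members) == pytest.approx(
                s.expected_effect(members)
            )

    def test_planted_synergy_shifts_and_antagonism_depresses(self):
        up = sy.generate_surface(4, 2, seed=0, noise_sd=0.0,
                                 interactions=[({0, 1, 2}, 0.3)])
        down = sy.generate_surface(4, 2, seed=0, noise_sd=0.0,
                                   interactions=[({0, 1, 2}, -0.3)])
        members = [(0, 0), (1, 0), (2, 0)]
        tau = 0.1
        assert sy.score_interaction(
            up.observed_effect(members), up.expected_effect(members), tau
        ).value == 2
        assert sy.score_interaction(
            down.observed_effect(members), down.expected_effect(members), tau
        ).value == 0
        # an uninvolved triple stays additive
        other = [(0, 0), (1, 0), (3, 0)]
        assert sy.score_interaction(
            up.observed_effect(other), up.expected_effect(other), tau
        ).value == 1


class TestRingSearch:
    def test_null_surface_finds_nothing_and_tests_every_ring(self):
        wm = dilution_layout(3, 6)
        surf = sy.generate_surface(6, 3, seed=11, noise_sd=0.0)
        res = sy.ring_search(wm, surf, tau=0.1)
        assert res.found_sets == []
        assert res.combos_tested == 3 * cb.binom(6, 3)
        assert res.droplets_used == 3 * res.combos_tested
        assert [s.kind for s in res.steps] == ["ring"] * 3

    def test_planted_triple_found_on_first_ring_with_focus(self):
        wm = dilution_layout(3, 8)
        surf = sy.generate_surface(8, 3, seed=5, noise_sd=0.0,
                                   interactions=[({1, 4, 6}, 0.3)])
        res = sy.ring_search(wm, surf, tau=0.1)
        assert res.found_sets == [frozenset({1, 4, 6})]
        # one ring of C(8,3) combos plus the 3^3 dilution focus grid
        assert res.combos_tested == cb.binom(8, 3) + 27
        assert res.combos_tested < cb.meaningful_combinations(3, 8)
        assert [s.kind for s in res.steps] == ["ring", "focus"]

    def test_search_counters_are_consistent(self):
        wm = dilution_layout(3, 6)
        surf = sy.generate_surface(6, 3, seed=2, noise_sd=0.0,
                                   interactions=[({0, 1, 2}, 0.3)])
        res = sy.ring_search(wm, surf, tau=0.1)
        assert res.droplets_used == 3 * res.combos_tested
        spp = wm.config.seconds_per_position
        assert res.model_time_days == pytest.approx(
            res.positions_used * spp / 86_400
        )

    def test_exhaustive_strategy_visits_all_rings(self):
        wm = dilution_layout(3, 6)
        surf = sy.generate_surface(6, 3, seed=2, noise_sd=0.0,
                                   interactions=[({0, 1, 2}, 0.3)])
        res = sy.ring_search(wm, surf, strategy="exhaustive-ml", tau=0.1)
        assert res.found_sets == [frozenset({0, 1, 2})]
        ring_steps = [s for s in res.steps if s.kind == "ring"]
        assert len(ring_steps) == 3  # never stops early
        focus_steps = [s for s in res.steps if s.kind == "focus"]
        assert len(focus_steps) == 1  # each implicated set focused once

    def test_non_canonical_layout_rejected(self, layout_3x3):
        from rotoscreen.geometry import with_cell_well
        wm = with_cell_well(layout_3x3, 0, 0)
        surf = sy.generate_surface(3, 3, seed=0)
        with pytest.raises(ValueError, match="canonical dilution layout"):
            sy.ring_search(wm, surf)
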