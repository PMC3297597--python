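import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearbold import EmptyPopulationError, PopulationState
from fearbold.predation import (
    attack_event_probabilities,
    group_selection_probability,
    per_capita_kill_probability,
    run_attack_sequence,
    simulate_attack,
)

from conftest import make_params, rng


def state_from_counts(counts_f, counts_b):
    return PopulationState(
        counts_f=np.array(counts_f), counts_b=np.array(counts_b)
    )


class TestGroupSelection:
    def test_frequency_dependent_direct_substitution(self):
        p = make_params(beta=0.5)
        assert group_selection_probability("F", 10, 20, p) == pytest.approx(0.2)

    def test_absent_group_never_selected(self):
        p = make_params(beta=0.5)
        assert group_selection_probability("F", 0, 5, p) == 0.0

    def test_frequency_independent_symmetric_at_beta_one(self):
        p = make_params(beta=1.0, risk_mode="frequency_independent")
        assert group_selection_probability("F", 3, 97, p) == pytest.approx(0.5)

    def test_empty_population_is_error(self):
        with pytest.raises(EmptyPopulationError):
            group_selection_probability("F", 0, 0, make_params())

    @given(
        n_f=st.integers(0, 30),
        n_b=st.integers(0, 30),
        beta=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_group_probabilities_sum_to_one(self, n_f, n_b, beta):
        if n_f + n_b == 0:
            return
        p = make_params(beta=beta)
        pf = group_selection_probability("F", n_f, n_b, p)
        pb = group_selection_probability("B", n_f, n_b, p)
        if beta * n_f + n_b > 0:
            assert pf + pb == pytest.approx(1.0)
        assert 0.0 <= pf <= 1.0 and 0.0 <= pb <= 1.0


class TestPerCapitaRisk:
    def test_symmetric_substitution(self):
        p = make_params(beta=1.0, p_capture_f=0.5)
        assert per_capita_kill_probability("F", 10, 10, p) == pytest.approx(0.025)

    def test_modes_coincide_at_equal_counts(self):
        for beta, pf, pb in itertools.product(
            (0.2, 0.5, 1.0), (0.1, 0.8), (0.3, 0.6)
        ):
            dep = make_params(beta=beta, p_capture_f=pf, p_capture_b=pb)
            ind = dataclasses.replace(dep, risk_mode="frequency_independent")
            for n in (1, 5, 17):
                for ph in ("F", "B"):
                    assert per_capita_kill_probability(
                        ph, n, n, dep
                    ) == pytest.approx(per_capita_kill_probability(ph, n, n, ind))

    def test_known_value_both_modes(self):
        dep = make_params(beta=0.5, p_capture_b=0.8)
        ind = dataclasses.replace(dep, risk_mode="frequency_independent")
        expected = 0.8 / 7.5
        assert per_capita_kill_probability("B", 5, 5, dep) == pytest.approx(expected)
        assert per_capita_kill_probability("B", 5, 5, ind) == pytest.approx(expected)

    def test_absent_phenotype_is_error(self):
        with pytest.raises(EmptyPopulationError):
            per_capita_kill_probability("F", 0, 5, make_params())

    def test_risk_sharing_inequality_small_grid(self):
        # frequency dependence shifts F-risk below the fixed-share risk
        # exactly when F is the rarer phenotype
        for beta in (0.1, 0.5, 0.9):
            dep = make_params(beta=beta, p_capture_f=0.4)
            ind = dataclasses.replace(dep, risk_mode="frequency_independent")
            for n_f in range(1, 12):
                for n_b in range(1, 12):
                    r_dep = per_capita_kill_probability("F", n_f, n_b, dep)
                    r_ind = per_capita_kill_probability("F", n_f, n_b, ind)
                    if n_f < n_b:
                        assert r_dep < r_ind
                    elif n_f == n_b:
                        assert r_dep == pytest.approx(r_ind)
                    else:
                        assert r_dep > r_ind

    def test_dilution_f_risk_nonincreasing_in_n_b(self):
        p = make_params(beta=0.6, p_capture_f=0.5)
        risks = [
            per_capita_kill_probability("F", 4, n_b, p) for n_b in range(0, 20)
        ]
        assert all(a >= b for a, b in zip(risks, risks[1:]))


class TestSimulateAttack:
    def test_zero_capture_leaves_state_unchanged(self):
        p = make_params(p_capture_f=0.0, p_capture_b=0.0)
        s = state_from_counts([3, 2], [1, 4])
        simulate_attack(s, p, rng())
        assert s.counts_f.tolist() == [3, 2]
        assert s.counts_b.tolist() == [1, 4]
        assert s.kills_this_season == 0

    def test_only_f_present_kill_probability_is_p_capture_f(self):
        p = make_params(beta=0.5, p_capture_f=0.2)
        kills = 0
        r = rng(5)
        n = 20_000
        for _ in range(n):
            s = state_from_counts([3, 0], [0, 0])
            simulate_attack(s, p, r)
            kills += s.kills_this_season
        se = (0.2 * 0.8 / n) ** 0.5
        assert abs(kills / n - 0.2) < 4 * se

    def test_outcome_frequencies_match_trinomial(self):
        # fixed counts (3, 2): empirical {no kill, F kill, B kill} versus
        # the closed-form per-attack probabilities, 4-sigma band
        p = make_params(beta=0.5, p_capture_f=0.2, p_capture_b=0.6)
        q_f, q_b = attack_event_probabilities(3, 2, p)
        n = 100_000
        r = rng(11)
        observed = {"F": 0, "B": 0, "none": 0}
        template = state_from_counts([3, 0, 0], [2, 0, 0])
        for _ in range(n):
            s = template.copy()
            simulate_attack(s, p, r)
            if s.n_f < 3:
                observed["F"] += 1
            elif s.n_b < 2:
                observed["B"] += 1
            else:
                observed["none"] += 1
        for key, prob in (("F", q_f), ("B", q_b), ("none", 1 - q_f - q_b)):
            se = (prob * (1 - prob) / n) ** 0.5
            assert abs(observed[key] / n - prob) < 4 * se, key

    def test_empty_population_is_error(self):
        with pytest.raises(EmptyPopulationError):
            simulate_attack(state_from_counts([0], [0]), make_params(), rng())


class TestAttackSequence:
    def test_no_attacks_no_change(self):
        p = make_params(n_attacks=0)
        s = state_from_counts([2, 3], [4, 1])
        run_attack_sequence(s, p, rng())
        assert s.total == 10 and s.kills_this_season == 0

    def test_certain_capture_kills_exactly_min_attacks_population(self):
        p = make_params(
            n_total=3, n_attacks=5, beta=1.0, p_capture_f=1.0, p_capture_b=1.0
        )
        s = state_from_counts([2, 0], [1, 0])
        run_attack_sequence(s, p, rng())
        assert s.total == 0
        assert s.kills_this_season == 3
        assert s.extinct

    def test_deaths_bounded_by_attack_count(self):
        p = make_params(n_total=20, n_attacks=4, p_capture_f=0.9, p_capture_b=0.9)
        for seed in range(10):
            s = state_from_counts([10, 0], [10, 0])
            run_attack_sequence(s, p, rng(seed))
            assert 20 - s.total == s.kills_this_season <= 4

    def test_sequence_distribution_matches_dp_oracle(self):
        # (2, 2) with two attacks: Monte-Carlo versus exact enumeration
        from fearbold import attack_outcome_distribution

        p = make_params(
            n_total=4, n_attacks=2, beta=0.5, p_capture_f=0.2, p_capture_b=0.6
        )
        exact = attack_outcome_distribution(2, 2, p)
        n = 50_000
        r = rng(17)
        counts = {}
        for _ in range(n):
            s = state_from_counts([2], [2])
            run_attack_sequence(s, p, r)
            key = (s.n_f, s.n_b)
            counts[key] = counts.get(key, 0) + 1
        assert set(counts) <= set(exact)
        for key, prob in exact.items():
            se = max((prob * (1 - prob) / n) ** 0.5, 1e-9)
            assert abs(counts.get(key, 0) / n - prob) < 4 * se, key
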