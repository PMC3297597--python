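"""Per-attack selection, capture, and the stochastic attack sequence.

Each predator attack is realized as a three-stage draw: the predator first
selects a phenotype *group*, then a victim uniformly at random within that
group, and finally captures the victim with the phenotype's capture
probability. Two risk-sharing modes are supported:

frequency-dependent
    The F-group is selected with probability ``beta*n_F / (beta*n_F + n_B)``;
    risk dilutes with group size (each individual in a large group is less
    likely to be the one attacked).

frequency-independent
    The F-group is selected with fixed probability ``beta / (1 + beta)``,
    regardless of the population composition.

The two modes yield identical per-capita risk exactly when ``n_F = n_B``;
away from that point the frequency-dependent mode shifts risk toward the
more numerous phenotype (risk sharing).
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .state import EmptyPopulationError, PopulationState


def group_selection_probability(
    phenotype: str, n_f: int, n_b: int, params: ModelParams
) -> float:
    """Probability that the predator selects the given phenotype group.

    In the degenerate frequency-dependent case where the weighted
    denominator is zero (``beta = 0`` with only F-individuals alive), no
    group can be selected and both probabilities are 0.
    """
    if n_f + n_b == 0:
        raise EmptyPopulationError("cannot select a group in an empty population")
    if params.risk_mode == "frequency_independent":
        p_f = params.beta / (1.0 + params.beta)
        return p_f if phenotype == "F" else 1.0 - p_f
    denom = params.beta * n_f + n_b
    if denom == 0.0:
        return 0.0
    if phenotype == "F":
        return params.beta * n_f / denom
    return n_b / denom


def per_capita_kill_probability(
    phenotype: str, n_f: int, n_b: int, params: ModelParams
) -> float:
    """Probability that one specific individual dies in a single attack.

    Composition of group selection, uniform victim choice within the group,
    and the capture Bernoulli. Undefined (raises) when the queried
    phenotype is absent.
    """
    count = n_f if phenotype == "F" else n_b
    if count < 1:
        raise EmptyPopulationError(
            f"per-capita risk undefined: no {phenotype}-individuals present"
        )
    p_capture = params.p_capture_f if phenotype == "F" else params.p_capture_b
    return group_selection_probability(phenotype, n_f, n_b, params) * p_capture / count


def attack_event_probabilities(
    n_f: int, n_b: int, params: ModelParams
) -> tuple[float, float]:
    """Whole-population outcome probabilities of one attack.

    Returns ``(q_f, q_b)``: the probability that the attack kills an
    F-individual / a B-individual. ``1 - q_f - q_b`` is the no-kill
    probability. This is the single source of truth shared by the
    stochastic simulator and the exact dynamic-programming oracle.
    """
    beta = params.beta
    p_f, p_b = params.p_capture_f, params.p_capture_b
    if params.risk_mode == "frequency_independent":
        s_f = beta / (1.0 + beta)
        s_b = 1.0 - s_f
        if params.empty_group_policy == "renormalize":
            if n_f == 0 and n_b > 0:
                return 0.0, p_b
            if n_b == 0 and n_f > 0:
                return p_f, 0.0
        return (s_f * p_f if n_f > 0 else 0.0, s_b * p_b if n_b > 0 else 0.0)
    denom = beta * n_f + n_b
    if denom == 0.0:
        return 0.0, 0.0
    return beta * n_f * p_f / denom, n_b * p_b / denom


def _remove_uniform_victim(
    state: PopulationState, phenotype: str, rng: np.random.Generator
) -> None:
    # victim chosen uniformly over individuals => age class with probability
    # proportional to its count (the risk model is age-blind)
    counts = state.counts_f if phenotype == "F" else state.counts_b
    n = state.n_f if phenotype == "F" else state.n_b
    j = int(rng.integers(n))
    age_index = int(np.searchsorted(np.cumsum(counts), j, side="right"))
    state.remove_one(phenotype, age_index)


def simulate_attack(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """Realize one predator attack in place; at most one individual dies."""
    if state.total == 0:
        raise EmptyPopulationError("cannot attack an empty population")
    q_f, q_b = attack_event_probabilities(state.n_f, state.n_b, params)
    u = rng.random()
    if u < q_f:
        _remove_uniform_victim(state, "F", rng)
        state.kills_this_season += 1
    elif u < q_f + q_b:
        _remove_uniform_victim(state, "B", rng)
        state.kills_this_season += 1
    return state


def run_attack_sequence(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """Apply the season's ``n_attacks`` sequential attacks in place.

    The outcome probabilities of attack ``k + 1`` use the counts left after
    attack ``k``. If the population empties mid-sequence the remaining
    attacks are skipped and the state is flagged extinct.
    """
    for _ in range(params.n_attacks):
        if state.total == 0:
            break
        simulate_attack(state, params, rng)
    if state.total == 0:
        state.extinct = True
    return state
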