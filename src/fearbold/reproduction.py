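"""End-of-season energy accounting, reproduction, and age advancement.

A fearful individual flees at every threat, so over a season it escapes all
``a + d`` events and retains ``x_F = max(0, e0 - (a + d) * c)`` energy. A
bold individual flees only at the ``a`` real attacks and retains
``x_B = max(0, e0 - a * c)``. Reproductive success is
``f(x) = repro_scale * x ** repro_exponent`` (linear by default).

The population is kept at ``N`` by replacing exactly the season's deaths:
``D = kills + (post-attack individuals at age A)``. Offspring are allocated
to phenotypes with expectation proportional to
``count * f(energy) * background_fitness`` over the post-attack survivors
(age-A individuals reproduce before they are removed), realized as a single
binomial draw so the total is exactly ``D`` and offspring inherit their
mother's phenotype.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .state import EmptyPopulationError, PopulationState


def energy_reserves(phenotype: str, params: ModelParams) -> float:
    """Season-end energy of a surviving individual of the given phenotype.

    Clipped at zero; the clip only matters for configurations in which the
    escape costs exceed the seasonal energy gain.
    """
    n_escapes = params.n_attacks
    if phenotype == "F":
        n_escapes += params.n_disturbances
    return max(0.0, params.energy_gain - n_escapes * params.energy_cost_escape)


def reproductive_success(x: float, params: ModelParams) -> float:
    """Reproductive success f(x) of an individual with energy reserves x."""
    if x < 0:
        raise ValueError(f"energy reserves must be >= 0, got {x}")
    return params.repro_scale * x**params.repro_exponent


def background_fitness(
    n_f: int, n_b: int, params: ModelParams
) -> tuple[float, float]:
    """Competition multipliers (Phi_F, Phi_B); (1, 1) when disabled.

    Linear Lotka-Volterra-style density dependence on the phenotype counts,
    clipped at zero.
    """
    comp = params.competition
    if comp is None:
        return 1.0, 1.0
    phi_f = max(0.0, comp.r_f - comp.a_ff * n_f - comp.a_fb * n_b)
    phi_b = max(0.0, comp.r_b - comp.a_bf * n_f - comp.a_bb * n_b)
    return phi_f, phi_b


def expected_offspring(
    n_f_post: int, n_b_post: int, deaths_total: int, params: ModelParams
) -> tuple[float, float]:
    """Expected numbers of F- and B-offspring (W_F, W_B), W_F + W_B = D.

    Allocation weight of each phenotype is ``count * f(energy) * Phi`` on
    the post-attack counts. If both weights vanish while survivors exist
    (e.g. every phenotype's energy clipped to zero), offspring are
    allocated proportionally to survivor counts instead, so the population
    never silently vanishes under exotic configurations.
    """
    if deaths_total == 0:
        return 0.0, 0.0
    if n_f_post + n_b_post == 0:
        raise EmptyPopulationError(
            "no survivors left to reproduce; population is extinct"
        )
    phi_f, phi_b = background_fitness(n_f_post, n_b_post, params)
    w_f = n_f_post * reproductive_success(energy_reserves("F", params), params) * phi_f
    w_b = n_b_post * reproductive_success(energy_reserves("B", params), params) * phi_b
    denom = w_f + w_b
    if denom > 0.0:
        share_f = w_f / denom
    else:
        share_f = n_f_post / (n_f_post + n_b_post)
    wf = deaths_total * share_f
    return wf, deaths_total - wf


def realize_offspring(
    w_f: float, deaths_total: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (k_F, k_B) with k_F ~ Binomial(D, W_F / D) and k_F + k_B = D."""
    if deaths_total == 0:
        return 0, 0
    if not 0.0 <= w_f <= deaths_total:
        raise ValueError(
            f"expected F-offspring {w_f} outside [0, {deaths_total}]"
        )
    k_f = int(rng.binomial(deaths_total, w_f / deaths_total))
    return k_f, deaths_total - k_f


def advance_season(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """End-of-season bookkeeping, in place; returns the next season start.

    Order of events: post-attack survivors (including the age-A cohort)
    reproduce; the age-A cohort is removed; every remaining survivor ages
    one season; the ``D`` newborns enter at age 1. The returned state again
    holds exactly ``n_total`` individuals.
    """
    if state.total == 0:
        state.extinct = True
        return state
    age_a_f = int(state.counts_f[-1])
    age_a_b = int(state.counts_b[-1])
    deaths_total = state.kills_this_season + age_a_f + age_a_b
    w_f, _ = expected_offspring(state.n_f, state.n_b, deaths_total, params)
    k_f, k_b = realize_offspring(w_f, deaths_total, rng)

    counts_f = state.counts_f
    counts_b = state.counts_b
    counts_f[1:] = counts_f[:-1]  # survivors age by one season
    counts_b[1:] = counts_b[:-1]
    counts_f[0] = k_f  # newborns enter at age 1
    counts_b[0] = k_b
    state.n_f = state.n_f - age_a_f + k_f
    state.n_b = state.n_b - age_a_b + k_b
    state.kills_this_season = 0
    state.season_index += 1
    return state
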