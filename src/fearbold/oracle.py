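"""Exact small-population reference computations.

Two layers of ground truth against which the stochastic engine is checked:

* :func:`attack_outcome_distribution` — the exact distribution of the
  post-attack counts after the season's sequential attacks, by dynamic
  programming over the (n_F, n_B) lattice.
* :func:`season_transition_kernel` / :func:`exact_fixation_probability` —
  in the non-overlapping-generation limit (max_age = 1) every individual is
  removed at season end, so the season-to-season dynamics of n_F is a
  Markov chain on {0, ..., N}. Composing the attack DP with the binomial
  offspring draw gives the exact one-season kernel, and the absorbing-chain
  linear solve gives the exact fixation probabilities that the
  Monte-Carlo protocol estimates.

The A = 1 restriction keeps the state space one-dimensional; it exercises
the predation, energy, allocation, and absorption logic end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import ModelParams, validate_params
from .predation import attack_event_probabilities
from .reproduction import expected_offspring


def attack_outcome_distribution(
    n_f: int, n_b: int, params: ModelParams
) -> dict[tuple[int, int], float]:
    """Exact distribution of (n_F', n_B') after the attack sequence.

    Dynamic programming: each attack maps a count state to at most three
    successors (no kill, F killed, B killed) with the same per-attack
    probabilities the simulator uses. The empty state is absorbing.
    """
    if n_f + n_b == 0:
        raise ValueError("initial population must be non-empty")
    dist: dict[tuple[int, int], float] = {(n_f, n_b): 1.0}
    for _ in range(params.n_attacks):
        nxt: dict[tuple[int, int], float] = {}
        for (f, b), p in dist.items():
            if f + b == 0:
                nxt[(f, b)] = nxt.get((f, b), 0.0) + p
                continue
            q_f, q_b = attack_event_probabilities(f, b, params)
            q_none = 1.0 - q_f - q_b
            if q_f > 0.0:
                nxt[(f - 1, b)] = nxt.get((f - 1, b), 0.0) + p * q_f
            if q_b > 0.0:
                nxt[(f, b - 1)] = nxt.get((f, b - 1), 0.0) + p * q_b
            if q_none > 0.0:
                nxt[(f, b)] = nxt.get((f, b), 0.0) + p * q_none
        dist = nxt
    return dist


@dataclass
class SeasonKernel:
    """Exact one-season transition kernel for the A = 1 chain.

    ``matrix[i, j]`` is the probability that a season starting with ``i``
    fearful individuals (out of N) starts the next season with ``j``;
    ``extinct[i]`` is the probability that the attacks wipe out the whole
    population mid-season (possible only when n_attacks >= N with high
    capture probabilities). Each row of ``[matrix | extinct]`` sums to 1.
    """

    matrix: np.ndarray
    extinct: np.ndarray


def season_transition_kernel(params: ModelParams) -> SeasonKernel:
    """Exact season-to-season kernel of n_F; requires max_age = 1.

    With A = 1 every post-attack survivor is at the maximum age, so all N
    slots are refilled each season: the next-season F-count is binomial
    with mean W_F computed on the exact post-attack counts.
    """
    validate_params(params)
    if params.max_age != 1:
        raise ValueError("season_transition_kernel requires max_age = 1")
    n = params.n_total
    support = np.arange(n + 1)
    matrix = np.zeros((n + 1, n + 1))
    extinct = np.zeros(n + 1)
    for i in range(n + 1):
        for (f, b), p in attack_outcome_distribution(i, n - i, params).items():
            if f + b == 0:
                extinct[i] += p
                continue
            # D = kills + all survivors (every survivor is age A = 1) = N
            w_f, _ = expected_offspring(f, b, n, params)
            matrix[i] += p * stats.binom.pmf(support, n, w_f / n)
    return SeasonKernel(matrix=matrix, extinct=extinct)


def exact_fixation_probability(params: ModelParams) -> np.ndarray:
    """Exact probability of F-fixation from each initial count n_F.

    Solves the absorbing-Markov-chain linear system on the season kernel:
    rho(0) = 0, rho(N) = 1, and for transient states
    ``(I - Q) rho = t_N`` where ``t_N`` is the one-step probability of
    hitting the all-F state. Mid-season extinction is a third absorbing
    outcome and contributes nothing to rho. Requires max_age = 1 and
    competition disabled (so the pure states are absorbing).
    """
    if params.competition is not None:
        raise ValueError(
            "exact_fixation_probability requires competition disabled"
        )
    kernel = season_transition_kernel(params)
    n = params.n_total
    rho = np.zeros(n + 1)
    rho[n] = 1.0
    if n >= 2:
        transient = np.arange(1, n)
        q = kernel.matrix[np.ix_(transient, transient)]
        t_n = kernel.matrix[transient, n]
        rho[transient] = np.linalg.solve(np.eye(n - 1) - q, t_n)
    return rho
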