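"""Season loop, run-to-fixation replicates, and experiment drivers.

The phenotypes are inherited without mutation, so with competition disabled
the pure-F and pure-B populations are absorbing: every replicate either
fixes for fearfulness, fixes for boldness, goes extinct (possible only when
the attacks can wipe out the whole population within one season), or hits
the season cap. The fixation frequency rho_F estimates the probability of
absorbing at the all-F state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .params import ModelParams, validate_params
from .predation import run_attack_sequence
from .reproduction import advance_season
from .state import PopulationState, initial_state

logger = logging.getLogger(__name__)

OUTCOME_F_FIXED = "F_fixed"
OUTCOME_B_FIXED = "B_fixed"
OUTCOME_TIMEOUT = "timeout"
OUTCOME_EXTINCT = "extinct"


@dataclass
class ReplicateResult:
    """Outcome of one run-to-fixation replicate."""

    outcome: str
    seasons_elapsed: int
    trajectory: Optional[list[tuple[int, int, int]]] = None


@dataclass
class FixationEstimate:
    """Monte-Carlo estimate of the fixation frequency rho_F.

    ``rho_f = n_f_fixed / n_replicates`` with a 95% Wilson score interval.
    Timeouts and extinctions are reported separately and never counted as
    fixations.
    """

    n_replicates: int
    n_f_fixed: int
    n_b_fixed: int
    n_timeout: int
    n_extinct: int
    rho_f: float
    ci_low: float
    ci_high: float


@dataclass
class CoexistenceSummary:
    """Trajectory statistics of a fixed-length coexistence run."""

    mean_freq_f_window: float
    sd_freq_f_window: float
    window: int
    persisted: bool
    seasons_run: int


def replicate_rng(base_seed: int, replicate_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate.

    Uses a counter-based SeedSequence spawn key, so replicates are
    uncorrelated and the experiment parallelizes without coordination.
    """
    return np.random.default_rng(
        np.random.SeedSequence(base_seed, spawn_key=(replicate_index,))
    )


def run_season(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """One full breeding season: attack sequence, then reproduction."""
    run_attack_sequence(state, params, rng)
    if state.extinct:
        return state
    return advance_season(state, params, rng)


def _absorbed(state: PopulationState, n_total: int) -> Optional[str]:
    if state.n_b == 0 and state.n_f == n_total:
        return OUTCOME_F_FIXED
    if state.n_f == 0 and state.n_b == n_total:
        return OUTCOME_B_FIXED
    return None


def run_replicate(
    params: ModelParams,
    replicate_index: int,
    record_trajectory: bool = False,
) -> ReplicateResult:
    """Run one replicate until fixation, extinction, or the season cap.

    The replicate's random stream is fully determined by
    ``(params.base_seed, replicate_index)``.
    """
    rng = replicate_rng(params.base_seed, replicate_index)
    state = initial_state(params, rng)
    trajectory = [(0, state.n_f, state.n_b)] if record_trajectory else None

    outcome = _absorbed(state, params.n_total)
    while outcome is None and state.season_index < params.max_seasons:
        run_season(state, params, rng)
        if record_trajectory:
            trajectory.append((state.season_index, state.n_f, state.n_b))
        if state.extinct:
            outcome = OUTCOME_EXTINCT
            break
        outcome = _absorbed(state, params.n_total)
    if outcome is None:
        outcome = OUTCOME_TIMEOUT
    return ReplicateResult(
        outcome=outcome,
        seasons_elapsed=state.season_index,
        trajectory=trajectory,
    )


def estimate_fixation_frequency(
    params: ModelParams,
    n_replicates: int | None = None,
) -> FixationEstimate:
    """Estimate rho_F over independent replicates (default 1000).

    Counts every terminal outcome separately; the Wilson interval is on
    the F-fixation proportion among *all* replicates.
    """
    validate_params(params)
    m = params.n_replicates if n_replicates is None else n_replicates
    counts = {
        OUTCOME_F_FIXED: 0,
        OUTCOME_B_FIXED: 0,
        OUTCOME_TIMEOUT: 0,
        OUTCOME_EXTINCT: 0,
    }
    for i in range(m):
        counts[run_replicate(params, i).outcome] += 1
        if (i + 1) % 100 == 0:
            logger.info("replicate %d/%d done", i + 1, m)
    rho_f = counts[OUTCOME_F_FIXED] / m
    ci_low, ci_high = proportion_confint(
        counts[OUTCOME_F_FIXED], m, alpha=0.05, method="wilson"
    )
    return FixationEstimate(
        n_replicates=m,
        n_f_fixed=counts[OUTCOME_F_FIXED],
        n_b_fixed=counts[OUTCOME_B_FIXED],
        n_timeout=counts[OUTCOME_TIMEOUT],
        n_extinct=counts[OUTCOME_EXTINCT],
        rho_f=rho_f,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def run_coexistence_experiment(
    params: ModelParams,
    n_seasons: int,
    window: int = 100,
    replicate_index: int = 0,
) -> tuple[np.ndarray, CoexistenceSummary]:
    """Fixed-length run for coexistence statistics (no fixation stop).

    Runs exactly ``n_seasons`` seasons (continuing through fixation, where
    the frequency simply stays pegged) and summarizes the F-frequency over
    the trailing ``window`` seasons: its mean and its standard deviation
    (the strength of random fluctuation). ``persisted`` is true when both
    phenotypes are present at the final season. An extinction terminates
    the trajectory early with ``persisted = False``.

    Returns ``(trajectory, summary)`` where trajectory rows are
    ``(season, n_f, n_b)`` including season 0.
    """
    validate_params(params)
    if params.competition is None:
        raise ValueError("coexistence experiments require competition parameters")
    if not 1 <= window <= n_seasons:
        raise ValueError(f"window must lie in [1, n_seasons], got {window}")
    rng = replicate_rng(params.base_seed, replicate_index)
    state = initial_state(params, rng)
    rows = [(0, state.n_f, state.n_b)]
    for _ in range(n_seasons):
        run_season(state, params, rng)
        if state.extinct:
            break
        rows.append((state.season_index, state.n_f, state.n_b))
    trajectory = np.asarray(rows, dtype=np.int64)
    seasons_run = int(trajectory[-1, 0])
    tail = trajectory[-min(window, len(trajectory)):]
    freq = tail[:, 1] / (tail[:, 1] + tail[:, 2])
    persisted = (not state.extinct) and state.n_f > 0 and state.n_b > 0
    summary = CoexistenceSummary(
        mean_freq_f_window=float(freq.mean()),
        sd_freq_f_window=float(freq.std()),
        window=window,
        persisted=persisted,
        seasons_run=seasons_run,
    )
    return trajectory, summary
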