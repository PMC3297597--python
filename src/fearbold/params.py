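"""Model parameters, validation, and JSON configuration handling.

One :class:`ModelParams` instance fully describes a simulation scenario: the
demography (population size ``N``, maximum age ``A``), the predation regime
(``a`` attacks and ``d`` non-lethal disturbances per breeding season, the
selection bias ``beta`` and the capture probabilities), the energy budget
(seasonal gain ``e0`` and per-escape cost ``c``), the optional
Lotka-Volterra-style competition ("background fitness"), and the replicate
protocol (initial condition, season cap, replicate count, base seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

RISK_MODES = ("frequency_dependent", "frequency_independent")
AGE_DISTRIBUTIONS = ("uniform", "all_youngest")
EMPTY_GROUP_POLICIES = ("fail", "renormalize")


class ParameterError(ValueError):
    """A model parameter violates its admissible range."""


class ConfigError(ValueError):
    """A configuration file is malformed (unknown key, bad nesting, ...)."""


@dataclass(frozen=True)
class CompetitionParams:
    """Coefficients of the Lotka-Volterra-style background fitness.

    The background fitness of each phenotype is a linear function of the
    post-attack phenotype counts, clipped at zero::

        Phi_F = max(0, r_f - a_ff * n_F - a_fb * n_B)
        Phi_B = max(0, r_b - a_bf * n_F - a_bb * n_B)

    Subscript convention: the *first* index is the affected phenotype, the
    *second* is the source. ``a_fb`` is the per-capita effect of bold
    individuals on fearful individuals.
    """

    r_f: float
    r_b: float
    a_ff: float = 0.0
    a_fb: float = 0.0
    a_bf: float = 0.0
    a_bb: float = 0.0


@dataclass(frozen=True)
class ModelParams:
    """All biological and protocol constants of one scenario.

    Parameters
    ----------
    n_total : int
        Total population size ``N``; held constant at every season start.
    max_age : int
        Maximum natural life ``A`` in breeding seasons. Individuals that
        reach age ``A`` are removed at the end of that season even if they
        escaped every predator.
    n_attacks : int
        Number of real (potentially lethal) predator attacks per season.
    n_disturbances : int
        Number of non-lethal disturbing events per season. Disturbances
        never kill; they only drain the energy of fearful individuals, who
        flee at every threat.
    beta : float
        Relative probability that a fearful individual is selected by the
        predator, compared with a bold one. ``beta`` near 0 means fearful
        individuals are almost never targeted; ``beta = 1`` shares the
        targeting risk equally.
    p_capture_f, p_capture_b : float
        Probability that a selected fearful / bold individual is actually
        captured. Boldness typically implies a higher capture probability
        (the bold bird stays on alert instead of fleeing at once).
    energy_gain : float
        Total energy ``e0`` gained over a breeding season.
    energy_cost_escape : float
        Energy ``c`` lost per escape flight.
    repro_scale : float
        Proportionality constant of the reproductive-success function
        ``f(x) = repro_scale * x ** repro_exponent``. It cancels in the
        offspring-allocation ratio and is exposed only for completeness.
    repro_exponent : float
        Exponent of the reproductive-success function; 1.0 gives the
        default linear form ("reproductive success proportional to energy
        reserves").
    risk_mode : str
        ``"frequency_dependent"``: the predator targets a phenotype group
        in proportion to its (beta-weighted) abundance, producing an
        emergent dilution effect. ``"frequency_independent"``: the target
        group is chosen with fixed probability beta/(1+beta) regardless of
        the population composition.
    empty_group_policy : str
        Frequency-independent mode only: what happens when the selected
        group is empty. ``"fail"`` (default) wastes the attack;
        ``"renormalize"`` redirects it to the non-empty group.
    competition : CompetitionParams or None
        ``None`` disables background fitness (Phi identically 1).
    init_freq_f : float
        Initial proportion of fearful individuals.
    init_age_distribution : str
        ``"uniform"``: each founder's age drawn independently uniform on
        1..A. ``"all_youngest"``: every founder starts at age 1
        (deterministic; useful for tests).
    max_seasons : int
        Cap on seasons per replicate; replicates that hit it are reported
        as timeouts, never as fixations.
    n_replicates : int
        Default replicate count for fixation-frequency estimates.
    base_seed : int
        Root of the reproducible random stream. Replicate ``i`` uses the
        spawn-key child ``(base_seed, i)``.
    """

    n_total: int
    max_age: int
    n_attacks: int = 0
    n_disturbances: int = 0
    beta: float = 1.0
    p_capture_f: float = 0.0
    p_capture_b: float = 0.0
    energy_gain: float = 1.0
    energy_cost_escape: float = 0.0
    repro_scale: float = 1.0
    repro_exponent: float = 1.0
    risk_mode: str = "frequency_dependent"
    empty_group_policy: str = "fail"
    competition: CompetitionParams | None = None
    init_freq_f: float = 0.5
    init_age_distribution: str = "uniform"
    max_seasons: int = 100_000
    n_replicates: int = 1000
    base_seed: int = 0

    def validated(self) -> "ModelParams":
        """Return ``self`` unchanged if every invariant holds."""
        return validate_params(self)


_PROBABILITY_FIELDS = ("beta", "p_capture_f", "p_capture_b", "init_freq_f")
_NONNEGATIVE_FIELDS = ("energy_gain", "energy_cost_escape")
_POSITIVE_FIELDS = ("repro_scale", "repro_exponent")


def validate_params(params: ModelParams) -> ModelParams:
    """Validate a :class:`ModelParams`, raising :class:`ParameterError`.

    The error message always names the offending field.
    """
    if params.n_total < 2:
        raise ParameterError(
            f"n_total must be >= 2 for a two-phenotype contest, got {params.n_total}"
        )
    if params.max_age < 1:
        raise ParameterError(f"max_age must be >= 1, got {params.max_age}")
    if params.n_attacks < 0:
        raise ParameterError(f"n_attacks must be >= 0, got {params.n_attacks}")
    if params.n_disturbances < 0:
        raise ParameterError(
            f"n_disturbances must be >= 0, got {params.n_disturbances}"
        )
    for name in _PROBABILITY_FIELDS:
        value = getattr(params, name)
        if not 0.0 <= value <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {value}")
    for name in _NONNEGATIVE_FIELDS:
        value = getattr(params, name)
        if value < 0.0:
            raise ParameterError(f"{name} must be >= 0, got {value}")
    for name in _POSITIVE_FIELDS:
        value = getattr(params, name)
        if value <= 0.0:
            raise ParameterError(f"{name} must be > 0, got {value}")
    if params.risk_mode not in RISK_MODES:
        raise ParameterError(
            f"risk_mode must be one of {RISK_MODES}, got {params.risk_mode!r}"
        )
    if params.init_age_distribution not in AGE_DISTRIBUTIONS:
        raise ParameterError(
            "init_age_distribution must be one of "
            f"{AGE_DISTRIBUTIONS}, got {params.init_age_distribution!r}"
        )
    if params.empty_group_policy not in EMPTY_GROUP_POLICIES:
        raise ParameterError(
            "empty_group_policy must be one of "
            f"{EMPTY_GROUP_POLICIES}, got {params.empty_group_policy!r}"
        )
    if params.max_seasons < 1:
        raise ParameterError(f"max_seasons must be >= 1, got {params.max_seasons}")
    if params.n_replicates < 1:
        raise ParameterError(
            f"n_replicates must be >= 1, got {params.n_replicates}"
        )
    comp = params.competition
    if comp is not None:
        if comp.r_f <= 0 or comp.r_b <= 0:
            raise ParameterError(
                f"competition r_f and r_b must be > 0, got ({comp.r_f}, {comp.r_b})"
            )
        for name in ("a_ff", "a_fb", "a_bf", "a_bb"):
            value = getattr(comp, name)
            if value < 0:
                raise ParameterError(
                    f"competition coefficient {name} must be >= 0, got {value}"
                )
    return params


def round_half_up(x: float) -> int:
    """Deterministic round-half-up, so 0.5 grids map to exact counts."""
    return int(math.floor(x + 0.5))


# --- JSON configuration -----------------------------------------------------

_MODEL_FIELDS = {f.name for f in fields(ModelParams)}
_COMPETITION_FIELDS = {f.name for f in fields(CompetitionParams)}


def params_from_dict(data: dict[str, Any]) -> ModelParams:
    """Build validated :class:`ModelParams` from a plain dict.

    Keys must be ModelParams field names; unknown keys raise
    :class:`ConfigError` (this catches typos early). Keys starting with an
    underscore are ignored, which allows comment fields in JSON configs.
    """
    clean: dict[str, Any] = {}
    for key, value in data.items():
        if key.startswith("_"):
            continue
        if key not in _MODEL_FIELDS:
            raise ConfigError(f"unknown configuration key: {key!r}")
        clean[key] = value
    comp = clean.get("competition")
    if comp is not None:
        if not isinstance(comp, dict):
            raise ConfigError("competition must be an object or null")
        unknown = set(comp) - _COMPETITION_FIELDS
        if unknown:
            raise ConfigError(f"unknown competition key(s): {sorted(unknown)}")
        clean["competition"] = CompetitionParams(**comp)
    return validate_params(ModelParams(**clean))


def params_to_dict(params: ModelParams) -> dict[str, Any]:
    """Inverse of :func:`params_from_dict` (competition as nested dict)."""
    return asdict(params)


def load_config(path: str | Path) -> tuple[ModelParams, dict[str, list] | None]:
    """Load a JSON config file.

    The file holds ModelParams fields at the top level, plus an optional
    ``sweep_axes`` object mapping parameter names to lists of values (used
    by the sweep subcommands). Returns ``(params, sweep_axes)``.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a JSON object")
    axes = data.pop("sweep_axes", None)
    if axes is not None:
        if not isinstance(axes, dict):
            raise ConfigError("sweep_axes must be an object of name -> list")
        for name, values in axes.items():
            if name not in _MODEL_FIELDS:
                raise ConfigError(f"sweep_axes references unknown parameter {name!r}")
            if not isinstance(values, list) or not values:
                raise ConfigError(f"sweep_axes[{name!r}] must be a non-empty list")
    params = params_from_dict(data)
    return params, axes
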