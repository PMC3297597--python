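"""Age-structured population state within a breeding season."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, round_half_up


class EmptyPopulationError(RuntimeError):
    """An operation that requires living individuals met an empty population."""


@dataclass
class PopulationState:
    """Counts of fearful (F) and bold (B) individuals per age class.

    ``counts_f[i]`` / ``counts_b[i]`` hold the number of individuals of age
    ``i + 1`` (ages run 1..A). Totals are cached in ``n_f`` / ``n_b`` and
    kept in sync by the mutating operations in :mod:`fearbold.predation`
    and :mod:`fearbold.reproduction`.
    """

    counts_f: np.ndarray
    counts_b: np.ndarray
    kills_this_season: int = 0
    season_index: int = 0
    extinct: bool = False
    n_f: int = field(init=False)
    n_b: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts_f = np.asarray(self.counts_f, dtype=np.int64)
        self.counts_b = np.asarray(self.counts_b, dtype=np.int64)
        if self.counts_f.shape != self.counts_b.shape:
            raise ValueError("counts_f and counts_b must have equal length")
        if (self.counts_f < 0).any() or (self.counts_b < 0).any():
            raise ValueError("age-class counts must be non-negative")
        self.n_f = int(self.counts_f.sum())
        self.n_b = int(self.counts_b.sum())

    @property
    def total(self) -> int:
        return self.n_f + self.n_b

    @property
    def freq_f(self) -> float:
        """Proportion of fearful individuals (nan when empty)."""
        total = self.total
        return self.n_f / total if total else float("nan")

    def remove_one(self, phenotype: str, age_index: int) -> None:
        """Remove one individual of `phenotype` from age class `age_index`."""
        counts = self.counts_f if phenotype == "F" else self.counts_b
        if counts[age_index] <= 0:
            raise ValueError(
                f"no {phenotype}-individual to remove at age index {age_index}"
            )
        counts[age_index] -= 1
        if phenotype == "F":
            self.n_f -= 1
        else:
            self.n_b -= 1

    def copy(self) -> "PopulationState":
        return PopulationState(
            counts_f=self.counts_f.copy(),
            counts_b=self.counts_b.copy(),
            kills_this_season=self.kills_this_season,
            season_index=self.season_index,
            extinct=self.extinct,
        )


def initial_state(params: ModelParams, rng: np.random.Generator) -> PopulationState:
    """Draw the founding population at the start of season 0.

    The number of fearful founders is ``round_half_up(init_freq_f * N)``
    (exact on the 10%-step grids used in fixation sweeps). Ages are either
    iid uniform on 1..A or all set to 1, per ``init_age_distribution``.
    """
    n = params.n_total
    a = params.max_age
    n_f = round_half_up(params.init_freq_f * n)
    n_b = n - n_f
    if params.init_age_distribution == "all_youngest":
        counts_f = np.zeros(a, dtype=np.int64)
        counts_b = np.zeros(a, dtype=np.int64)
        counts_f[0] = n_f
        counts_b[0] = n_b
    else:  # uniform ages
        counts_f = np.bincount(rng.integers(0, a, size=n_f), minlength=a)
        counts_b = np.bincount(rng.integers(0, a, size=n_b), minlength=a)
    return PopulationState(counts_f=counts_f, counts_b=counts_b)
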