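"""Experiment sweep drivers and CSV output.

A sweep is the cross-product of one or more parameter axes over a base
configuration: e.g. initial F-proportion x population size for the
fixation-frequency experiments, attack count x population size for the
predation-intensity experiments, or escape cost x population size. Each
cell runs a full replicate protocol and contributes one CSV row.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import estimate_fixation_frequency, run_coexistence_experiment
from .params import ConfigError, ModelParams, params_to_dict, validate_params

logger = logging.getLogger(__name__)

_MODEL_FIELDS = {f.name for f in fields(ModelParams)}

FIXATION_COLUMNS = [
    "n_replicates",
    "n_f_fixed",
    "n_b_fixed",
    "n_timeout",
    "n_extinct",
    "rho_f",
    "ci_low",
    "ci_high",
    "seed",
]
COEXISTENCE_COLUMNS = [
    "seasons_run",
    "window",
    "mean_freq_f_window",
    "sd_freq_f_window",
    "persisted",
    "seed",
]


@dataclass
class SweepSpec:
    """Cross-product sweep over ModelParams fields.

    ``axes`` maps parameter names to value lists; cells iterate in
    row-major order over the axes in insertion order. ``pair_seeds=True``
    gives every cell the same base seed (common random numbers), which
    pairs replicate trajectories across cells and sharpens monotonicity
    comparisons; the default derives an independent seed per cell.
    """

    base: ModelParams
    axes: dict[str, Sequence[Any]] = field(default_factory=dict)
    n_replicates: int | None = None
    base_seed: int | None = None
    pair_seeds: bool = False

    def __post_init__(self) -> None:
        validate_params(self.base)
        for name in self.axes:
            if name not in _MODEL_FIELDS:
                raise ConfigError(f"sweep axis {name!r} is not a model parameter")
            if name == "competition":
                raise ConfigError("competition cannot be swept directly")
            if len(self.axes[name]) == 0:
                raise ConfigError(f"sweep axis {name!r} is empty")

    @property
    def root_seed(self) -> int:
        return self.base.base_seed if self.base_seed is None else self.base_seed

    def cells(self):
        """Yield (cell_index, {name: value}, cell_params)."""
        names = list(self.axes)
        for index, values in enumerate(itertools.product(*self.axes.values())):
            overrides = dict(zip(names, values))
            seed = self._cell_seed(index)
            params = replace(self.base, base_seed=seed, **overrides)
            if self.n_replicates is not None:
                params = replace(params, n_replicates=self.n_replicates)
            yield index, overrides, validate_params(params)

    def _cell_seed(self, index: int) -> int:
        if self.pair_seeds:
            return self.root_seed
        seq = np.random.SeedSequence(self.root_seed, spawn_key=(index,))
        return int(seq.generate_state(1)[0])


def run_fixation_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run a fixation-frequency estimate in every cell of the sweep.

    Column order: the swept parameter columns (axis order), then
    ``FIXATION_COLUMNS``.
    """
    rows = []
    for index, overrides, params in spec.cells():
        logger.info("fixation sweep cell %d: %s", index, overrides)
        est = estimate_fixation_frequency(params)
        rows.append(
            {
                **overrides,
                "n_replicates": est.n_replicates,
                "n_f_fixed": est.n_f_fixed,
                "n_b_fixed": est.n_b_fixed,
                "n_timeout": est.n_timeout,
                "n_extinct": est.n_extinct,
                "rho_f": est.rho_f,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "seed": params.base_seed,
            }
        )
    return pd.DataFrame(rows, columns=list(spec.axes) + FIXATION_COLUMNS)


def run_coexistence_sweep(
    spec: SweepSpec, n_seasons: int, window: int = 100
) -> pd.DataFrame:
    """Run a fixed-length coexistence experiment in every cell."""
    if spec.base.competition is None:
        raise ValueError("coexistence sweeps require competition parameters")
    rows = []
    for index, overrides, params in spec.cells():
        logger.info("coexistence sweep cell %d: %s", index, overrides)
        _, summary = run_coexistence_experiment(params, n_seasons, window)
        rows.append(
            {
                **overrides,
                "seasons_run": summary.seasons_run,
                "window": summary.window,
                "mean_freq_f_window": summary.mean_freq_f_window,
                "sd_freq_f_window": summary.sd_freq_f_window,
                "persisted": summary.persisted,
                "seed": params.base_seed,
            }
        )
    return pd.DataFrame(rows, columns=list(spec.axes) + COEXISTENCE_COLUMNS)


def write_results_csv(
    rows: pd.DataFrame,
    path: str | Path,
    params: ModelParams | Mapping[str, Any] | None = None,
) -> None:
    """Write a result table with a '#'-prefixed resolved-parameter header.

    The header embeds the full base parameter set so any row can be
    reproduced from the file alone. Floats use 8 significant digits;
    row order is the cell iteration order.
    """
    path = Path(path)
    header_lines = []
    if params is not None:
        mapping = params_to_dict(params) if isinstance(params, ModelParams) else params
        for key, value in mapping.items():
            header_lines.append(f"# {key} = {value!r}")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        rows.to_csv(fh, index=False, float_format="%.8g")


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_results_csv`."""
    return pd.read_csv(path, comment="#")
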