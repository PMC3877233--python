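"""Model skill metrics and the one-at-a-time parameter sensitivity protocol.

Skill is measured as mean percent error (MPE, here the normalised mean
absolute error 100·mean|obs − pred| / mean(obs)) and root mean square
deviation (RMSD).  Sensitivity follows the classic one-at-a-time design:
each tested parameter is perturbed by ±20%, the model is re-run for a year,
and the RMS deviation of the perturbed trajectory from the base run —
normalised by the base annual mean — flags the parameter as sensitive when
it exceeds 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcing import ForcingSeries, N_DAYS
from .model_core import ModelParameters, ModelState, SigmoidParams
from .simulate import SimulationResult, STATE_VARS, run_year

__all__ = [
    "ObservationSeries",
    "SensitivityReport",
    "mpe",
    "rmsd",
    "match_observations",
    "sensitivity_analysis",
    "DEFAULT_SENSITIVITY_TARGETS",
    "SENSITIVITY_THRESHOLD_PCT",
]

SENSITIVITY_THRESHOLD_PCT = 10.0
PERTURBATION = 0.20

#: parameters perturbed for each state variable: growth/consumption/predation
#: terms directly driving that equation
DEFAULT_SENSITIVITY_TARGETS: tuple[tuple[str, str], ...] = (
    ("P", "pbm"),
    ("P", "wa"),
    ("P", "phtl"),
    ("M", "phtlz"),
    ("B", "alpha"),
    ("B", "kmn1"),
)


class MetricError(ValueError):
    """Invalid input to a skill metric."""


@dataclass(frozen=True)
class ObservationSeries:
    """Sparse pseudo-observations of one variable by day-of-year."""

    day: np.ndarray
    value: np.ndarray
    variable: str = "B"
    site: str = "synthetic"

    def __post_init__(self) -> None:
        day = np.asarray(self.day, dtype=int)
        value = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "value", value)
        if day.shape != value.shape:
            raise ValueError("day and value must have equal length")
        if not np.all(np.isfinite(value)):
            raise ValueError("observation values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "value": self.value,
             "variable": self.variable, "site": self.site}
        )


@dataclass(frozen=True)
class SensitivityReport:
    """Tidy ±20% sensitivity table: one row per (variable, parameter, sign)."""

    table: pd.DataFrame

    def sensitive(self, variable: str, parameter: str) -> bool:
        """True if either perturbation direction exceeded the threshold."""
        rows = self.table[
            (self.table.variable == variable) & (self.table.parameter == parameter)
        ]
        if rows.empty:
            raise KeyError(f"no sensitivity rows for ({variable}, {parameter})")
        return bool(rows.sensitive.any())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise MetricError("observed and predicted must be 1-D of equal length")
    if obs.size == 0:
        raise MetricError("need at least one observation")
    return obs, pred


def mpe(observed, predicted) -> float:
    """Mean percent error: 100 · mean(|obs − pred|) / mean(obs).

    The normalisation by the mean observation (rather than per-point
    division) keeps the metric finite when individual observations are
    near zero.  Zero iff the series are identical.
    """
    obs, pred = _check_pair(observed, predicted)
    denom = float(np.mean(obs))
    if denom <= 0:
        raise MetricError("mean of observed values must be > 0 for MPE")
    return float(100.0 * np.mean(np.abs(obs - pred)) / denom)


def rmsd(observed, predicted) -> float:
    """Root mean square deviation, in the units of the inputs."""
    obs, pred = _check_pair(observed, predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def match_observations(
    result: SimulationResult, obs: ObservationSeries, variable: str
) -> tuple[np.ndarray, np.ndarray]:
    """Inner-join observations to the daily trajectory on day-of-year.

    Returns ``(observed, predicted)`` aligned arrays; observation days
    outside 1..365 are dropped with a warning.
    """
    if variable not in STATE_VARS:
        raise KeyError(f"variable must be one of {STATE_VARS}")
    in_range = (obs.day >= 1) & (obs.day <= N_DAYS)
    n_dropped = int(np.sum(~in_range))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} observation(s) outside days 1..{N_DAYS} excluded",
            stacklevel=2,
        )
    days = obs.day[in_range]
    if days.size == 0:
        raise MetricError("no observations fall within the model year")
    predicted = result.frame[variable].to_numpy()[days - 1]
    return obs.value[in_range], predicted


def sensitivity_analysis(
    params: ModelParameters,
    forcing: ForcingSeries,
    sigmoid: SigmoidParams | None = None,
    init: ModelState | None = None,
    targets: tuple[tuple[str, str], ...] = DEFAULT_SENSITIVITY_TARGETS,
    perturbation: float = PERTURBATION,
) -> SensitivityReport:
    """±perturbation one-at-a-time sensitivity over one model year.

    For each (state variable, parameter) pair the model is re-run with the
    parameter scaled by (1 ± perturbation); rms is the RMS deviation of the
    perturbed from the base daily trajectory of that variable, and
    percent difference = 100·rms / annual mean of the base trajectory.
    A pair is flagged sensitive when the percent difference exceeds 10%.
    """
    base = run_year(params, forcing, sigmoid, init)
    rows = []
    for variable, parameter in targets:
        base_traj = base.state_series(variable)
        base_mean = float(np.mean(base_traj))
        per_dir = {}
        for sign, label in ((-1.0, "-"), (+1.0, "+")):
            factor = 1.0 + sign * perturbation
            perturbed = run_year(
                params.with_scaled(parameter, factor), forcing, sigmoid, init
            )
            rms = float(
                np.sqrt(np.mean((perturbed.state_series(variable) - base_traj) ** 2))
            )
            per_dir[label] = rms
        avg_rms = 0.5 * (per_dir["-"] + per_dir["+"])
        for label in ("-", "+"):
            rms = per_dir[label]
            pct = 100.0 * rms / base_mean if base_mean > 0 else 0.0
            rows.append(
                {
                    "variable": variable,
                    "parameter": parameter,
                    "direction": f"{label}{perturbation:.0%}",
                    "rms": rms,
                    "average_rms": avg_rms,
                    "percent_difference": pct,
                    "sensitive": pct > SENSITIVITY_THRESHOLD_PCT,
                }
            )
    return SensitivityReport(table=pd.DataFrame(rows))
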