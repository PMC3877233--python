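"""Daily environmental forcing: synthetic climatology, DO scenarios, CSV IO.

The model is driven by a 365-day series of water temperature (°C),
photosynthetically active radiation (PAR, mol photons m⁻² d⁻¹), dissolved
oxygen (DO, mg O₂ l⁻¹), sediment particulate organic carbon (POC, g C m⁻³)
and dissolved inorganic nitrogen (DIN, g N m⁻³).  Hypoxia experiments force
the DO series to a target concentration over Julian-day windows, with linear
ramps on either side so the model never sees a step change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

__all__ = [
    "ForcingSeries",
    "DOScenario",
    "ClimatologyConfig",
    "build_synthetic_climatology",
    "apply_do_scenario",
    "scenario_table",
    "read_forcing_csv",
    "write_forcing_csv",
    "read_scenario_config",
]

N_DAYS = 365

FORCING_COLUMNS = ("day", "temperature", "par", "do_conc", "poc", "din")


class ForcingError(ValueError):
    """Invalid forcing series or forcing file."""


class ScenarioError(ValueError):
    """Invalid DO scenario definition."""


@dataclass(frozen=True)
class ForcingSeries:
    """One model year of daily drivers.

    All arrays have length 365 and ``day`` runs 1..365 (leap years are
    ignored; the model year is always 365 days).
    """

    day: np.ndarray
    temperature: np.ndarray
    par: np.ndarray
    do_conc: np.ndarray
    poc: np.ndarray
    din: np.ndarray

    def __post_init__(self) -> None:
        for name in ("day", "temperature", "par", "do_conc", "poc", "din"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if len(self.day) != N_DAYS:
            raise ForcingError(f"forcing must have {N_DAYS} records, got {len(self.day)}")
        if not np.array_equal(self.day, np.arange(1, N_DAYS + 1)):
            raise ForcingError("days must be exactly 1..365 in order")
        for name in ("par", "do_conc", "poc", "din"):
            arr = getattr(self, name)
            if len(arr) != N_DAYS:
                raise ForcingError(f"{name} must have {N_DAYS} values")
            if not np.all(np.isfinite(arr)):
                raise ForcingError(f"{name} contains non-finite values")
            bad = np.where(arr < 0)[0]
            if bad.size:
                raise ForcingError(
                    f"{name} must be >= 0; first violation on day {int(bad[0]) + 1}"
                )
        if not np.all(np.isfinite(self.temperature)):
            raise ForcingError("temperature contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day.astype(int),
                "temperature": self.temperature,
                "par": self.par,
                "do_conc": self.do_conc,
                "poc": self.poc,
                "din": self.din,
            }
        )

    def with_do(self, do_conc: np.ndarray) -> "ForcingSeries":
        return replace(self, do_conc=np.asarray(do_conc, dtype=float))


@dataclass(frozen=True)
class DOScenario:
    """A forced-DO experiment: one or more Julian-day windows at a target DO.

    Window endpoints are inclusive; ``ramp_days`` of linear adjustment sit
    *outside* each window so window days are fully at the target.
    """

    scenario_id: str
    windows: tuple[tuple[int, int, float], ...]
    ramp_days: int = 3

    def __post_init__(self) -> None:
        windows = tuple(
            (int(s), int(e), float(t)) for s, e, t in self.windows
        )
        object.__setattr__(self, "windows", windows)
        if self.ramp_days < 0:
            raise ScenarioError("ramp_days must be >= 0")
        prev_end = 0
        for start, end, target in windows:
            if not (1 <= start <= end <= N_DAYS):
                raise ScenarioError(
                    f"{self.scenario_id}: window {start}-{end} outside 1..{N_DAYS}"
                )
            if target < 0:
                raise ScenarioError(f"{self.scenario_id}: target DO must be >= 0")
            if start <= prev_end:
                raise ScenarioError(
                    f"{self.scenario_id}: windows must be sorted and non-overlapping"
                )
            prev_end = end

    def duration_days(self) -> int:
        """Total window days (inclusive endpoints), excluding ramps."""
        return sum(end - start + 1 for start, end, _ in self.windows)


@dataclass(frozen=True)
class ClimatologyConfig:
    """Synthetic lower-estuary annual climatology.

    Temperature and PAR are single-harmonic sinusoids (mean, amplitude,
    peak day); DO follows a seasonal drawdown — at its baseline most of the
    year, dipping by ``do_drawdown`` around the warm-season trough day.
    POC and DIN are constant baselines.  Optional i.i.d. Gaussian noise
    (SD per variable's units) is added to every driver, with DO, PAR, POC
    and DIN clipped at zero.
    """

    temp_mean: float = 16.0
    temp_amplitude: float = 10.0
    temp_peak_day: int = 212
    par_mean: float = 28.0
    par_amplitude: float = 18.0
    par_peak_day: int = 172
    do_base: float = 7.0
    do_drawdown: float = 2.0
    do_trough_day: int = 212
    poc_base: float = 2.0
    din_base: float = 0.2
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.temp_amplitude < 0 or self.par_amplitude < 0 or self.do_drawdown < 0:
            raise ForcingError("amplitudes must be non-negative")
        for name in ("temp_peak_day", "par_peak_day", "do_trough_day"):
            d = getattr(self, name)
            if not (1 <= d <= N_DAYS):
                raise ForcingError(f"{name} must lie in 1..{N_DAYS}")
        if self.noise_sd < 0:
            raise ForcingError("noise_sd must be >= 0")


def _sinusoid(days: np.ndarray, mean: float, amplitude: float, peak_day: int) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * np.pi * (days - peak_day) / N_DAYS)


def build_synthetic_climatology(
    config: ClimatologyConfig | None = None, seed: int = 0
) -> ForcingSeries:
    """Generate one deterministic-plus-noise year of forcing.

    With ``noise_sd = 0`` the output is fully deterministic: temperature and
    PAR peak exactly at their configured days, and DO attains its minimum
    ``do_base - do_drawdown`` at the trough day.
    """
    config = config or ClimatologyConfig()
    days = np.arange(1, N_DAYS + 1, dtype=float)
    temperature = _sinusoid(days, config.temp_mean, config.temp_amplitude, config.temp_peak_day)
    par = _sinusoid(days, config.par_mean, config.par_amplitude, config.par_peak_day)
    # seasonal drawdown: DO sits at do_base in winter, dips by do_drawdown in summer
    drawdown = 0.5 * config.do_drawdown * (
        1.0 + np.cos(2.0 * np.pi * (days - config.do_trough_day) / N_DAYS)
    )
    do_conc = config.do_base - drawdown
    poc = np.full(N_DAYS, config.poc_base)
    din = np.full(N_DAYS, config.din_base)
    if config.noise_sd > 0:
        rng = np.random.default_rng(seed)
        temperature = temperature + rng.normal(0.0, config.noise_sd, N_DAYS)
        par = par + rng.normal(0.0, config.noise_sd, N_DAYS)
        do_conc = do_conc + rng.normal(0.0, config.noise_sd, N_DAYS)
        poc = poc + rng.normal(0.0, config.noise_sd, N_DAYS)
        din = din + rng.normal(0.0, 0.1 * config.noise_sd, N_DAYS)
    return ForcingSeries(
        day=np.arange(1, N_DAYS + 1),
        temperature=temperature,
        par=np.clip(par, 0.0, None),
        do_conc=np.clip(do_conc, 0.0, None),
        poc=np.clip(poc, 0.0, None),
        din=np.clip(din, 0.0, None),
    )


def apply_do_scenario(base: ForcingSeries, scenario: DOScenario) -> ForcingSeries:
    """Force the DO series per a scenario; every other driver is untouched.

    Window days (inclusive) are held at the target concentration.  In the
    ``ramp_days`` days immediately before each window DO descends linearly
    from the base series toward the target, and in the ``ramp_days`` days
    after it returns linearly to the base series.  The operation is
    idempotent: window interiors are overwritten, not accumulated.
    """
    do = base.do_conc.copy()
    ramp = scenario.ramp_days
    prev_span_end = 0
    for start, end, target in scenario.windows:
        if start - ramp < 1 or end + ramp > N_DAYS:
            raise ScenarioError(
                f"{scenario.scenario_id}: window {start}-{end} with {ramp}-day ramps "
                f"exceeds 1..{N_DAYS}"
            )
        if start - ramp <= prev_span_end:
            raise ScenarioError(
                f"{scenario.scenario_id}: windows overlap after ramp expansion"
            )
        prev_span_end = end + ramp
        do[start - 1 : end] = target
        # descending ramp: fractions k/(ramp+1) so the line runs from the
        # base value (just before the ramp) down to the target at the window
        down_anchor = base.do_conc[max(start - ramp - 1, 1) - 1]
        up_anchor = base.do_conc[min(end + ramp + 1, N_DAYS) - 1]
        for k in range(1, ramp + 1):
            frac = k / (ramp + 1.0)
            do[(start - ramp + k - 1) - 1] = down_anchor + (target - down_anchor) * frac
            do[(end + k) - 1] = target + (up_anchor - target) * frac
    return base.with_do(np.clip(do, 0.0, None))


#: Table of the nine standard hypoxia experiments: S1–S4 vary duration at
#: 0.5 mg O₂ l⁻¹ (S4 is intermittent, a 14-day neap–spring cycle); S5–S9 vary
#: severity from 2.0 down to 0.0 mg O₂ l⁻¹ over a fixed 60-day midsummer window.
_SCENARIOS: tuple[tuple[str, tuple[tuple[int, int, float], ...]], ...] = (
    ("S1", ((148, 267, 0.5),)),
    ("S2", ((178, 237, 0.5),)),
    ("S3", ((191, 222, 0.5),)),
    ("S4", ((162, 176, 0.5), (190, 204, 0.5), (218, 232, 0.5), (246, 260, 0.5))),
    ("S5", ((178, 237, 2.0),)),
    ("S6", ((178, 237, 1.5),)),
    ("S7", ((178, 237, 1.0),)),
    ("S8", ((178, 237, 0.5),)),
    ("S9", ((178, 237, 0.0),)),
)


def scenario_table() -> list[DOScenario]:
    """The nine standard duration/severity scenarios with 3-day ramps."""
    return [DOScenario(sid, windows) for sid, windows in _SCENARIOS]


def get_scenario(scenario_id: str) -> DOScenario:
    for s in scenario_table():
        if s.scenario_id == scenario_id:
            return s
    raise ScenarioError(f"unknown scenario id {scenario_id!r}")


def write_forcing_csv(series: ForcingSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_forcing_csv(path) -> ForcingSeries:
    """Read and validate a daily forcing CSV (columns: day, temperature,
    par, do_conc, poc, din)."""
    df = pd.read_csv(path)
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ForcingError(f"forcing CSV missing column(s): {', '.join(missing)}")
    for col in FORCING_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ForcingError(
                f"non-numeric value in column {col!r} at row {int(bad[0]) + 2}"
            )
        if vals.isna().any():
            raise ForcingError(f"missing value in column {col!r}")
        df[col] = vals
    return ForcingSeries(
        day=df["day"].to_numpy(),
        temperature=df["temperature"].to_numpy(),
        par=df["par"].to_numpy(),
        do_conc=df["do_conc"].to_numpy(),
        poc=df["poc"].to_numpy(),
        din=df["din"].to_numpy(),
    )


def read_scenario_config(path) -> DOScenario:
    """Load a scenario from a flat key-value file.

    Format::

        scenario_id = custom
        ramp_days = 3
        windows = 178-237@0.5, 250-260@1.0
    """
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ScenarioError(f"malformed scenario line: {line!r}")
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    try:
        windows = []
        for chunk in fields["windows"].split(","):
            span, _, target = chunk.strip().partition("@")
            start, _, end = span.partition("-")
            windows.append((int(start), int(end), float(target)))
        return DOScenario(
            scenario_id=fields.get("scenario_id", "custom"),
            windows=tuple(windows),
            ramp_days=int(fields.get("ramp_days", 3)),
        )
    except (KeyError, ValueError) as exc:
        raise ScenarioError(f"invalid scenario config: {exc}") from exc
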