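"""Seeded generators for every input the pipeline needs.

Two products: (1) sigmoid-structured (DO, biomass) observation pairs with
multiplicative lognormal noise, emulating biweekly summer grab samples used
to fit the oxygen-mortality modifier; (2) sparse pseudo-observation series
sampled from a simulated trajectory with additive Gaussian noise, standing
in for monitoring-program verification data.  Everything is reproducible
from an explicit integer seed — no generator touches global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import SigmoidParams, unnormalized_sigmoid
from .zprime_fit import BiomassDOObservations
from .evaluate import ObservationSeries
from .forcing import N_DAYS
from .simulate import SimulationResult  # noqa: F401  (typing)

__all__ = [
    "SyntheticConfig",
    "gen_biomass_do_pairs",
    "gen_observation_series",
    "biweekly_summer_days",
]

#: biweekly sampling from May through October (days 121..304 step 14)
def biweekly_summer_days() -> list[int]:
    return list(range(121, 305, 14))


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic observation generators.

    ``truth`` is the sigmoid the pair generator samples from; ``noise_cv``
    is the coefficient of variation of the multiplicative lognormal noise
    on biomass; ``low_do_fraction`` oversamples the hypoxic rise (uniform
    DO sampling alone under-covers it and leaves fits poorly identified).
    """

    truth: SigmoidParams = field(default_factory=lambda: SigmoidParams(a=50.0, b=2.0, c=4.0))
    n_obs: int = 60
    noise_cv: float = 0.2
    do_range: tuple[float, float] = (0.0, 8.0)
    low_do_fraction: float = 0.5   # fraction of points forced below 2 mg/l
    sampling_days: tuple[int, ...] = field(
        default_factory=lambda: tuple(biweekly_summer_days())
    )
    obs_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if self.noise_cv < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        lo, hi = self.do_range
        if not lo < hi:
            raise ValueError("do_range must satisfy min < max")
        if not 0.0 <= self.low_do_fraction <= 1.0:
            raise ValueError("low_do_fraction must lie in [0, 1]")


def gen_biomass_do_pairs(config: SyntheticConfig) -> BiomassDOObservations:
    """Draw (DO, biomass) pairs from the truth sigmoid with lognormal noise.

    Biomass = sigmoid(DO; truth) × LN(mean 1, CV ``noise_cv``); DO is
    uniform over ``do_range`` with ``low_do_fraction`` of the points drawn
    from the hypoxic sub-range below 2 mg O₂ l⁻¹ (clipped to do_range).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.do_range
    n_low = int(round(config.low_do_fraction * config.n_obs))
    low_hi = min(2.0, hi)
    do = np.concatenate(
        [
            rng.uniform(lo, low_hi, n_low),
            rng.uniform(lo, hi, config.n_obs - n_low),
        ]
    )
    rng.shuffle(do)
    curve = unnormalized_sigmoid(do, config.truth)
    if config.noise_cv > 0:
        # lognormal with mean exactly 1: sigma^2 = ln(1 + CV^2), mu = -sigma^2/2
        sigma2 = np.log1p(config.noise_cv**2)
        noise = rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2),
                              size=config.n_obs)
    else:
        noise = np.ones(config.n_obs)
    return BiomassDOObservations(do_conc=do, biomass=curve * noise)


def gen_observation_series(
    truth_run: SimulationResult,
    config: SyntheticConfig,
    variable: str = "B",
) -> ObservationSeries:
    """Sample a simulated trajectory at fixed days with additive noise.

    Gaussian noise of SD ``obs_noise_sd`` is added and the result clipped
    at zero (biomass observations cannot be negative).
    """
    days = np.asarray(config.sampling_days, dtype=int)
    if np.any(days < 1) or np.any(days > N_DAYS):
        raise ValueError(f"sampling days must lie in 1..{N_DAYS}")
    rng = np.random.default_rng(config.seed)
    truth = truth_run.frame[variable].to_numpy()[days - 1]
    if config.obs_noise_sd > 0:
        values = truth + rng.normal(0.0, config.obs_noise_sd, size=days.size)
    else:
        values = truth.copy()
    return ObservationSeries(
        day=days, value=np.clip(values, 0.0, None), variable=variable
    )
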