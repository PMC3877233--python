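"""Fit the biomass-vs-DO sigmoid to field observations and normalise it.

Macrobenthic biomass plotted against dissolved oxygen follows a sharp
sigmoid: biomass collapses below a threshold of roughly 1–2 mg O₂ l⁻¹ and
plateaus under normoxia.  Fitting B(DO) = c / (1 + a·e^(−b·DO)) to paired
(DO, biomass) observations and then replacing the numerator c with 1 yields
the dimensionless 0–1 oxygen-mortality modifier Z' used by the model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_core import SigmoidParams, unnormalized_sigmoid

__all__ = [
    "BiomassDOObservations",
    "FitResult",
    "fit_sigmoid",
    "normalize_sigmoid",
    "read_observations_csv",
    "write_fit_report",
]

MIN_OBSERVATIONS = 6
HYPOXIC_DO = 2.0   # need coverage below this for the rise to be identifiable
NORMOXIC_DO = 4.0  # ... and above this for the plateau

A_MAX = 1e12
B_MAX = 100.0


class FitError(RuntimeError):
    """Sigmoid fit could not be attempted or did not converge."""


class IdentifiabilityError(FitError):
    """Observations do not span the sigmoid's rise and plateau."""


@dataclass(frozen=True)
class BiomassDOObservations:
    """Paired (DO, biomass) field observations, e.g. biweekly grab samples."""

    do_conc: np.ndarray      # mg O2 l-1
    biomass: np.ndarray      # g C m-2 (or an AFDW-derived equivalent)
    site: np.ndarray | None = None
    date: np.ndarray | None = None

    def __post_init__(self) -> None:
        do = np.asarray(self.do_conc, dtype=float)
        bm = np.asarray(self.biomass, dtype=float)
        object.__setattr__(self, "do_conc", do)
        object.__setattr__(self, "biomass", bm)
        if do.shape != bm.shape:
            raise ValueError("do_conc and biomass must have equal length")
        if np.any(do < 0) or np.any(bm < 0):
            raise ValueError("do_conc and biomass must be >= 0")
        if not (np.all(np.isfinite(do)) and np.all(np.isfinite(bm))):
            raise ValueError("observations must be finite")

    def __len__(self) -> int:
        return len(self.do_conc)


@dataclass(frozen=True)
class FitResult:
    params: SigmoidParams
    rss: float  # residual sum of squares on the fitted scale (log or linear)
    converged: bool
    n_obs: int
    covariance: np.ndarray | None = None  # Gauss-Newton (JᵀJ)⁻¹·s² proxy


def _default_init(do: np.ndarray, biomass: np.ndarray) -> SigmoidParams:
    # crude logistic moment matching: amplitude from the observed maximum,
    # steepness from the DO span, offset placing the midpoint at median DO
    c0 = float(np.max(biomass))
    span = float(np.ptp(do)) or 1.0
    b0 = 4.0 / span
    a0 = float(np.exp(b0 * np.median(do)))
    return SigmoidParams(a=a0, b=b0, c=max(c0, 1e-12))


def fit_sigmoid(
    obs: BiomassDOObservations,
    init: SigmoidParams | None = None,
    seed: int | None = None,
    loss: str = "log",
) -> FitResult:
    """Nonlinear least squares for (a, b, c) on biomass residuals.

    The default ``loss="log"`` minimises squared residuals of log biomass,
    which matches the multiplicative error structure of benthic biomass
    data (spread grows with the mean) and keeps the low-biomass hypoxic
    rise — the region that identifies a and b — from being swamped by the
    plateau.  ``loss="linear"`` gives plain unweighted least squares on
    biomass.

    Deterministic given the observations and starting point (``seed`` is
    accepted for interface symmetry; the optimisation itself draws no
    random numbers).  Raises :class:`IdentifiabilityError` when the data
    do not cover both the hypoxic rise (DO < 2) and the normoxic plateau
    (DO > 4) — a fit to one flat region would be silently meaningless.
    """
    if loss not in ("log", "linear"):
        raise ValueError("loss must be 'log' or 'linear'")
    if len(obs) < MIN_OBSERVATIONS:
        raise FitError(
            f"need at least {MIN_OBSERVATIONS} observations, got {len(obs)}"
        )
    do, biomass = obs.do_conc, obs.biomass
    if not np.any(do < HYPOXIC_DO):
        raise IdentifiabilityError(
            "all observations normoxic: sigmoid rise not identifiable"
        )
    if not np.any(do > NORMOXIC_DO):
        raise IdentifiabilityError(
            "all observations hypoxic: sigmoid plateau not identifiable"
        )
    p0 = init or _default_init(do, biomass)

    eps = 1e-12  # guards log() against exact zeros in either curve or data

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, c = theta
        pred = c / (1.0 + a * np.exp(-b * do))
        if loss == "log":
            return np.log(pred + eps) - np.log(biomass + eps)
        return pred - biomass

    sol = least_squares(
        residuals,
        x0=[p0.a, p0.b, p0.c],
        bounds=([1e-12, 1e-12, 1e-12], [A_MAX, B_MAX, np.inf]),
        method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    rss = float(2.0 * sol.cost)
    converged = bool(sol.success)
    cov = None
    if converged:
        # covariance proxy: s^2 (J^T J)^-1 from the Jacobian at the optimum
        dof = max(len(obs) - 3, 1)
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / dof)
        except np.linalg.LinAlgError:
            cov = None
    a, b, c = sol.x
    return FitResult(
        params=SigmoidParams(a=float(a), b=float(b), c=float(c)),
        rss=rss,
        converged=converged,
        n_obs=len(obs),
        covariance=cov,
    )


def normalize_sigmoid(fit: FitResult) -> SigmoidParams:
    """Replace the fitted numerator c with 1, yielding the 0–1 modifier Z'.

    Idempotent; a and b pass through unchanged, so
    z_prime(DO) · c == unnormalized_sigmoid(DO) identically.
    """
    if not fit.converged:
        raise FitError("cannot normalise an unconverged fit")
    return replace(fit.params, c=1.0)


def read_observations_csv(path) -> BiomassDOObservations:
    """Read paired observations (columns do_conc, biomass[, site, date])."""
    df = pd.read_csv(path)
    for col in ("do_conc", "biomass"):
        if col not in df.columns:
            raise ValueError(f"observations CSV missing column {col!r}")
    return BiomassDOObservations(
        do_conc=df["do_conc"].to_numpy(dtype=float),
        biomass=df["biomass"].to_numpy(dtype=float),
        site=df["site"].to_numpy() if "site" in df.columns else None,
        date=df["date"].to_numpy() if "date" in df.columns else None,
    )


def write_fit_report(fit: FitResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"a = {fit.params.a!r}\n")
        fh.write(f"b = {fit.params.b!r}\n")
        fh.write(f"c = {fit.params.c!r}\n")
        fh.write(f"rss = {fit.rss!r}\n")
        fh.write(f"n_obs = {fit.n_obs}\n")
        fh.write(f"converged = {fit.converged}\n")


def read_sigmoid_config(path) -> SigmoidParams:
    """Read a, b, c from a flat key-value file (e.g. a fit report)."""
    vals: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key in ("a", "b", "c"):
                vals[key] = float(value)
    if not {"a", "b"} <= vals.keys():
        raise ValueError(f"sigmoid config {path} must define a and b")
    return SigmoidParams(a=vals["a"], b=vals["b"], c=vals.get("c", 1.0))
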