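"""Governing rate formulations for the three-state estuarine biomass model.

State variables
---------------
P : phytoplankton biomass (g C m⁻³)
M : zooplankton biomass (g C m⁻³), micro- and mesozooplankton combined
B : macrobenthos biomass (g C m⁻²), deposit and suspension feeders combined

The benthic-pelagic coupling runs through two oxygen-response sigmoids:
``Z`` (parameterised by the DO at 50% and 25% of maximum function) scales
macrobenthic respiration and ingestion, while the empirically fitted,
normalised ``Z'`` controls hypoxia-induced macrobenthic mortality,
m = mzero_b·(1 − Z'(DO)).  Zooplankton suffer a separate linear hypoxic
mortality below a 2 mg O₂ l⁻¹ threshold, and predation on macrobenthos is
a quadratic closure whose rate β carries an Arrhenius temperature factor
and a Monod DO dependence (predators hunt less under hypoxia).

Nutrient recycling, a separate suspension-feeder state variable and the
three-pool sediment-carbon split of the parent eutrophication model are
deliberately excluded; sediment POC enters as a single total pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelState",
    "ModelParameters",
    "SigmoidParams",
    "RateDiagnostics",
    "z_function",
    "z_prime",
    "unnormalized_sigmoid",
    "zoo_hypoxic_mortality",
    "arrhenius",
    "predation_rate",
    "phytoplankton_derivative",
    "zooplankton_derivative",
    "macrobenthos_derivative",
    "default_sigmoid",
]


class ParameterError(ValueError):
    """A model parameter violates its constraint."""


class ModelState(NamedTuple):
    """Instantaneous biomass of the three state variables."""

    P: float  # phytoplankton, g C m-3
    M: float  # zooplankton, g C m-3
    B: float  # macrobenthos, g C m-2


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the oxygen-response sigmoid c / (1 + a·e^(−b·DO)).

    ``a`` sets the horizontal offset (midpoint at DO = ln(a)/b), ``b`` the
    steepness in l (mg O₂)⁻¹, and ``c`` the amplitude in g C m⁻²; the
    normalised 0–1 modifier used in the model has c = 1.
    """

    a: float
    b: float
    c: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ParameterError("sigmoid parameters a, b, c must all be > 0")

    @property
    def midpoint_do(self) -> float:
        """DO at which the sigmoid reaches half its amplitude (mg O₂ l⁻¹)."""
        return math.log(self.a) / self.b


def default_sigmoid() -> SigmoidParams:
    """Default normalised oxygen-mortality modifier Z'.

    A steep sigmoid with midpoint ≈ 1.3 mg O₂ l⁻¹: mortality is fully
    engaged below ~1 mg l⁻¹ and nearly off above ~1.8 mg l⁻¹.  This is the
    package's default calibration, chosen to reproduce the qualitative
    severity response of the reference system; override via config or by
    fitting field (DO, biomass) pairs with :mod:`benthox.zprime_fit`.
    """
    return SigmoidParams(a=4.4e5, b=10.0, c=1.0)


@dataclass(frozen=True)
class ModelParameters:
    """Every rate constant of the governing equations, with units.

    Defaults constitute the package's documented desk-scale calibration for
    a lower-Chesapeake-style mesohaline estuary; all values are overridable
    individually or via a flat key-value config file.
    """

    # --- phytoplankton (volumetric, d-1 unless noted)
    pbm: float = 1.0          # max photosynthetic rate, d-1 at t_ref
    resp_p: float = 0.08      # respiration, d-1
    wa: float = 0.08          # settling loss, d-1
    phtl: float = 0.6         # zooplankton grazing coefficient, m3 (g C)-1 d-1
    light_k: float = 8.0      # PAR half-saturation, mol photons m-2 d-1
    kdin: float = 0.1         # DIN half-saturation, g N m-3
    theta_p: float = 1.068    # Arrhenius base for phytoplankton growth
    # --- zooplankton
    gz_max: float = 0.5       # max growth, d-1 at t_ref
    kp_graze: float = 0.3     # prey half-saturation for Gz, g C m-3
    bmz: float = 0.04         # basal metabolism, d-1
    mzero_z: float = 0.2      # hypoxic mortality at zero DO, d-1
    docrit_z: float = 2.0     # DO threshold for zooplankton mortality, mg O2 l-1
    phtlz: float = 0.08       # predator field x clearance on zooplankton, d-1
    theta_z: float = 1.07     # Arrhenius base for zooplankton growth
    # --- macrobenthos (areal)
    alpha: float = 0.4        # carbon assimilation efficiency, dimensionless
    i0: float = 0.85          # ingestion rate, g sediment (g C biomass)-1 d-1 at t_ref
    m2: float = 0.5           # sediment solids concentration, kg l-1
    kmn1: float = 0.4         # Michaelis-Menten carbon limitation K1, g C m-2
    resp_b: float = 0.04      # macrobenthos respiration, d-1
    beta_hat: float = 0.2     # reference predation rate, m2 (g C)-1 d-1 at t_ref
    kdo: float = 2.0          # predation DO half-saturation, mg O2 l-1
    mzero_b: float = 0.3      # macrobenthic mortality at zero DO, d-1
    do_gx: float = 1.5        # DO at 50% macrobenthic function, mg O2 l-1
    do_qx: float = 1.3        # DO at 25% macrobenthic function, mg O2 l-1
    theta_b: float = 1.05     # Arrhenius base for benthic ingestion
    theta_pred: float = 1.10  # Arrhenius base for predation on macrobenthos
    t_ref: float = 20.0       # Arrhenius reference temperature, degC
    # --- coupling & numerics
    depth_h: float = 8.0      # water-column depth coupling plankton to the bed, m
    biomass_floor: float = 0.05  # minimum state value (recruitment proxy)

    def __post_init__(self) -> None:
        nonneg = (
            "pbm resp_p wa phtl light_k kdin gz_max kp_graze bmz mzero_z phtlz "
            "i0 m2 kmn1 resp_b beta_hat mzero_b theta_p theta_z theta_b theta_pred"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0 < self.alpha <= 1):
            raise ParameterError("alpha must lie in (0, 1]")
        if not self.do_qx < self.do_gx:
            raise ParameterError("do_qx must be < do_gx")
        if self.docrit_z <= 0 or self.kdo <= 0 or self.depth_h <= 0:
            raise ParameterError("docrit_z, kdo and depth_h must be > 0")
        if self.biomass_floor < 0:
            raise ParameterError("biomass_floor must be >= 0")

    def with_scaled(self, name: str, factor: float) -> "ModelParameters":
        """Return a copy with one parameter multiplied by ``factor``."""
        if not hasattr(self, name):
            raise ParameterError(f"unknown parameter {name!r}")
        return replace(self, **{name: getattr(self, name) * factor})

    # --- flat key-value config serialization ------------------------------
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)!r}\n")

    @classmethod
    def from_file(cls, path) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        kwargs: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in known:
                    raise ParameterError(f"unknown parameter {key!r} in {path}")
                kwargs[key] = float(value)
        return cls(**kwargs)


class RateDiagnostics(NamedTuple):
    """Per-step rate terms reported alongside the state derivatives."""

    Z: float        # respiration/ingestion oxygen modifier, 0-1
    Zprime: float   # mortality oxygen modifier, 0-1
    Mz: float       # zooplankton hypoxic mortality, d-1
    doref: float    # clamped DO used in the Mz formulation, mg O2 l-1
    beta: float     # predation rate on macrobenthos, m2 (g C)-1 d-1
    m: float        # macrobenthic hypoxic mortality, d-1
    PM: float       # plankton food available to the bed, g C m-3
    PR: float       # predation on phytoplankton, g C m-3 d-1
    PRz: float      # predation on zooplankton, g C m-3 d-1


# ---------------------------------------------------------------------------
# oxygen-response functions


def z_function(do_conc, do_gx: float, do_qx: float):
    """Oxygen modifier Z for macrobenthic respiration and ingestion.

    A logistic in DO pinned at 0.5 when DO = ``do_gx`` (50% of maximum
    function) and 0.25 when DO = ``do_qx`` (25%), which fixes the slope at
    k = ln 3 / (do_gx − do_qx).  Strictly increasing, limits 0 and 1.
    """
    if not do_qx < do_gx:
        raise ParameterError("do_qx must be < do_gx")
    k = math.log(3.0) / (do_gx - do_qx)
    return 1.0 / (1.0 + np.exp(-k * (np.asarray(do_conc, dtype=float) - do_gx)))


def z_prime(do_conc, params: SigmoidParams):
    """Normalised oxygen-mortality modifier Z' = 1 / (1 + a·e^(−b·DO))."""
    do = np.asarray(do_conc, dtype=float)
    if np.any(do < 0):
        raise ValueError("dissolved oxygen must be >= 0")
    return 1.0 / (1.0 + params.a * np.exp(-params.b * do))


def unnormalized_sigmoid(do_conc, params: SigmoidParams):
    """Fitted biomass-vs-DO sigmoid c / (1 + a·e^(−b·DO)), g C m⁻²."""
    return params.c * z_prime(do_conc, params)


def zoo_hypoxic_mortality(do_conc: float, params: ModelParameters) -> tuple[float, float]:
    """Zooplankton hypoxic mortality Mz (d⁻¹) and the clamped DO (DOREF).

    DOREF equals DO below the threshold ``docrit_z`` and the threshold
    itself otherwise, so Mz = mzero_z·(1 − DOREF/DOCRITz) is exactly zero
    under normoxia, equals mzero_z at zero DO, and falls linearly and
    continuously in between.
    """
    if do_conc < 0:
        raise ValueError("dissolved oxygen must be >= 0")
    doref = min(do_conc, params.docrit_z)
    mz = params.mzero_z * (1.0 - doref / params.docrit_z)
    return mz, doref


def arrhenius(temp: float, theta: float, t_ref: float):
    """Arrhenius temperature multiplier θ^(T − Tref)."""
    if theta <= 0:
        raise ParameterError("theta must be > 0")
    return theta ** (np.asarray(temp, dtype=float) - t_ref)


def predation_rate(temp: float, do_conc: float, params: ModelParameters):
    """Predation rate β on macrobenthos, m² (g C)⁻¹ d⁻¹.

    β = beta_hat · θ_pred^(T−Tref) · DO/(K_DO + DO): predation warms up with
    temperature and shuts down as DO → 0 (predators abandon hypoxic bottoms).
    """
    do = np.asarray(do_conc, dtype=float)
    if np.any(do < 0):
        raise ValueError("dissolved oxygen must be >= 0")
    return (
        params.beta_hat
        * arrhenius(temp, params.theta_pred, params.t_ref)
        * do / (params.kdo + do)
    )


# ---------------------------------------------------------------------------
# state derivatives


def _shared_diagnostics(state: ModelState, rec, params: ModelParameters,
                        sigmoid: SigmoidParams) -> RateDiagnostics:
    z = float(z_function(rec.do_conc, params.do_gx, params.do_qx))
    zp = float(z_prime(rec.do_conc, sigmoid))
    mz, doref = zoo_hypoxic_mortality(rec.do_conc, params)
    beta = float(predation_rate(rec.temperature, rec.do_conc, params))
    m = params.mzero_b * (1.0 - zp)
    pm = state.P + state.M
    pr = params.phtl * state.M * state.P
    prz = params.phtlz * state.M
    return RateDiagnostics(Z=z, Zprime=zp, Mz=mz, doref=doref, beta=beta,
                           m=m, PM=pm, PR=pr, PRz=prz)


def phytoplankton_derivative(state: ModelState, rec, params: ModelParameters,
                             sigmoid: SigmoidParams | None = None):
    """dP/dt = (G − R − Wa)·P − PR  (g C m⁻³ d⁻¹).

    Growth G is the maximum photosynthetic rate scaled by Monod light and
    DIN limitation and an Arrhenius temperature factor; PR is zooplankton
    grazing, bilinear in P and M.
    """
    sigmoid = sigmoid or default_sigmoid()
    diag = _shared_diagnostics(state, rec, params, sigmoid)
    growth = (
        params.pbm
        * rec.par / (params.light_k + rec.par)
        * rec.din / (params.kdin + rec.din)
        * float(arrhenius(rec.temperature, params.theta_p, params.t_ref))
    )
    dpdt = (growth - params.resp_p - params.wa) * state.P - diag.PR
    return dpdt, diag


def zooplankton_derivative(state: ModelState, rec, params: ModelParameters,
                           sigmoid: SigmoidParams | None = None):
    """dM/dt = (Gz − BMz − Mz)·M − PRz  (g C m⁻³ d⁻¹).

    Gz saturates in prey biomass P; BMz is basal metabolism; Mz is the
    linear below-threshold hypoxic mortality; PRz is closure predation by
    an implicit predator field (planktivorous fish, gelatinous zooplankton).
    """
    sigmoid = sigmoid or default_sigmoid()
    diag = _shared_diagnostics(state, rec, params, sigmoid)
    gz = (
        params.gz_max
        * state.P / (params.kp_graze + state.P)
        * float(arrhenius(rec.temperature, params.theta_z, params.t_ref))
    )
    dmdt = (gz - params.bmz - diag.Mz) * state.M - diag.PRz
    return dmdt, diag


def macrobenthos_derivative(state: ModelState, rec, params: ModelParameters,
                            sigmoid: SigmoidParams | None = None):
    """dB/dt for macrobenthos (g C m⁻² d⁻¹).

    Assimilated ingestion of a single Michaelis–Menten-limited food pool —
    total sediment POC (m₂·POC) plus water-column plankton converted to an
    areal density via ``depth_h`` — is modulated by Z; losses are
    Z-modulated respiration, quadratic predation β·B², and hypoxic
    mortality m·B with m = mzero_b·(1 − Z′).
    """
    sigmoid = sigmoid or default_sigmoid()
    diag = _shared_diagnostics(state, rec, params, sigmoid)
    food = params.m2 * rec.poc + diag.PM * params.depth_h  # g C m-2
    gain_rate = (
        params.alpha
        * params.i0
        * float(arrhenius(rec.temperature, params.theta_b, params.t_ref))
        * food / (params.kmn1 + food)
        * diag.Z
    )
    losses = params.resp_b * diag.Z + diag.beta * state.B + diag.m
    dbdt = (gain_rate - losses) * state.B
    return dbdt, diag
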