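# Methods

## Scope and intent

`benthox` is a deliberately small, biomass-based ecosystem model of
benthic–pelagic coupling under seasonal hypoxia in a temperate mesohaline
estuary. It descends from the benthic sub-model family of large Chesapeake
eutrophication models but strips them to three state variables —
phytoplankton P (g C m⁻³), combined micro/mesozooplankton M (g C m⁻³) and
combined deposit/suspension-feeding macrobenthos B (g C m⁻²) — with a
single total sediment-POC food pool, no nutrient recycling, no separate
suspension-feeder equation and no hydrodynamics. The scientific point is
the oxygen response: an empirically constrainable sigmoid (Z′) controls
hypoxia-induced benthic mortality, and everything else exists to give that
response a realistic seasonal context.

## Governing equations

With daily forcing record (T, PAR, DO, POC, DIN):

- **Phytoplankton** `dP/dt = (G − R − Wa)·P − PR`, where
  `G = P^b_m · PAR/(K_I + PAR) · DIN/(K_DIN + DIN) · θ_p^(T−Tref)` and
  grazing `PR = Phtl·M·P`. Monod light limitation is used; the parent
  models' exact light formulation is not public, and at daily resolution a
  saturating form captures what matters (light-replete summers, dim
  winters).
- **Zooplankton** `dM/dt = (Gz − BMz − Mz)·M − PRz`, with
  `Gz = Gz_max · P/(K_P + P) · θ_z^(T−Tref)`, basal metabolism BMz, hypoxic
  mortality `Mz = MZERO_z·(1 − DOREF/DOCRIT_z)` (DOREF = min(DO, DOCRIT_z),
  so Mz is zero at or above the 2 mg O₂ l⁻¹ threshold, MZERO_z at anoxia,
  linear and continuous between), and closure predation `PRz = PHTlz·M` by
  an implicit planktivore field.
- **Macrobenthos** `dB/dt = [α·I₀·θ_b^(T−Tref)·F/(K₁+F)·Z − r·Z − β·B −
  m]·B`. The food pool `F = m₂·POC + (P+M)·H` merges sediment carbon with
  water-column plankton converted to an areal density through the coupling
  depth H (m); the model never resolves vertical structure, so H is the
  effective depth of water whose plankton a unit area of bed can access.
  Losses are Z-scaled respiration, quadratic predation `β·B²` with
  `β = β̂·θ_pred^(T−Tref)·DO/(K_DO+DO)`, and hypoxic mortality
  `m = MZERO_b·(1 − Z′(DO))`.

Oxygen responses:

- `Z(DO)` is the logistic through (DOqx, 0.25) and (DOgx, 0.5), i.e. slope
  `k = ln3/(DOgx − DOqx)`; it scales respiration and ingestion only.
- `Z′(DO) = 1/(1 + a·e^(−b·DO))` is the normalised biomass–DO sigmoid; it
  controls mortality only. Keeping the two separate lets field data
  constrain mortality without re-tuning the metabolic response.

## Default calibration

Defaults are a documented desk-scale calibration for a lower-Chesapeake
style system; every value can be overridden individually or via a flat
key-value config file. Units and values live next to each field in
`ModelParameters`. The choices that matter most:

| parameter | default | why |
| --- | --- | --- |
| `mzero_b` | 0.3 d⁻¹ | collapse to near-zero biomass within 2–3 weeks of severe hypoxia, matching observed defaunation timescales |
| Z′ (a, b) | 4.4·10⁵, 10 l mg⁻¹ (midpoint ≈ 1.3 mg l⁻¹) | mortality fully engaged below ~1 mg l⁻¹, nearly off above ~1.8; reproduces the sharp severity contrast between 2.0 and ≤1.0 mg l⁻¹ windows |
| DOgx, DOqx | 1.5, 1.3 mg l⁻¹ | ingestion/respiration shut down over the same narrow band |
| `beta_hat`, `kdo` | 0.2 m² g C⁻¹ d⁻¹, 2 mg l⁻¹ | quadratic closure caps summer benthic standing stock near 2–3 g C m⁻²; predation relaxes under hypoxia (predator avoidance) |
| `alpha`, `i0`, `kmn1` | 0.4, 0.85 g g C⁻¹ d⁻¹, 0.4 g C m⁻² | net benthic growth ≈ 0.4–0.5 d⁻¹ at summer food saturation, fast enough for the observed few-week post-hypoxia rebound; food is saturating (F ≫ K₁), which is why K₁ is insensitive in the one-at-a-time protocol while α is strongly sensitive |
| `biomass_floor` | 0.05 (native units) | see below |
| `t_ref` | 20 °C | Arrhenius reference for all θ |

The biomass floor is a standing recruitment stock, not a numerical
nicety. A purely multiplicative model clamped at ~0 can never recover,
but real benthos rebound within weeks of reoxygenation because planktonic
larvae settle immediately into the vacated, organic-rich bed. A floor of
0.05 g C m⁻² (and the same value in g C m⁻³ for plankton overwintering
stocks) is the smallest seed from which the calibrated growth rates regain
pre-hypoxia biomass on that observed timescale.

## Numerics

The reference integrator is explicit forward Euler with Δt = 1 day over a
365-day year — one calculation per day, matching the temporal grain of the
forcing. A `substeps` argument refines Δt for artifact checks (the test
suite verifies the daily scheme tracks the closed-form exponential within
its analytic discretisation error, 5.22 % after ten days at k = 0.1 d⁻¹),
but the daily trajectory is the model output. States are clamped at the
floor after every (sub)step; a non-finite derivative aborts with the
offending day. With loss rates up to ~0.5 d⁻¹ the explicit scheme is
stable; the collapse phase under severe hypoxia is fast but bounded.

DO scenario ramps: windows are inclusive Julian-day spans held exactly at
the target DO; the 3 ramp days sit *outside* the window, linearly
interpolating with fractions k/(ramp+1) so a 3-day ramp's middle day is the
exact midpoint between the ambient and target concentrations. Printed
durations are taken from the day ranges (endpoints inclusive); the model
year is always 365 days.

## Fitting Z′

`fit_sigmoid` estimates (a, b, c) of `c/(1 + a·e^(−b·DO))` from paired
(DO, biomass) observations by bounded trust-region least squares
(`scipy.optimize.least_squares`, a ≤ 10¹², b ≤ 100). The default loss is
squared *log*-biomass residuals: benthic biomass errors are multiplicative
(spread grows with the mean), and a log loss both matches that structure
and keeps the low-biomass hypoxic rise — the region that identifies a and
b — from being swamped by plateau scatter. Plain linear residuals are
available via `loss="linear"`. Initialisation is crude moment matching
(c from the observed maximum, b = 4/DO-range, midpoint at the median DO).
Data that are all-hypoxic or all-normoxic raise an identifiability error
rather than returning a silently meaningless fit. `normalize_sigmoid`
replaces c with 1, producing the dimensionless modifier the model uses.

## Skill metrics and sensitivity

- `MPE = 100·mean(|obs − pred|)/mean(obs)` — a normalised mean absolute
  error, finite even when individual observations are near zero.
- `RMSD = sqrt(mean((obs − pred)²))` in the variable's units.
- One-at-a-time sensitivity: each tested parameter is scaled by 1 ± 0.2,
  the year re-run, and `rms = sqrt(mean over 365 days of (perturbed −
  base)²)` computed for the targeted state variable; the percent
  difference is 100·rms divided by the base annual mean, and a parameter
  is flagged sensitive above 10 %. The default target list covers the
  growth/consumption/predation parameters of each equation (P: P^b_m, Wa,
  Phtl; M: PHTlz; B: α, K₁).

## Synthetic data

The generators emulate the *shapes* of monitoring data, not any particular
dataset:

- climatology: single-harmonic sinusoids for temperature (16 ± 10 °C,
  peak day 212) and PAR (28 ± 18 mol photons m⁻² d⁻¹, peak day 172); DO as
  a seasonal drawdown from a 7 mg l⁻¹ baseline dipping to 5 mg l⁻¹ at the
  warm-season trough; constant POC (2 g C m⁻³) and DIN (0.2 g N m⁻³);
  optional Gaussian noise, everything clipped non-negative;
- biomass–DO pairs: DO uniform over [0, 8] mg l⁻¹ with half the points
  forced below 2 (uniform sampling alone under-covers the sigmoid rise and
  leaves fits ill-identified), biomass = truth sigmoid × lognormal noise
  with mean exactly 1 and CV 0.2;
- pseudo-observation series: the simulated trajectory sampled on a
  biweekly May–October schedule (days 121–303) with additive Gaussian
  noise, clipped at zero.

What the synthetic world deliberately lacks: interannual variability,
storm-driven reoxygenation events, spatial heterogeneity between sites,
observation-operator mismatches (chlorophyll→carbon, AFDW→carbon), and any
correlation between DO and the other drivers beyond the shared seasonal
cycle. Tests passing on this world therefore demonstrate internal
consistency and qualitative response patterns — collapse, recovery,
severity ordering, inverse plankton responses — not predictive skill
against field data, whose absolute verification statistics depend on
forcing and calibration outside this package's scope.

## Known limitations

- Euler at Δt = 1 d overshoots during the fastest collapse days; the floor
  absorbs this, but sub-daily mortality dynamics are not resolved.
- The quadratic predation closure is the only density dependence on B;
  there is no prey refuge at low biomass, so the predation-free severe
  hypoxia scenarios (DO → 0 ⇒ β → 0) can decay marginally slower than
  mild ones — a closure artifact held small by the steep Z′ default.
- Zooplankton recover slowly after long hypoxia (closure predation is
  linear and unconditional), echoing the known difficulty of calibrating a
  single combined zooplankton pool.
- The fitted Z′ is a phenomenological dose–response; it folds together
  asphyxiation, sulfide toxicity and emergence-driven predation, and
  transfers between systems only through refitting.
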