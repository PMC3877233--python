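# benthox

An estuarine benthic–pelagic ecosystem model for studying how the duration
and severity of seasonal hypoxia (dissolved oxygen ≤ 2 mg O₂ l⁻¹) reshape
macrobenthic biomass, built for coastal ecologists and water-quality
modellers working in Chesapeake-style temperate estuaries.

## The model

Three biomass state variables are integrated over a 365-day year with daily
forward-Euler steps, driven by daily water temperature, PAR, dissolved
oxygen (DO), sediment particulate organic carbon (POC) and dissolved
inorganic nitrogen (DIN):

```
dP/dt = (G − R − Wa)·P − PR                         phytoplankton, g C m⁻³
dM/dt = (Gz − BMz − Mz)·M − PRz                     zooplankton,   g C m⁻³
dB/dt = [α·I₀·θ^(T−Tref)·f(food)·Z − r·Z − β·B − m]·B   macrobenthos, g C m⁻²
```

Growth terms carry Monod light/nutrient/prey limitation and Arrhenius
temperature factors θ^(T−Tref). The oxygen responses are the heart of the
package:

- **Z(DO)** — a logistic pinned at 0.5 and 0.25 at the parameters DOgx and
  DOqx, scaling macrobenthic respiration r and ingestion I₀;
- **Z′(DO) = 1/(1 + a·e^(−b·DO))** — a normalised sigmoid, fitted to paired
  (DO, biomass) field observations, that drives hypoxia-induced macrobenthic
  mortality m = MZERO_b·(1 − Z′);
- **Mz = MZERO_z·(1 − DOREF/DOCRITz)** — linear zooplankton hypoxic
  mortality below the 2 mg O₂ l⁻¹ threshold, with DO clamped at the
  threshold (DOREF);
- **β = β̂·θ^(T−Tref)·DO/(K_DO + DO)** — a quadratic predation closure on
  the benthos that shuts down as predators abandon hypoxic bottoms.

Nine standard experiments force the DO series (with 3-day linear ramps):
S1–S3 hold 0.5 mg O₂ l⁻¹ for 120/60/30 days, S4 cycles hypoxia on a 14-day
neap–spring rhythm, and S5–S9 hold a 60-day midsummer window (days 178–237)
at 2.0 down to 0.0 mg O₂ l⁻¹.

Everything runs on synthetic forcing generated in-package (sinusoidal
climatology, sigmoid-structured biomass–DO pairs, pseudo-observation
series), so no external data are required.

## Worked example

```python
from benthox import *

forcing = build_synthetic_climatology(seed=1)   # deterministic default year
params = ModelParameters()

baseline = run_scenario("baseline", params, forcing)
s8 = run_scenario("S8", params, forcing)        # 60 d at 0.5 mg O2/l
for label, run in [("baseline", baseline), ("S8", s8)]:
    w = summarize_window(run, 178, 237)
    print(f"{label}: B mean {w['B'].mean:.2f} (SD {w['B'].sd:.2f}), "
          f"P mean {w['P'].mean:.3f}, M mean {w['M'].mean:.3f}")

obs = gen_biomass_do_pairs(SyntheticConfig(seed=1))  # noisy (DO, biomass) pairs
fit = fit_sigmoid(obs)
zp = normalize_sigmoid(fit)
print(f"fitted sigmoid: a={fit.params.a:.1f}, b={fit.params.b:.2f}, "
      f"c={fit.params.c:.2f}; normalized midpoint {zp.midpoint_do:.2f} mg/l")
```

prints

```
baseline: B mean 1.61 (SD 0.03), P mean 0.062, M mean 1.142
S8: B mean 0.12 (SD 0.28), P mean 0.323, M mean 1.097
fitted sigmoid: a=54.9, b=2.09, c=3.84; normalized midpoint 1.91 mg/l
```

Sixty days of severe hypoxia collapse mean benthic biomass more than
ten-fold relative to the normoxic baseline, zooplankton decline, and
phytoplankton increase five-fold as they are released from grazing — the
inverse plankton response characteristic of seasonal dead zones. The fitted
sigmoid recovers the generator's truth (a=50, b=2, c=4) to within a few
percent; normalising c to 1 yields the Z′ mortality modifier.

The same operations are available from a shell:

```sh
benthox scenarios
benthox simulate --scenario S8 --out run.csv
benthox fit --obs pairs.csv --out fit.cfg
benthox verify --run run.csv --obs obs.csv --variable B
benthox sensitivity --out sens.csv
benthox make-fixtures --out fixtures/ --seed 1
```

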