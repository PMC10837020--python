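# photothermal

Analysis toolkit for leaf photosynthesis thermal-response studies:

- **FvCB A–Ci curve fitting** — estimates Vcmax, J₁₅₀₀, TPU and Rd from
  CO₂-response curves with mesophyll-conductance coupling (Cc = Ci − An/gm),
  limitation transitions assigned automatically by the min-rule model rather
  than by the operator. Multistart nonlinear least squares plus a J-profile
  refinement stage for robustness against the min-rule's narrow basins.
- **Temperature-response modelling** — peaked Arrhenius fits (deactivation
  energy held fixed at 200 kJ mol⁻¹) with closed-form T_opt, quadratic fits
  with vertex extraction, nested-regression model selection
  (common line vs separate lines, extra-sum-of-squares F-tests), and
  fixed-effects ANOVA with Fisher LSD / Tukey HSD letters.
- **T_crit estimation** — critical temperature of PSII from F₀-vs-temperature
  ramps, as the intersection of regression lines fitted to the flat and steep
  portions; the boundary is chosen by exhaustive two-segment least squares,
  with guards that refuse to fabricate a breakpoint on flat traces.
- **Metabolite-table statistics** — internal-standard / fresh-mass /
  average-signal normalization, PCA, permutational multivariate ANOVA
  (pseudo-F on squared Euclidean distances; the univariate case reduces
  exactly to the classic one-way ANOVA F), and fold-change ranking of
  treatment-responsive compounds.
- **Synthetic data generation** — every input the pipeline consumes can be
  generated from known ground truth (A–Ci curve sets over a genotype ×
  night-temperature design, F₀ ramps, metabolite tables with planted
  class-structured effects), so all stages are testable end to end without
  any external download.

The packaged default kinetic configuration (`wheat_default`) carries the
wheat constants: gm = 5.5 μmol m⁻² s⁻¹ Pa⁻¹ (Ea 47.65 kJ mol⁻¹),
K_air = 772 μmol mol⁻¹ (Ea 93.72), Γ* = 37.74 μmol mol⁻¹ (Ea 24.42),
96 kPa chamber pressure. Temperatures are °C at all public boundaries and
Kelvin internally; CO₂ is μmol mol⁻¹ at boundaries and Pa internally.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (configuration
fidelity, unit conversion, FvCB round-trip recovery, peaked-Arrhenius and
T_crit recovery under noise, PERMANOVA calibration and power, model-selection
correctness), one test per criterion at its stated tolerance.

## CLI

```bash
# generate a full synthetic study with known ground truth
photothermal simulate --seed 42 --out data/

# fit FvCB capacities to every curve, standardized to 28 degC
photothermal aci-fit --input data/gas_exchange.csv --config wheat_default \
    --std-temp 28 --out fits.csv

# temperature-response fits per genotype x night-temperature cell
photothermal thermal-fit --fits fits.csv --trait Vcmax --model peaked --out topt.csv

# T_crit from F0 ramps (0.5 degC smoothing window by default)
photothermal tcrit --input data/f0_ramps.csv --smooth 0.5 --out tcrit.csv

# metabolite normalization + PCA + PERMANOVA
photothermal metab --input data/metabolites.csv --classes data/metabolite_classes.csv \
    --permutations 999 --seed 2254 --out results/

# everything end to end (simulates any missing inputs); writes manifest.json
photothermal run --out results/ --seed 42
```

## Layout

```
src/photothermal/
  kinetics.py      # kinetic constants, Arrhenius / peaked Arrhenius, T_opt
  fvcb.py          # forward FvCB model with gm coupling
  aci.py           # A-Ci fitting, standardization, pooling
  thermal.py       # temperature-response fits, model selection, ANOVA
  tcrit.py         # F0 ramp breakpoint estimation
  metabolomics.py  # normalization, PCA, PERMANOVA, responders
  simulate.py      # ground-truth synthetic data for every stage
  io.py, cli.py    # CSV readers/writers, pipeline runner, CLI
  data/wheat_default.yaml
```
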