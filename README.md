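# mesotox

Statistical analysis of chronic herbicide mesocosm ecotoxicology experiments,
built around a Bayesian hormetic concentration–response model for
caged-amphipod survival, with mixed-model analyses of tadpole and amphipod
endpoints, phytoplankton community analytics, exposure-fate summaries, and a
synthetic experiment generator that makes every stage verifiable without raw
field data.

**Who it is for:** ecotoxicologists analyzing replicated mesocosm designs
(here: a control plus five diquat treatments, 74–1153 µg/L nominal, five
tanks each) who need defensible toxicity metrics with full uncertainty — and
anyone who wants a tested reference implementation of hormetic binomial
regression with closed-form LCx derivation.

## The core model

Survival of caged amphipods (20 per cage, 2 cages per tank, scored at weeks
2/4/6) is binomial with a quadratic dose polynomial on the logit scale in
x = log2(c + 1), plus a tank random intercept for extra-binomial variation:

    n_alive ~ Binomial(n_atrisk, p)
    logit(p) = β₀[week] + β₁x + β₂x² + u_tank,   u_tank ~ N(0, σ²)

Hormesis (survival rising at low doses, falling at high doses) corresponds to
β₁ > 0, β₂ < 0. Every toxicity quantity is a closed-form posterior quantity
via the quadratic equation, each with a 95% highest-density interval:

* LCx — the descending-limb root of β₂x² + β₁x + (β₀ − logit((1−f)p₀)) = 0,
  back-transformed as c = 2^x − 1;
* peak (vertex) concentration x\* = −β₁/2β₂ and peak survival;
* the limiting concentration of stimulation (survival back at control level)
  x_lim = −β₁/β₂ = 2x\*, hence c_lim = (c\* + 1)² − 1.

The tank effects are integrated out by Gauss–Hermite quadrature and the
marginal posterior sampled by ensemble MCMC (4 independent ensembles, split-R̂
gate at 1.01); candidate models (quadratic vs. monotone logistic vs. no
effect) are compared by **exact leave-one-out cross-validation** — a true
refit per held-out cage, scored by log pointwise predictive density.

Around the core model: Laplace binomial GLMMs with observation-level random
effects, Gaussian LMMs with per-doubling effect reporting, AICc selection,
ANOVA + Tukey HSD, Kruskal–Wallis, BCa bootstrap intervals, Holm–Bonferroni
adjustment, Shannon diversity contrasts, Bray–Curtis / NMDS / PERMANOVA with
a dispersion-homogeneity check, and first-order dissipation fits with
detection-limit censoring.

## Worked example

Simulate an experiment at the default study conditions and analyze it:

```bash
mesotox simulate --seed 1 --out data/
mesotox run --input data/ --seed 2 --out results/
```

or in Python:

```python
from mesotox import SimConfig, simulate_experiment, RunConfig, run_pipeline
ds = simulate_experiment(SimConfig(), seed=1)
out, report = run_pipeline(ds, RunConfig(seed=2))
print(report)
```

which prints (abridged):

```
measured/nominal at 1 h: 82.4% +/- 1.7% (n=25, range 64.0-101.9%)
week 2: LC50 median 179 ug/L (95% HDI 167-191)
week 4: LC50 median 163 ug/L (95% HDI 148-179)
week 6: LC50 median 159 ug/L (95% HDI 146-174)
growth ANOVA: F(3,32) = 152.21, p = 5.12e-19
reproduction GLMM: best = treatment (dAICc = 7.04)
tadpole survival: overall 84.9%; best model linear; conditional predictions
  75.6% (control) -> 90.2% (top)
development rate (stages/day): control 0.091, treated 0.357
mass: +1.57% per concentration doubling
HNE: Kruskal-Wallis p = 0.59; mean 325.4 (95% BCa CI 291.3-373.6)
day 7: PERMANOVA R2 = 0.82, p = 0.001 (dispersion p = 0.00); NMDS stress = 0.002
```

Reading the numbers: the measured 1-h concentrations averaged ~82% of nominal
(the generator's truth is 84%). The week-6 LC50 posterior median of 159 µg/L
recovers the generating value of 155 µg/L well inside its credible interval,
and the LC50 is essentially stable across exposure weeks — the hallmark that
declining control survival, not a shifting concentration response, drives the
weekly differences. Tadpole survival *rises* with dose (an indirect
food-resource effect), development roughly triples in treated tanks, and the
day-7 phytoplankton composition separates sharply from the control
(PERMANOVA p = 0.001) with an ordination stress low enough to trust.

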