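# paceshape

Bayesian Siler mortality modelling and sensitivity analysis in the
life-expectancy / lifespan-equality landscape.

## The problem

Long-term field studies of wild primates (and captive-population records)
yield individual observation histories: a time of birth (sometimes unknown),
a first and last detection, and a fate that may be death, permanent
out-migration from the study area, or unknown. From such records one wants
the age-specific mortality schedule, and from the schedule two summary
axes of a population's demography:

* **pace** — life expectancy at birth, `e₀ = ∫₀^∞ S(x) dx`;
* **shape** — lifespan equality, `ε = −log H`, where
  `H = −∫ S log S dx / e₀` is the Keyfitz entropy (H = 1 for a constant
  hazard; small H / large ε means deaths concentrate at old ages).

Across populations of one genus, (e₀, ε) points fall close to a line
`ε = β₀ + β₁ e₀`. This package asks — and answers analytically — which
mortality parameters a population must change to move along that line.

## The model

Mortality follows the five-parameter Siler ("bathtub") hazard

    μ(x) = exp(a0 − a1·x) + c + exp(b0 + b1·x),  x ≥ 0,

with infant parameters (a0, a1), age-independent ("background") mortality
c, and senescent parameters (b0, b1); b1 is the rate of ageing. The
cumulative hazard has the closed form
`U(x) = (e^{a0}/a1)(1 − e^{−a1 x}) + c x + (e^{b0}/b1)(e^{b1 x} − 1)` and
S = e^{−U}.

Observation model (wild data): an animal first detected at age `x_f` and
last detected at age `x_l` either died shortly after its last detection
(latent state o = 0, density `f(x_l)/S(x_f) · (1−π)`) or permanently
out-migrated (o = 1, `S(x_l)/S(x_f) · π · g(x_l − α)`), where g is a gamma
density of dispersal ages above a class minimum α and π the out-migration
probability (natal and immigrant classes are separate). Unknown fates get
latent states, unknown births are imputed subject to `birth ≤ first
detection`, and everything is sampled by Metropolis-within-Gibbs MCMC with
conjugate Beta updates for π. Captive data use the same machinery with the
out-migration parts removed. Convergence is monitored with the classic
Gelman–Rubin PSRF.

The analytical core is the sensitivity calculus: writing
`S_θ = −S·U_θ` for each parameter θ,

    e_θ = ∫ S_θ dx,
    ε_θ = [ e_θ (1 + 1/H) − (1/H) ∫ S_θ U dx ] / e,

give the gradient vector (e_θ, ε_θ) — the displacement in the landscape per
unit change in θ — and the length-scaled path integral

    Θ = (1/L) ∫ (1/θ) [ 1/e_θ + β₁/ε_θ ] de

along a genus line measures how much log θ must change to traverse it.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on synthetic
cohorts (the real primate datasets are proprietary; the generator
reproduces their statistical structure — Siler deaths, Bernoulli
out-migration with gamma dispersal ages, left truncation by study entry,
unknown births and fates):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_fit_survival.py
python analysis/03_sensitivity_vectors.py
python analysis/04_landscape_paths.py
```

`01` simulates from θ = (a0 −2, a1 1, c 0.01, b0 −5, b1 0.15):

```
generating schedule: e0 = 14.27 y, H = 0.522, eps = 0.651
wild cohort: 403 records after left truncation; fates {'dead': 270,
'out_migrated': 46, 'unknown': 87}; 119 unknown birth dates
```

`02` recovers the schedule from the fully observed cohort
(`e = 14.44 +/- 0.27 y`, all PSRF ≤ 1.014) and fits the wild cohort with
latent out-migration — note the much wider infant-parameter intervals once
births and fates are partly unknown. `03` prints the gradient vectors; at
the fitted schedule the background-mortality and rate-of-ageing vectors are
by far the largest (norms ≈ 142 and 52 versus ≤ 4 for the rest). `04` fits
the synthetic genus line and computes collinearities and path integrals:

```
genus line: eps = -0.823 + 0.1052 e  (slope SE 0.0016, p = 3.50e-07)
param  collinearity  abs_theta
   a0        0.9997     0.7799
   a1        0.9998     1.0258
    c        0.9998     1.3738
   b0        0.9959        NaN   (reported singularity: eps_b0 crosses zero)
   b1        0.9900     0.1597
```

Reading: early-life parameters (a0, a1, c) are the most collinear with the
genus line and must change roughly 5–9× more on the log scale than the rate
of ageing b1 to traverse it — within-genus variation in pace and shape is
an early-life story, while b1 stays comparatively invariant.

A `paceshape` CLI wraps the same stages
(`paceshape simulate|fit|sensitivity|landscape|pipeline --config run.yaml`).

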