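# Methods

## Demographic quantities and numerics

All ages are in years, hazards per year. The Siler hazard
`μ(x) = exp(a0 − a1 x) + c + exp(b0 + b1 x)` has support constraints
a1, c, b1 ≥ 0 with a0, b0 ∈ ℝ; `SilerParams` enforces them at
construction. The cumulative hazard uses the closed form with `expm1` for
numerical stability and the analytic limits `e^{a0}x`, `e^{b0}x` when a1 or
b1 is (numerically) zero.

Improper integrals (`e`, `H`, the sensitivity integrals) are truncated at
an upper age chosen adaptively: doubling from 1 year until `S < 1e−12`,
capped at `max_upper` (default 200 y — Siler survival decays
super-exponentially when b1 > 0, so this covers any realistic primate or
human schedule). If survival at the cap still exceeds the quadrature
`abs_tol` the computation raises rather than silently truncating mass;
long-lived near-constant-hazard schedules (e.g. c = 0.05 alone implies
e₀ = 20 y and S(200) ≈ 5e−5) need `max_upper` raised explicitly.
Integration is adaptive Gauss–Kronrod (`scipy.integrate.quad`,
abs_tol 1e−10, rel_tol 1e−8); fixed-step trapezoids appear only as test
oracles.

## Sensitivity calculus

`S_θ = −S·U_θ` with closed-form `U_θ` per parameter; the a1 and b1
derivatives suffer catastrophic cancellation as the parameter → 0, so below
1e−5 they switch to their series expansions
(`U_a1 → e^{a0}(−x²/2 + a1x³/3)`, `U_b1 → e^{b0}(x²/2 + b1x³/3)`).
`ε_θ = [e_θ(1 + 1/H) − (1/H)∫S_θU dx]/e` shares the truncation age with
`e`; `S_θ·U` decays like S, so the shared upper age is valid. The whole
module is validated against central finite differences (relative step
1e−6, one-sided at the support boundary) — the primary oracle of the
package.

## Synthetic cohorts

The generator emulates a long-term field study. Births fall uniformly on
the study window extended left by a burn-in (default 50 y) so the cohort
contains left-truncated adults; death ages are drawn by inverse-CDF on the
closed-form cumulative hazard (bracketing + Brent root finding), optionally
conditioned on survival to study entry. With class probability π an
individual instead out-migrates at age α + Gamma(shape, rate) — the gamma
is parameterized shape–rate to match the per-year units used elsewhere.
Records ending before the window are discarded (left truncation); animals
still present at the window end are coded `unknown` by default (the
faithful choice: the two-branch likelihood treats them as late deaths or
emigrations) or `censored` for the optional right-censoring branch.
Configured fractions of out-migrations are relabelled fate-unknown and of
births hidden. A single seed expands to per-stage substreams
(structure/deaths/dispersal/labels) so each stage is independently
reproducible.

What the generator does **not** emulate: seasonal birth pulses, density
dependence, social-group structure, observation gaps between detections,
and age-estimation error beyond a missing birth date. Passing recovery
tests therefore shows the estimator is correct under the model's own
assumptions, not that real data meet them.

The life-table converter expands `round(radix·(l_k − l_{k+1}))`
pseudo-individuals per age class, placed uniformly within the class
(midpoints would create ties and spurious likelihood modes); the rounding
residual goes to the open-ended last class. Yearly tables cannot resolve
hazard features faster than one age class: with a1 ≳ 1/yr the infant
decline happens inside the first class and the fitted a0/a1 are biased at
high radix (the posterior concentrates faster than the discretization
error shrinks). The round-trip validation therefore uses a schedule with
a1 = 0.5/yr, whose infant decline spans several classes; users fitting
yearly human tables should treat sub-year infant parameters as
approximate.

## The sampler

Metropolis-within-Gibbs over (θ, γ₁, γ₂, π, latent o, latent births),
entirely in log space so extreme proposals underflow to −∞ rather than
NaN. During burn-in, proposals are componentwise Gaussian random walks
with scales adapted every 50 iterations toward a 0.15–0.5 acceptance
window. The Siler parameters are strongly correlated a posteriori
(especially b0–b1), and componentwise walks mix too slowly for short
chains, so after burn-in the sampler switches to a joint 5-d multivariate
normal proposal with covariance `(2.38²/5)·Σ̂` estimated from the second
half of burn-in (likewise 2-d joint proposals for each gamma pair).
Adaptation stops at burn-in, so the post-burn-in kernel is fixed and
detailed balance holds for the retained draws.

π has an exact Beta conjugate update given the latent states
(Beta(1+k, 1+n−k) under the default Beta(1,1) prior). Latent states are
redrawn every iteration from their full conditional
`π S g / (π S g + (1−π) f)` — the left-truncation factor cancels — and are
forced to 0 below the class minimum age α (α is fixed run configuration,
never estimated). Unknown births take vectorized independent random-walk
updates constrained to `[t_f − max_age, t_f]` (max_age default 100 y; the
observation model gives no other support information).

Priors are normal, truncated to the parameter support where needed:
vague (sd 10) on mortality and natal-dispersal parameters, informative
(sd 0.5) on immigrant-dispersal parameters. Chains start from a crude
data-driven point (exponential rate of the observed detection spans,
jittered per chain); an explicit `init_theta` is available for invariance
checks. Six chains of 25 000 iterations with 5 000 burn-in are the
configured defaults; the bundled analyses and tests run scaled-down chains
(5 000 iterations, 1 500 burn-in for fully observed cohorts; 4 000/1 500
with three chains for wild cohorts) — at these problem sizes (n ≈ 400–10 000
records) the PSRF is < 1.05 and recovery is already stable, and a full run
changes nothing but runtime. PSRF is the classic two-or-more-chain
`sqrt(((n−1)/n·W + B/n)/W)` without split-chain refinement, computed on
post-burn-in draws; identical draws up to rounding noise raise an error
rather than reporting a meaningless ratio.

Point estimates are posterior means; `e`, `H`, `ε` are evaluated at the
posterior-mean parameters, and SE(e) is the standard deviation of `e`
recomputed on every 50th pooled draw (draws whose integrals fail to
truncate are skipped and counted out).

## Landscape analysis

Genus lines are weighted least squares of ε on e (weights typically
1/SE(e)); the slope's two-sided t-test (n−2 df) is reported alongside the
coefficients. Collinearity between the line direction `(1, β₁)/√(1+β₁²)`
and a sensitivity vector is the absolute cosine, in the raw (years,
dimensionless) units of the landscape.

The path integral of parameter change needs θ as a function of position on
the line, which no observable defines; the package's explicit modelling
choice is interpolation of the fitted populations' parameters in e —
linear for a0, b0 (already log-scale quantities), log-linear for the
positive parameters — clamped to the line's e-range and isolated behind
`parameter_trajectory` so alternatives (e.g. per-population anchoring) can
be swapped in. Midpoint-rule integration over n_segments (default 200)
avoids endpoint evaluation; the integrand `(1/θ)(1/e_θ + β₁/ε_θ)` is
smooth away from zeros of e_θ, ε_θ or θ. Such zeros make the integral
genuinely improper: they raise `SingularPathError` with the location
rather than being regularized away (the β₁/ε_θ term is defined as 0 only
in the removable β₁ = 0 case). On the bundled synthetic genus, ε_b0
crosses zero mid-line, so Θ_b0 is a reported singularity — visible in the
ranking output's `errors` channel.

The synthetic genus itself fixes b0 and b1 across six populations and
varies a0 (−0.2 → −3.2, linear), a1 (0.6 → 1.6) and c (0.06 → 0.005, log
scale), spanning e₀ ≈ 3.5–16.6 y with a significantly positive line —
within-genus variation driven by early-life mortality with an invariant
rate of ageing, the regime the theory targets. On this genus the early-life
parameters must change ≈ 5–9× more on the log scale than b1 to traverse
the line (c ≈ 8.6×, a1 ≈ 6.4×, a0 ≈ 4.9×). The gap is qualitative-robust
across every realistic parameterization we scanned but its exact magnitude
depends on the genus's parameter magnitudes: Θ_b1 stays moderate because
its 1/e_θ and β₁/ε_θ terms only partially cancel at the ≈ 0.1 slopes that
early-life variation produces, and Θ_a0 is bounded by 1/|a0|. A uniform
full order of magnitude for all three early-life parameters is not
reproduced under these synthetic conditions.

## Known limitations

* The Siler model has no late-life mortality plateau; fits to low-mortality
  human schedules under-estimate b1.
* The o = 0 branch assumes death shortly after last detection; no
  detection-gap tolerance is modelled.
* Sexes are fitted separately (no joint model), and there is no
  hierarchical pooling across populations.
* The trajectory along a genus line is an interpolation device, not an
  estimated quantity; path integrals inherit its assumptions.
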