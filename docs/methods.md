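# Methods

## Model

A continuous outcome X in each of two groups is modelled as skew-normal
with common scale and shape: group i has mean μᵢ, common SD σ and
common shape α. In the direct parameterisation (location ξ, scale w,
shape α) the density is (2/w)·φ(z)·Φ(αz), z = (x−ξ)/w; the centred
parameters used throughout the interface map to it via

    μ_z = √(2/π)·α/√(1+α²),  w = σ/√(1−μ_z²),  ξ = μ − w·μ_z,

so that the distribution has exactly mean μ and SD σ. α = 0 gives the
normal distribution and every skew-normal computation reduces exactly
to its normal counterpart (enforced by test).

The tail probability below a cut-point x₀ is evaluated in closed form
as Φ(z) − 2·T(z, α) with Owen's T function (`scipy.special.owens_t`);
adaptive quadrature of the density (`scipy.integrate.quad`, absolute
tolerance 1e-10) is retained as an independent oracle and fallback.
The derivative of the tail probability with respect to the mean is
p′(μ) = −(2/w)·φ(z)·Φ(αz) — minus the density at the cut-point — and
the delta method gives

    var(p̂) = (σ²/n)·p′(μ)².

Note the variance carries 1/n, not 1/√n: with 1/n the closed form
reproduces the published worked-example SE (0.004 for the
low-birthweight difference; a literal 1/√n reading gives ≈ 0.019) and
yields nominal simulated coverage, both verified by tests. Only the
mean's sampling variability is propagated; the variability of σ̂ and α̂
is ignored by the SE formulas. This is a good approximation for the
two-group contrasts because the nuisance parameters are shared, so
their estimation error largely cancels between groups — the simulation
criteria below verify it directly.

Comparisons take the exposed group as minuend/numerator:
d = p₁ − p₂, rr = p₁/p₂, or = odds₁/odds₂, with

    se(d)² = var(p̂₁) + var(p̂₂)
    se(log rr)² = var(p̂₁)/p₁² + var(p̂₂)/p₂²
    se(log or)² = var(p̂₁)/(p₁(1−p₁))² + var(p̂₂)/(p₂(1−p₂))².

Distributional confidence intervals are point ± z·se with the standard
normal quantile (no small-sample t correction: the method is a
large-sample approximation); ratio intervals are built on the log
scale and exponentiated. A cut-point whose tail probability is
numerically 0 or 1 (≈ 10 SD out) raises a degenerate-tail error rather
than returning a meaningless interval.

## Pooling and fitting

With raw data, the normal method uses group sample means and the
df-weighted pooled SD √(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)). The
skew-normal method fits both groups jointly by maximum likelihood with
free means and shared (σ, α) — our reading of a "pooled skew
coefficient" under the equal-variance, equal-skewness assumption.
Estimation is performed in the centred parameterisation (μ, log σ, α)
because the direct parameterisation has singular Fisher information at
α = 0; Nelder-Mead is multi-started from α = 0 and from the
method-of-moments value. The method-of-moments inversion of the
skewness formula is available in closed form; sample skewness beyond
the attainable bound |γ₁| < 0.9953 (e.g. strongly lognormal data) is
clipped to the boundary and flagged in the fit diagnostics rather than
rejected. Fitted |α| is capped at 200, beyond which shapes are
observationally indistinguishable.

`method_guard` encodes the practical decision rule observed in the
robustness study: use the normal method when |α̂| ≤ 1 (small deviation
from normality, where the skew-normal method is itself unreliable
unless n is large) or when either group has fewer than 50
observations; otherwise use the skew-normal method. Both thresholds
are arguments.

## Transforms

Strictly monotone transforms preserve threshold-defined proportions:
increasing transforms (log, sqrt, square — all on positive values)
keep the tail direction, decreasing ones (inverse on positive values,
negation, reflect-and-log log(c − x) for left-skewed outcomes, c
user-supplied, e.g. 45 weeks for gestational age) flip it. Threshold
mapping is automatic and invertible. Empirical counts use the strict
convention (below: x < x₀; above: x > x₀), under which count
preservation is exact for strictly monotone maps; for the continuous
fitted distributions P(X < x₀) = P(X ≤ x₀), so estimates do not depend
on the convention.

## Simulation study

Scenarios generate two groups from either a lognormal distribution
(skewness indexed by the log-SD, 0.02–1; the mean/median ratio is
exp(σ²_log/2)) or a skew-normal distribution (α from −20 to 20; ±1 is
a small deviation from normality). Design ranges are enforced unless a
scenario is explicitly marked as an override. Choices where the design
was open, fixed once before the validation runs:

* **Effect size** is the standardised mean difference (mean difference
  over SD), imposed on the natural scale: the exposed lognormal group
  shifts its log-mean so its mean exceeds the reference mean by
  δ·SD_ref with the log-SD unchanged. A printed reading of "mean
  difference over standard error" is available as
  `effect_scale="se"`. Defaults: effect sizes {0.1, 0.2, 0.5}.
* **Cut-points** are placed at fixed true tail probabilities of the
  reference group ({0.05, 0.1, 0.2}, lower tail by default), keeping
  cut-points comparable across skewness levels.
* **Replicates** default to 20 000 per scenario; the heavier validation
  tests run 2 000 with binomial Monte-Carlo tolerances, and the two
  SE-validity settings run the full 20 000 (vectorised, a few seconds
  each). These sizes are the package's own test design.
* **True values** come from the generating distribution's CDF
  (lognormal or skew-normal), also when the analysis model is
  misspecified — misspecification is the point of the robustness
  arm.

Each replicate computes group means, the pooled SD and (skew-normal
method only) a re-estimated shared shape, then the full estimator path.
Per-replicate shape estimation over 20 000 replicates makes full joint
MLE impractical, so the default is a pooled-residual *profile* maximum
likelihood: means fixed at sample means, scale at the pooled SD, and α
maximised by an iterative grid refinement on the arctan(α) scale,
vectorised across replicates (resolution ~1e-3 in arctan α). This
estimator satisfies the SE-validity criterion below; the noisier
method-of-moments α̂ (`shape_estimation="moments"`) is retained for
sensitivity analysis but does not, which is why it is not the default.
Replicates with degenerate tail estimates are excluded and counted; a
scenario fails if more than 1% degenerate.

Aggregation follows the study design: mean estimate, SD of estimates,
mean SE, relative bias (mean estimate vs analytic truth; undefined at
zero truth), relative SE bias (mean SE vs SD of estimates — computed on
the log scale for rr/or, the scale their SEs live on) and 95% DCI
coverage. Grid summaries per (family, method, n, skewness) cell report
the 3rd quartile of absolute biases and the coverage quartiles/IQR
across the varying effect-size × cut-point dimensions. The quantile
rule is linear interpolation (numpy default, type 7), with a
nearest-observation option.

## What the generator does and does not emulate

Synthetic data are i.i.d. within group with exactly equal scale and
shape across groups. Real outcomes violate this in ways the study
deliberately brackets (lognormal data under a skew-normal analysis)
but passing tests do not certify performance under unequal variances,
covariate structure, measurement rounding, or heavier-than-lognormal
tails. The worked examples run from published rounded summary
statistics, so agreement is asserted at printed precision only.

## Numerical choices

* Owen's-T closed form for all CDF evaluations; quadrature only as
  oracle/fallback, raising with diagnostics on non-convergence.
* Probabilities clipped to [0, 1] after the Owen's-T combination;
  degenerate tails raise rather than propagate.
* Finite-difference validation of p′ uses central differences with
  step 1e-4 on the mean, balancing truncation against rounding in the
  far tails.
* All computation in double precision; fits are deterministic given
  the data (fixed multi-starts, no randomised optimisation).
* Simulation seeds feed `numpy.random.default_rng`; scenario grids
  derive per-scenario sub-seeds from one master seed.

## Known limitations

* Unadjusted two-group comparisons only; no regression adjustment.
* The skew-normal columns of published real-data tables require the
  original raw data to estimate α, so only the computation's structure
  — not those printed numbers — can be validated.
* SE formulas ignore the sampling variability of σ̂ and α̂; adequate
  for shared-nuisance contrasts (verified by simulation), not for a
  single group's proportion at cut-points far from the mean.
* The skew-normal method underperforms on nearly symmetric data unless
  n is large; `method_guard` routes such cases to the normal method
  instead of attempting a correction.
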