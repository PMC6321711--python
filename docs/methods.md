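# Methods

## Effect-size estimation

For a binary outcome tabulated by exposure class, the logistic model
with class indicators is saturated, so the MLE of each class's odds
ratio versus the reference is the closed-form 2×2 ratio
θ_j = (a_j d_ref)/(b_j c_ref) with
Var(log θ_j) = 1/a_j + 1/b_j + 1/c_ref + 1/d_ref (a/b: class-j
events/non-events; c/d: reference events/non-events).
`odds_ratios_from_table` implements the closed form;
`fit_logistic_classes` fits the same model iteratively (statsmodels
Newton, relative log-likelihood tolerance 1e-10, 100 iterations) and
the test suite asserts the two agree to 1e-8 relative error. The
simulation loop uses the closed form, which is exact and ~100× faster.

For a time-to-event outcome, `fit_cox_effects` maximizes the Cox
partial likelihood with class-indicator covariates by Newton–Raphson
with step-halving (same tolerance/iteration budget). Ties are handled
by Breslow's approximation — simulated event times are continuous, so
ties have probability zero and the choice is immaterial there;
variances come from the inverse observed information. Because the
design rows are one-hot, the at-risk outer-product sums collapse onto
the at-risk linear sums, making each iteration O(n) after one sort;
this is what keeps a 1000-replicate survival study in seconds. The fit
is validated against lifelines (run at tightened precision) to 1e-6 on
fixed data and against null simulations at n = 50,000.

Conventions throughout: the reference class has θ = 1 exactly, σ² = 0
and centered median m\* = 0; class intervals are lower-inclusive
half-open with the top interval closed (so a BMI of exactly 25 is
"overweight" and the upper range limit belongs to the top class).

## The ten trend tests

All ten methods regress θ\*_j = θ_j − 1 on m\*_j = m_j − m_ref and
t-test the slope. The registry encodes each method's weight rule,
whether the fit passes through the reference point and how residual
degrees of freedom are counted:

| id | weights            | realization                       | df    | valid |
|----|--------------------|-----------------------------------|-------|-------|
| 1  | none               | through origin, ref point counted | r − 1 | no    |
| 2  | none               | intercept, all r points           | r − 2 | yes   |
| 3  | none               | through origin, non-ref points    | r − 2 | yes   |
| 4  | (θ²σ²)⁻¹           | through origin, non-ref points    | r − 2 | yes   |
| 5  | (θσ)⁻¹             | through origin, non-ref points    | r − 2 | yes   |
| 6  | (σ²)⁻¹             | through origin, non-ref points    | r − 2 | yes   |
| 7  | (σ)⁻¹              | through origin, non-ref points    | r − 2 | yes   |
| 8  | n_j                | through origin, ref point counted | r − 1 | no    |
| 9  | n_j                | through origin, non-ref points    | r − 2 | yes   |
| 10 | n_j                | intercept, all r points           | r − 2 | yes   |

A genuinely open design question was how the variance-weighted methods
treat the reference class, whose log-effect variance is exactly zero
(an infinite inverse-variance weight). This package resolves it by
taking the limit seriously: the reference point is an exact linear
constraint, the intercept is consumed by it, and the fit reduces to a
through-origin regression on the non-reference points with df = r − 2.
The two methods that instead count the reference's identically-zero
residual as a degree of freedom (1 and 8) share the constrained
methods' slopes and residual sums of squares but divide by r − 1;
that extra df is exactly why they are anticonservative, and they are
flagged `valid = False`. Some descriptions label the constrained
variants "with intercept" because the constraint is conceptually an
intercept pinned at the reference; the realization here is the one
that exactly reproduces the published worked-example p-values (an
ordinary 3-point intercept fit does not — it gives p ≈ 0.14 where
0.023 is published), and the surface `TrendMethod` dataclass keeps
both the descriptive flags and the computational ones.

Numerical details: p-values use the Student-t tail at the stated df
(via `scipy.special.stdtr`); slopes and SEs come from closed-form
weighted sums and are asserted equal to a generic statsmodels WLS fit
of the equivalent design to 1e-10 over 10,000 random instances. If all
θ\* are zero the result is slope 0, p = 1 with a `no-variation` flag; a
residual sum of squares below 1e-13 of the weighted response scale is
reported as an exact fit with p = 0 rather than dividing by zero.
Ratio-scale weight rules (methods 4/5) reject non-positive θ, which
cannot arise from genuine ratio estimates. The θ\* centering constant
(1, the null ratio) and the median centering (the reference median, 23
kg/m² for the WHO scheme) are configurable through `EffectEstimates`
and `ClassScheme`.

## Simulation models

Binary outcomes: logit p_i = α + β(z_i − 25) (linear) or
α + β(z_i − 14.2)² (quadratic; 14.2 kg/m² is the population minimum, so
the form is monotone increasing over the observed range). One uniform
per subject; y_i = 1 iff u_i < p_i.

Survival outcomes: event times T_i = −log U_i / exp(β g(z_i)) with the
same linear/quadratic g and a unit-rate exponential baseline; censoring
C_i ~ uniform(0, b); records are (min(T, C), I(T < C), class). Under
β = 0 the event probability has the closed form 1 − (1 − e^(−b))/b,
and `calibrate_censor_bound` inverts the general case by Monte-Carlo
bisection with common random numbers (200,000 subjects, tolerance
0.005), which makes the empirical event fraction monotone in b and the
search deterministic given the generator state.

Exposure samples of n = 1000 draw 80% with replacement from the whole
population and 20% from the underweight class (fraction configurable;
the forced count rounds half away from zero). Without oversampling the
underweight class (<2% of the population) would frequently contain no
events, making class effects inestimable. Replicates in which a class
still has a zero cell (binary) or no events (survival) are dropped and
counted — no continuity correction is applied — and a study aborts if
more than half its replicates are degenerate. Rejection is p < 0.05
(configurable); each study is fully reproducible from its integer seed.

Default study sizes are desk-scale: 2,000 replicates for size studies
and 3,000 for power, at n = 1000; the CLI `--profile full` raises
these to 10,000/30,000. Monte-Carlo standard errors
(sqrt(r(1 − r)/replicates)) are reported alongside every rate.

## Synthetic exposure population

The generator emulates the marginal BMI distribution of the survey
sample behind the worked example: class shares 1.7/27.3/34.6/36.5%
(printed percentages; normalized to sum to one), class medians
17.8/22.7/27.5/34.0 kg/m², range 14.2–67.3, mean 28.9, SD 6.6. Class
membership is multinomial; within a class, values follow a log-normal
truncated to the class interval, with the location solved (Brent) so
the truncated median hits the class target. The log-scale SD is
(log hi − log lo)/4 for the three bounded classes and 0.30 for the
obese tail, the latter chosen so the overall mean and SD land on the
targets (realized ≈ 28.9 and 6.4 at n = 200,000). Only the printed
marginals constrain the generator, so it reproduces class shares,
class medians and overall moments but not any finer structure of the
real data (within-class multimodality, survey design effects,
demographic covariates). Tests that pass on this population therefore
validate the estimators and test procedures under a realistic BMI
shape, not any claim about the original survey microdata, which is
also why the worked-example checks run from the published cell counts
rather than from the synthetic population.

## Observed operating characteristics

The acceptance tests compute, rather than assume, the headline
behavior: across null intercepts α = log 0.2 … log 0.8 (binary,
2,000 replicates) methods 2 and 10 sit within 3 MC SEs of 0.05,
methods 1 and 8 above it, methods 3–7 and 9 below it (conservative);
the survival null behaves the same at heavy censoring. Under the
linear alternative β = log 1.1 at α = log 0.5, methods 6 and 9 lead
the valid field. Power grows with β for methods 3/6/7/9; for methods
4/5 it *falls* between OR 1.05 and 1.1 — the ratio-scale variance
(≈ θ²σ²) inflates with the ratio itself, so their weights degrade
exactly when the signal strengthens. This decline is a real property
of those weight rules, not a Monte-Carlo artifact, and the tests
assert it rather than a blanket monotonicity. Under a strong
monotone-quadratic alternative (β = 0.003, α = log 0.2) the best
weighted method (6 at this prevalence) beats unweighted regression.

## Limitations

- Observations are assumed independent; clustered or survey-weighted
  designs are out of scope (the shipped contingency tables are
  unweighted counts, and the survey's design weights are ignored).
- Cox fitting supports Breslow ties only; with heavily discretized
  times Efron's correction would differ.
- Covariate adjustment beyond the class indicators is not implemented.
- The trend is tested on the ratio scale (θ − 1), not on log θ;
  rank-based alternatives are not provided.
- The quadratic simulation form is monotone only for exposures above
  its centering constant; it is not meant for exposures below 14.2.
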