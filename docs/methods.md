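# Methods

## The model

`hpburden` quantifies the societal burden of delayed access to a medicine by
chaining four components:

1. **Mortality law.** The Heligman–Pollard (HP) model expresses the annual
   death probability as

   q_x = A (x + B)^C + D exp(−E (ln x − ln F)²) + G H^x / (1 + G H^x),

   a childhood-decline term, a log-normal "accident hump", and a logistic
   Gompertz-type senescent term. All eight parameters are strictly positive
   and H > 1 in any realistic fit. On the package's default study window
   (ages 45–86, a cardiovascular-risk cohort) the senescent term dominates
   the other two by roughly two orders of magnitude, so G and H are the
   well-identified parameters; A–F are close to nuisance parameters there.

2. **Delay as an age shift.** A patient diagnosed at age a who waits
   `delay` years experiences the mortality of age a + delay
   (x = age of diagnosis + delay). A binary health-policy indicator switches
   the delay off: effective delay = 0 whenever the policy is in force.
   Delays are stored in years; day-denominated reimbursement delays are
   divided by 365.25 at the I/O boundary.

3. **Cohort propagation.** Starting from l₀ people alive at the diagnosis
   age, deaths per interval are d_x = l_x · q̂_x and survivors
   l_{x+step} = l_x − d_x. Two modes are exposed and always named in
   reports:
   * `replication` applies the annual q̂ at every sub-annual step
     unadjusted. This is the convention under which the default cohort of
     160,000 diagnosed at 45 collapses below one part in 10³ by age 72 on a
     quarterly grid; it reproduces the historical analysis this package
     systematises.
   * `actuarial` converts per step as q_step = 1 − (1 − q̂)^step and is the
     defensible default for new analyses; it always yields higher
     survivorship than replication mode for the same annual q̂.

4. **Burden metrics.** YLL = Σ d_x·e_x with e_x the remaining life
   expectancy; YPPLL groups deaths into five-year bands (45–49 … 80–84 by
   default) and credits each band deaths × (retirement age − mean band
   age); CPL = YPPLL × GDP per capita (flat human-capital valuation, no
   discounting, no age-earnings profile).

## Estimation

Parameters are estimated by minimizing one of eight registered losses:
relative SSE Σ(1 − q̂/q)² (the classic HP objective and the default),
absolute SSE, log SSE, Pearson-weighted SSE, binomial deviance, Poisson
deviance, absolute error, and relative absolute error. Searches run in a
log-parameterization (log p for A–G, log(H−1) for H) so positivity and
H > 1 hold by construction, inside box bounds (default [1e−12, 1e6] per
parameter, C ≤ 200, H ≤ 2). Smooth sum-of-squares losses go through
trust-region least squares with an analytic Jacobian (deviances via signed
deviance residuals, with a numeric Jacobian); the absolute-error losses use
bounded Nelder–Mead. Convergence is declared at 1e−10 relative objective
change; the returned loss never exceeds the loss at the start point.

Default starting values are the package's reference estimates. A start
outside the box (e.g. H ≤ 1 after multiplicative jitter) is projected onto
the box and, because a projected start can strand the local search on the
boundary, a data-driven fallback start is also tried: when senescence
dominates, logit(q) is nearly linear in age, so a least-squares line gives
G = exp(intercept), H = exp(slope). The better of the two final losses is
returned. The HP objective is multimodal; no global-optimality claim is
made.

**Goodness of fit.** The binomial deviance against the saturated model,
D = 2 Σ [d ln(d/ê) + (n−d) ln((n−d)/(n−ê))] with ê = n·q̂ and
0·ln(0/·) := 0, is referred to chi-square on (#ages − 8) degrees of
freedom. A fitted q of exactly 0 or 1 against discordant counts yields an
infinite deviance, reported as such.

**Uncertainty.** The default bootstrap is parametric: deaths are redrawn
per age from Binomial(exposure, q̂) and the model refitted (warm-started at
the point estimate, with a 1e−8 refit tolerance — solver noise at that
level is far below the bootstrap dispersion). Nonparametric age-resampling
is available behind a flag. Confidence intervals use the percentile method.
Because percentile intervals of positivity-constrained parameters can never
cross zero, p-values for H₀: parameter = 0 instead use the basic
(reflected) bootstrap interval: the reported p is the smallest level at
which that interval excludes 0, floored at 1/(B+1). Replicates that fail to
converge are dropped and counted; more than 20% failures aborts.

## Synthetic data

The empirical schedule behind the motivating application is not publicly
deposited, so the generator produces statistical stand-ins with the assumed
structure: per grid age, deaths ~ Binomial(exposure, q_true) with q_true
the HP law at a known parameter set — binomial rather than Poisson because
q_x is a probability, not a rate. Defaults are the study conditions:
reference parameters, ages 45–86, cohort l₀ = 160,000, and either a
quarterly grid (164 ages) or a daily grid (~15,000 age points) thinned to
the four quarter points of each whole year, reproducing the retention step
of the source analysis. The default exposure of 10,000 per age gives
observed probabilities a few percent of relative noise — enough to exercise
every estimation path without overwhelming the senescent signal.

What the generator does **not** emulate: treatment effects (the framework
models delay purely as an age shift), cause-of-death composition,
heterogeneity between patients, and any real-world deviation from the HP
functional form. Passing tests therefore demonstrate internal correctness
and statistical calibration under the assumed model, not fidelity to any
particular trial population.

Reproducibility: every generator operation derives its stream as
`default_rng([seed, OP_CODE])` with a distinct code per operation, so one
pipeline seed gives stable, independent streams end to end.

## Numerical choices

* q_x is clamped at 1 − 1e−12 with a warning when the raw three-term sum
  exceeds 1 (possible at extreme ages); the generator instead *rejects*
  configurations whose raw curve leaves (0, 1), since a clamped curve is
  outside the probability interpretation.
* The senescent term is evaluated as expit(ln G + x ln H) for stability.
* Ages are interval left endpoints; intervals are half-open [x, x + step).
  Grids never overshoot the end age (a fractional trailing step is
  dropped).
* Deaths within an interval receive a half-interval credit:
  e_x = step · Σ_{k>x} l_k / l_x + step/2, and e_x = step/2 at the last
  grid age. Where l_x = 0, e_x is undefined and reported as 0 with a
  warning.
* The cohort recursion is an explicit loop so l₀ = l_end + Σ d_x holds to
  machine precision.
* Band mean ages default to the death-weighted mean of grid ages
  (statistically faithful); a band-midpoint rule (lower + 2.5) is provided
  because "mean band age" is not uniquely defined. Bands whose mean age is
  at or past retirement contribute zero YPPLL by default — negative "lost
  productive years" are meaningless under the human-capital approach — with
  an untruncated literal mode behind a flag.
* The delay sweep re-propagates the full cohort for every delay rather than
  re-indexing one trajectory, so e_x stays consistent with each shifted
  start age; bands are the default five-year bands that fit inside the
  shifted grid.

## Test problem sizes

The statistical suites run at sizes chosen to make their Monte-Carlo error
small relative to the acceptance bands: deviance calibration uses 500
simulated schedules at exposure 10⁴ on the 164 quarterly ages;
bootstrap coverage uses 200 Monte-Carlo repetitions on an annual grid at
exposure 10⁶ with 100 bootstrap replicates each (the minimum the API
accepts); the trial-cohort unbiasedness check uses 200 replicate cohorts.

## Known limitations

* Remaining life expectancy is model-derived from the fitted trajectory by
  default; analyses that require an external (national) life table can read
  one from CSV. Headline YLL totals depend strongly on this choice.
* p-values for positivity-constrained parameters are an interpretation (see
  above); other constructions are defensible and can give different values.
* The framework collapses mortality to age-specific totals: no sex, cause,
  or period stratification.
* No discounting, friction-cost method, or QALY/DALY computation.
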