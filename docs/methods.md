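# Methods

## The model

`pgamsurv` analyzes right-censored (optionally left-truncated)
time-to-event data by turning the censored-data likelihood into a Poisson
pseudo-likelihood and modeling the log-hazard with penalized splines.

For subject *i* observed on (E_i, F_i] with event indicator δ_i, the
likelihood contribution is h(F_i)^δ_i · exp(−∫_{E_i}^{F_i} h(t) dt).  The
integral is replaced by a Gauss–Lobatto (GL) quadrature sum
∑_j w_ij h(t_ij).  Because the GL node set contains both endpoints, the
subject's entry and exit times appear exactly in the expanded data: the
record becomes n pseudo-observations (one per node) with Poisson response
d_ij = δ_i at the exit node and 0 elsewhere, and offset log w_ij.  Two
consequences follow from the endpoint property: no subject can fail at
its entry time, and the exit time/event status are represented without
discretization error.

The log-hazard is an additive model

  log h(t_ij) = λ₀(t_ij) + x_i β [+ β_T^NC(t) x_i^T] [+ Σ_k λ_k(t) strata]
                [+ tensor smooths over time scales] [+ z_k b frailty],

with each smooth a penalized cubic regression spline.  An n-node GL rule
integrates polynomials to degree 2n−3 exactly and its remainder is
A(n) (F−E)^{2n−1} f^{(2n−2)}(ξ) with
A(n) = −n(n−1)³[(n−2)!]⁴ / ((2n−1)[(2n−2)!]³); since the spline
log-hazard is locally cubic, the (2n−2)-th derivative of
f = exp(cubic) is computed exactly by the power-series recurrence
g_{m+1} = g_m′ + g_m·P′ (f^{(m)} = g_m f), carried in log space with
explicit rescaling so orders up to 20 nodes neither overflow nor lose
precision.  Penalizing the spline's curvature shrinks the cubic
coefficient and therefore also tightens this quadrature error — the
smoothing penalty and the numerical approximation pull in the same
direction.

## Fitting

Coefficients maximize the penalized Poisson log-likelihood
ℓ(ψ) − ½ Σ λ_k ψᵀS_kψ by iteratively reweighted least squares
(canonical log link, weights μ, step-halving on the penalized deviance;
convergence when the relative deviance change drops below 1e−8, cap 200
iterations).  Smoothing parameters are selected by REML — the Laplace
approximation to the marginal likelihood of the mixed-model
representation, −ℓ_p + ½log|XᵀWX+S_λ| − ½log|S_λ|₊ — minimized by
Nelder–Mead on the log-λ scale (GCV is available as an alternative); a
vanishing nudge (−1e−9 Σ log λ) breaks flat stretches toward the smoother
model.  The reported covariance is the Bayesian posterior
V = (XᵀWX + S_λ)⁻¹ at convergence; effective degrees of freedom are
tr(V XᵀWX), also reported per term.

Bases: cubic regression splines in the cardinal parameterization (one
coefficient per knot; penalty S = DᵀB⁻¹D whose null space is exactly the
constant and linear functions), default 8 knots at quantiles of the
pseudo-observation node times, linear extrapolation beyond the knot
range.  Smooths carry a sum-to-zero constraint so they coexist with the
intercept; "by"-variable smooths multiply the constrained basis by the
covariate, so the parametric term is the constant effect component and
the smooth its time-varying deviation — the Wald test of the by-smooth
block (pseudo-inverse with rank-adjusted df when the penalized block is
numerically singular) is the proportionality-of-hazards test.  Stratified
baselines give each stratum a full, unconstrained smooth and drop the
global intercept.  Tensor products are row-wise products of two marginal
bases with one penalty per margin (their joint pseudo-determinant is
evaluated from the summed block).  Frailty terms place one identity-
penalized coefficient per cluster level (iid Gaussian effects, common
variance).

## Effect measures

All nonlinear functionals use the same posterior simulation: K draws
ψ̃ ~ N(ψ̂, V) (default K = 1000; the covariance is symmetrized and tiny
negative eigenvalues floored), each transformed, then summarized by the
draw mean and 2.5/97.5 percentiles.  Percentile rather than Wald
intervals are used for all curve-valued measures because the transforms
are nonlinear.  Survival per draw is exp(−∫₀ᵗ h), the cumulative hazard
integrated with a fresh 10-node GL rule per requested time, independent
of the expansion rule used in fitting.  HR(t) = h₁/h₀; RR(t) and ARD(t)
are ratio and difference of event risks 1−S(t) (experimental minus
control, so negative ARD favors treatment); the restricted mean survival
time over [0, T_max] is the 10-node GL integral of each arm's survival
curve.  RR is undefined (reported NaN with a warning) while the reference
arm has no event risk.  Population-averaged (corrected group prognosis)
effects push every cohort member through the model under both
counterfactual arm assignments, average survival and hazard within arm
over the cohort, and only then form ratios/differences — averaging
precedes contrast formation.

## Simulators

The built-in generators reproduce the benchmark designs at their stated
operating points (time in months):

* Parametric baselines — Weibull h = scale·shape·t^{shape−1} (the
  proportional-hazards simulation convention), Gompertz
  h = scale·e^{shape·t}, Lognormal (meanlog, sdlog) — with the four
  printed parameter sets per family packaged as named fixtures.  A
  negative Gompertz shape is defective; lifetimes beyond the search
  horizon are administratively censored there and flagged.
* General baselines A–D defined by quadratic log-hazards, sampled by the
  inverse-cumulative-hazard method: H is tabulated by cumulative Simpson
  on a doubling grid and inverted with Newton steps refined by a local
  7-node GL correction (tolerance 1e−8).
* Two-arm deviations add logHR + a·t + b·t² to the baseline log-hazard;
  proportional/linear/quadratic/linear-quadratic shapes draw their
  parameters per replicate uniformly from
  [log 0.7, log 0.9]×[−0.1, 0.1]×[−0.009, 0.009].
* Censoring is independent exponential with the rate solved from
  P(C < T) = target (30% or 70%) against the equal-allocation two-arm
  mixture, via the substitution u = 1−e^{−ct} and Brent root finding to
  1e−6.

What the generators do not emulate: covariate-dependent or informative
censoring, staggered accrual, ties from coarse measurement, and
time-varying covariates.  Passing benchmarks therefore demonstrate
correctness of the estimator under independent exponential censoring and
smooth hazards, not robustness to those real-data features.

## Performance evaluation

The study harness is matched-pair: replicate seeds derive only from
(master seed, scenario index, replicate index), so every compared method
(Poisson GAM, Cox partial likelihood via lifelines, Kaplan–Meier with
lifelines' exponential-Greenwood log(−log) intervals) sees identical
datasets.  Metrics per scenario: standardized bias
100·mean(err)/SD(err) (n−1 divisor), MSE, coverage of nominal-95%
intervals with the binomial acceptability band p ± 2√(p(1−p)/N), and
mean interval length.  Survival probabilities are evaluated at 50% and
95% of each replicate's maximum observation time against the analytic
truth; the true RMST difference is integrated from the simulated hazards
by adaptive Gauss–Kronrod quadrature.  Replicate failures are counted
and excluded, never silently dropped.

The shipped benchmark suites run four scenarios per flavor at 100
replicates each (300 subjects per arm), chosen to span baseline family,
deviation shape and both censoring levels; the full 48/32-scenario,
500-replicate grids are available through `make_scenarios`/`run_study`
but are not exercised by the default suites.  At 100 replicates a
per-scenario standardized bias has Monte-Carlo noise of about 10 points,
so the suites additionally report a pooled standardized bias — errors
pooled over the four scenarios' matched replicates (noise ≈ 5 points) —
as the headline number compared against the acceptability thresholds.

## Quadrature-error survey

The survey draws (γ, a, b, c) for the hazard exp(γ + at + bt² + ct³)
from an unscrambled 4-d Sobol sequence mapped to [−1,1]³×[0,1],
fast-forwarded past the origin (whose c = 0 point can make the mean
survival time infinite).  The coefficients live on an annual time scale —
e^γ ∈ [0.37, 2.7] per year matches the monthly-scale baselines A–D — and
each point's mean survival time (the integral of its survival function,
computed by a high-accuracy adaptive ODE solve of S′ = −hS) is restricted
to a four-year horizon: the domain contains near-zero cubic coefficients
whose survival plateaus would otherwise imply mean survival times of
decades, which no finite trial could observe.  The worst-case GL error
for each point maximizes |A(n)(F−E)^{2n−1} f^{(2n−2)}(ξ)| over ξ with
E = 0, F = the point's restricted MST, by a 4001-point scan of the
closed interval polished with bounded scalar optimization.  MST sample
statistics are reported in months (×12).  The survey is deterministic by
construction; its sample statistics are specific to the Sobol direction
numbers used (scipy's), so small shifts against other implementations'
samples are expected.

## Numerical choices and edge cases

* Default expansion order: 10 nodes (user range 3–50).  The error survey
  shows the expected log10 likelihood error near −15 at 10 nodes, far
  below statistical noise, and benchmark estimates move by <0.005 on the
  log-HR scale between 10 and 20 nodes.
* n = 2 expansion (bare trapezoid) is allowed only with a warning; an
  event at a subject's entry time is rejected at record construction.
* Zero events leave the hazard level unidentified and raise; a
  rank-deficient parametric block raises naming the aliased terms.
* Linear predictors are clipped at ±700 before exponentiation; lifetimes
  whose target cumulative hazard is unreachable within the simulation
  horizon (1000 months) are administratively censored and flagged.
* Predictions beyond the fitted time range warn (linear extrapolation of
  the log-hazard), they do not fail.
* Serialized fits are JSON (exactly round-tripping floats via repr), and
  reloaded fits reproduce predictions bit-for-bit given the same seed.

## Known limitations

Interval censoring, competing risks, time-varying covariates and
covariate-dependent censoring are out of scope.  The frailty covariance
is σ²I (no correlated random effects).  Smoothing-parameter uncertainty
is not propagated into V; intervals are conditional on the selected λ,
matching standard penalized-GAM practice.  The proportionality test's
penalized block can be numerically rank deficient under heavy smoothing;
the rank-adjusted pseudo-inverse handles it but the test's small-sample
size is then approximate.
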