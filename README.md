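# pgamsurv

Flexible survival analysis for clinical trials by **Gauss–Lobatto time
splitting** and **penalized Poisson generalized additive models**
(PGAMs), with simulation-based treatment-effect measures beyond the
hazard ratio.

## Who this is for

Trial statisticians and methods researchers who need more than a single
Cox hazard ratio from censored data: smooth baseline-hazard and survival
estimates, a test of the proportional-hazards assumption, time-varying
hazard ratios, relative risks, absolute risk differences, restricted
mean survival time (RMST), covariate-adjusted and population-averaged
effects — all from one model fit and one simulation pass.

## The idea

The censored-data likelihood for subject *i*, observed on (E_i, F_i]
with event indicator δ_i, is

    h(F_i)^{δ_i} · exp( −∫_{E_i}^{F_i} h(t) dt ).

Splitting each subject's follow-up at the nodes t_ij of a Gauss–Lobatto
rule with weights w_ij replaces the integral by Σ_j w_ij h(t_ij), which
is the kernel of a Poisson likelihood with offsets log w_ij and
responses d_ij = δ_i at the exit node, 0 elsewhere.  Because Lobatto
nodes include both endpoints, entry and exit times are represented
exactly, and the rule's spectral accuracy means ~10 nodes per subject
suffice (the package ships a quasi-random survey of the worst-case
quadrature error to back this up).  The log-hazard is then a penalized
additive model

    log h(t) = λ₀(t) + xβ + β_T^NC(t)·x_T + Σ_k λ_k(t) + te(t, c) + z b,

covering stratified baselines, non-proportional (time-varying) effects,
multiple time scales and frailty.  Fitting is penalized IRLS with REML
smoothing selection; every nonlinear functional (survival, HR(t), RR(t),
ARD(t), RMST) is summarized from draws ψ̃ ~ N(ψ̂, V̂).

## Worked example

```python
import numpy as np
import pgamsurv as pg

base = pg.ParametricBaseline("weibull", 1.0, 0.1)   # exponential, 0.1/month
scenario = pg.TrialScenario(n_per_arm=300, baseline=base,
                            deviation=pg.DeviationSpec(log_hr=np.log(0.7)),
                            censoring=0.3, seed=1)
records = pg.simulate_trial(
    scenario, censoring_rate=pg.calibrate_censoring(scenario, 0.3))

fit = pg.fit_model(pg.expand(records, n_nodes=10), "arm + s(t)")
a, _ = fit.term_map["arm"]
print(fit.beta[a], np.sqrt(fit.cov[a, a]))

curve = pg.predict_survival(fit, {"arm": 0.0}, [6.0, 12.0, 24.0],
                            K=1000, seed=7)
print(curve.estimate)
```

prints (exactly what `examples/01_fit_and_survival_curve.py` computes)

```
log-HR estimate: -0.282 (SE 0.098; truth -0.357)
arm 0  S(   6 mo) = 0.554 [0.505, 0.601]  (truth 0.549)
arm 0  S(  12 mo) = 0.313 [0.263, 0.362]  (truth 0.301)
arm 0  S(  24 mo) = 0.094 [0.064, 0.129]  (truth 0.091)
```

The log-HR matches what a Cox model estimates on the same data to well
within a standard error, and the survival bands are percentile intervals
over 1000 posterior coefficient draws.  The `examples/` directory has
one short script per capability: survival curves, non-proportional
effects and the proportionality test, the quadrature-error survey, the
matched-pair performance study against Cox, and population-averaged
(corrected group prognosis) subgroup effects.

A thin CLI wraps the same functions:

```bash
pgamsurv fit --input trial.csv --formula "arm + s(t)" --covariates arm --out fit.json
pgamsurv effects --fit fit.json --measure rmst --tmax 40 --draws 1000 --seed 7 --out rmst.csv
pgamsurv quaderr --points 1000 --orders 5,7,10,15,20 --out survey.csv
```

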