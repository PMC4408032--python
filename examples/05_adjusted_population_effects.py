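"""Covariate-adjusted and population-averaged treatment effects.

Simulates a trial whose event risk depends strongly on a baseline
biomarker as well as the treatment, fits an adjusted model, and contrasts
the conditional effect with the population-averaged (corrected group
prognosis) effect: every patient is predicted under both counterfactual
arm assignments, predictions are averaged within arm over the cohort, and
only then are ratios and differences formed.
"""

import numpy as np
import pandas as pd

import pgamsurv as pg

rng = np.random.default_rng(8)
n = 600
arm = np.repeat([0.0, 1.0], n // 2)
biomarker = rng.normal(0.0, 1.0, n)
lam = np.exp(np.log(0.08) + np.log(0.7) * arm + 0.8 * biomarker)
t = rng.exponential(1.0 / lam)
c = rng.exponential(25.0, n)
records = [pg.SurvivalRecord(
    id=i, entry=0.0, exit=float(min(ti, ci)), event=int(ti <= ci),
    covariates={"arm": float(a), "z": float(z)})
    for i, (ti, ci, a, z) in enumerate(zip(t, c, arm, biomarker))]

fit = pg.fit_model(pg.expand(records, 10), "arm + z + s(t)")
a_idx, _ = fit.term_map["arm"]
z_idx, _ = fit.term_map["z"]
print(f"adjusted log-HR (arm): {fit.beta[a_idx]:.3f} (truth {np.log(0.7):.3f})")
print(f"biomarker log-HR:      {fit.beta[z_idx]:.3f} (truth 0.8)")

cohort = pd.DataFrame({"arm": arm, "z": biomarker})
times = [6.0, 12.0]
cgp = pg.corrected_group_prognosis(fit, cohort, "arm", times, K=1000, seed=2)
high_risk = pg.corrected_group_prognosis(fit, cohort, "arm", times,
                                         subgroup=biomarker > 1.0,
                                         K=1000, seed=2)
for i, tt in enumerate(times):
    print(f"t={tt:4.0f}  population ARD = {cgp['ARD'].estimate[i]:+.3f} "
          f"[{cgp['ARD'].lower[i]:+.3f}, {cgp['ARD'].upper[i]:+.3f}]   "
          f"high-biomarker subgroup ARD = {high_risk['ARD'].estimate[i]:+.3f}")
print("ARD < 0: treatment lowers absolute event risk. The high-biomarker "
      "subgroup shows the larger early benefit (more events to prevent); "
      "its absolute benefit fades once most of the subgroup has failed, "
      "even though the hazard ratio is shared across patients.")
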