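"""Detect and summarize a non-proportional treatment effect.

Simulates a trial whose experimental-arm log-hazard drifts linearly away
from the control baseline (so the hazard ratio is truly time-varying),
fits both a proportional and a non-proportional Poisson GAM, tests the
proportionality assumption, and prints HR(t), RR(t), ARD(t) and the RMST
difference -- four complementary views of the same treatment effect.
"""

import numpy as np

import pgamsurv as pg

base = pg.GeneralBaseline(np.log(0.08), 0.05, 0.01)
scenario = pg.TrialScenario(
    n_per_arm=300, baseline=base,
    deviation=pg.DeviationSpec(log_hr=np.log(0.5), a=0.20),  # linear drift
    censoring=0.2, seed=3)
records = pg.simulate_trial(scenario)
expanded = pg.expand(records, 10)

nph = pg.fit_model(expanded, "arm + s(t) + s(t, by=arm)")
stat, df, p = pg.test_term_zero(nph, "s(t,by=arm)")
print(f"proportionality test: X2 = {stat:.2f} on {df} df, p = {p:.4f}")
print("(a small p rejects proportional hazards: the time-varying "
      "component of the arm effect is needed)")

t_max = max(r.exit for r in records)
times = np.linspace(1.0, 0.8 * t_max, 6)
curves = pg.effect_curves(nph, ({"arm": 0.0}, {"arm": 1.0}), times,
                          K=1000, seed=5)
print(f"{'t':>6} {'HR(t)':>8} {'RR(t)':>8} {'ARD(t)':>9}")
for i, t in enumerate(times):
    print(f"{t:6.1f} {curves['HR'].estimate[i]:8.3f} "
          f"{curves['RR'].estimate[i]:8.3f} {curves['ARD'].estimate[i]:9.3f}")
print("HR rises with time (the linear drift erodes the early benefit); "
      "ARD is the absolute event-risk difference, negative favoring the "
      "experimental arm.")

est = pg.rmst_difference(nph, ({"arm": 0.0}, {"arm": 1.0}),
                         t_max=t_max, K=1000, seed=5)
print(f"RMST difference over [0, {t_max:.1f}]: {est.estimate:.2f} months "
      f"[{est.lower:.2f}, {est.upper:.2f}] "
      "(positive = extra mean survival time in the experimental arm; here "
      "the late excess hazard cancels the early benefit on the time scale)")
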