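"""Benchmark the Poisson GAM against Cox on matched simulated trials.

Runs a small matched-pair study (identical datasets for both methods) on
two proportional-hazards scenarios and prints standardized bias, MSE,
coverage and mean confidence-interval length for the log hazard ratio.
"""

from pgamsurv.evaluate import make_scenarios, run_study

scenarios = make_scenarios("hr", subset=[
    "weibull(0.8/0.1)|HR=0.7|cens=30",
    "gompertz(0.1/0.05)|HR=0.5|cens=30",
])
summary, replicates = run_study(scenarios, methods=("pgam", "cox"),
                                reps=25, seed=42, K=50)
cols = ["scenario", "method", "std_bias_pct", "mse", "coverage",
        "acceptable", "cil"]
print(summary[cols].to_string(index=False))
print("\nBoth methods see the same 25 datasets per scenario; standardized "
      "bias is the mean estimation error in percent of the empirical SD, "
      "and 'acceptable' marks coverage inside the binomial band around "
      "95%. At this small scale the bands are wide; the shipped benchmark "
      "suites use 100 replicates.")
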