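"""How many Gauss-Lobatto nodes does a survival likelihood need?

Surveys the worst-case integration error of the rule over 200
quasi-random cubic log-hazards (the local behavior of any cubic-spline
log-hazard model), each integrated over its own mean survival time, and
prints the expected and maximum log10 error by quadrature order.
"""

import numpy as np

import pgamsurv as pg

survey = pg.survey_error(200, orders=[5, 7, 10, 15, 20])
print(f"MST sample over {survey.n_points} hazards: "
      f"mean {survey.mst.mean():.1f}, median {np.median(survey.mst):.1f}, "
      f"range [{survey.mst.min():.1f}, {survey.mst.max():.1f}] months")
print(f"{'order':>6} {'E[log10 err]':>13} {'max log10 err':>14}")
for n, mean_e, max_e in zip(survey.orders, survey.expected_log10_error,
                            survey.max_log10_error):
    print(f"{n:6d} {mean_e:13.2f} {max_e:14.2f}")
print("Each extra block of nodes buys orders of magnitude of likelihood "
      "accuracy; around 10 nodes the approximation error is already far "
      "below statistical uncertainty, which is why 10 is the default "
      "expansion order.")
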