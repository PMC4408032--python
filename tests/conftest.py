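import numpy as np
import pytest

import pgamsurv as pg


@pytest.fixture()
def exponential_records():
    """500 uncensored exponential(0.1) lifetimes as survival records."""
    rng = np.random.default_rng(20240301)
    t = rng.exponential(10.0, 500)
    return [pg.SurvivalRecord(id=i, entry=0.0, exit=float(ti), event=1)
            for i, ti in enumerate(t)]


@pytest.fixture()
def two_arm_trial():
    """One 300/arm exponential trial with true HR 0.7 and 30% censoring."""
    base = pg.ParametricBaseline("weibull", 1.0, 0.1)
    sc = pg.TrialScenario(n_per_arm=300, baseline=base,
                          deviation=pg.DeviationSpec(log_hr=np.log(0.7)),
                          censoring=0.3)
    rate = pg.calibrate_censoring(sc, 0.3)
    rng = np.random.default_rng(77)
    return pg.simulate_trial(sc, rng=rng, censoring_rate=rate)
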