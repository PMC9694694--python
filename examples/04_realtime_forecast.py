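"""Replay the real-time forecasting loop through one test meal.

Opens a session at mealtime with the 5 presamples, feeds CGM samples one by
one, and prints the membership weights and the weighted 30-min prediction as
they evolve.
"""

import numpy as np

from csarima import (
    ClusterSearchGrid,
    PipelineConfig,
    SimConfig,
    generate_subject,
    segment_postprandial,
    split_train_test,
    start_pp,
    step,
)
from csarima.pipeline import fit_csarima
from csarima.seasonal_models import SarimaGrid

config = PipelineConfig(
    seed=4,
    test_days=4,
    cluster_grid=ClusterSearchGrid(nC_range=(2, 3), m_grid=(2.0,), restarts=2),
    sarima_grid=SarimaGrid(p_range=(1,), q_range=(0,), d_range=(0,),
                           P_range=(1,), Q_range=(0,), D_range=(0,)),
)
series, events, _ = generate_subject(SimConfig(days=12, seed=4))
train, test = split_train_test(series, events, test_days=config.test_days)
bundle, _ = fit_csarima(train, config)

pp = segment_postprandial(*test)[0]
state = start_pp(pp.presamples, bundle, ph_minutes=(30,))
print("slot  sample   weights              yhat(t+30)  target(t+30)")
for t in range(1, min(pp.observed_length, 12) + 1):
    state = step(state, pp.window[t - 1])
    target = pp.window[t + 5] if t + 6 <= pp.observed_length else np.nan
    if state.output is None:
        print(f"{t:4d}  {pp.window[t-1]:7.1f}   (burn-in)")
    else:
        w = np.array2string(state.weights, precision=2, floatmode="fixed")
        print(f"{t:4d}  {pp.window[t-1]:7.1f}   {w:<18}  {state.output[30]:8.1f}"
              f"    {target:8.1f}")
# no output during the 3-sample burn-in; afterwards the prediction is the
# membership-weighted sum of the per-cluster SARIMA forecasts
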