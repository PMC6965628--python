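"""Recover network response latencies (time-to-peak) from noisy epochs.

Generates epoch ensembles whose evoked bumps peak at the study's network
latencies — DAN 500 ms, SN 700 ms (increases), DMN 1000 ms (decrease) —
computes each electrode's TTP from its trial-mean response, and fits the
mixed-model recipe testing the network effect.
"""

import numpy as np
import pandas as pd

from netlag.dynamics import time_to_peak
from netlag.stats import run_recipe
from netlag.synth import simulate_epoch_ensemble

rng = np.random.default_rng(5)
rows = []
for subject in range(6):
    for net, sign, ttp in (("DAN", +1, 500.0), ("SN", +1, 700.0),
                           ("DMN", -1, 1000.0)):
        for elec in range(4):
            epochs = simulate_epoch_ensemble(
                n_trials=100, fs_env=100.0, t_start=-0.8, t_stop=1.6,
                ttp_ms=ttp, sign=sign, amplitude=0.5, noise_sd=1.0, seed=rng)
            times_ms = (-0.8 + np.arange(epochs.shape[1]) / 100.0) * 1000.0
            rec = time_to_peak(epochs.mean(axis=0), times_ms, sign=sign)
            rows.append({"subject": f"s{subject}", "network": net,
                         "ttp_ms": rec.ttp_ms})

table = pd.DataFrame(rows)
print(table.groupby("network")["ttp_ms"].median().rename("median TTP (ms)"))
res = run_recipe("ttp_network", table)
t = res.tests["C(network)"]
print(f"\nnetwork effect: F({t.df_num}, {t.df_den:.1f}) = {t.f_stat:.1f}, "
      f"p = {t.p:.2e}")
print(f"ordering DAN < SN < DMN recovered: {res.extras['ordering_recovered']}")
# Median TTPs should land within tens of ms of the 500/700/1000 ms truth.
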