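"""Moving-window palatability coding of simulated gustatory-cortex units.

Twenty units are simulated with palatability coupling switching on 500 ms
after taste delivery; the 250 ms / 25 ms moving-window Spearman correlation
between firing rates and the four-taste hedonic ranking is computed per unit
and averaged.  The printed time course should sit at the chance level early
and plateau after the coupling ramp.
"""

import numpy as np

from ctamem.palatability import PalatabilityMap, population_timecourse
from ctamem.synthetic import (DEFAULT_PALATABILITY, TasteSimParams,
                              expected_null_abs_rho, simulate_taste_units)

params = TasteSimParams(onset_ms=500.0, ramp_ms=300.0, seed=7)
spikes, _ = simulate_taste_units(params)
ranks = PalatabilityMap(dict(DEFAULT_PALATABILITY))
tc = population_timecourse(spikes, ranks)

null_mean, null_sd = expected_null_abs_rho(params.trials_per_taste)
print(f"chance |rho| at 60 trials: {null_mean:.3f}")
print("time (ms)  mean|rho|  sem")
for t, m, s in zip(tc.window_center_ms[::8], tc.mean_abs_rho[::8],
                   tc.sem_abs_rho[::8]):
    bar = "#" * int(m * 40)
    print(f"  {t:6.0f}    {m:.3f}    {s:.3f}  {bar}")

pre = tc.mean_abs_rho[tc.window_start_ms + 250 <= params.onset_ms].mean()
post = tc.mean_abs_rho[tc.window_start_ms >= 800].mean()
print(f"\npre-onset mean |rho| {pre:.3f} (chance); plateau {post:.3f} - the"
      "\ncorrelation rises only once the rate ordering starts following the"
      "\nhedonic ranking.")
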