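"""Compute the Displacement Index of a single simulated road trial.

Simulates one 60 s cobblestone trial at 50 Hz and walks the statistic's
chain: consecutive-sample distances -> per-second D_i -> trial mean D̄x.
"""

import numpy as np

from roadvib import SurfaceModel, simulate_trial, displacement_series, trial_summary

model = SurfaceModel(surface="C", speed=60, target_dbar=4.44, between_trial_sd=0.09)
trace = simulate_trial(model, duration=60.0, f=50, seed=1)
series = displacement_series(trace)
result = trial_summary(series, model.surface, model.speed)

print(f"trace: {trace.n_samples} samples at {trace.f} Hz ({trace.duration:.0f} s)")
print(f"per-second D_i values: {len(series)} (first five: {np.round(series.values[:5], 2)})")
print(f"trial mean D̄x = {result.dbar:.3f}  (min D_i {result.min_di:.2f}, max D_i {result.max_di:.2f})")
print()
print("D̄x near 4.4 is the heavy-vibration regime of cobblestone at 60 km/h;")
print("each D_i is the mean distance between consecutive tri-axial readings")
print("within one second, so gravity cancels and only shaking remains.")
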