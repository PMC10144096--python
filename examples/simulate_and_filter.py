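"""Generate a noisy trajectory and clean it up with the classical filters.

Builds one synthetic walking/running track with heteroscedastic
measurement noise, runs the constant-velocity Kalman filter and the EMA
smoother, and prints the position RMSE of each estimate.  Lower is better;
the filters should roughly halve the raw measurement error.
"""

import numpy as np

from lstmkf.benchmark import rmse, simulate_sequence
from lstmkf.kalman import constant_velocity_model, ema_smoother, run_filter

seq = simulate_sequence(seed=7, duration=30.0, rate=30.0)
print(f"{len(seq.times)} frames, regimes: {sorted(map(str, set(seq.regimes)))}, "
      f"{(~seq.present).sum()} dropout frames")

cv = constant_velocity_model(space_dim=3, dt=seq.dt, q=1.0, r=0.2)
kf_est = run_filter(cv, list(seq.measurements)).means[:, 0::2]
ema_est = ema_smoother(seq.measurements, alpha=0.3)

raw = seq.measurements.copy()
for t in range(1, len(raw)):  # hold last value through dropouts
    if np.isnan(raw[t]).all():
        raw[t] = raw[t - 1]

for name, est in [("raw measurements", raw), ("constant-velocity KF", kf_est),
                  ("EMA smoother", ema_est)]:
    print(f"{name:22s} position RMSE {rmse(seq.positions[1:], est[1:]):.3f} m")
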