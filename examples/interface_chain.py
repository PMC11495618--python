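"""The EMG-to-cursor signal chain on synthetic calibration recordings.

Builds a synthetic maximum-contraction and rest recording, runs the real
calibration (smoothing, tail means, log-normal noise threshold), scales a
test contraction to a control signal, and integrates a constant control
signal to show the full-screen traverse time.
"""

import numpy as np

from myolearn import emg_interface as emg, synthetic_participant as sp

rng = np.random.default_rng(0)

# 10 s maximal contraction and 15 s rest, rendered as amplitude-modulated
# noise (raw SD 1.0 during contraction, 0.02 at rest)
max_raw = sp.synthesize_raw_emg(np.full(10 * 2048, 1.0), 1.0, 0.02, rng)
rest_raw = sp.synthesize_raw_emg(np.zeros(15 * 2048), 1.0, 0.02, rng)

calib = emg.calibrate(max_raw, rest_raw)
print(f"max power          : {calib.max_power:.4f}  (mean smoothed power, final 4 s)")
print(f"noise baseline     : {calib.noise_baseline:.4f}  (mean smoothed power, final 10 s)")
print(f"noise threshold    : {calib.threshold:.4f}  (log-normal 99.99th pct + 1% max)")

# a contraction at 35% of maximum power maps to a control signal of 1
test_power = np.full(100, 0.35 * calib.max_power + calib.threshold)
profile = emg.control_signal(test_power, calib)
print(f"control at 35% max : {profile.values[-1]:.3f}  (definition of unit control)")

# a unit control signal crosses the 1080 px screen in 1080/2500 s
print(f"screen traverse    : {emg.traverse_time():.3f} s  (1080 px at 2500 px/s)")
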