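"""The EMG-to-cursor signal chain.

Raw bipolar EMG sampled at 2048 Hz is rectified and smoothed with a causal
weighted-average kernel (a 256-sample triangular kernel for the main task, a
4096-sample uniform kernel for the power-cycle task).  A per-channel noise
threshold is subtracted and negative values clamped to zero, and the result
is scaled so that 35 % of the channel's calibrated maximum power maps to a
control signal of 1 (uncapped above 1).  The two channel profiles h(t)
(hand) and s(t) (shin) are combined in a weighted sum, scaled by a constant
velocity factor alpha = 2500 px/s, and integrated to give the cursor
trajectory.  With these constants a control signal held at 1 traverses the
1080 px screen in 0.432 s.

Congruent mapping: right hand -> rightward velocity (w1 = +1), left shin ->
leftward velocity (w2 = -1).  Incongruent mapping: both signs flipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

FS_DEFAULT = 2048
ALPHA_DEFAULT = 2500.0        # px/s per unit control signal
SCREEN_WIDTH_PX = 1080.0
SCALE_FRACTION = 0.35         # fraction of max power mapping to control 1
THRESHOLD_FRACTION = 0.01     # 1 % of max power added to the noise threshold
NOISE_QUANTILE = 0.9999       # log-normal percentile for the main-task threshold
TRIANGULAR_LEN = 256
UNIFORM_LEN = 4096
MAX_TASK_DURATION = 10.0      # s; mean over final 4 s -> max power
MAX_TAIL = 4.0
REST_TASK_DURATION = 15.0     # s; mean over final 10 s -> noise baseline
REST_TAIL = 10.0
POWER_CYCLE_LINE_PX = 640.0


@dataclass(frozen=True)
class InterfaceConfig:
    """Constants of the myoelectric interface."""

    alpha: float = ALPHA_DEFAULT
    w_hand: int = 1
    w_shin: int = -1
    fs: int = FS_DEFAULT
    kernel: str = "triangular-256"
    screen_width_px: float = SCREEN_WIDTH_PX

    def __post_init__(self):
        if abs(self.w_hand) != 1 or self.w_hand != -self.w_shin:
            raise ValueError("channel weights must be +/-1 and opposite")
        if self.alpha <= 0 or self.fs <= 0:
            raise ValueError("alpha and fs must be positive")

    @classmethod
    def for_group(cls, congruence: str, **kw) -> "InterfaceConfig":
        if congruence == "congruent":
            return cls(w_hand=1, w_shin=-1, **kw)
        if congruence == "incongruent":
            return cls(w_hand=-1, w_shin=1, **kw)
        raise ValueError(f"unknown congruence {congruence!r}")


def kernel_weights(kernel: str = "triangular-256") -> np.ndarray:
    """Normalised causal kernel weights, index 0 = most recent sample.

    Triangular weights decrease linearly with lag: w_i proportional to
    (K - i) for i = 0..K-1, so the most recent sample of the 256-tap kernel
    has weight 2/257.  Uniform weights are 1/K.
    """
    if kernel == "triangular-256":
        k = TRIANGULAR_LEN
        w = (k - np.arange(k)).astype(float)
    elif kernel == "uniform-4096":
        w = np.ones(UNIFORM_LEN)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return w / w.sum()


def smooth(raw: np.ndarray, kernel: str = "triangular-256") -> np.ndarray:
    """Causal rectify-and-weighted-average of a raw EMG sequence.

    The signal is implicitly zero-padded before t = 0, so the first K-1
    output samples form a warm-up ramp.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("raw must be a non-empty 1-D sequence")
    w = kernel_weights(kernel)
    # fftconvolve(|x|, w)[t] = sum_i w[i] |x[t-i]|, truncated to input length
    out = signal.fftconvolve(np.abs(raw), w)[: raw.size]
    return np.maximum(out, 0.0)  # guard tiny FFT negatives


def _tail_mean(smoothed: np.ndarray, tail_s: float, fs: int) -> float:
    smoothed = np.asarray(smoothed, dtype=float)
    n_tail = int(round(tail_s * fs))
    if smoothed.size < n_tail:
        raise ValueError(
            f"need at least {tail_s} s ({n_tail} samples) of data, "
            f"got {smoothed.size} samples"
        )
    return float(smoothed[-n_tail:].mean())


def compute_max_power(smoothed: np.ndarray, fs: int = FS_DEFAULT) -> float:
    """Maximum power level: mean smoothed power over the final 4 s of the
    10 s maximum-contraction task."""
    return _tail_mean(smoothed, MAX_TAIL, fs)


def compute_noise_baseline(smoothed: np.ndarray, fs: int = FS_DEFAULT) -> float:
    """Noise baseline: mean smoothed power over the final 10 s of the 15 s
    relaxation task."""
    return _tail_mean(smoothed, REST_TAIL, fs)


def fit_threshold(
    baseline_samples: np.ndarray, max_power: float, mode: str = "main-task"
) -> float:
    """Per-channel noise threshold.

    main-task: a log-normal distribution is fitted to the baseline smoothed
    power (method of moments on the log samples) and the threshold is its
    99.99th percentile plus 1 % of the maximum power.  power-cycle: the 1 %
    of maximum power term only (avoids a dead zone under position control).
    """
    if max_power <= 0:
        raise ValueError("max_power must be positive")
    floor_term = THRESHOLD_FRACTION * max_power
    if mode == "power-cycle":
        return floor_term
    if mode != "main-task":
        raise ValueError(f"unknown threshold mode {mode!r}")
    x = np.asarray(baseline_samples, dtype=float)
    if x.size < 2 or np.any(x <= 0):
        raise ValueError(
            "main-task threshold needs >= 2 strictly positive baseline samples"
        )
    logs = np.log(x)
    mu, sd = logs.mean(), logs.std(ddof=1)
    z = stats.norm.ppf(NOISE_QUANTILE)
    return float(np.exp(mu + z * sd) + floor_term)


@dataclass(frozen=True)
class CalibrationResult:
    max_power: float
    noise_baseline: float
    threshold: float
    mode: str = "main-task"

    def __post_init__(self):
        if self.max_power <= 0:
            raise ValueError("max_power must be positive")
        if self.threshold < THRESHOLD_FRACTION * self.max_power - 1e-12:
            raise ValueError("threshold below 1% of max power")


def calibrate(
    max_trace_raw: np.ndarray,
    rest_trace_raw: np.ndarray,
    fs: int = FS_DEFAULT,
    kernel: str = "triangular-256",
    mode: str = "main-task",
) -> CalibrationResult:
    """Run the full calibration chain on raw contraction/rest recordings."""
    smoothed_max = smooth(max_trace_raw, kernel)
    smoothed_rest = smooth(rest_trace_raw, kernel)
    max_power = compute_max_power(smoothed_max, fs)
    baseline = compute_noise_baseline(smoothed_rest, fs)
    tail = smoothed_rest[-int(round(REST_TAIL * fs)):]
    if mode == "main-task":
        threshold = fit_threshold(tail, max_power, mode)
    else:
        threshold = fit_threshold(np.empty(0), max_power, mode)
    return CalibrationResult(max_power, baseline, threshold, mode)


@dataclass(frozen=True)
class ChannelProfile:
    """Non-negative control signal of one channel at the EMG sampling rate."""

    values: np.ndarray
    channel: str  # "hand" or "shin"
    fs: int = FS_DEFAULT


def control_signal(
    smoothed: np.ndarray,
    calib: CalibrationResult,
    channel: str = "hand",
    fs: int = FS_DEFAULT,
) -> ChannelProfile:
    """Threshold-subtract, clamp at zero and scale the smoothed power.

    35 % of the calibrated maximum power produces an output of 1; values
    above 1 are not capped.
    """
    if calib.max_power <= 0:
        raise ValueError("max_power must be positive")
    vals = np.asarray(smoothed, dtype=float) - calib.threshold
    np.maximum(vals, 0.0, out=vals)
    vals /= SCALE_FRACTION * calib.max_power
    return ChannelProfile(values=vals, channel=channel, fs=fs)


@dataclass(frozen=True)
class CursorTrajectory:
    """Signed horizontal cursor displacement from screen centre."""

    positions: np.ndarray  # px, positions[0] = 0
    velocity: np.ndarray   # px/s
    fs: int = FS_DEFAULT

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.positions.size) / self.fs


def cursor_from_profiles(
    h: ChannelProfile, s: ChannelProfile, config: InterfaceConfig
) -> CursorTrajectory:
    """Weighted sum of channel profiles, scaled by alpha and integrated.

    velocity(t) = alpha * (w_hand * h(t) + w_shin * s(t)); positions are the
    running left-Riemann integral at step 1/fs starting from zero, matching
    a per-sample real-time update loop.
    """
    if h.values.size != s.values.size:
        raise ValueError("channel profiles must have equal length")
    velocity = config.alpha * (config.w_hand * h.values + config.w_shin * s.values)
    positions = np.empty_like(velocity)
    positions[0] = 0.0
    np.cumsum(velocity[:-1] / config.fs, out=positions[1:])
    return CursorTrajectory(positions=positions, velocity=velocity, fs=config.fs)


def traverse_time(
    config: InterfaceConfig | None = None, control_value: float = 1.0
) -> float:
    """Time for a constant control signal to traverse the full screen width.

    Computed by integrating the velocity and interpolating the crossing of
    the screen-width displacement (0.432 s at the defaults).
    """
    config = config or InterfaceConfig()
    n = int(np.ceil(2.0 * config.fs))
    prof = ChannelProfile(np.full(n, control_value), "hand", config.fs)
    zero = ChannelProfile(np.zeros(n), "shin", config.fs)
    traj = cursor_from_profiles(prof, zero, config)
    x = np.abs(traj.positions)
    if x[-1] < config.screen_width_px:
        raise ValueError("trajectory never reaches the screen width")
    return float(np.interp(config.screen_width_px, x, traj.times))


def power_cycle_position(
    profile: ChannelProfile, line_height_px: float = POWER_CYCLE_LINE_PX
) -> np.ndarray:
    """Vertical circle position in the power-cycle task.

    The scaled power, clamped to [0, 1], maps linearly onto a line of
    640 px height measured from its bottom.
    """
    return np.clip(profile.values, 0.0, 1.0) * line_height_px
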