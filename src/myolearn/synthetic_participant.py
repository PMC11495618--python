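"""Virtual participants and raw-EMG trial synthesis.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any recorded data:

* raw EMG is amplitude-modulated Gaussian noise, so stronger contractions
  produce more variable raw signals (signal-dependent noise) and the
  rectified-and-smoothed signal tracks a fixed multiple of the envelope;
* each participant has idiosyncratic per-channel burst shapes (width,
  asymmetry, gain) that are re-used across leftward and rightward paths;
* each trial activates the two channels in the order dictated by the path
  direction and the participant's congruence condition, with the two peak
  times drawn from a correlated bivariate normal;
* per-condition peak amplitudes are drawn around a fixed repertoire entry
  (the repertoire never changes across sessions — no new outputs appear
  with practice), with session-wise geometric decay of timing bias and of
  timing/amplitude spread emulating learning.

All cohort hyperparameters are stand-ins chosen for plausibility; they are
not estimates of any real population and are recorded verbatim in outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from myolearn import task_design
from myolearn.emg_interface import (
    FS_DEFAULT,
    SCALE_FRACTION,
    CalibrationResult,
    calibrate,
    kernel_weights,
)
from myolearn.task_design import TrialCondition, TrialTiming

HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)  # E|N(0,1)|

CHANNELS = ("hand", "shin")
CONGRUENCES = ("congruent", "incongruent")


@dataclass(frozen=True)
class CohortConfig:
    """Hyperparameters of the synthetic cohort.

    Defaults are the reference task conditions: two groups of 10 participants,
    five sessions, and the full session schedule (3 rounds of two train-test
    pairs; 30 trials per trained condition, 5 per test condition).  Burst
    timing centres on the canonical path: the ideal first-channel velocity
    lobe peaks at 1.105 s and the displacement peak crosses at 1.21 s.
    """

    n_per_group: int = 10
    n_sessions: int = 5
    fs: int = FS_DEFAULT
    timing: TrialTiming = field(default_factory=TrialTiming)
    rounds: int = task_design.ROUNDS_PER_SESSION
    train_reps: int = task_design.TRAIN_TRIALS_PER_CONDITION
    test_reps: int = task_design.TEST_TRIALS_PER_CONDITION

    # per-channel burst idiosyncrasies (log-normal / truncated-normal hyperpriors)
    gain_log_sd: float = 0.12          # amplitude gain around the ideal
    width_mean_s: float = 0.25         # total burst duration
    width_log_sd: float = 0.12
    asym_mean: float = 0.45            # rise fraction of the burst
    asym_sd: float = 0.06

    # timing structure (seconds)
    first_peak_mean_s: float = 1.105   # ideal first-channel peak time
    first_peak_mean_sd: float = 0.02
    ipi_mean_s: float = 0.25           # ideal inter-peak interval
    ipi_mean_sd: float = 0.02
    rho_mean: float = 0.6              # peak-time correlation
    rho_sd: float = 0.12

    # session-1 spread and learning (geometric decay per session)
    timing_sd0_s: float = 0.06
    timing_sd_decay: float = 0.85
    timing_bias0_s: float = 0.10       # late-onset bias in session 1
    timing_bias_decay: float = 0.7
    amp_jitter0: float = 0.15          # log-SD of amplitude around repertoire
    amp_jitter_decay: float = 0.85
    incongruent_sd_scale: float = 1.4  # larger initial spread, slower learning

    # noise model
    k_mean: float = 1.0                # raw SD per unit envelope
    k_log_sd: float = 0.1
    floor_frac: float = 0.02           # baseline raw SD as fraction of max envelope
    max_envelope: float = 1.0          # envelope at maximal contraction (power units)
    carrier: str = "gaussian"          # or "deterministic" (noise-free rendering)

    alpha: float = 2500.0              # interface velocity scale used for tuning

    def __post_init__(self):
        for name in (
            "gain_log_sd", "width_mean_s", "width_log_sd", "asym_sd",
            "timing_sd0_s", "amp_jitter0", "k_mean", "max_envelope",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")
        if not 0 < self.rho_mean < 1:
            raise ValueError("rho_mean must lie in (0, 1)")


@dataclass(frozen=True)
class ChannelShape:
    """Idiosyncratic burst shape of one channel (re-used across directions).

    ``family`` selects the bump form: "squared-sine" (default, the
    realistic asymmetric burst) or "sine" (piecewise quarter-sine lobes —
    the exact shape of the canonical path's velocity, used by the ideal
    noise-free participant).
    """

    gain: float
    width_s: float
    asym: float  # rise fraction in (0, 1)
    family: str = "squared-sine"

    @property
    def rise_s(self) -> float:
        return self.asym * self.width_s

    @property
    def fall_s(self) -> float:
        return (1.0 - self.asym) * self.width_s


@dataclass(frozen=True)
class ParticipantModel:
    id: str
    congruence: str
    shapes: dict[str, ChannelShape]            # channel -> shape
    repertoire: dict[tuple[str, int], float]   # (channel, magnitude) -> amplitude
    first_peak_mean_s: float
    ipi_mean_s: float
    rho: float
    timing_sd0_s: float
    timing_bias0_s: float
    amp_jitter0: float
    timing_sd_decay: float
    timing_bias_decay: float
    amp_jitter_decay: float
    k: float                                   # raw SD per unit envelope
    floor: float                               # baseline raw SD (power units)
    max_envelope: float
    carrier: str = "gaussian"
    #: cancel the kernel's post-burst flush tail by lifting the opposing
    #: channel (leaves the velocity sum exact; used by the ideal
    #: positive-control participant — real profiles keep the tail)
    compensate_flush: bool = False

    def timing_sd(self, session: int) -> float:
        return self.timing_sd0_s * self.timing_sd_decay ** (session - 1)

    def timing_bias(self, session: int) -> float:
        return self.timing_bias0_s * self.timing_bias_decay ** (session - 1)

    def amp_jitter(self, session: int) -> float:
        return self.amp_jitter0 * self.amp_jitter_decay ** (session - 1)

    def first_channel(self, direction: str) -> str:
        """Channel whose activation initiates movement in ``direction``.

        The hand drives rightward velocity in the congruent mapping, so a
        rightward path starts with the hand for congruent participants and
        with the shin for incongruent ones.
        """
        hand_first = (direction == "R") == (self.congruence == "congruent")
        return "hand" if hand_first else "shin"


def sample_participant(
    seed: int, congruence: str, config: CohortConfig | None = None,
    pid: str | None = None,
) -> ParticipantModel:
    """Draw one participant's idiosyncratic parameters from the hyperpriors.

    Deterministic under a fixed ``(seed, congruence, config)``.
    """
    config = config or CohortConfig()
    if congruence not in CONGRUENCES:
        raise ValueError(f"congruence must be one of {CONGRUENCES}")
    rng = np.random.default_rng([int(seed), CONGRUENCES.index(congruence)])
    sd_scale = (
        config.incongruent_sd_scale if congruence == "incongruent" else 1.0
    )
    shapes: dict[str, ChannelShape] = {}
    repertoire: dict[tuple[str, int], float] = {}
    for ch in CHANNELS:
        shape = ChannelShape(
            gain=float(np.exp(rng.normal(0.0, config.gain_log_sd))),
            width_s=float(
                config.width_mean_s * np.exp(rng.normal(0.0, config.width_log_sd))
            ),
            asym=float(np.clip(rng.normal(config.asym_mean, config.asym_sd),
                               0.2, 0.8)),
        )
        shapes[ch] = shape
        for m in task_design.MAGNITUDES:
            # amplitude whose squared-sine burst area integrates to the
            # path's displacement amplitude: alpha * a * width / 2 = 90 m
            ideal = (
                2.0 * task_design.PX_PER_MAGNITUDE * m
                / (config.alpha * shape.width_s)
            )
            repertoire[(ch, m)] = float(ideal * shape.gain)
    rho = float(np.clip(rng.normal(config.rho_mean, config.rho_sd), 0.05, 0.95))
    return ParticipantModel(
        id=pid or f"{congruence[0].upper()}{seed}",
        congruence=congruence,
        shapes=shapes,
        repertoire=repertoire,
        first_peak_mean_s=float(
            rng.normal(config.first_peak_mean_s, config.first_peak_mean_sd)
        ),
        ipi_mean_s=float(rng.normal(config.ipi_mean_s, config.ipi_mean_sd)),
        rho=rho,
        timing_sd0_s=config.timing_sd0_s * sd_scale,
        timing_bias0_s=config.timing_bias0_s * sd_scale,
        amp_jitter0=config.amp_jitter0 * sd_scale,
        timing_sd_decay=config.timing_sd_decay,
        timing_bias_decay=config.timing_bias_decay,
        amp_jitter_decay=config.amp_jitter_decay,
        k=float(config.k_mean * np.exp(rng.normal(0.0, config.k_log_sd))),
        floor=float(config.floor_frac * config.max_envelope),
        max_envelope=config.max_envelope,
        carrier=config.carrier,
    )


def synthesize_raw_emg(
    envelope: np.ndarray,
    k: float,
    floor: float,
    seed: int | np.random.Generator,
    carrier: str = "gaussian",
) -> np.ndarray:
    """Render a non-negative envelope to a signed raw EMG sequence.

    With the Gaussian carrier, ``raw(t) = (envelope(t) * k + floor) * xi(t)``
    for independent standard-normal ``xi``, so the rectified-and-smoothed
    output tracks ``sqrt(2/pi) * (envelope * k + floor)`` in expectation.
    The deterministic carrier replaces ``xi`` with an alternating-sign
    sequence of that same expected magnitude, giving an exactly noise-free
    rendering with the identical smoothed output in expectation.
    """
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise ValueError("envelope must be non-negative")
    sd = envelope * k + floor
    if carrier == "gaussian":
        rng = (
            seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        return sd * rng.standard_normal(envelope.size)
    if carrier == "deterministic":
        signs = np.where(np.arange(envelope.size) % 2 == 0, 1.0, -1.0)
        return sd * HALF_NORMAL_MEAN * signs
    raise ValueError(f"unknown carrier {carrier!r}")


@dataclass(frozen=True)
class TrialLatents:
    """Generating-process truth stored alongside each synthetic trial."""

    first_channel: str
    peak_time_hand_s: float
    peak_time_shin_s: float
    amp_hand: float
    amp_shin: float


@dataclass(frozen=True)
class RawTrial:
    hand_raw: np.ndarray
    shin_raw: np.ndarray
    fs: int
    condition: TrialCondition
    session: int
    participant: str
    congruence: str
    seed: int
    latents: TrialLatents


def burst_envelope(
    times: np.ndarray, peak_time: float, amplitude: float,
    rise_s: float, fall_s: float, family: str = "squared-sine",
) -> np.ndarray:
    """Asymmetric compactly-supported bump peaking at ``peak_time``.

    "squared-sine": sin^2 rise and fall segments.  "sine": quarter-sine
    rise and fall segments (for equal rise/fall this is a single sine lobe,
    the exact shape of the canonical path's velocity profile).
    """
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    up = (t >= peak_time - rise_s) & (t <= peak_time)
    down = (t > peak_time) & (t <= peak_time + fall_s)
    up_phase = np.pi * (t[up] - (peak_time - rise_s)) / (2 * rise_s)
    down_phase = np.pi * ((peak_time + fall_s) - t[down]) / (2 * fall_s)
    if family == "squared-sine":
        out[up] = np.sin(up_phase) ** 2
        out[down] = np.sin(down_phase) ** 2
    elif family == "sine":
        out[up] = np.sin(up_phase)
        out[down] = np.sin(down_phase)
    else:
        raise ValueError(f"unknown burst family {family!r}")
    return amplitude * out


def calibrate_participant(
    participant: ParticipantModel,
    seed: int,
    config: CohortConfig | None = None,
) -> dict[str, CalibrationResult]:
    """Simulate the session-1 calibration tasks through the real chain.

    Maximum-contraction (10 s at the participant's maximal envelope) and
    relaxation (15 s at the noise floor) recordings are synthesised and run
    through the actual smoothing/threshold-fitting operations.  Only the
    session-1 calibration sets the interface gain.
    """
    config = config or CohortConfig()
    fs = config.fs
    out: dict[str, CalibrationResult] = {}
    for i, ch in enumerate(CHANNELS):
        rng = np.random.default_rng([int(seed), 1000 + i])
        max_env = np.full(int(10.0 * fs), participant.max_envelope)
        rest_env = np.zeros(int(15.0 * fs))
        max_raw = synthesize_raw_emg(
            max_env, participant.k, participant.floor, rng, participant.carrier
        )
        rest_raw = synthesize_raw_emg(
            rest_env, participant.k, participant.floor, rng, participant.carrier
        )
        out[ch] = calibrate(max_raw, rest_raw, fs=fs, kernel="triangular-256")
    return out


def draw_trial_plan(
    participant: ParticipantModel,
    condition: TrialCondition,
    session: int,
    rng: np.random.Generator,
) -> TrialLatents:
    """Draw the latent peak times and amplitudes of one trial.

    The first-activating channel is set by (direction, congruence); the two
    peak times are a correlated bivariate-normal draw whose means carry the
    session-decayed late-onset bias; amplitudes are log-normal around the
    condition's fixed repertoire entry with session-decayed jitter.
    """
    first = participant.first_channel(condition.path.direction)
    second = "shin" if first == "hand" else "hand"
    sd = participant.timing_sd(session)
    bias = participant.timing_bias(session)
    mean = np.array([
        participant.first_peak_mean_s + bias,
        participant.first_peak_mean_s + bias + participant.ipi_mean_s,
    ])
    cov = sd**2 * np.array([[1.0, participant.rho], [participant.rho, 1.0]])
    p_first, p_second = rng.multivariate_normal(mean, cov)
    jit = participant.amp_jitter(session)
    m = condition.path.magnitude
    amps = {
        first: participant.repertoire[(first, m)] * np.exp(rng.normal(0, jit)),
        second: participant.repertoire[(second, m)] * np.exp(rng.normal(0, jit)),
    }
    peaks = {first: float(p_first), second: float(p_second)}
    return TrialLatents(
        first_channel=first,
        peak_time_hand_s=peaks["hand"],
        peak_time_shin_s=peaks["shin"],
        amp_hand=float(amps["hand"]),
        amp_shin=float(amps["shin"]),
    )


def _sd_for_control(
    ctrl: np.ndarray,
    calib: CalibrationResult,
    participant: "ParticipantModel",
    fs: int,
    weights: np.ndarray,
) -> np.ndarray:
    """Raw-SD profile whose smoothed rectified rendering reproduces the
    control target through the calibrated chain.

    The smoothed-power target equals threshold + scaled control inside the
    burst and tapers smoothly to the rest level outside (so the
    thresholded profile has no edge artefacts), then the kernel is
    deconvolved out.
    """
    rest = HALF_NORMAL_MEAN * participant.floor
    support = ctrl > 0
    dist_s = ndimage.distance_transform_edt(~support) / fs
    ramp_s = 0.06
    taper = np.where(
        dist_s < ramp_s, np.cos(np.pi * dist_s / (2 * ramp_s)) ** 2, 0.0
    )
    power_target = (
        rest
        + (calib.threshold - rest) * taper
        + SCALE_FRACTION * calib.max_power * ctrl
    )
    return _deconvolve_target(power_target / HALF_NORMAL_MEAN, weights)


def _achieved_control(
    sd: np.ndarray, calib: CalibrationResult, weights: np.ndarray,
    floor: float = 0.0,
) -> np.ndarray:
    """Expected control-signal output of a raw-SD profile after the chain.

    The rendering clamps the raw SD at the participant's noise floor, so
    the same clamp is applied here.
    """
    sd_eff = np.maximum(sd, floor)
    power = HALF_NORMAL_MEAN * np.convolve(sd_eff, weights)[: sd.size]
    return np.maximum(power - calib.threshold, 0.0) / (
        SCALE_FRACTION * calib.max_power
    )


def _deconvolve_target(target: np.ndarray, weights: np.ndarray,
                       reg: float = 1e-4) -> np.ndarray:
    """Pre-distort a smooth target so the causal kernel reproduces it.

    Regularised (Wiener-style) FFT deconvolution compensating the lag and
    attenuation of the smoothing kernel; the result is clamped
    non-negative.  The burst targets are smooth and low-frequency relative
    to the kernel, so the compensation is near-exact.
    """
    n = target.size
    nfft = int(2 ** np.ceil(np.log2(n + weights.size)))
    H = np.fft.rfft(weights, nfft)
    T = np.fft.rfft(target, nfft)
    X = T * np.conj(H) / (np.abs(H) ** 2 + reg)
    x = np.fft.irfft(X, nfft)[:n]
    return np.maximum(x, 0.0)


def render_trial(
    participant: ParticipantModel,
    condition: TrialCondition,
    session: int,
    seed: int,
    calibrations: dict[str, CalibrationResult],
    config: CohortConfig | None = None,
    latents: TrialLatents | None = None,
) -> RawTrial:
    """Render one trial's latent plan to raw two-channel EMG.

    The target control profile of each channel is converted to a smoothed-
    power target using that channel's calibration (inverting the threshold
    subtraction and 35 %-of-max scaling), pre-distorted to undo the
    smoothing kernel, and synthesised as amplitude-modulated noise.
    """
    config = config or CohortConfig()
    if not 1 <= session <= config.n_sessions:
        raise ValueError(f"session must be in 1..{config.n_sessions}")
    # separate streams so the carrier noise is identical whether the latent
    # plan is drawn here or supplied from a manifest
    rng = np.random.default_rng([int(seed), 7])
    if latents is None:
        plan_rng = np.random.default_rng([int(seed), 3])
        latents = draw_trial_plan(participant, condition, session, plan_rng)
    fs = config.fs
    n = int(round(config.timing.record_duration * fs))
    times = np.arange(n) / fs
    weights = kernel_weights("triangular-256")

    peak_times = {"hand": latents.peak_time_hand_s,
                  "shin": latents.peak_time_shin_s}
    amps = {"hand": latents.amp_hand, "shin": latents.amp_shin}
    targets = {}
    for ch in CHANNELS:
        shape = participant.shapes[ch]
        targets[ch] = burst_envelope(times, peak_times[ch], amps[ch],
                                     shape.rise_s, shape.fall_s, shape.family)
    sds = {
        ch: _sd_for_control(targets[ch], calibrations[ch], participant, fs,
                            weights)
        for ch in CHANNELS
    }
    if participant.compensate_flush:
        # velocity-preserving correction: the kernel's flush tail after a
        # burst cannot be removed from one channel (raw power is
        # non-negative), but lifting the *opposing* channel by the excess
        # cancels it in the weighted velocity sum
        w = {"hand": 1.0, "shin": -1.0}
        if participant.congruence == "incongruent":
            w = {"hand": -1.0, "shin": 1.0}
        lifted = {ch: targets[ch].copy() for ch in CHANNELS}
        for _ in range(40):
            achieved = {
                ch: _achieved_control(sds[ch], calibrations[ch], weights,
                                      participant.floor)
                for ch in CHANNELS
            }
            v_err = sum(
                w[ch] * (achieved[ch] - targets[ch]) for ch in CHANNELS
            )
            for ch in CHANNELS:
                # move against the velocity error, never below the original
                # burst target (control signals are non-negative)
                lifted[ch] = np.maximum(
                    targets[ch], lifted[ch] - 0.5 * w[ch] * v_err
                )
                sds[ch] = _sd_for_control(
                    lifted[ch], calibrations[ch], participant, fs, weights
                )
    raws: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        envelope = (
            np.maximum(sds[ch] - participant.floor, 0.0) / participant.k
        )
        raws[ch] = synthesize_raw_emg(
            envelope, participant.k, participant.floor, rng, participant.carrier
        )
    return RawTrial(
        hand_raw=raws["hand"],
        shin_raw=raws["shin"],
        fs=fs,
        condition=condition,
        session=session,
        participant=participant.id,
        congruence=participant.congruence,
        seed=int(seed),
        latents=latents,
    )


def simulate_trial(
    participant: ParticipantModel,
    condition: TrialCondition,
    session: int,
    seed: int,
    calibrations: dict[str, CalibrationResult] | None = None,
    config: CohortConfig | None = None,
) -> RawTrial:
    """Draw a latent plan and render it to raw EMG (see ``render_trial``)."""
    if calibrations is None:
        calibrations = calibrate_participant(participant, seed, config)
    return render_trial(participant, condition, session, seed,
                        calibrations, config)


def ideal_participant(
    congruence: str = "congruent", config: CohortConfig | None = None,
) -> ParticipantModel:
    """A noise- and jitter-free participant tuned to the canonical path.

    Used as a closed-loop positive control: its rendered trials should
    reproduce the target path almost exactly after the full analysis chain.
    """
    config = config or CohortConfig(carrier="deterministic")
    shape = task_design.PathShapeParams()
    # one channel renders the rising velocity lobe of the canonical path,
    # the other the falling lobe
    shapes: dict[str, ChannelShape] = {}
    repertoire: dict[tuple[str, int], float] = {}
    hand_first = congruence == "congruent"  # rightward path
    role_width = {
        "hand": shape.rise if hand_first else shape.fall,
        "shin": shape.fall if hand_first else shape.rise,
    }
    for ch in CHANNELS:
        w = role_width[ch]
        shapes[ch] = ChannelShape(gain=1.0, width_s=w, asym=0.5, family="sine")
        for m in task_design.MAGNITUDES:
            # peak of the velocity lobe of a squared-sine displacement ramp
            repertoire[(ch, m)] = (
                np.pi * task_design.PX_PER_MAGNITUDE * m
                / (2.0 * w * config.alpha)
            )
    zone = TrialTiming().zone_arrival
    first_peak = zone + shape.rise / 2.0
    second_peak = zone + shape.rise + shape.fall / 2.0
    return ParticipantModel(
        id=f"ideal-{congruence}",
        congruence=congruence,
        shapes=shapes,
        repertoire=repertoire,
        first_peak_mean_s=first_peak,
        ipi_mean_s=second_peak - first_peak,
        rho=0.5,
        timing_sd0_s=1e-12,
        timing_bias0_s=0.0,
        amp_jitter0=1e-12,
        timing_sd_decay=1.0,
        timing_bias_decay=1.0,
        amp_jitter_decay=1.0,
        k=config.k_mean,
        floor=config.floor_frac * config.max_envelope,
        max_envelope=config.max_envelope,
        carrier="deterministic",
        compensate_flush=True,
    )


@dataclass
class Cohort:
    """A reproducible synthetic dataset: participants, session-1
    calibrations, and a manifest with one row per trial (including the
    generating latents, for parameter-recovery checks).

    Raw trials are re-rendered on demand from the recorded seeds rather
    than held in memory.
    """

    config: CohortConfig
    master_seed: int
    participants: dict[str, ParticipantModel]
    calibrations: dict[str, dict[str, CalibrationResult]]
    manifest: pd.DataFrame

    def render(self, row: pd.Series) -> RawTrial:
        """Re-render the raw trial described by one manifest row."""
        p = self.participants[row["participant"]]
        cond = TrialCondition(
            path=task_design.build_path(row["direction"], int(row["magnitude"])),
            preview_time=float(row["preview_time"]),
            feedback=bool(row["feedback"]),
        )
        latents = TrialLatents(
            first_channel=row["first_channel"],
            peak_time_hand_s=row["true_peak_time_hand"],
            peak_time_shin_s=row["true_peak_time_shin"],
            amp_hand=row["true_amp_hand"],
            amp_shin=row["true_amp_shin"],
        )
        return render_trial(
            p, cond, int(row["session"]), int(row["trial_seed"]),
            self.calibrations[p.id], self.config, latents=latents,
        )

    def trials(self):
        for _, row in self.manifest.iterrows():
            yield self.render(row)


def _trial_seed(master_seed: int, p_index: int, session: int,
                block_index: int, trial_index: int) -> int:
    rng = np.random.default_rng(
        [int(master_seed), p_index, session, block_index, trial_index]
    )
    return int(rng.integers(2**31))


def simulate_cohort(
    config: CohortConfig | None = None, master_seed: int = 0
) -> Cohort:
    """Generate the full cohort manifest with per-trial latents.

    Identical ``(config, master_seed)`` give identical cohorts.  The
    default configuration produces 10 congruent + 10 incongruent
    participants over 5 sessions with the full session schedule.
    """
    config = config or CohortConfig()
    participants: dict[str, ParticipantModel] = {}
    calibrations: dict[str, dict[str, CalibrationResult]] = {}
    rows = []
    p_index = 0
    for congruence in CONGRUENCES:
        for j in range(config.n_per_group):
            pid = f"{congruence[0].upper()}{j + 1}"
            p_seed = _trial_seed(master_seed, p_index, 0, 0, 0)
            p = sample_participant(p_seed, congruence, config, pid=pid)
            participants[pid] = p
            calibrations[pid] = calibrate_participant(p, p_seed, config)
            for session in range(1, config.n_sessions + 1):
                schedule = task_design.generate_session_schedule(
                    session, _trial_seed(master_seed, p_index, session, 999, 0),
                    rounds=config.rounds,
                    train_reps=config.train_reps,
                    test_reps=config.test_reps,
                )
                for block in schedule.blocks:
                    for ti, cond in enumerate(block.trials):
                        seed = _trial_seed(
                            master_seed, p_index, session, block.index, ti
                        )
                        plan_rng = np.random.default_rng([seed, 3])
                        latents = draw_trial_plan(p, cond, session, plan_rng)
                        rows.append({
                            "participant": pid,
                            "congruence": congruence,
                            "session": session,
                            "round": block.round_index,
                            "block_type": block.block_type,
                            "block_index": block.index,
                            "trial_index": ti,
                            "direction": cond.path.direction,
                            "magnitude": cond.path.magnitude,
                            "preview_time": cond.preview_time,
                            "feedback": cond.feedback,
                            "trial_seed": seed,
                            "first_channel": latents.first_channel,
                            "true_peak_time_hand": latents.peak_time_hand_s,
                            "true_peak_time_shin": latents.peak_time_shin_s,
                            "true_amp_hand": latents.amp_hand,
                            "true_amp_shin": latents.amp_shin,
                        })
            p_index += 1
    return Cohort(
        config=config,
        master_seed=int(master_seed),
        participants=participants,
        calibrations=calibrations,
        manifest=pd.DataFrame(rows),
    )
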