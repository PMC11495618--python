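"""Per-trial features of channel profiles and cursor trajectories.

The analysis separates trajectory *shape* from trajectory *timing* by peak
alignment: the cursor trajectory's amplitude peak (its maximal displacement
between the two channel-profile peak times) is shifted to a fixed reference
time of 1.21 s, and shape measures (RMS error against the target path, and
the percentage of the 25 targets hit) are computed on the aligned,
1000 Hz-resampled trajectory.  The pre-alignment peak time is kept as the
timing measure.

A channel peak must occur between 0.7 s and 1.8 s after trial start and
inside a run of more than 16 consecutive strictly-positive control-signal
samples; trials without a qualifying peak in both channels, or whose
channel-activation order contradicts the path direction under the
participant's mapping, are excluded from the model fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from myolearn.emg_interface import ChannelProfile, CursorTrajectory
from myolearn.task_design import TargetPath, TargetPoint, TrialTiming

PEAK_WINDOW_S = (0.7, 1.8)
MIN_RUN_SAMPLES = 16          # a qualifying run must be strictly longer
ALIGNED_FS = 1000
ALIGNED_PEAK_TIME_S = 1.21
MAX_REQUIRED_AMPLITUDE_PX = 270.0


@dataclass(frozen=True)
class ChannelPeakFeatures:
    peak_amplitude: float
    peak_time: float        # seconds, trial clock
    initiation_time: float  # start of the qualifying positive run
    valid: bool

    @classmethod
    def invalid(cls) -> "ChannelPeakFeatures":
        return cls(np.nan, np.nan, np.nan, False)


def _positive_runs(values: np.ndarray):
    """(start, stop) index pairs of maximal runs of strictly positive samples."""
    pos = np.asarray(values) > 0
    if not pos.any():
        return []
    padded = np.concatenate(([False], pos, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_stops = np.flatnonzero(d == -1)
    return list(zip(run_starts, run_stops))


def find_channel_peak(
    profile: ChannelProfile,
    window_s: tuple[float, float] = PEAK_WINDOW_S,
    min_run: int = MIN_RUN_SAMPLES,
) -> ChannelPeakFeatures:
    """Locate the channel-profile peak under the run-length rule.

    The peak is the maximum control-signal value lying inside the trial-time
    window and inside a run of more than ``min_run`` consecutive
    strictly-positive samples; ties go to the earliest sample.  Returns the
    invalid sentinel when no sample qualifies.
    """
    values = np.asarray(profile.values, dtype=float)
    fs = profile.fs
    lo = int(np.ceil(window_s[0] * fs))
    hi = int(np.floor(window_s[1] * fs))
    best: tuple[float, int, int] | None = None  # (value, index, run_start)
    for start, stop in _positive_runs(values):
        if stop - start <= min_run:
            continue
        a, b = max(start, lo), min(stop, hi + 1)
        if a >= b:
            continue
        idx = a + int(np.argmax(values[a:b]))
        val = values[idx]
        if best is None or val > best[0]:
            best = (float(val), idx, start)
    if best is None:
        return ChannelPeakFeatures.invalid()
    val, idx, run_start = best
    return ChannelPeakFeatures(
        peak_amplitude=val,
        peak_time=idx / fs,
        initiation_time=run_start / fs,
        valid=True,
    )


def classify_order(
    hand: ChannelPeakFeatures,
    shin: ChannelPeakFeatures,
    direction: str,
    congruence: str,
) -> bool:
    """Did the channels peak in the order the path direction requires?

    The channel mapped to the path's initial movement direction must peak
    first: hand first for congruent-rightward and incongruent-leftward,
    shin first otherwise.
    """
    if not (hand.valid and shin.valid):
        raise ValueError("both channel peaks must be valid to classify order")
    hand_should_lead = (direction == "R") == (congruence == "congruent")
    hand_leads = hand.peak_time < shin.peak_time
    return hand_leads == hand_should_lead


def _interpeak_argmax(
    traj: CursorTrajectory,
    hand: ChannelPeakFeatures,
    shin: ChannelPeakFeatures,
) -> int:
    """Sample index of maximal |displacement| between the two channel peaks."""
    if not (hand.valid and shin.valid):
        raise ValueError("both channel peaks must be valid")
    t_lo = min(hand.peak_time, shin.peak_time)
    t_hi = max(hand.peak_time, shin.peak_time)
    lo = int(np.ceil(t_lo * traj.fs))
    hi = min(int(np.floor(t_hi * traj.fs)), traj.positions.size - 1)
    seg = np.abs(traj.positions[lo : hi + 1])
    return lo + int(np.argmax(seg))


def trajectory_peak_time(
    traj: CursorTrajectory,
    hand: ChannelPeakFeatures,
    shin: ChannelPeakFeatures,
) -> float:
    """Pre-alignment time of maximal |displacement| between channel peaks."""
    return _interpeak_argmax(traj, hand, shin) / traj.fs


@dataclass(frozen=True)
class AlignedTrajectory:
    positions: np.ndarray  # px, sampled at 1000 Hz from t = 0
    fs: int = ALIGNED_FS
    peak_time_aligned: float = ALIGNED_PEAK_TIME_S

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.positions.size) / self.fs

    def at(self, t) -> np.ndarray:
        """Linear interpolation with boundary extension."""
        return np.interp(t, self.times, self.positions)


def align_trajectory(
    traj: CursorTrajectory,
    hand: ChannelPeakFeatures,
    shin: ChannelPeakFeatures,
    out_fs: int = ALIGNED_FS,
    peak_ref_s: float = ALIGNED_PEAK_TIME_S,
) -> AlignedTrajectory:
    """Shift the trajectory so its amplitude peak sits at 1.21 s and
    resample from 2048 Hz to 1000 Hz (linear interpolation, boundary values
    extended)."""
    peak_idx = _interpeak_argmax(traj, hand, shin)
    shift = peak_ref_s - peak_idx / traj.fs
    duration = traj.positions.size / traj.fs
    t_out = np.arange(int(round(duration * out_fs))) / out_fs
    positions = np.interp(t_out - shift, traj.times, traj.positions)
    return AlignedTrajectory(positions=positions, fs=out_fs,
                             peak_time_aligned=peak_ref_s)


def rms_error(
    aligned: AlignedTrajectory,
    path: TargetPath,
    timing: TrialTiming | None = None,
) -> float:
    """RMS difference (px) between the peak-aligned trajectory and the
    target path over the crossing window, on the aligned 1000 Hz grid."""
    timing = timing or TrialTiming()
    t0, t1 = timing.zone_arrival, timing.zone_arrival + timing.cross_duration
    if aligned.times[-1] < t1 - 1e-9:
        raise ValueError("aligned trajectory does not cover the crossing window")
    mask = (aligned.times >= t0) & (aligned.times <= t1)
    t = aligned.times[mask]
    target = path.displacement(t - timing.zone_arrival)
    return float(np.sqrt(np.mean((aligned.positions[mask] - target) ** 2)))


def hit_percentage(
    aligned: AlignedTrajectory, targets: list[TargetPoint]
) -> float:
    """Percent of targets whose centre passes within its radius of the
    cursor tip, evaluated at each target's crossing time."""
    hits = 0
    for tp in targets:
        if abs(float(aligned.at(tp.crossing_time)) - tp.x_px) <= tp.radius_px:
            hits += 1
    return 100.0 * hits / len(targets)


def mean_profile(
    profiles: list[ChannelProfile],
    peaks: list[ChannelPeakFeatures],
    peak_ref_s: float = ALIGNED_PEAK_TIME_S,
) -> np.ndarray:
    """Average profile after shifting each so its peak sits at the common
    reference time (linear interpolation, boundary extension)."""
    if not profiles:
        raise ValueError("need at least one profile")
    if len(profiles) != len(peaks):
        raise ValueError("profiles and peaks must match")
    fs = profiles[0].fs
    n = profiles[0].values.size
    t_out = np.arange(n) / fs
    acc = np.zeros(n)
    for prof, pk in zip(profiles, peaks):
        if not pk.valid:
            raise ValueError("all peaks must be valid")
        shift = peak_ref_s - pk.peak_time
        acc += np.interp(t_out - shift, np.arange(prof.values.size) / prof.fs,
                         prof.values)
    return acc / len(profiles)


def qc_exclude(
    mean_amplitude_px: float,
    mean_peak_time_s: float,
    max_required_px: float = MAX_REQUIRED_AMPLITUDE_PX,
    trial_end_s: float = 1.5,
) -> bool:
    """Participant exclusion rule: extremely large mean cursor amplitude
    (more than double the maximum required) or mean trajectory peak time
    after the trial end."""
    return bool(
        mean_amplitude_px > 2.0 * max_required_px
        or mean_peak_time_s > trial_end_s
    )


@dataclass(frozen=True)
class TrialFeatures:
    epsilon: float               # peak-aligned RMS error, px
    hit_pct: float
    traj_peak_time: float        # s, pre-alignment
    traj_peak_amplitude: float   # px, |displacement| at the peak
    order_correct: bool
    inter_peak_interval: float   # s, signed by direction
    hand: ChannelPeakFeatures
    shin: ChannelPeakFeatures
    valid: bool


def extract_trial_features(
    hand_profile: ChannelProfile,
    shin_profile: ChannelProfile,
    traj: CursorTrajectory,
    path: TargetPath,
    congruence: str,
    timing: TrialTiming | None = None,
) -> TrialFeatures:
    """Compute all per-trial features from the channel profiles and the
    cursor trajectory of one trial."""
    from myolearn.task_design import make_target_points

    timing = timing or TrialTiming()
    hand = find_channel_peak(hand_profile)
    shin = find_channel_peak(shin_profile)
    if not (hand.valid and shin.valid):
        return TrialFeatures(
            epsilon=np.nan, hit_pct=np.nan, traj_peak_time=np.nan,
            traj_peak_amplitude=np.nan, order_correct=False,
            inter_peak_interval=np.nan, hand=hand, shin=shin, valid=False,
        )
    order_ok = classify_order(hand, shin, path.direction, congruence)
    aligned = align_trajectory(traj, hand, shin)
    eps = rms_error(aligned, path, timing)
    hits = hit_percentage(aligned, make_target_points(path, timing))
    pk_time = trajectory_peak_time(traj, hand, shin)
    pk_amp = float(np.abs(traj.positions[_interpeak_argmax(traj, hand, shin)]))
    t_first = min(hand.peak_time, shin.peak_time)
    t_second = max(hand.peak_time, shin.peak_time)
    sign = 1.0 if path.direction == "R" else -1.0
    return TrialFeatures(
        epsilon=eps,
        hit_pct=hits,
        traj_peak_time=pk_time,
        traj_peak_amplitude=pk_amp,
        order_correct=order_ok,
        inter_peak_interval=sign * (t_second - t_first),
        hand=hand,
        shin=shin,
        valid=True,
    )


def features_to_row(f: TrialFeatures) -> dict:
    """Flatten TrialFeatures to the tidy per-trial schema."""
    return {
        "epsilon": f.epsilon,
        "hit_pct": f.hit_pct,
        "traj_peak_time": f.traj_peak_time,
        "traj_peak_amplitude": f.traj_peak_amplitude,
        "order_correct": f.order_correct,
        "inter_peak_interval": f.inter_peak_interval,
        "hand_peak_amplitude": f.hand.peak_amplitude,
        "hand_peak_time": f.hand.peak_time,
        "hand_initiation_time": f.hand.initiation_time,
        "shin_peak_amplitude": f.shin.peak_amplitude,
        "shin_peak_time": f.shin.peak_time,
        "shin_initiation_time": f.shin.initiation_time,
        "valid": f.valid,
    }


def participant_qc_table(features: pd.DataFrame) -> pd.DataFrame:
    """Per-participant QC summary and exclusion flag over all trials."""
    rows = []
    for pid, grp in features.groupby("participant"):
        valid = grp[grp["valid"]]
        mean_amp = float(valid["traj_peak_amplitude"].mean())
        mean_pk = float(valid["traj_peak_time"].mean())
        rows.append({
            "participant": pid,
            "mean_amplitude_px": mean_amp,
            "mean_peak_time_s": mean_pk,
            "exclude": qc_exclude(mean_amp, mean_pk),
        })
    return pd.DataFrame(rows)
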