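"""Target paths, target points, trial timing and session schedules.

The path-following task presents a bump-shaped target path that descends
towards a horizontal "cursor zone".  Six path variants are used: two
directions (leftward / rightward peak) crossed with three magnitudes whose
displacement amplitudes are 90, 180 and 270 pixels.  All variants are scaled
or mirrored versions of one canonical shape.

Trial clock convention (used throughout the package): ``t = 0`` when the
descending box starts moving; the top of the path reaches the cursor zone at
``t = 1.0 s``; the path crosses the zone during ``[1.0, 1.5] s``; the cursor
is hidden from ``t = 0.75 s`` (0.25 s before path arrival).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PX_PER_MAGNITUDE = 90.0
TARGET_COUNT = 25
TARGET_RADIUS_PX = 6.0

DIRECTIONS = ("L", "R")
MAGNITUDES = (1, 2, 3)
PREVIEW_TIMES = (0.5, 0.8)


@dataclass(frozen=True)
class TrialTiming:
    """Timing constants of one trial on the trial clock (seconds)."""

    zone_arrival: float = 1.0     # path top reaches the cursor zone
    cross_duration: float = 0.5   # time for the path to cross the zone
    cursor_hide: float = 0.75     # cursor invisible from here on
    trial_end: float = 1.5        # end of the crossing window
    record_duration: float = 2.0  # raw-EMG window simulated per trial


@dataclass(frozen=True)
class PathShapeParams:
    """Parameters of the canonical bump shape.

    The canonical path is a piecewise squared-sine bump in the crossing-time
    offset tau in [0, cross_duration]: it rises over ``rise`` seconds and
    falls over the remainder, so the displacement peak crosses the cursor
    zone ``rise`` seconds after the path's leading edge — i.e. at trial time
    1.21 s with the defaults, which is the reference time used for peak
    alignment downstream.
    """

    rise: float = 0.21
    cross_duration: float = 0.5

    @property
    def fall(self) -> float:
        return self.cross_duration - self.rise


@dataclass(frozen=True)
class TargetPath:
    """One of the six scaled/mirrored variants of the canonical path."""

    direction: str           # "L" or "R"
    magnitude: int           # 1, 2 or 3
    amplitude_px: float      # 90 * magnitude
    shape: PathShapeParams = field(default_factory=PathShapeParams)

    @property
    def name(self) -> str:
        return f"{self.direction}{self.magnitude}"

    @property
    def peak_offset(self) -> float:
        """Crossing-time offset of the displacement peak (seconds)."""
        return self.shape.rise

    def displacement(self, tau):
        """Signed horizontal displacement (px) at crossing offset ``tau``.

        ``tau`` is measured from the moment the path's leading edge reaches
        the cursor zone; values outside [0, cross_duration] map to 0.
        """
        tau = np.asarray(tau, dtype=float)
        p = self.shape
        out = np.zeros_like(tau)
        rising = (tau >= 0) & (tau <= p.rise)
        falling = (tau > p.rise) & (tau <= p.cross_duration)
        out[rising] = np.sin(np.pi * tau[rising] / (2.0 * p.rise)) ** 2
        out[falling] = (
            np.sin(np.pi * (p.cross_duration - tau[falling]) / (2.0 * p.fall)) ** 2
        )
        sign = 1.0 if self.direction == "R" else -1.0
        return sign * self.amplitude_px * out

    def velocity(self, tau):
        """Time derivative of :meth:`displacement` (px/s) at offset ``tau``.

        The derivative of each squared-sine half is a single-lobed sine
        bump, which is also the shape of the per-channel control signal an
        ideal participant would produce.
        """
        tau = np.asarray(tau, dtype=float)
        p = self.shape
        out = np.zeros_like(tau)
        rising = (tau >= 0) & (tau <= p.rise)
        falling = (tau > p.rise) & (tau <= p.cross_duration)
        out[rising] = (np.pi / (2.0 * p.rise)) * np.sin(np.pi * tau[rising] / p.rise)
        out[falling] = -(np.pi / (2.0 * p.fall)) * np.sin(
            np.pi * (p.cross_duration - tau[falling]) / p.fall
        )
        sign = 1.0 if self.direction == "R" else -1.0
        return sign * self.amplitude_px * out


def build_path(
    direction: str,
    magnitude: int,
    shape: PathShapeParams | None = None,
) -> TargetPath:
    """Construct one of the six target-path variants.

    Raises
    ------
    ValueError
        If ``direction`` is not ``"L"``/``"R"`` or ``magnitude`` not in
        ``{1, 2, 3}``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if magnitude not in MAGNITUDES:
        raise ValueError(f"magnitude must be one of {MAGNITUDES}, got {magnitude!r}")
    return TargetPath(
        direction=direction,
        magnitude=int(magnitude),
        amplitude_px=PX_PER_MAGNITUDE * magnitude,
        shape=shape or PathShapeParams(),
    )


def path_from_name(name: str, shape: PathShapeParams | None = None) -> TargetPath:
    """Build a path from its short name, e.g. ``"R3"`` or ``"L1"``."""
    return build_path(name[0], int(name[1:]), shape)


@dataclass(frozen=True)
class TargetPoint:
    """One of the 25 circular targets strung along the path."""

    index: int
    crossing_time: float  # trial-clock time its centre crosses the cursor zone
    x_px: float           # signed horizontal displacement
    radius_px: float = TARGET_RADIUS_PX


def make_target_points(
    path: TargetPath, timing: TrialTiming | None = None
) -> list[TargetPoint]:
    """Place the 25 targets uniformly over the path's crossing interval."""
    timing = timing or TrialTiming()
    times = np.linspace(
        timing.zone_arrival, timing.zone_arrival + timing.cross_duration, TARGET_COUNT
    )
    xs = path.displacement(times - timing.zone_arrival)
    return [
        TargetPoint(index=i, crossing_time=float(t), x_px=float(x))
        for i, (t, x) in enumerate(zip(times, xs))
    ]


@dataclass(frozen=True)
class TrialCondition:
    """A path variant plus preview time and post-trial feedback flag."""

    path: TargetPath
    preview_time: float  # 0.5 or 0.8 s
    feedback: bool

    @property
    def label(self) -> str:
        return f"{self.path.name}/p{self.preview_time:g}"


# The two trained conditions: small- and large-rightward, 0.8 s preview,
# post-trial feedback.
def trained_conditions(shape: PathShapeParams | None = None) -> list[TrialCondition]:
    return [
        TrialCondition(build_path("R", m, shape), preview_time=0.8, feedback=True)
        for m in (1, 3)
    ]


def test_conditions(shape: PathShapeParams | None = None) -> list[TrialCondition]:
    """The 12 no-feedback test conditions: 6 paths x 2 preview times."""
    return [
        TrialCondition(build_path(d, m, shape), preview_time=q, feedback=False)
        for d, m, q in itertools.product(DIRECTIONS, MAGNITUDES, PREVIEW_TIMES)
    ]


@dataclass(frozen=True)
class Block:
    block_type: str  # "practice", "training" or "test"
    index: int       # position of the block within the session
    round_index: int
    trials: tuple[TrialCondition, ...]
    checkpoint_after: bool = False  # inert marker: noise re-check after round


@dataclass(frozen=True)
class SessionSchedule:
    session_index: int
    seed: int
    blocks: tuple[Block, ...]


class ScheduleGenerationError(RuntimeError):
    """Pseudo-randomisation failed within the retry budget."""


TRAIN_TRIALS_PER_CONDITION = 30
TEST_TRIALS_PER_CONDITION = 5
MIN_SPACING = 3  # minimum intervening other-condition trials between repeats
ROUNDS_PER_SESSION = 3
PAIRS_PER_ROUND = 2


def _spacing_ok(labels: list[str], min_spacing: int) -> bool:
    last_seen: dict[str, int] = {}
    for i, lab in enumerate(labels):
        if lab in last_seen and i - last_seen[lab] <= min_spacing:
            return False
        last_seen[lab] = i
    return True


def _pseudorandomise(
    conditions: list[TrialCondition],
    counts: int,
    rng: np.random.Generator,
    min_spacing: int = MIN_SPACING,
    max_tries: int = 10_000,
) -> list[TrialCondition]:
    """Random ordering with no condition repeated within ``min_spacing``
    trials of other conditions.

    Built sequentially: each next condition is drawn among those not used
    in the last ``min_spacing`` slots, weighted by remaining count; dead
    ends trigger a restart (rejection sampling over constructions).
    """
    n_cond = len(conditions)
    total = n_cond * counts
    if min_spacing == 0:
        pool = [c for c in conditions for _ in range(counts)]
        return [pool[i] for i in rng.permutation(total)]
    for _ in range(max_tries):
        remaining = np.full(n_cond, counts)
        order: list[int] = []
        ok = True
        for pos in range(total):
            recent = set(order[-min_spacing:])
            allowed = np.flatnonzero(remaining > 0)
            allowed = allowed[[a not in recent for a in allowed]]
            if allowed.size == 0:
                ok = False
                break
            weights = remaining[allowed] / remaining[allowed].sum()
            pick = int(rng.choice(allowed, p=weights))
            order.append(pick)
            remaining[pick] -= 1
        if ok:
            result = [conditions[i] for i in order]
            assert _spacing_ok([c.label for c in result], min_spacing)
            return result
    raise ScheduleGenerationError(
        f"no valid ordering found in {max_tries} tries "
        f"({n_cond} conditions x {counts})"
    )


def generate_session_schedule(
    session_index: int,
    seed: int,
    shape: PathShapeParams | None = None,
    rounds: int = ROUNDS_PER_SESSION,
    train_reps: int = TRAIN_TRIALS_PER_CONDITION,
    test_reps: int = TEST_TRIALS_PER_CONDITION,
) -> SessionSchedule:
    """Generate the block schedule of one session.

    A session holds three rounds of two alternating train–test block pairs.
    Training blocks contain 30 trials of each of the two trained conditions
    in pseudorandom order; test blocks contain 5 trials of each of the 12
    test conditions with no condition repeated within 3 trials of other
    conditions.  Session 1 is preceded by a 12-trial practice block (one
    trial of each test-path condition, with feedback).
    """
    if not 1 <= session_index <= 5:
        raise ValueError(f"session_index must be in 1..5, got {session_index}")
    rng = np.random.default_rng([int(seed), int(session_index)])
    trained = trained_conditions(shape)
    testing = test_conditions(shape)

    blocks: list[Block] = []
    idx = 0
    if session_index == 1:
        practice = [replace(c, feedback=True) for c in testing]
        order = rng.permutation(len(practice))
        blocks.append(
            Block("practice", idx, 0, tuple(practice[i] for i in order))
        )
        idx += 1
    for rnd in range(1, rounds + 1):
        for pair in range(PAIRS_PER_ROUND):
            train = _pseudorandomise(trained, train_reps, rng, min_spacing=0)
            blocks.append(Block("training", idx, rnd, tuple(train)))
            idx += 1
            test = _pseudorandomise(testing, test_reps, rng)
            last_pair = pair == PAIRS_PER_ROUND - 1
            blocks.append(
                Block("test", idx, rnd, tuple(test), checkpoint_after=last_pair)
            )
            idx += 1
    return SessionSchedule(session_index, seed, tuple(blocks))


def check_abort(
    cursor_x: np.ndarray,
    times: np.ndarray,
    visibility_end: float | None = None,
    limit_px: float = 10.0,
) -> bool:
    """Early-movement abort rule.

    Returns True iff the cursor moved strictly more than ``limit_px`` pixels
    from centre at any time before the cursor became invisible.
    """
    if visibility_end is None:
        visibility_end = TrialTiming().cursor_hide
    cursor_x = np.asarray(cursor_x, dtype=float)
    times = np.asarray(times, dtype=float)
    visible = times < visibility_end
    if not visible.any():
        return False
    return bool(np.any(np.abs(cursor_x[visible]) > limit_px))


def schedule_to_frame(schedule: SessionSchedule) -> pd.DataFrame:
    """Flatten a schedule to one row per trial (plain tabular form)."""
    rows = []
    for block in schedule.blocks:
        for i, cond in enumerate(block.trials):
            rows.append(
                {
                    "session": schedule.session_index,
                    "round": block.round_index,
                    "block_type": block.block_type,
                    "block_index": block.index,
                    "trial_index": i,
                    "direction": cond.path.direction,
                    "magnitude": cond.path.magnitude,
                    "preview_time": cond.preview_time,
                    "feedback": cond.feedback,
                }
            )
    return pd.DataFrame(rows)


def path_geometry_frame(
    paths: list[TargetPath] | None = None, n_grid: int = 101
) -> pd.DataFrame:
    """Tabulate path displacement on a uniform crossing-offset grid."""
    if paths is None:
        paths = [build_path(d, m) for d in DIRECTIONS for m in MAGNITUDES]
    frames = []
    for p in paths:
        tau = np.linspace(0.0, p.shape.cross_duration, n_grid)
        frames.append(
            pd.DataFrame({"path": p.name, "tau": tau, "x_px": p.displacement(tau)})
        )
    return pd.concat(frames, ignore_index=True)
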