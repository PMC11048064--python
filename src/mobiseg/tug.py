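"""Timed-Up-and-Go segmentation and features.

The test is partitioned by six events:

* T1 — movement onset (start of standing up),
* T2 — start of walking toward the cone,
* T3 — start of the turn around the cone,
* T4 — start of walking back toward the chair,
* T5 — start of the final turn-and-sit,
* T6 — end of the test (seated, signals back at rest).

T1/T6 come from the earliest onset / latest offset among the trunk and both
thigh resultant angular velocities. T3/T4/T5 are anchored to the two large
turn bumps in trunk angular velocity (their edges estimated with the
symmetric half-crossing estimator); T3 is additionally snapped to the last
foot-acceleration step peak preceding the turn, and T2 to the onset of the
first step after T1. Ten features follow: the five section times, their
total, step counts toward cone and chair, and the two section cadences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    InvalidWindowError,
    NoMovementError,
    SegmentationError,
)
from .preprocess import (
    FilterSpec,
    KinematicRecording,
    bump_bounds,
    lowpass_filter,
    onset_offset,
    refine_peak,
)

__all__ = [
    "TugConfig",
    "TugEvents",
    "TugFeatures",
    "detect_tug_events",
    "count_steps",
    "extract_tug_features",
]


@dataclass(frozen=True)
class TugConfig:
    """Detector thresholds for the TUG test (all times in seconds)."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    baseline_window_s: float = 0.5
    k_sigma: float = 3.0
    sustain_s: float = 0.1
    gyr_floor: float = 3.0  # deg/s; absolute onset-threshold floor
    turn_height_frac: float = 0.5  # turn bumps must reach this fraction of max
    turn_min_sep_s: float = 2.0
    step_prominence_frac: float = 0.3  # of the 95th percentile of the window
    step_floor: float = 1.0  # m/s^2; absolute step-peak floor
    min_step_s: float = 0.25
    walk_onset_lead_s: float = 0.10  # gait-initiation latency before 1st peak
    t3_snap_pre_s: float = 0.45
    t3_snap_post_s: float = 0.10
    # Step-count windows are widened by the event-timing tolerance so a foot
    # plant on a section boundary is not lost to a few-ms event error; kept
    # well below min_step_s so no neighbouring step can be double counted.
    window_slack_s: float = 0.05


@dataclass(frozen=True)
class TugEvents:
    """The six TUG event times, seconds from recording start."""

    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    t6: float

    def __post_init__(self) -> None:
        times = self.as_tuple()
        if not all(a < b for a, b in zip(times, times[1:])):
            raise SegmentationError(f"TUG events are not strictly ordered: {times}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.t1, self.t2, self.t3, self.t4, self.t5, self.t6)

    def shift(self, delta: float) -> "TugEvents":
        return TugEvents(*(t + delta for t in self.as_tuple()))


@dataclass(frozen=True)
class TugFeatures:
    """The ten TUG measures."""

    total_time: float
    sit_to_stand_time: float
    walk_to_cone_time: float
    turn_cone_time: float
    walk_to_chair_time: float
    turn_and_sit_time: float
    steps_to_cone: int
    steps_to_chair: int
    cadence_to_cone: float
    cadence_to_chair: float

    def __post_init__(self) -> None:
        sections = (
            self.sit_to_stand_time,
            self.walk_to_cone_time,
            self.turn_cone_time,
            self.walk_to_chair_time,
            self.turn_and_sit_time,
        )
        if any(s < 0 for s in sections) or self.total_time < 0:
            raise SegmentationError("section times must be non-negative")
        if abs(sum(sections) - self.total_time) > 1e-9:
            raise SegmentationError(
                "section times do not partition the total time"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "total_time": self.total_time,
            "sit_to_stand_time": self.sit_to_stand_time,
            "walk_to_cone_time": self.walk_to_cone_time,
            "turn_cone_time": self.turn_cone_time,
            "walk_to_chair_time": self.walk_to_chair_time,
            "turn_and_sit_time": self.turn_and_sit_time,
            "steps_to_cone": float(self.steps_to_cone),
            "steps_to_chair": float(self.steps_to_chair),
            "cadence_to_cone": self.cadence_to_cone,
            "cadence_to_chair": self.cadence_to_chair,
        }


# ---------------------------------------------------------------------------
# Step-peak detection
# ---------------------------------------------------------------------------


def _step_peaks(
    x: np.ndarray, fs: float, config: TugConfig, prominence_scale: float = 1.0
) -> np.ndarray:
    """Step-peak times (s) in a filtered, baseline-removed foot-acceleration
    resultant, using an adaptive prominence threshold."""
    thr = max(
        config.step_prominence_frac * float(np.percentile(x, 95)),
        config.step_floor,
    ) * prominence_scale
    idx, _ = find_peaks(x, height=thr, prominence=thr, distance=max(int(config.min_step_s * fs), 1))
    return np.array([refine_peak(x, i, fs)[0] for i in idx])


def _merge_feet(times_l: np.ndarray, times_r: np.ndarray, min_sep: float) -> np.ndarray:
    """Merge per-foot peak times, dropping duplicates closer than min_sep."""
    merged = np.sort(np.concatenate([times_l, times_r]))
    if merged.size == 0:
        return merged
    keep = [merged[0]]
    for t in merged[1:]:
        if t - keep[-1] >= min_sep:
            keep.append(t)
    return np.array(keep)


def count_steps(
    foot_acc_L: np.ndarray,
    foot_acc_R: np.ndarray,
    window: tuple[float, float],
    fs: float,
    config: TugConfig | None = None,
    prominence_scale: float = 1.0,
) -> int:
    """Number of step peaks across both feet inside ``window``.

    Inputs are *filtered* resultant foot accelerations (gravity baseline is
    removed internally via the series median). A peak counts as a step if it
    clears an adaptive prominence threshold (a configurable fraction of the
    windowed signal's 95th percentile, floored absolutely); peaks on the
    same foot closer than ``min_step_s`` are suppressed, and near-duplicate
    peaks across feet are merged. ``prominence_scale`` rescales the
    threshold (used to probe threshold sensitivity).
    """
    config = config or TugConfig()
    start_s, end_s = window
    if end_s - start_s < config.min_step_s:
        raise InvalidWindowError(
            f"window of {end_s - start_s:.3f} s shorter than min_step_s"
        )
    # Pad the slice so peaks sitting exactly on a window edge are still
    # visible to the peak finder; the time filter below restores the window.
    pad = int(0.5 * fs)
    i0 = max(int(np.floor(start_s * fs)) - pad, 0)
    i1 = min(int(np.ceil(end_s * fs)) + 1 + pad, len(foot_acc_L))
    if i1 <= i0:
        raise InvalidWindowError("window lies outside the recording")
    eps = 0.5 / fs
    times = []
    for x in (foot_acc_L, foot_acc_R):
        seg = np.asarray(x[i0:i1], dtype=float)
        seg = seg - np.median(seg)
        pk = _step_peaks(seg, fs, config, prominence_scale) + i0 / fs
        times.append(pk[(pk >= start_s - eps) & (pk <= end_s + eps)])
    merged = _merge_feet(times[0], times[1], config.min_step_s / 2.0)
    return int(merged.size)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------


def _filtered_gyr(rec: KinematicRecording, loc: str, spec: FilterSpec) -> np.ndarray:
    return lowpass_filter(rec.gyr_magnitude(loc), spec, rec.fs)


def _filtered_acc(rec: KinematicRecording, loc: str, spec: FilterSpec) -> np.ndarray:
    x = lowpass_filter(rec.acc_magnitude(loc), spec, rec.fs)
    return x - np.median(x)


def _refined_onset(x: np.ndarray, fs: float, onset_idx: int, base: float) -> float:
    """Refine a coarse onset to the estimated edge of the first bump after it."""
    hi = min(onset_idx + int(3.0 * fs), len(x))
    seg = x[onset_idx:hi]
    if seg.size == 0:
        return onset_idx / fs
    peak = onset_idx + int(np.argmax(seg))
    t_edge = bump_bounds(x, fs, peak, base=base).onset
    # Guard against pathological estimates (e.g. strongly asymmetric bumps).
    if not onset_idx / fs - 0.75 <= t_edge <= peak / fs:
        return onset_idx / fs
    return t_edge


def _refined_offset(x: np.ndarray, fs: float, offset_idx: int, base: float) -> float:
    lo = max(offset_idx - int(3.0 * fs), 0)
    seg = x[lo : offset_idx + 1]
    if seg.size == 0:
        return offset_idx / fs
    peak = lo + int(np.argmax(seg))
    t_edge = bump_bounds(x, fs, peak, base=base).end
    if not peak / fs <= t_edge <= offset_idx / fs + 0.75:
        return offset_idx / fs
    return t_edge


def detect_tug_events(
    rec: KinematicRecording, config: TugConfig | None = None
) -> TugEvents:
    """Detect T1..T6 in a TUG recording.

    Raises :class:`~mobiseg.errors.NoMovementError` for a quiet recording,
    :class:`~mobiseg.errors.SegmentationError` when the two trunk turn bumps
    cannot be found unambiguously (the cases the reference protocol resolved
    by manual adjustment), and an ``InsufficientGaitError``-flavoured
    :class:`~mobiseg.errors.SegmentationError` when no steps are present.
    """
    config = config or TugConfig()
    fs = rec.fs
    spec = config.filter

    trunk = _filtered_gyr(rec, "sternum", spec)
    thigh_l = _filtered_gyr(rec, "thigh_L", spec)
    thigh_r = _filtered_gyr(rec, "thigh_R", spec)
    foot_l = _filtered_acc(rec, "foot_L", spec)
    foot_r = _filtered_acc(rec, "foot_R", spec)

    # --- T1 / T6: earliest onset, latest offset among trunk + thighs -------
    onsets = []
    offsets: dict[str, float] = {}
    for name, x in (("trunk", trunk), ("thigh_L", thigh_l), ("thigh_R", thigh_r)):
        try:
            on, off = onset_offset(
                x,
                fs,
                baseline_window_s=config.baseline_window_s,
                k_sigma=config.k_sigma,
                sustain_s=config.sustain_s,
                min_delta=config.gyr_floor,
            )
        except NoMovementError:
            continue
        base = float(np.mean(x[: int(config.baseline_window_s * fs)]))
        onsets.append(_refined_onset(x, fs, on, base))
        offsets[name] = _refined_offset(x, fs, off, base)
    if not onsets:
        raise NoMovementError("no movement detected on trunk or thigh sensors")
    t1 = min(onsets)

    # Provisional end of activity, used only to bracket the turn search.
    t6_coarse = max(offsets.values())

    # --- Turn bumps in trunk angular velocity ------------------------------
    height = config.turn_height_frac * float(np.max(trunk))
    pk_idx, _ = find_peaks(
        trunk, height=height, distance=max(int(config.turn_min_sep_s * fs), 1)
    )
    pk_idx = pk_idx[(pk_idx / fs > t1) & (pk_idx / fs < t6_coarse + 0.5)]
    if len(pk_idx) < 2:
        raise SegmentationError(
            f"expected 2 trunk turn bumps, found {len(pk_idx)}; manual review needed"
        )
    if len(pk_idx) > 2:
        # Keep the two most prominent candidates, preserving order.
        order = np.argsort(trunk[pk_idx])[-2:]
        pk_idx = np.sort(pk_idx[order])
    p1, p2 = int(pk_idx[0]), int(pk_idx[1])

    # Walking baseline: trunk angular velocity is at its plateau for most of
    # the active interval, so the median is a robust estimate.
    active = trunk[int(t1 * fs) : int(t6_coarse * fs) + 1]
    walk_base = float(np.median(active))

    bump1 = bump_bounds(trunk, fs, p1, base=walk_base)
    bump2 = bump_bounds(trunk, fs, p2, base=walk_base)
    t3_raw, t4, t5 = bump1.onset, bump1.end, bump2.onset

    # T6: latest offset among the three segments. The trunk candidate is the
    # end of the final turn-and-sit bump: its half-amplitude crossings sit
    # well above the post-test drop to rest, so the estimate is not
    # contaminated by the trunk's direct settling edge (which merges the
    # bump's fall with the drop of the walking baseline).
    t6 = max([v for k, v in offsets.items() if k != "trunk"] + [bump2.end])

    # --- Foot step peaks ----------------------------------------------------
    steps_l = _step_peaks(foot_l, fs, config)
    steps_r = _step_peaks(foot_r, fs, config)
    all_steps = _merge_feet(steps_l, steps_r, config.min_step_s / 2.0)
    all_steps = all_steps[(all_steps > t1) & (all_steps < t6)]
    if all_steps.size == 0:
        raise SegmentationError("no steps detected inside the active interval")

    # T3: snap to the stride end (last step peak) just before the turn bump.
    near = all_steps[
        (all_steps >= t3_raw - config.t3_snap_pre_s)
        & (all_steps <= t3_raw + config.t3_snap_post_s)
    ]
    t3 = float(near[-1]) if near.size else t3_raw

    # T2: first step peak after T1, less the configured gait-initiation lead.
    before_turn = all_steps[all_steps < t3_raw]
    if before_turn.size == 0:
        raise SegmentationError("no steps detected before the first turn")
    t2 = float(before_turn[0]) - config.walk_onset_lead_s

    events = (t1, t2, t3, t4, t5, t6)
    if not all(a < b for a, b in zip(events, events[1:])):
        raise SegmentationError(f"detected events are not strictly ordered: {events}")
    if events[-1] > rec.duration or events[0] < 0:
        raise SegmentationError("detected events fall outside the recording")
    return TugEvents(*events)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def extract_tug_features(
    rec: KinematicRecording,
    events: TugEvents,
    config: TugConfig | None = None,
) -> TugFeatures:
    """The ten TUG measures from a recording and its detected events.

    Section times are pairwise differences of T1..T6 (they partition the
    total by construction); steps are counted strictly inside the walking
    windows (T2, T3) and (T4, T5); each cadence is ``60 * steps / section
    time``, so ``cadence * time = 60 * steps`` holds exactly.
    """
    config = config or TugConfig()
    spec = config.filter
    foot_l = _filtered_acc(rec, "foot_L", spec)
    foot_r = _filtered_acc(rec, "foot_R", spec)

    s = config.window_slack_s
    steps_cone = count_steps(
        foot_l, foot_r, (events.t2 - s, events.t3 + s), rec.fs, config
    )
    steps_chair = count_steps(
        foot_l, foot_r, (events.t4 - s, events.t5 + s), rec.fs, config
    )

    d = np.diff(events.as_tuple())
    return TugFeatures(
        total_time=events.t6 - events.t1,
        sit_to_stand_time=float(d[0]),
        walk_to_cone_time=float(d[1]),
        turn_cone_time=float(d[2]),
        walk_to_chair_time=float(d[3]),
        turn_and_sit_time=float(d[4]),
        steps_to_cone=steps_cone,
        steps_to_chair=steps_chair,
        cadence_to_cone=60.0 * steps_cone / float(d[1]),
        cadence_to_chair=60.0 * steps_chair / float(d[3]),
    )
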