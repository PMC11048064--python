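"""Heel-strike / toe-off detection and 10 m-walk features.

Each stride produces two distinct peaks in the resultant linear
acceleration of the shank: the first at toe-off (TO, swing onset), the
second at heel strike (HS, swing end). Peaks are detected per side with an
adaptive prominence threshold, partitioned into strides by inter-peak gap
statistics (the within-stride TO→HS gap is shorter than the between-stride
HS→TO gap whenever the swing phase occupies less than half the stride), and
labelled by within-stride order.

Seven features: total walk time, step count, cadence, mean swing fraction,
mean single-support fraction, gait speed and stride duration. ``Single
support`` here is the fraction of a stride during which exactly one foot is
in ground contact, computed from the bilateral TO/HS interleaving (stance =
HS to next same-side TO); with symmetric gait this equals twice the swing
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientGaitError, SegmentationError
from .preprocess import (
    FilterSpec,
    KinematicRecording,
    lowpass_filter,
    refine_peak,
)

__all__ = [
    "GaitConfig",
    "GaitEvents",
    "GaitFeatures",
    "detect_gait_events",
    "extract_gait_features",
    "walk_window",
]


@dataclass(frozen=True)
class GaitConfig:
    """Detector thresholds for shank-acceleration gait events."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    prominence_frac: float = 0.3  # of the 95th percentile of the series
    peak_floor: float = 0.5  # m/s^2 absolute floor
    min_peak_sep_s: float = 0.08
    label_by: str = "order"  # "order" (TO first) or "amplitude" (HS taller)


@dataclass(frozen=True)
class GaitEvents:
    """Per-side heel-strike and toe-off times, seconds, ordered."""

    hs_L: tuple[float, ...]
    to_L: tuple[float, ...]
    hs_R: tuple[float, ...]
    to_R: tuple[float, ...]

    def __post_init__(self) -> None:
        for side in ("L", "R"):
            hs = getattr(self, f"hs_{side}")
            to = getattr(self, f"to_{side}")
            if len(hs) != len(to):
                raise SegmentationError(f"side {side}: unpaired TO/HS events")
            for i, (t_to, t_hs) in enumerate(zip(to, hs)):
                if not t_to < t_hs:
                    raise SegmentationError(
                        f"side {side}, stride {i}: TO must precede HS"
                    )
                if i + 1 < len(to) and not t_hs < to[i + 1]:
                    raise SegmentationError(
                        f"side {side}: stride {i} HS overlaps the next stride"
                    )

    @property
    def first(self) -> float:
        return min(self.to_L[0], self.to_R[0])

    @property
    def last(self) -> float:
        return max(self.hs_L[-1], self.hs_R[-1])


@dataclass(frozen=True)
class GaitFeatures:
    """The seven 10 m-walk measures."""

    walk_time: float
    steps: int
    cadence: float
    mean_swing_pct: float
    single_support_pct: float
    gait_speed: float
    stride_duration: float

    def __post_init__(self) -> None:
        if self.walk_time <= 0:
            raise SegmentationError("walk_time must be positive")
        if not 0.0 < self.mean_swing_pct < 1.0:
            raise SegmentationError("mean swing fraction must lie in (0, 1)")

    def as_dict(self) -> dict[str, float]:
        return {
            "walk_time": self.walk_time,
            "steps": float(self.steps),
            "cadence": self.cadence,
            "mean_swing_pct": self.mean_swing_pct,
            "single_support_pct": self.single_support_pct,
            "gait_speed": self.gait_speed,
            "stride_duration": self.stride_duration,
        }


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _side_peaks(x: np.ndarray, fs: float, config: GaitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Candidate peak times and heights in one shank's filtered resultant."""
    x = np.asarray(x, dtype=float)
    x = x - np.median(x)  # remove the gravity baseline
    thr = max(config.prominence_frac * float(np.percentile(x, 95)), config.peak_floor)
    idx, _ = find_peaks(
        x, height=thr, prominence=thr, distance=max(int(config.min_peak_sep_s * fs), 1)
    )
    if idx.size == 0:
        return np.array([]), np.array([])
    refined = np.array([refine_peak(x, i, fs) for i in idx])
    return refined[:, 0], refined[:, 1]


def _partition_strides(times: np.ndarray) -> list[tuple[int, int]]:
    """Group an alternating TO/HS peak sequence into (i_first, i_second)
    index pairs using the bimodal inter-peak gap distribution."""
    gaps = np.diff(times)
    med = float(np.median(gaps))
    lower = gaps[gaps <= med]
    upper = gaps[gaps > med]
    if upper.size == 0 or lower.size == 0:
        # Degenerate: all gaps equal; pair sequentially.
        split = np.inf
    else:
        split = 0.5 * (float(np.median(lower)) + float(np.median(upper)))

    pairs: list[tuple[int, int]] = []
    i = 0
    n = len(times)
    while i < n:
        if i + 1 < n and gaps[i] < split:
            pairs.append((i, i + 1))
            i += 2
        else:
            raise SegmentationError(
                "unpaired shank-acceleration peak after stride partitioning"
            )
    return pairs


def detect_gait_events(
    shank_acc_L: np.ndarray,
    shank_acc_R: np.ndarray,
    fs: float,
    config: GaitConfig | None = None,
) -> GaitEvents:
    """Detect TO/HS events from *filtered* resultant shank accelerations.

    Sides are processed independently. Within each stride the first peak is
    labelled TO and the second HS (the ``amplitude`` labelling alternative
    assigns HS to the taller peak of the pair). Fewer than two strides on
    either side raises :class:`~mobiseg.errors.InsufficientGaitError`.
    """
    config = config or GaitConfig()
    out: dict[str, tuple[float, ...]] = {}
    for side, x in (("L", shank_acc_L), ("R", shank_acc_R)):
        times, heights = _side_peaks(x, fs, config)
        if times.size < 4:
            raise InsufficientGaitError(
                f"side {side}: fewer than 2 strides detected"
            )
        pairs = _partition_strides(times)
        if len(pairs) < 2:
            raise InsufficientGaitError(
                f"side {side}: fewer than 2 strides detected"
            )
        to, hs = [], []
        for a, b in pairs:
            if config.label_by == "amplitude" and heights[a] > heights[b]:
                hs.append(times[a])
                to.append(times[b])
            else:
                to.append(times[a])
                hs.append(times[b])
        out[f"to_{side}"] = tuple(to)
        out[f"hs_{side}"] = tuple(hs)
    return GaitEvents(
        hs_L=out["hs_L"], to_L=out["to_L"], hs_R=out["hs_R"], to_R=out["to_R"]
    )


def walk_window(
    shank_acc_L: np.ndarray,
    shank_acc_R: np.ndarray,
    fs: float,
    config: GaitConfig | None = None,
) -> tuple[float, float]:
    """Window of the walking bout: first to last detected gait event."""
    events = detect_gait_events(shank_acc_L, shank_acc_R, fs, config)
    return events.first, events.last


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def _stance_intervals(hs: tuple[float, ...], to: tuple[float, ...]) -> list[tuple[float, float]]:
    """Ground-contact intervals of one foot: HS_i to the following TO."""
    return [(hs[i], to[i + 1]) for i in range(len(hs) - 1)]


def _occupancy(intervals: list[tuple[float, float]], t0: float, t1: float) -> float:
    """Total time within [t0, t1] covered by the (disjoint) intervals."""
    total = 0.0
    for a, b in intervals:
        total += max(0.0, min(b, t1) - max(a, t0))
    return total


def extract_gait_features(
    events: GaitEvents,
    walk_time: float,
    distance_m: float = 10.0,
) -> GaitFeatures:
    """The seven walk measures from detected gait events.

    ``steps`` is the total heel-strike count over both sides; ``cadence =
    60 * steps / walk_time`` and ``gait_speed = distance / walk_time`` hold
    exactly. Stride duration averages consecutive same-side HS-to-HS
    intervals; the swing fraction of a stride is (HS − preceding TO) /
    stride duration (so swing + stance = 1 per stride by construction); and
    single support is the mean fraction of a stride during which exactly one
    foot is in stance.
    """
    if walk_time <= 0:
        raise SegmentationError("walk_time must be positive")
    if not (events.hs_L and events.hs_R):
        raise InsufficientGaitError("gait events present on one side only")

    steps = len(events.hs_L) + len(events.hs_R)

    stride_durs: list[float] = []
    swing_fracs: list[float] = []
    for side in ("L", "R"):
        hs = getattr(events, f"hs_{side}")
        to = getattr(events, f"to_{side}")
        for i in range(len(hs) - 1):
            dur = hs[i + 1] - hs[i]
            stride_durs.append(dur)
            swing_fracs.append((hs[i + 1] - to[i + 1]) / dur)

    # Single support from bilateral interleaving.
    stance = {
        "L": _stance_intervals(events.hs_L, events.to_L),
        "R": _stance_intervals(events.hs_R, events.to_R),
    }
    coverage = {
        s: (stance[s][0][0], stance[s][-1][1]) for s in ("L", "R") if stance[s]
    }
    single_fracs: list[float] = []
    if len(coverage) == 2:
        for side, other in (("L", "R"), ("R", "L")):
            hs = getattr(events, f"hs_{side}")
            for i in range(len(hs) - 1):
                t0, t1 = hs[i], hs[i + 1]
                if t0 < coverage[other][0] or t1 > coverage[other][1]:
                    continue  # the opposite side's stance state is unknown here
                both = _paired_overlap(stance[side], stance[other], t0, t1)
                any_contact = (
                    _occupancy(stance[side], t0, t1)
                    + _occupancy(stance[other], t0, t1)
                    - both
                )
                single_fracs.append((any_contact - both) / (t1 - t0))

    return GaitFeatures(
        walk_time=walk_time,
        steps=steps,
        cadence=60.0 * steps / walk_time,
        mean_swing_pct=float(np.mean(swing_fracs)),
        single_support_pct=float(np.mean(single_fracs)) if single_fracs else float("nan"),
        gait_speed=distance_m / walk_time,
        stride_duration=float(np.mean(stride_durs)),
    )


def _paired_overlap(
    a: list[tuple[float, float]], b: list[tuple[float, float]], t0: float, t1: float
) -> float:
    """Time within [t0, t1] where intervals from both lists overlap."""
    total = 0.0
    for a0, a1 in a:
        for b0, b1 in b:
            lo = max(a0, b0, t0)
            hi = min(a1, b1, t1)
            if hi > lo:
                total += hi - lo
    return total
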