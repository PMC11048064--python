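"""Five-repetition sit-to-stand segmentation and features.

Each sit-stand-sit cycle appears as a pair of convex lobes in thigh
resultant angular velocity: one for rising, one for sitting back down.
Detection thresholds the (default: left/right-averaged) thigh signal against
its quiescent baseline, groups supra-threshold runs into lobes, refines each
lobe's edges with the symmetric half-crossing estimator, and pairs
consecutive lobes into cycles (first = up, second = down).

Eight features: total active time, mean cycle time, mean up and down phase
durations, and the RMS resultant angular velocity of the trunk (sternum),
pelvis (sacrum) and both thighs over the active interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoMovementError, SegmentationError
from .preprocess import (
    FilterSpec,
    KinematicRecording,
    bump_bounds,
    lowpass_filter,
)

__all__ = [
    "StsConfig",
    "StsCycles",
    "StsFeatures",
    "detect_sts_cycles",
    "extract_sts_features",
]


@dataclass(frozen=True)
class StsConfig:
    """Detector thresholds for the sit-to-stand test."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    n_cycles: int = 5
    baseline_window_s: float = 0.5
    k_sigma: float = 3.0
    gyr_floor: float = 3.0  # deg/s
    min_lobe_s: float = 0.3  # reject supra-threshold runs shorter than this
    merge_gap_s: float = 0.08  # merge runs separated by less than this
    max_intra_cycle_gap_s: float = 3.0
    side: str = "mean"  # "mean", "L" or "R"


@dataclass(frozen=True)
class StsCycles:
    """Cycle boundaries: (up_start, up_end, down_start, down_end) each."""

    cycles: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for cyc in self.cycles:
            us, ue, ds, de = cyc
            if not (us < ue <= ds < de):
                raise SegmentationError(f"malformed cycle {cyc}")
            if us <= prev_end:
                raise SegmentationError("cycles overlap or are out of order")
            prev_end = de

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def start(self) -> float:
        return self.cycles[0][0]

    @property
    def end(self) -> float:
        return self.cycles[-1][3]


@dataclass(frozen=True)
class StsFeatures:
    """The eight sit-to-stand measures (times s, RMS deg/s)."""

    total_time: float
    mean_cycle_time: float
    mean_up_time: float
    mean_down_time: float
    rms_thorax: float
    rms_pelvis: float
    rms_thigh_R: float
    rms_thigh_L: float

    def __post_init__(self) -> None:
        vals = (
            self.total_time,
            self.mean_cycle_time,
            self.mean_up_time,
            self.mean_down_time,
            self.rms_thorax,
            self.rms_pelvis,
            self.rms_thigh_R,
            self.rms_thigh_L,
        )
        if any(v < 0 for v in vals):
            raise SegmentationError("sit-to-stand features must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "total_time": self.total_time,
            "mean_cycle_time": self.mean_cycle_time,
            "mean_up_time": self.mean_up_time,
            "mean_down_time": self.mean_down_time,
            "rms_thorax": self.rms_thorax,
            "rms_pelvis": self.rms_pelvis,
            "rms_thigh_R": self.rms_thigh_R,
            "rms_thigh_L": self.rms_thigh_L,
        }


# ---------------------------------------------------------------------------


def _lobes(
    x: np.ndarray, fs: float, config: StsConfig
) -> list[tuple[float, float]]:
    """Detect convex lobes in a filtered thigh resultant, as (start, end) s.

    Runs above the baseline threshold are merged across sub-``merge_gap_s``
    dips, runs shorter than ``min_lobe_s`` are discarded, and the surviving
    lobes' edges are refined from the half-amplitude width about the lobe
    peak (see :func:`mobiseg.preprocess.bump_bounds`).
    """
    n_base = int(config.baseline_window_s * fs)
    base_mean = float(np.mean(x[:n_base]))
    thr = base_mean + max(config.k_sigma * float(np.std(x[:n_base])), config.gyr_floor)

    above = x > thr
    if not above.any():
        raise NoMovementError("thigh angular velocity never exceeds the threshold")
    padded = np.concatenate(([0], above.astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive

    # Merge runs separated by brief dips.
    merged: list[tuple[int, int]] = []
    gap = int(config.merge_gap_s * fs)
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    min_len = int(config.min_lobe_s * fs)
    lobes = []
    for s, e in merged:
        if e - s < min_len:
            continue
        peak = s + int(np.argmax(x[s:e]))
        bounds = bump_bounds(x, fs, peak, base=base_mean)
        t_start, t_end = bounds.onset, bounds.end
        # Fall back to the threshold crossings if the estimate is implausible.
        if not s / fs - 0.75 <= t_start < peak / fs:
            t_start = s / fs
        if not peak / fs < t_end <= (e - 1) / fs + 0.75:
            t_end = (e - 1) / fs
        lobes.append((t_start, t_end))
    if not lobes:
        raise NoMovementError("no sustained thigh-angular-velocity lobes found")
    return lobes


def detect_sts_cycles(
    thigh_gyr_L: np.ndarray,
    thigh_gyr_R: np.ndarray,
    fs: float,
    config: StsConfig | None = None,
) -> StsCycles:
    """Segment a sit-to-stand trial into its configured number of cycles.

    Inputs are *filtered* resultant thigh angular velocities. By default the
    two sides are averaged before detection (suppressing unilateral noise,
    relevant for hemiparetic movement); ``config.side`` selects a single
    side instead. Exactly ``2 * n_cycles`` lobes are expected; anything else
    raises :class:`~mobiseg.errors.SegmentationError`.
    """
    config = config or StsConfig()
    if config.side == "mean":
        x = 0.5 * (np.asarray(thigh_gyr_L, float) + np.asarray(thigh_gyr_R, float))
    elif config.side == "L":
        x = np.asarray(thigh_gyr_L, float)
    elif config.side == "R":
        x = np.asarray(thigh_gyr_R, float)
    else:
        raise SegmentationError(f"unknown side {config.side!r}")

    lobes = _lobes(x, fs, config)
    if len(lobes) != 2 * config.n_cycles:
        raise SegmentationError(
            f"expected {2 * config.n_cycles} lobes, found {len(lobes)}; "
            "manual review needed"
        )

    cycles = []
    for i in range(config.n_cycles):
        us, ue = lobes[2 * i]
        ds, de = lobes[2 * i + 1]
        if ds - ue > config.max_intra_cycle_gap_s:
            raise SegmentationError(
                f"gap between up and down lobes of cycle {i + 1} exceeds "
                f"{config.max_intra_cycle_gap_s} s"
            )
        # Mirror refinement can nudge edges past each other at high noise.
        ds = max(ds, ue + 1.0 / fs)
        cycles.append((us, ue, ds, de))
    return StsCycles(cycles=tuple(cycles))


def extract_sts_features(
    rec: KinematicRecording,
    cycles: StsCycles,
    config: StsConfig | None = None,
) -> StsFeatures:
    """The eight sit-to-stand measures.

    Total time spans the first lobe's start to the last lobe's end
    (including inter-cycle rests); the mean cycle time is total / n_cycles
    by definition. RMS values are computed on the filtered resultant angular
    velocity of each segment over the full active interval.
    """
    config = config or StsConfig()
    if len(cycles) < 1:
        raise SegmentationError("need at least one cycle")
    fs = rec.fs
    i0 = int(np.floor(cycles.start * fs))
    i1 = int(np.ceil(cycles.end * fs)) + 1

    def _rms_of(loc: str) -> float:
        x = lowpass_filter(rec.gyr_magnitude(loc), config.filter, fs)
        seg = x[i0:i1]
        return float(np.sqrt(np.mean(seg**2)))

    total = cycles.end - cycles.start
    ups = [ue - us for us, ue, _, _ in cycles.cycles]
    downs = [de - ds for _, _, ds, de in cycles.cycles]
    return StsFeatures(
        total_time=total,
        mean_cycle_time=total / len(cycles),
        mean_up_time=float(np.mean(ups)),
        mean_down_time=float(np.mean(downs)),
        rms_thorax=_rms_of("sternum"),
        rms_pelvis=_rms_of("sacrum"),
        rms_thigh_R=_rms_of("thigh_R"),
        rms_thigh_L=_rms_of("thigh_L"),
    )
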