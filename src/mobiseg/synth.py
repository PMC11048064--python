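"""Synthetic kinematic recordings with known ground truth.

The generators emulate exactly the signal features the detectors consume —
not full-body biomechanics:

* walking: a double-peaked resultant linear acceleration on each shank/foot
  (one peak at toe-off, one at heel strike) riding on the gravity magnitude;
* turning: a raised-cosine bump in trunk resultant angular velocity spanning
  the turn, dominating a low walking baseline;
* sit/stand transitions: paired convex (raised-cosine) lobes in thigh
  resultant angular velocity, with scaled copies on the trunk and pelvis.

Each generator returns the recording together with a :class:`GroundTruth`
carrying the true event times and feature values, so every downstream
detector can be validated by round-trip. A cohort generator draws
subject-level parameters per group x cognitive-load cell from truncated
normals, giving a repeated-measures cohort with known cell means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import InvalidParamsError, InvalidSpecError
from .preprocess import (
    GRAVITY,
    LOCATIONS,
    KinematicRecording,
    SensorStream,
    TrialMeta,
)

__all__ = [
    "GroundTruth",
    "TugTrialParams",
    "StsTrialParams",
    "WalkTrialParams",
    "CohortSpec",
    "generate_tug_trial",
    "generate_sts_trial",
    "generate_walk_trial",
    "generate_cohort",
    "draw_cohort_params",
    "default_cohort_spec",
]


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """True event times (seconds) and feature values of a synthetic trial.

    ``events`` maps an event-family name (e.g. ``"tug"``, ``"hs_L"``) to a
    strictly increasing list of times; ``features`` maps feature names to
    their true values.
    """

    events: dict[str, list[float]] = field(default_factory=dict)
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, times in self.events.items():
            arr = np.asarray(times, dtype=float)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise InvalidParamsError(
                    f"ground-truth event family {name!r} is not strictly increasing"
                )


# ---------------------------------------------------------------------------
# Waveform primitives
# ---------------------------------------------------------------------------


def _raised_cosine(t: np.ndarray, start: float, duration: float, amp: float) -> np.ndarray:
    """Convex lobe: 0 at both edges, ``amp`` at the centre, zero outside."""
    out = np.zeros_like(t)
    if duration <= 0 or amp == 0:
        return out
    inside = (t >= start) & (t <= start + duration)
    phase = (t[inside] - start) / duration
    out[inside] = 0.5 * amp * (1.0 - np.cos(2.0 * np.pi * phase))
    return out


def _gaussian(t: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _plateau(t: np.ndarray, start: float, end: float, level: float) -> np.ndarray:
    out = np.zeros_like(t)
    out[(t >= start) & (t < end)] = level
    return out


def _blank_channels(n: int) -> dict[str, dict[str, np.ndarray]]:
    ch: dict[str, dict[str, np.ndarray]] = {}
    for loc in LOCATIONS:
        ch[loc] = {"gyr": np.zeros((n, 3)), "acc": np.zeros((n, 3))}
        ch[loc]["acc"][:, 2] = GRAVITY  # resting acceleration = gravity magnitude
    return ch


def _assemble(
    ch: dict[str, dict[str, np.ndarray]],
    meta: TrialMeta,
    fs: float,
    rng: np.random.Generator,
    noise_sd_gyr: float,
    noise_sd_acc: float,
) -> KinematicRecording:
    streams = {}
    for loc in LOCATIONS:
        gyr = ch[loc]["gyr"]
        acc = ch[loc]["acc"]
        if noise_sd_gyr > 0:
            gyr = gyr + rng.normal(0.0, noise_sd_gyr, gyr.shape)
        if noise_sd_acc > 0:
            acc = acc + rng.normal(0.0, noise_sd_acc, acc.shape)
        streams[loc] = SensorStream(location=loc, ang_vel=gyr, lin_acc=acc, fs=fs)
    return KinematicRecording(streams=streams, meta=meta)


def _alternate_feet(times: np.ndarray, first: str = "foot_R") -> dict[str, np.ndarray]:
    """Assign consecutive step times to alternating feet."""
    other = "foot_L" if first == "foot_R" else "foot_R"
    return {first: times[0::2], other: times[1::2]}


#: Width (standard deviation, seconds) of the Gaussian acceleration peak that
#: stands in for a foot-contact / push-off transient (~60 ms wide at half max).
STEP_SIGMA_S = 0.025


# ---------------------------------------------------------------------------
# TUG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TugTrialParams:
    """Parameters of one synthetic Timed-Up-and-Go trial.

    ``phase_durations`` are the five section durations in seconds:
    sit-to-stand, walk-to-cone, turn-around-cone, walk-to-chair,
    turn-and-sit. Defaults reproduce the control-group single-task means of
    the reference protocol (total 13.34 s).
    """

    phase_durations: tuple[float, float, float, float, float] = (
        1.37,
        3.95,
        1.75,
        3.33,
        2.94,
    )
    steps_to_cone: int = 6
    steps_to_chair: int = 5
    noise_sd_acc: float = 0.15
    noise_sd_gyr: float = 1.5
    turn_peak_gyr: float = 100.0
    walk_base_gyr: float = 10.0
    sts_peak_gyr: float = 40.0
    thigh_lobe_gyr: float = 60.0
    thigh_walk_gyr: float = 5.0
    step_peak_acc: float = 6.0
    first_step_delay_s: float = 0.10
    lead_s: float = 1.5
    tail_s: float = 1.5
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.phase_durations) != 5 or any(d <= 0 for d in self.phase_durations):
            raise InvalidParamsError("phase_durations must be five positive durations")
        if self.steps_to_cone < 2 or self.steps_to_chair < 2:
            raise InvalidParamsError("step counts must be >= 2")
        if self.noise_sd_acc < 0 or self.noise_sd_gyr < 0:
            raise InvalidParamsError("noise SDs must be >= 0")
        for steps, dur in (
            (self.steps_to_cone, self.phase_durations[1]),
            (self.steps_to_chair, self.phase_durations[3]),
        ):
            rate = steps / dur
            if not 0.3 <= rate <= 3.0:
                raise InvalidParamsError(
                    f"infeasible cadence: {steps} steps over {dur} s "
                    f"({rate:.2f} steps/s outside [0.3, 3])"
                )


def generate_tug_trial(
    params: TugTrialParams | None = None,
    meta: TrialMeta | None = None,
) -> tuple[KinematicRecording, GroundTruth]:
    """Synthesize a TUG trial with known events T1..T6.

    The trunk shows a convex sit-to-stand bump over [T1, T2], a constant
    walking baseline over [T2, T6] and raised-cosine turn bumps over
    [T3, T4] and [T5, T6]. Thighs show convex lobes during the two chair
    transfers. Foot acceleration carries one Gaussian peak per step inside
    the walking phases only, alternating feet, the first peak a fixed
    gait-initiation latency after the phase start and the last exactly at
    the phase end (the foot plant that initiates the turn).
    """
    p = params or TugTrialParams()
    meta = meta or TrialMeta("synthetic", "control", "ST", "TUG")
    d1, d2, d3, d4, d5 = p.phase_durations
    t1 = p.lead_s
    t2 = t1 + d1
    t3 = t2 + d2
    t4 = t3 + d3
    t5 = t4 + d4
    t6 = t5 + d5
    n = int(round((t6 + p.tail_s) * p.fs)) + 1
    t = np.arange(n) / p.fs
    ch = _blank_channels(n)

    # Trunk (sternum) and pelvis (sacrum) angular velocity.
    trunk = (
        _raised_cosine(t, t1, d1, p.sts_peak_gyr)
        + _plateau(t, t2, t6, p.walk_base_gyr)
        + _raised_cosine(t, t3, d3, p.turn_peak_gyr - p.walk_base_gyr)
        + _raised_cosine(t, t5, d5, p.turn_peak_gyr - p.walk_base_gyr)
    )
    ch["sternum"]["gyr"][:, 0] = trunk
    ch["sacrum"]["gyr"][:, 0] = 0.8 * trunk

    # Thigh angular velocity: chair-transfer lobes + low swing baseline.
    for loc in ("thigh_L", "thigh_R"):
        ch[loc]["gyr"][:, 0] = (
            _raised_cosine(t, t1, d1, p.thigh_lobe_gyr)
            + _plateau(t, t2, t5, p.thigh_walk_gyr)
            + _raised_cosine(t, t5, d5, p.thigh_lobe_gyr)
        )

    # Step peaks on foot (and attenuated on shank) acceleration.
    for (start, end, steps) in (
        (t2, t3, p.steps_to_cone),
        (t4, t5, p.steps_to_chair),
    ):
        times = np.linspace(start + p.first_step_delay_s, end, steps)
        for foot, foot_times in _alternate_feet(times).items():
            shank = "shank_L" if foot == "foot_L" else "shank_R"
            for tc in foot_times:
                ch[foot]["acc"][:, 2] += _gaussian(t, tc, STEP_SIGMA_S, p.step_peak_acc)
                ch[shank]["acc"][:, 2] += _gaussian(
                    t, tc, STEP_SIGMA_S, 0.8 * p.step_peak_acc
                )

    rng = np.random.default_rng(p.seed)
    rec = _assemble(ch, meta, p.fs, rng, p.noise_sd_gyr, p.noise_sd_acc)

    sections = {
        "sit_to_stand_time": d1,
        "walk_to_cone_time": d2,
        "turn_cone_time": d3,
        "walk_to_chair_time": d4,
        "turn_and_sit_time": d5,
    }
    truth = GroundTruth(
        events={"tug": [t1, t2, t3, t4, t5, t6]},
        features={
            "total_time": t6 - t1,
            **sections,
            "steps_to_cone": float(p.steps_to_cone),
            "steps_to_chair": float(p.steps_to_chair),
            "cadence_to_cone": 60.0 * p.steps_to_cone / d2,
            "cadence_to_chair": 60.0 * p.steps_to_chair / d4,
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# STS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StsTrialParams:
    """Parameters of one synthetic five-repetition sit-to-stand trial.

    Each cycle is an "up" lobe (sit-to-stand) and a "down" lobe
    (stand-to-sit) separated by ``inter_phase_gap``; cycles are separated by
    ``inter_cycle_gap``. Optional ``*_rms`` targets rescale a channel's
    noiseless waveform so its RMS over the active interval matches the
    target (the reference tables print trunk/pelvis/thigh RMS values whose
    absolute scale is configuration here).
    """

    n_cycles: int = 5
    up_duration: float = 1.75
    down_duration: float = 1.81
    inter_phase_gap: float = 0.12
    inter_cycle_gap: float = 0.35
    lobe_peak_gyr: float = 60.0
    trunk_scale: float = 0.55
    pelvis_scale: float = 0.50
    trunk_rms: float | None = None
    pelvis_rms: float | None = None
    thigh_rms_R: float | None = None
    thigh_rms_L: float | None = None
    noise_sd_gyr: float = 1.5
    lead_s: float = 1.5
    tail_s: float = 1.5
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise InvalidParamsError("n_cycles must be >= 1")
        if self.up_duration <= 0 or self.down_duration <= 0:
            raise InvalidParamsError("lobe durations must be positive")
        if self.inter_phase_gap <= 0 or self.inter_cycle_gap <= 0:
            raise InvalidParamsError("lobes must not overlap (gaps must be > 0)")
        if self.lobe_peak_gyr < 0 or self.noise_sd_gyr < 0:
            raise InvalidParamsError("amplitudes and noise SDs must be >= 0")


def generate_sts_trial(
    params: StsTrialParams | None = None,
    meta: TrialMeta | None = None,
) -> tuple[KinematicRecording, GroundTruth]:
    """Synthesize a sit-stand-sit trial with known cycle boundaries."""
    p = params or StsTrialParams()
    meta = meta or TrialMeta("synthetic", "control", "ST", "STS")

    cycles: list[tuple[float, float, float, float]] = []
    cursor = p.lead_s
    for _ in range(p.n_cycles):
        up_start = cursor
        up_end = up_start + p.up_duration
        down_start = up_end + p.inter_phase_gap
        down_end = down_start + p.down_duration
        cycles.append((up_start, up_end, down_start, down_end))
        cursor = down_end + p.inter_cycle_gap

    total_end = cycles[-1][3]
    n = int(round((total_end + p.tail_s) * p.fs)) + 1
    t = np.arange(n) / p.fs

    unit = np.zeros(n)
    for (us, ue, ds, de) in cycles:
        unit += _raised_cosine(t, us, ue - us, 1.0)
        unit += _raised_cosine(t, ds, de - ds, 1.0)

    active = (t >= cycles[0][0]) & (t <= total_end)
    rms_unit = float(np.sqrt(np.mean(unit[active] ** 2))) if active.any() else 0.0

    def _amp(target_rms: float | None, default_amp: float) -> float:
        if target_rms is None:
            return default_amp
        if rms_unit == 0.0:
            return 0.0
        return target_rms / rms_unit

    amp_thigh_L = _amp(p.thigh_rms_L, p.lobe_peak_gyr)
    amp_thigh_R = _amp(p.thigh_rms_R, p.lobe_peak_gyr)
    amp_trunk = _amp(p.trunk_rms, p.trunk_scale * p.lobe_peak_gyr)
    amp_pelvis = _amp(p.pelvis_rms, p.pelvis_scale * p.lobe_peak_gyr)

    ch = _blank_channels(n)
    ch["thigh_L"]["gyr"][:, 0] = amp_thigh_L * unit
    ch["thigh_R"]["gyr"][:, 0] = amp_thigh_R * unit
    ch["sternum"]["gyr"][:, 0] = amp_trunk * unit
    ch["sacrum"]["gyr"][:, 0] = amp_pelvis * unit

    rng = np.random.default_rng(p.seed)
    rec = _assemble(ch, meta, p.fs, rng, p.noise_sd_gyr, 0.05)

    total_time = total_end - cycles[0][0]
    boundaries = [b for cyc in cycles for b in cyc]
    truth = GroundTruth(
        events={"sts_bounds": boundaries},
        features={
            "total_time": total_time,
            "mean_cycle_time": total_time / p.n_cycles,
            "mean_up_time": p.up_duration,
            "mean_down_time": p.down_duration,
            "rms_thorax": amp_trunk * rms_unit,
            "rms_pelvis": amp_pelvis * rms_unit,
            "rms_thigh_R": amp_thigh_R * rms_unit,
            "rms_thigh_L": amp_thigh_L * rms_unit,
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# 10 m walk
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WalkTrialParams:
    """Parameters of one synthetic straight-line walking trial.

    Per stride and side: a toe-off peak at swing onset and a heel-strike
    peak ``swing_fraction * stride_duration`` later; the right side is
    offset from the left by half a stride.
    """

    distance_m: float = 10.0
    n_strides_per_side: int = 9
    stride_duration: float = 1.21
    swing_fraction: float = 0.38
    to_peak: float = 4.0
    hs_peak: float = 6.0
    noise_sd_acc: float = 0.15
    noise_sd_gyr: float = 1.5
    trunk_base_gyr: float = 10.0
    lead_s: float = 1.5
    tail_s: float = 1.5
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.swing_fraction < 1.0:
            raise InvalidParamsError("swing_fraction must be in (0, 1)")
        if not 0.4 <= self.stride_duration <= 3.0:
            raise InvalidParamsError("stride_duration must be in [0.4, 3] s")
        if self.n_strides_per_side < 2:
            raise InvalidParamsError("need at least 2 strides per side")
        if self.distance_m <= 0:
            raise InvalidParamsError("distance_m must be positive")
        if self.noise_sd_acc < 0 or self.noise_sd_gyr < 0:
            raise InvalidParamsError("noise SDs must be >= 0")
        swing_gap = self.swing_fraction * self.stride_duration
        stance_gap = (1.0 - self.swing_fraction) * self.stride_duration
        if min(swing_gap, stance_gap) < 0.08:
            raise InvalidParamsError(
                "toe-off and heel-strike peaks would be closer than 80 ms"
            )


def generate_walk_trial(
    params: WalkTrialParams | None = None,
    meta: TrialMeta | None = None,
) -> tuple[KinematicRecording, GroundTruth]:
    """Synthesize a 10 m walk with known heel-strike/toe-off times."""
    p = params or WalkTrialParams()
    meta = meta or TrialMeta("synthetic", "control", "ST", "10MWT")
    T = p.stride_duration
    swing = p.swing_fraction * T

    events: dict[str, list[float]] = {}
    for side, offset in (("L", 0.0), ("R", 0.5 * T)):
        to_times = p.lead_s + offset + np.arange(p.n_strides_per_side) * T
        hs_times = to_times + swing
        events[f"to_{side}"] = list(to_times)
        events[f"hs_{side}"] = list(hs_times)

    all_times = np.sort(np.concatenate([events[k] for k in events]))
    t_first, t_last = float(all_times[0]), float(all_times[-1])
    n = int(round((t_last + p.tail_s) * p.fs)) + 1
    t = np.arange(n) / p.fs

    ch = _blank_channels(n)
    for side in ("L", "R"):
        shank, foot = f"shank_{side}", f"foot_{side}"
        for tc in events[f"to_{side}"]:
            ch[shank]["acc"][:, 2] += _gaussian(t, tc, STEP_SIGMA_S, p.to_peak)
            ch[foot]["acc"][:, 2] += _gaussian(t, tc, STEP_SIGMA_S, 0.8 * p.to_peak)
        for tc in events[f"hs_{side}"]:
            ch[shank]["acc"][:, 2] += _gaussian(t, tc, STEP_SIGMA_S, p.hs_peak)
            ch[foot]["acc"][:, 2] += _gaussian(t, tc, STEP_SIGMA_S, 0.8 * p.hs_peak)
    ch["sternum"]["gyr"][:, 0] = _plateau(t, t_first, t_last, p.trunk_base_gyr)

    rng = np.random.default_rng(p.seed)
    rec = _assemble(ch, meta, p.fs, rng, p.noise_sd_gyr, p.noise_sd_acc)

    walk_time = t_last - t_first
    steps = 2 * p.n_strides_per_side  # one heel strike per step, both sides
    truth = GroundTruth(
        events=events,
        features={
            "walk_time": walk_time,
            "steps": float(steps),
            "cadence": 60.0 * steps / walk_time,
            "mean_swing_pct": p.swing_fraction,
            # With symmetric gait and stance = 1 - swing per side, exactly one
            # foot is in stance for a fraction 2*swing of each stride.
            "single_support_pct": 2.0 * p.swing_fraction,
            "gait_speed": p.distance_m / walk_time,
            "stride_duration": T,
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

Cell = tuple[float, float]  # (mean, sd)

#: Physiologic clipping bounds per drawn parameter (applied after +-3 SD
#: truncation) so that no draw can produce a degenerate trial.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "sit_to_stand": (0.5, 6.0),
    "walk_to_cone": (1.5, 15.0),
    "turn_cone": (0.6, 8.0),
    "walk_to_chair": (1.5, 15.0),
    "turn_and_sit": (1.0, 10.0),
    "steps_to_cone": (3.0, 15.0),
    "steps_to_chair": (3.0, 15.0),
    "up_duration": (0.6, 5.0),
    "down_duration": (0.6, 5.0),
    "rms_thorax": (0.5, 1e6),
    "rms_pelvis": (0.5, 1e6),
    "rms_thigh_R": (0.5, 1e6),
    "rms_thigh_L": (0.5, 1e6),
    "stride_duration": (0.6, 2.5),
    "swing_fraction": (0.15, 0.47),
    "steps": (8.0, 40.0),
}

_CELLS = ("control_ST", "control_DT", "stroke_ST", "stroke_DT")


@dataclass(frozen=True)
class CohortSpec:
    """Cell-level (group x cognitive load) parameter distributions.

    ``params[test][param][cell]`` is a ``(mean, sd)`` pair, with ``cell`` one
    of ``control_ST, control_DT, stroke_ST, stroke_DT``. Each subject is
    drawn in both conditions (repeated measures) with a shared subject-level
    random component of weight ``subject_corr``.
    """

    params: dict[str, dict[str, dict[str, Cell]]]
    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"control": 20, "stroke": 21}
    )
    subject_corr: float = 0.7
    empirical: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.params:
            raise InvalidSpecError("cohort spec has no tests")
        for test, pdict in self.params.items():
            if not pdict:
                raise InvalidSpecError(f"cohort spec for {test} has no parameters")
            for pname, cells in pdict.items():
                missing = [c for c in _CELLS if c not in cells]
                if missing:
                    raise InvalidSpecError(
                        f"{test}/{pname}: missing cells {missing}"
                    )
                for c, (_, sd) in cells.items():
                    if sd < 0:
                        raise InvalidSpecError(f"{test}/{pname}/{c}: SD must be >= 0")
        for g, ns in self.n_subjects.items():
            if ns < 2:
                raise InvalidSpecError(f"need >= 2 subjects per group, got {ns} for {g}")
        if not 0.0 <= self.subject_corr <= 1.0:
            raise InvalidSpecError("subject_corr must be in [0, 1]")


def _cells(
    control_st: float, control_dt: float, stroke_st: float, stroke_dt: float,
    sds: tuple[float, float, float, float],
) -> dict[str, Cell]:
    means = (control_st, control_dt, stroke_st, stroke_dt)
    return {c: (m, s) for c, m, s in zip(_CELLS, means, sds)}


def default_cohort_spec(
    n_control: int = 20,
    n_stroke: int = 21,
    seed: int = 0,
    tests: tuple[str, ...] = ("TUG", "STS", "10MWT"),
    rms_scale: float = 15.0,
) -> CohortSpec:
    """Cohort spec whose cell means/SDs follow the reference study's
    printed group x cognitive-load outcome table.

    ``rms_scale`` multiplies the printed sit-to-stand RMS angular-velocity
    cells (whose absolute units are uncertain — the printed ~1 deg/s is far
    below plausible trunk motion) up to a physiologically plausible scale;
    percent contrasts between cells are invariant to this factor.
    """
    params: dict[str, dict[str, dict[str, Cell]]] = {}
    if "TUG" in tests:
        params["TUG"] = {
            "sit_to_stand": _cells(1.37, 1.58, 1.84, 1.94, (0.5, 0.38, 0.82, 0.75)),
            "walk_to_cone": _cells(3.95, 4.34, 4.68, 5.27, (0.8, 0.78, 1.05, 1.07)),
            "turn_cone": _cells(1.75, 1.88, 1.87, 2.3, (0.48, 0.46, 0.46, 0.63)),
            "walk_to_chair": _cells(3.33, 3.72, 3.96, 4.71, (0.72, 0.75, 1.0, 1.32)),
            "turn_and_sit": _cells(2.94, 3.28, 3.79, 4.22, (0.57, 0.6, 0.92, 1.2)),
            "steps_to_cone": _cells(6.05, 6.15, 7.19, 7.57, (1.0, 1.04, 1.54, 1.54)),
            "steps_to_chair": _cells(4.8, 5.15, 6.05, 6.71, (0.83, 1.04, 1.56, 2.55)),
        }
    if "STS" in tests:
        r = rms_scale
        params["STS"] = {
            "up_duration": _cells(1.75, 1.85, 2.01, 2.06, (0.32, 0.42, 0.65, 0.63)),
            "down_duration": _cells(1.81, 1.96, 2.0, 2.06, (0.35, 0.45, 0.75, 0.79)),
            "rms_thorax": _cells(
                1.04 * r, 1.01 * r, 0.82 * r, 0.81 * r,
                (0.23 * r, 0.23 * r, 0.21 * r, 0.18 * r),
            ),
            "rms_pelvis": _cells(
                0.91 * r, 0.86 * r, 0.78 * r, 0.78 * r,
                (0.26 * r, 0.23 * r, 0.28 * r, 0.25 * r),
            ),
            "rms_thigh_R": _cells(
                1.03 * r, 0.97 * r, 0.97 * r, 0.95 * r,
                (0.21 * r, 0.21 * r, 0.24 * r, 0.21 * r),
            ),
            "rms_thigh_L": _cells(
                1.03 * r, 0.98 * r, 0.96 * r, 0.93 * r,
                (0.21 * r, 0.21 * r, 0.23 * r, 0.2 * r),
            ),
        }
    if "10MWT" in tests:
        params["10MWT"] = {
            "stride_duration": _cells(1.21, 1.27, 1.26, 1.38, (0.12, 0.13, 0.19, 0.21)),
            "swing_fraction": _cells(0.38, 0.37, 0.37, 0.35, (0.03, 0.02, 0.03, 0.04)),
            "steps": _cells(17.7, 18.8, 20.14, 21.57, (2.3, 2.63, 4.04, 4.42)),
        }
    return CohortSpec(
        params=params,
        n_subjects={"control": n_control, "stroke": n_stroke},
        seed=seed,
    )


def draw_cohort_params(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-trial parameter table of a cohort (no signals yet).

    One row per subject x condition x test, with the drawn parameter values
    in columns (NaN for parameters not used by that row's test) plus a
    deterministic per-trial ``trial_seed``. Reproducible: the same spec
    (including its seed) yields an identical table.

    With ``spec.empirical`` (the default) the standardized draws are centred
    within each group x condition cell before scaling, so the realized cell
    means reproduce the specified means exactly (up to truncation at the
    physiologic bounds) — the cohort's role is to deliver *known* cell-level
    conditions to the pipeline, not to add sampling error on top of them.
    Set ``empirical=False`` for plain i.i.d. truncated-normal sampling.
    """
    rng = np.random.default_rng(spec.seed)
    groups = sorted(spec.n_subjects)
    tests = sorted(spec.params)

    subjects: list[tuple[str, str]] = []
    for g in groups:
        tag = "ctrl" if g == "control" else "strk"
        subjects += [(f"{tag}{i + 1:03d}", g) for i in range(spec.n_subjects[g])]
    group_arr = np.array([g for _, g in subjects])
    n_all = len(subjects)

    rows: list[dict[str, object]] = [
        {
            "subject_id": sid,
            "group": group,
            "condition": cond,
            "test": test,
        }
        for test in tests
        for sid, group in subjects
        for cond in ("ST", "DT")
    ]

    rho = spec.subject_corr
    conds = ("ST", "DT")
    offset = 0
    for test in tests:
        pnames = sorted(spec.params[test])
        values: dict[str, np.ndarray] = {}
        for pname in pnames:
            z_subj = rng.standard_normal(n_all)
            z_cond = rng.standard_normal((n_all, 2))
            z = rho * z_subj[:, None] + np.sqrt(1.0 - rho**2) * z_cond
            if spec.empirical:
                for g in groups:
                    sel = group_arr == g
                    z[sel] -= z[sel].mean(axis=0, keepdims=True)
            z = np.clip(z, -3.0, 3.0)
            lo, hi = PARAM_BOUNDS.get(pname, (-np.inf, np.inf))
            vals = np.empty((n_all, 2))
            for ci, cond in enumerate(conds):
                for g in groups:
                    sel = group_arr == g
                    mean, sd = spec.params[test][pname][f"{g}_{cond}"]
                    vals[sel, ci] = mean + sd * z[sel, ci]
            values[pname] = np.clip(vals, lo, hi)
        for si in range(n_all):
            for ci in range(2):
                row = rows[offset + si * 2 + ci]
                for pname in pnames:
                    row[pname] = float(values[pname][si, ci])
        offset += n_all * 2

    df = pd.DataFrame(rows)
    # Deterministic per-trial seeds independent of row content.
    df["trial_seed"] = (
        np.arange(len(df), dtype=np.int64) * 9973 + int(spec.seed) * 131071
    ) % (2**31 - 1)
    return df


def trial_from_row(row: pd.Series) -> tuple[KinematicRecording, GroundTruth]:
    """Synthesize the trial described by one row of a cohort parameter table.

    Raises :class:`~mobiseg.errors.InvalidParamsError` when the drawn
    parameter combination is infeasible (e.g. a cadence outside the
    physiologic range); cohort consumers should record such trials as failed
    rather than aborting.
    """
    meta = TrialMeta(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        condition=str(row["condition"]),
        test=str(row["test"]),
    )
    seed = int(row["trial_seed"])
    if row["test"] == "TUG":

        def _steps(count: float, duration: float) -> int:
            # Steps and section durations are drawn marginally, so rare joint
            # draws can imply an impossible cadence; clamp the step count to
            # the feasible band for the drawn duration.
            lo = max(int(np.ceil(0.31 * duration)), 2)
            hi = max(int(np.floor(2.99 * duration)), lo)
            return int(np.clip(round(count), lo, hi))

        params = TugTrialParams(
            phase_durations=(
                float(row["sit_to_stand"]),
                float(row["walk_to_cone"]),
                float(row["turn_cone"]),
                float(row["walk_to_chair"]),
                float(row["turn_and_sit"]),
            ),
            steps_to_cone=_steps(float(row["steps_to_cone"]), float(row["walk_to_cone"])),
            steps_to_chair=_steps(float(row["steps_to_chair"]), float(row["walk_to_chair"])),
            seed=seed,
        )
        return generate_tug_trial(params, meta)
    if row["test"] == "STS":
        params = StsTrialParams(
            up_duration=float(row["up_duration"]),
            down_duration=float(row["down_duration"]),
            trunk_rms=float(row["rms_thorax"]),
            pelvis_rms=float(row["rms_pelvis"]),
            thigh_rms_R=float(row["rms_thigh_R"]),
            thigh_rms_L=float(row["rms_thigh_L"]),
            seed=seed,
        )
        return generate_sts_trial(params, meta)
    if row["test"] == "10MWT":
        params = WalkTrialParams(
            stride_duration=float(row["stride_duration"]),
            swing_fraction=float(row["swing_fraction"]),
            n_strides_per_side=max(int(round(float(row["steps"]) / 2.0)), 2),
            seed=seed,
        )
        return generate_walk_trial(params, meta)
    raise InvalidSpecError(f"unknown test {row['test']!r}")


def generate_cohort(
    spec: CohortSpec,
) -> tuple[Iterator[tuple[KinematicRecording, GroundTruth]], pd.DataFrame]:
    """Generate a repeated-measures cohort.

    Returns ``(trials, table)`` where ``table`` is the drawn parameter table
    (one row per trial, see :func:`draw_cohort_params`) and ``trials`` lazily
    yields ``(recording, ground_truth)`` in the table's row order.
    Recordings are synthesized on demand because a large cohort does not fit
    comfortably in memory all at once.
    """
    table = draw_cohort_params(spec)

    def _iter() -> Iterator[tuple[KinematicRecording, GroundTruth]]:
        for _, row in table.iterrows():
            yield trial_from_row(row)

    return _iter(), table
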