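"""Signal conditioning shared by all instrumented clinical tests.

Domain containers (sensor streams, whole-trial recordings, trial metadata)
plus the four primitive operations every detector builds on:

* :func:`resultant_magnitude` — Euclidean norm of a 3-axis channel,
* :func:`lowpass_filter` — 4th-order low-pass Butterworth (5 Hz default),
  zero-phase by default so event times carry no filter lag,
* :func:`rms` — root-mean-square of a scalar series,
* :func:`onset_offset` — baseline-referenced movement onset/offset detection.

Conventions: all times are seconds from recording start, sample indices are
0-based, ``t = i / fs``. Units are kept exactly as ingested (deg/s for angular
velocity, m/s^2 for linear acceleration); missing or NaN samples are a hard
error — no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal as _sig

from .errors import (
    InsufficientDataError,
    InvalidSignalError,
    InvalidSpecError,
    NoMovementError,
)

#: The eight sensor locations of the lower-body-and-trunk configuration.
LOCATIONS: tuple[str, ...] = (
    "foot_L",
    "foot_R",
    "shank_L",
    "shank_R",
    "thigh_L",
    "thigh_R",
    "sacrum",
    "sternum",
)

GROUPS = frozenset({"stroke", "control"})
CONDITIONS = frozenset({"ST", "DT"})
TESTS = frozenset({"TUG", "STS", "10MWT"})

#: Standard gravity magnitude, m/s^2 — the resting baseline of a resultant
#: linear-acceleration channel.
GRAVITY = 9.81


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification (order 4, 5 Hz cut-off default).

    ``zero_phase`` selects forward-backward filtering so that detected event
    times are not biased by group delay; set it to ``False`` for a causal
    single-pass filter.
    """

    order: int = 4
    cutoff_hz: float = 5.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidSpecError(f"filter order must be >= 1, got {self.order}")
        if self.cutoff_hz <= 0:
            raise InvalidSpecError(f"cutoff must be positive, got {self.cutoff_hz}")


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one trial: who, which group, which load, which test."""

    subject_id: str
    group: str
    condition: str
    test: str

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise InvalidSpecError("subject_id must be non-empty")
        if self.group not in GROUPS:
            raise InvalidSpecError(f"group must be one of {sorted(GROUPS)}, got {self.group!r}")
        if self.condition not in CONDITIONS:
            raise InvalidSpecError(
                f"condition must be one of {sorted(CONDITIONS)}, got {self.condition!r}"
            )
        if self.test not in TESTS:
            raise InvalidSpecError(f"test must be one of {sorted(TESTS)}, got {self.test!r}")


@dataclass
class SensorStream:
    """One IMU's synchronized 3-axis angular velocity and linear acceleration.

    ``ang_vel`` is in deg/s and ``lin_acc`` in m/s^2, both shaped ``(n, 3)``
    and sampled at ``fs`` Hz (100 Hz in the reference protocol).
    """

    location: str
    ang_vel: np.ndarray
    lin_acc: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise InvalidSpecError(
                f"location must be one of {LOCATIONS}, got {self.location!r}"
            )
        if self.fs <= 0:
            raise InvalidSpecError(f"fs must be positive, got {self.fs}")
        self.ang_vel = _as_vec3_series(self.ang_vel, "ang_vel")
        self.lin_acc = _as_vec3_series(self.lin_acc, "lin_acc")
        n = len(self.ang_vel)
        if len(self.lin_acc) != n:
            raise InvalidSignalError(
                f"{self.location}: ang_vel ({n}) and lin_acc ({len(self.lin_acc)}) "
                "lengths differ"
            )
        if n < 2 * self.fs:
            raise InsufficientDataError(
                f"{self.location}: stream must cover at least 2 s "
                f"({int(2 * self.fs)} samples), got {n}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.ang_vel)


@dataclass
class KinematicRecording:
    """All eight sensor streams of one trial plus its metadata."""

    streams: Mapping[str, SensorStream]
    meta: TrialMeta

    def __post_init__(self) -> None:
        missing = [loc for loc in LOCATIONS if loc not in self.streams]
        if missing:
            raise InvalidSpecError(f"recording is missing sensor streams: {missing}")
        ref = self.streams[LOCATIONS[0]]
        for loc in LOCATIONS:
            s = self.streams[loc]
            if s.fs != ref.fs:
                raise InvalidSpecError("all streams must share the sampling frequency")
            if s.n_samples != ref.n_samples:
                raise InvalidSpecError("all streams must share the sample count")

    @property
    def fs(self) -> float:
        return self.streams[LOCATIONS[0]].fs

    @property
    def n_samples(self) -> int:
        return self.streams[LOCATIONS[0]].n_samples

    @property
    def duration(self) -> float:
        """Trial duration in seconds (``n_samples / fs``)."""
        return self.n_samples / self.fs

    # Convenience accessors used by every detector -------------------------

    def gyr_magnitude(self, location: str) -> np.ndarray:
        """Resultant angular velocity of one sensor, deg/s."""
        return resultant_magnitude(self.streams[location].ang_vel)

    def acc_magnitude(self, location: str) -> np.ndarray:
        """Resultant linear acceleration of one sensor, m/s^2."""
        return resultant_magnitude(self.streams[location].lin_acc)


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


def _as_vec3_series(samples, name: str = "samples") -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InvalidSignalError(f"{name} must have shape (n, 3), got {arr.shape}")
    if not np.isfinite(arr).all():
        raise InvalidSignalError(f"{name} contains non-finite components")
    return arr


def resultant_magnitude(samples) -> np.ndarray:
    """Euclidean norm of each 3-axis sample.

    Invariant under axis permutation and sign flips; output is non-negative
    and has the same length as the input.
    """
    arr = _as_vec3_series(samples)
    return np.sqrt(np.einsum("ij,ij->i", arr, arr))


def lowpass_filter(x, spec: FilterSpec | None = None, fs: float = 100.0) -> np.ndarray:
    """Low-pass Butterworth filter of a scalar series.

    Zero-phase (forward-backward) by default: a symmetric input maps to a
    symmetric output and event times keep no group delay. The DC component is
    preserved (unit gain at 0 Hz).
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidSignalError(f"expected a 1-D series, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise InvalidSignalError("series contains non-finite samples")
    if spec.cutoff_hz >= fs / 2:
        raise InvalidSpecError(
            f"cutoff {spec.cutoff_hz} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    if len(x) <= 3 * (spec.order + 1):
        raise InsufficientDataError(
            f"series of length {len(x)} too short for an order-{spec.order} filter"
        )
    sos = _sig.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs, output="sos")
    if spec.zero_phase:
        return _sig.sosfiltfilt(sos, x)
    return _sig.sosfilt(sos, x)


def rms(x) -> float:
    """Root-mean-square of a scalar series: ``sqrt(mean(x**2))``."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("rms of an empty series is undefined")
    if not np.isfinite(x).all():
        raise InvalidSignalError("series contains non-finite samples")
    return float(np.sqrt(np.mean(np.square(x))))


def onset_offset(
    x,
    fs: float,
    baseline_window_s: float = 0.5,
    k_sigma: float = 3.0,
    sustain_s: float = 0.1,
    min_delta: float = 0.0,
) -> tuple[int, int]:
    """Movement onset and offset of a scalar series by baseline thresholding.

    The threshold is ``baseline_mean + max(k_sigma * baseline_sd, min_delta)``
    where the baseline statistics come from the first ``baseline_window_s``
    seconds (assumed quiescent). The onset is the first index at which the
    series exceeds the threshold for at least ``sustain_s`` seconds; the
    offset is the last index of the last such sustained excursion.

    ``min_delta`` puts an absolute floor under the threshold so that a
    noise-free (zero-variance) baseline does not yield a zero threshold.

    Returns ``(onset_index, offset_index)``; raises
    :class:`~mobiseg.errors.NoMovementError` if no sustained excursion exists.
    """
    x = np.asarray(x, dtype=float)
    n_base = int(round(baseline_window_s * fs))
    if len(x) <= n_base or n_base < 1:
        raise InsufficientDataError(
            f"series of length {len(x)} shorter than the baseline window "
            f"({n_base} samples)"
        )
    base = x[:n_base]
    thr = float(np.mean(base)) + max(k_sigma * float(np.std(base)), min_delta)
    sustain = max(int(round(sustain_s * fs)), 1)

    above = x > thr
    if not above.any():
        raise NoMovementError("signal never exceeds the baseline threshold")

    # Runs of consecutive supra-threshold samples.
    padded = np.concatenate(([0], above.astype(np.int8), [0]))
    d = np.diff(padded)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive
    long_enough = (run_ends - run_starts) >= sustain
    if not long_enough.any():
        raise NoMovementError(
            f"no supra-threshold excursion sustained for {sustain_s} s"
        )
    onset = int(run_starts[long_enough][0])
    offset = int(run_ends[long_enough][-1]) - 1
    return onset, offset


# ---------------------------------------------------------------------------
# Bump-edge estimation (shared by the TUG and STS detectors)
# ---------------------------------------------------------------------------


def refine_peak(x: np.ndarray, idx: int, fs: float) -> tuple[float, float]:
    """Sub-sample peak location by parabolic interpolation.

    Returns ``(time_s, height)``. Falls back to the sample itself at the
    series edges or when the three-point neighbourhood is not concave.
    """
    if idx <= 0 or idx >= len(x) - 1:
        return idx / fs, float(x[idx])
    y0, y1, y2 = float(x[idx - 1]), float(x[idx]), float(x[idx + 1])
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return idx / fs, y1
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = y1 - 0.25 * (y0 - y2) * delta
    return (idx + delta) / fs, height


@dataclass(frozen=True)
class BumpBounds:
    """Half-width-based estimate of a convex bump's extent, seconds."""

    onset: float
    apex: float
    end: float


def bump_bounds(
    x: np.ndarray,
    fs: float,
    peak_idx: int,
    base: float = 0.0,
) -> BumpBounds:
    """Estimate a convex bump's onset/apex/end from its half-amplitude width.

    For a raised-cosine bump rising from ``base``, the two half-amplitude
    crossings sit at one quarter and three quarters of the bump's duration,
    so its full width is twice the width at half amplitude and its edges lie
    half a half-width outside the crossings:

        onset = t_left - w/2,  end = t_right + w/2,  w = t_right - t_left.

    Both crossings are located on the steepest part of the bump, which makes
    this estimator far more noise-robust than thresholding near the base
    (where the slope vanishes) or mirroring about the apex (which is flat
    and therefore poorly localized under noise).
    """
    _, height = refine_peak(x, peak_idx, fs)
    half = base + 0.5 * (height - base)

    i = peak_idx
    while i > 0 and x[i] >= half:
        i -= 1
    if x[i] >= half:
        t_left = i / fs
    else:
        frac = (half - x[i]) / (x[i + 1] - x[i])
        t_left = (i + frac) / fs

    j = peak_idx
    last = len(x) - 1
    while j < last and x[j] >= half:
        j += 1
    if x[j] >= half:
        t_right = j / fs
    else:
        frac = (half - x[j]) / (x[j - 1] - x[j])
        t_right = (j - frac) / fs

    w = t_right - t_left
    return BumpBounds(
        onset=max(t_left - 0.5 * w, 0.0),
        apex=0.5 * (t_left + t_right),
        end=min(t_right + 0.5 * w, last / fs),
    )
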