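"""Basic diagnostic plots of detected segmentations.

These are quick-look figures for the visual-confirmation step (checking
that detected events line up with the raw signals), not publication
graphics.
"""

from __future__ import annotations

import numpy as np

from .gait import GaitEvents
from .preprocess import FilterSpec, KinematicRecording, lowpass_filter
from .sts import StsCycles
from .tug import TugEvents

__all__ = ["plot_tug_segmentation", "plot_sts_segmentation", "plot_gait_events"]


def _time(rec: KinematicRecording) -> np.ndarray:
    return np.arange(rec.n_samples) / rec.fs


def plot_tug_segmentation(rec: KinematicRecording, events: TugEvents, ax=None):
    """Trunk angular velocity and foot acceleration with T1..T6 markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    t = _time(rec)
    spec = FilterSpec()
    ax.plot(t, lowpass_filter(rec.gyr_magnitude("sternum"), spec, rec.fs),
            label="trunk |gyr| (deg/s)")
    ax.plot(t, lowpass_filter(rec.acc_magnitude("foot_R"), spec, rec.fs),
            label="right foot |acc| (m/s$^2$)", alpha=0.6)
    for i, ev in enumerate(events.as_tuple(), start=1):
        ax.axvline(ev, color="k", ls="--", lw=0.8)
        ax.annotate(f"T{i}", (ev, ax.get_ylim()[1]), ha="center", fontsize=8)
    ax.set_xlabel("time (s)")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_sts_segmentation(rec: KinematicRecording, cycles: StsCycles, ax=None):
    """Mean thigh angular velocity with up/down lobe boundaries."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    t = _time(rec)
    spec = FilterSpec()
    x = 0.5 * (
        lowpass_filter(rec.gyr_magnitude("thigh_L"), spec, rec.fs)
        + lowpass_filter(rec.gyr_magnitude("thigh_R"), spec, rec.fs)
    )
    ax.plot(t, x, label="mean thigh |gyr| (deg/s)")
    for us, ue, ds, de in cycles.cycles:
        ax.axvspan(us, ue, color="tab:green", alpha=0.2)
        ax.axvspan(ds, de, color="tab:orange", alpha=0.2)
    ax.set_xlabel("time (s)")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_gait_events(rec: KinematicRecording, events: GaitEvents, ax=None):
    """Shank accelerations with detected TO/HS markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    t = _time(rec)
    spec = FilterSpec()
    for side, color in (("L", "tab:blue"), ("R", "tab:red")):
        x = lowpass_filter(rec.acc_magnitude(f"shank_{side}"), spec, rec.fs)
        ax.plot(t, x, color=color, alpha=0.7, label=f"shank {side} |acc|")
        for tt in getattr(events, f"to_{side}"):
            ax.axvline(tt, color=color, ls=":", lw=0.8)
        for tt in getattr(events, f"hs_{side}"):
            ax.axvline(tt, color=color, ls="--", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.legend(loc="upper right", fontsize=8)
    return ax
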