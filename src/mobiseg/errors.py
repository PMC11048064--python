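"""Exception hierarchy for mobiseg.

All package-raised errors derive from :class:`MobisegError` so callers can
catch everything from one base. Errors that reflect bad *inputs* additionally
derive from ``ValueError``; errors that reflect a *failed analysis step*
(nothing wrong with the call, the data just did not support the operation)
derive from ``RuntimeError``.
"""


class MobisegError(Exception):
    """Base class for all mobiseg errors."""


class InvalidSignalError(MobisegError, ValueError):
    """A signal contains non-finite samples or has an invalid shape."""


class InsufficientDataError(MobisegError, ValueError):
    """A series/table is too short or too small for the requested operation."""


class InvalidSpecError(MobisegError, ValueError):
    """A filter or pipeline specification is internally inconsistent."""


class InvalidParamsError(MobisegError, ValueError):
    """Synthetic-trial parameters are outside their physiologic bounds."""


class InvalidWindowError(MobisegError, ValueError):
    """A requested analysis window is empty, reversed or too short."""


class NoMovementError(MobisegError, RuntimeError):
    """No movement onset could be detected in the signal."""


class SegmentationError(MobisegError, RuntimeError):
    """Automatic segmentation failed; the trial needs manual review."""


class InsufficientGaitError(SegmentationError):
    """Fewer than two strides detected on a side, or events on one side only."""


class UnbalancedDesignError(MobisegError, ValueError):
    """A subject is missing one of the repeated-measures conditions."""


class DegenerateDataError(MobisegError, ValueError):
    """The response has zero variance; the statistic is undefined."""


class UndefinedContrastError(MobisegError, ValueError):
    """A percent contrast is undefined (zero or non-positive reference)."""


class SchemaError(MobisegError, ValueError):
    """A CSV/YAML file does not match the declared column/key schema."""


class CorruptFileError(MobisegError, ValueError):
    """A recording file is structurally broken (e.g. non-monotone time)."""


class PipelineError(MobisegError, RuntimeError):
    """The end-to-end pipeline could not produce any usable output."""
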