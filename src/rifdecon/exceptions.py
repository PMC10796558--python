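"""Exception hierarchy for rifdecon.

All package errors derive from :class:`RifdeconError` so callers can catch
pipeline failures with a single except clause; the voxelwise driver converts
them into NaN map entries rather than aborting a run.
"""


class RifdeconError(Exception):
    """Base class for all rifdecon errors."""


class GridMismatchError(RifdeconError):
    """Two time series do not share the same time grid."""


class TooShortSeriesError(RifdeconError):
    """A time series is too short for the requested operation."""


class InsufficientTailError(RifdeconError):
    """Too few strictly positive residue samples in the tail window."""


class NonPhysicalSolutionError(RifdeconError):
    """A derived physiological quantity is outside the physical domain."""


class OverparameterizedError(RifdeconError):
    """Spline basis has more degrees of freedom than data points."""


class SingularSystemError(RifdeconError):
    """The stacked (design, penalty) system is rank deficient."""


class NoInputSignalError(RifdeconError):
    """The arterial input function carries no signal."""


class LowSignalError(RifdeconError):
    """Tissue curve indistinguishable from baseline noise (voxel masked)."""


class InvalidShiftError(RifdeconError):
    """Requested time shift exceeds the series window."""


class SchemaError(RifdeconError):
    """A sidecar or table file does not match the expected schema."""


class FitFailureError(RifdeconError):
    """All optimizer starts failed to converge."""


class DegenerateLCurveWarning(UserWarning):
    """L-curve norms are non-monotone beyond tolerance; smoothed fallback used."""


class DelayBoundWarning(UserWarning):
    """Delay estimate hit the search bound."""


class PartialVolumeWarning(UserWarning):
    """AIF mask touches the image border (partial-volume suspicion)."""
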