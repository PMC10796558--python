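"""Arterial input function extraction and preprocessing.

The AIF is image-derived: a mean over central voxels of the descending
aorta, large enough to be free of partial-volume effects.  Framed values
are upsampled to the 1-s grid the deconvolution runs on using a
shape-preserving (monotone piecewise-cubic) interpolant, which cannot
overshoot the frame values at the transition from 1-s to longer frames.

For tracers with plasma redistribution or radiometabolites the whole-blood
curve is converted to an effective parent-plasma input by multiplying with
user-supplied plasma-to-blood and parent-fraction curves (published values;
identity curves leave the AIF untouched, as appropriate for water and FDG).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .exceptions import PartialVolumeWarning, SchemaError
from .timecourse import FrameSchedule, TimeActivityCurve

__all__ = [
    "CorrectionCurve",
    "FramedCurve",
    "extract_aif",
    "resample_to_1s",
    "apply_blood_corrections",
]


@dataclass(frozen=True)
class CorrectionCurve:
    """Unitless ratio vs time: plasma-to-blood ratio or parent fraction."""

    t: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise SchemaError("correction curve t and value must match")
        if np.any(np.diff(t) <= 0):
            raise SchemaError("correction curve times must increase")
        if np.any(v <= 0) or np.any(v > 3):
            raise SchemaError("correction values must lie in (0, 3]")

    @classmethod
    def identity(cls) -> "CorrectionCurve":
        return cls(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    @classmethod
    def from_tsv(cls, path: str) -> "CorrectionCurve":
        df = pd.read_csv(path, sep="\t")
        for col in ("time_s", "value"):
            if col not in df.columns:
                raise SchemaError(f"correction TSV missing column {col!r}")
        return cls(df["time_s"].to_numpy(float), df["value"].to_numpy(float))

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation within the table, end values held outside."""
        return np.interp(t, self.t, self.value)


@dataclass(frozen=True)
class FramedCurve:
    """Per-frame values stamped at frame mid-times (seconds)."""

    mid_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mid_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "mid_times", m)
        object.__setattr__(self, "values", v)
        if m.shape != v.shape or m.ndim != 1:
            raise SchemaError("mid_times and values must be 1-D and equal length")
        if np.any(np.diff(m) <= 0):
            if np.any(np.diff(m) == 0):
                raise SchemaError("duplicate frame mid-times")
            raise SchemaError("frame mid-times must increase")


def extract_aif(voxels: np.ndarray, mask: np.ndarray,
                schedule: FrameSchedule) -> FramedCurve:
    """Per-frame mean over the mask voxels of a 4-D (x, y, z, frame) array."""
    voxels = np.asarray(voxels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != voxels.shape[:3]:
        raise SchemaError("mask shape does not match image")
    if not mask.any():
        raise SchemaError("empty AIF mask")
    if voxels.shape[3] != schedule.n_frames:
        raise SchemaError("frame count does not match schedule")
    border = np.zeros_like(mask)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    if np.any(mask & border):
        warnings.warn("AIF mask touches the image border; partial-volume "
                      "contamination possible", PartialVolumeWarning,
                      stacklevel=2)
    series = voxels[mask].mean(axis=0)
    return FramedCurve(schedule.mid_times, series)


def resample_to_1s(framed: FramedCurve) -> TimeActivityCurve:
    """Upsample framed samples to a 1-s grid from t = 0 to the last mid-time.

    Monotone piecewise-cubic (PCHIP) interpolation between mid-times, which
    preserves local monotonicity and cannot overshoot the data range within
    an interval; times before the first mid-time are zero-filled (pre-bolus).
    """
    if framed.mid_times.size < 3:
        raise SchemaError("need at least 3 frames to resample")
    tgrid = np.arange(0.0, np.floor(framed.mid_times[-1]) + 0.5, 1.0)
    interp = PchipInterpolator(framed.mid_times, framed.values,
                               extrapolate=False)
    values = interp(tgrid)
    values[tgrid < framed.mid_times[0]] = 0.0
    values = np.nan_to_num(values, nan=0.0)
    return TimeActivityCurve(tgrid, values)


def apply_blood_corrections(aif: TimeActivityCurve,
                            p2b: CorrectionCurve | None = None,
                            parent: CorrectionCurve | None = None,
                            ) -> TimeActivityCurve:
    """Whole blood -> effective parent-plasma input.

    c_corrected(t) = c(t) * p2b(t) * parent(t); omitted curves default to
    identity (no correction, as used for water and FDG).
    """
    p2b = p2b if p2b is not None else CorrectionCurve.identity()
    parent = parent if parent is not None else CorrectionCurve.identity()
    factor = p2b.at(aif.t) * parent.at(aif.t)
    return aif.with_values(aif.c * factor)
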