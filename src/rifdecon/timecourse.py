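"""Core time-series containers: frame schedules and time-activity curves.

A dynamic PET acquisition is a sequence of contiguous frames of varying
duration (e.g. forty 1-s frames over the bolus passage, lengthening to
minutes late in the scan).  :class:`FrameSchedule` captures that timing;
:class:`TimeActivityCurve` holds an activity-concentration series on a
uniform grid (after upsampling, usually 1 s), which is what the
deconvolution machinery consumes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, SchemaError

__all__ = ["FrameSchedule", "TimeActivityCurve", "read_tac_tsv", "write_tac_tsv"]


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame start times and durations, in seconds.

    Frames must be contiguous and non-overlapping:
    ``starts[i+1] == starts[i] + durations[i]``.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise SchemaError("starts and durations must be 1-D and equal length")
        if starts.size == 0:
            raise SchemaError("empty frame schedule")
        if np.any(durations <= 0):
            raise SchemaError("frame durations must be positive")
        expected = starts[:-1] + durations[:-1]
        if not np.allclose(starts[1:], expected, rtol=0, atol=1e-9):
            raise SchemaError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_blocks(cls, blocks: list[tuple[int, float]], t0: float = 0.0) -> "FrameSchedule":
        """Build from ``[(count, duration_s), ...]`` blocks, e.g. ``[(40, 1), (5, 4)]``."""
        durations = np.concatenate([np.full(int(n), float(d)) for n, d in blocks])
        starts = t0 + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times in seconds; the time stamp of a framed sample."""
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        """Total measurement duration T in seconds."""
        return float(self.durations.sum())

    def to_json(self, path: str) -> None:
        payload = {
            "FrameTimesStart": self.starts.tolist(),
            "FrameDuration": self.durations.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "FrameSchedule":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("FrameTimesStart", "FrameDuration"):
            if key not in payload:
                raise SchemaError(f"frame schedule JSON missing key {key!r}")
        return cls(np.asarray(payload["FrameTimesStart"], dtype=float),
                   np.asarray(payload["FrameDuration"], dtype=float))

    def frame_average(self, t: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Average a finely sampled curve ``c(t)`` over each frame window."""
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=float)
        out = np.empty(self.n_frames)
        for i, (s, e) in enumerate(zip(self.starts, self.ends)):
            sel = (t >= s) & (t < e)
            if not np.any(sel):
                raise GridMismatchError(
                    f"frame [{s}, {e}) s contains no samples of the fine grid")
            out[i] = c[sel].mean()
        return out


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration (kBq/mL) on a strictly uniform time grid.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing with constant spacing.
    c : ndarray
        Activity concentration per sample.
    dt : float
        Grid spacing in seconds (derived, stored for convenience).
    """

    t: np.ndarray
    c: np.ndarray
    dt: float = field(default=0.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "c", c)
        if t.ndim != 1 or t.shape != c.shape:
            raise GridMismatchError("t and c must be 1-D arrays of equal length")
        if t.size < 2:
            raise GridMismatchError("need at least two samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise GridMismatchError("time grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise GridMismatchError("time grid must be uniform")
        if not np.all(np.isfinite(c)):
            raise GridMismatchError("activity values must be finite")
        object.__setattr__(self, "dt", float(steps[0]))

    def __len__(self) -> int:
        return self.t.size

    def same_grid(self, other: "TimeActivityCurve") -> bool:
        return (len(self) == len(other)
                and np.allclose(self.t, other.t, rtol=0, atol=1e-9))

    def require_same_grid(self, other: "TimeActivityCurve") -> None:
        if not self.same_grid(other):
            raise GridMismatchError("time grids differ")

    def with_values(self, c: np.ndarray) -> "TimeActivityCurve":
        return TimeActivityCurve(self.t, np.asarray(c, dtype=float))

    def integral(self) -> float:
        """Trapezoidal time integral, kBq s/mL."""
        return float(np.trapezoid(self.c, self.t))


def read_tac_tsv(path: str) -> TimeActivityCurve:
    """Read a TAC from TSV with columns ``time_s`` and ``activity_kBq_per_mL``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "activity_kBq_per_mL"):
        if col not in df.columns:
            raise SchemaError(f"TAC TSV missing column {col!r}")
    return TimeActivityCurve(df["time_s"].to_numpy(float),
                             df["activity_kBq_per_mL"].to_numpy(float))


def write_tac_tsv(tac: TimeActivityCurve, path: str) -> None:
    pd.DataFrame({"time_s": tac.t, "activity_kBq_per_mL": tac.c}).to_csv(
        path, sep="\t", index=False)
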