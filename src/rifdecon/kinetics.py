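"""Forward tracer-kinetic model and physiology derived from a residue function.

The fundamental model of indicator-dilution kinetics relates the tissue
time-activity curve to the arterial input by a causal convolution,

    C_tis(t) = f * C_a(t) (x) RIF(t),        R(t) = f RIF(t),

where ``f`` is perfusion (blood flow per unit tissue volume) and the residue
impulse response function RIF(t) is the fraction of an instantaneously
delivered tracer bolus still present in the tissue ``t`` seconds later
(RIF(0) = 1, non-increasing for a physical system).  On a uniform grid the
convolution becomes a lower-triangular Toeplitz system ``C = dt A R``.

From a recovered ``R`` the module derives:

* perfusion (CBF) as the peak of ``R`` (equal to R(0) in the ideal case but
  robust to small regularization/delay shifts of the peak),
* the extraction fraction E from a log-linear fit to the slow tail of RIF,
* the unidirectional influx constant K1 = E x CBF,
* the mean transit time MTT as the area under RIF (with an analytic
  mono-exponential extension beyond the scan when the tail decays), and
* the distribution volume vd, either as the ratio of the tissue and arterial
  curve integrals (when the tissue curve has washed out by the end of the
  scan) or as CBF x MTT.

Internal units are seconds and s^-1; perfusion is reported in the
conventional mL blood min^-1 (100 mL tissue)^-1 (factor 6000).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.signal

from .config import PER_SECOND_TO_ML_MIN_100ML, DEFAULT_CONFIG, DeconvolutionConfig
from .exceptions import (
    GridMismatchError,
    InsufficientTailError,
    NonPhysicalSolutionError,
    TooShortSeriesError,
)
from .timecourse import TimeActivityCurve

__all__ = [
    "ResidueFunction",
    "TailFit",
    "PhysioParams",
    "discrete_convolve",
    "build_toeplitz",
    "rif_mtt",
    "estimate_extraction",
    "derive_physiology",
]


@dataclass(frozen=True)
class ResidueFunction:
    """Perfusion-scaled residue function R(t) = f RIF(t) on a uniform grid.

    ``r`` is in s^-1 (internal perfusion units); ``f = max(r)`` is the
    perfusion scale and ``rif = r / f`` the unit-peak residue function.
    """

    t: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise GridMismatchError("t and r must be 1-D arrays of equal length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "r", r)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def f(self) -> float:
        """Perfusion scale, s^-1: the peak of R."""
        return float(np.max(self.r))

    @property
    def rif(self) -> np.ndarray:
        """Unit-peak residue function; max(rif) == 1 exactly."""
        f = self.f
        if f <= 0:
            raise NonPhysicalSolutionError("residue function has non-positive peak")
        return self.r / f

    @property
    def peak_time(self) -> float:
        return float(self.t[int(np.argmax(self.r))])

    def clipped_fraction(self) -> float:
        """Fraction of samples below zero (diagnostic for regularized solutions)."""
        return float(np.mean(self.r < 0))

    def clipped(self) -> "ResidueFunction":
        """Copy with negative samples set to zero (used for physiology)."""
        return ResidueFunction(self.t, np.maximum(self.r, 0.0))


@dataclass(frozen=True)
class TailFit:
    """Log-linear fit ln(rif) ~ intercept + slope * t over a tail window."""

    slope: float        # s^-1, negative for decaying tails
    intercept: float    # ln(rif) extrapolated to t = 0
    t_start: float
    t_stop: float
    n_points: int

    @property
    def decay_rate(self) -> float:
        """Positive decay rate -slope, s^-1."""
        return -self.slope


@dataclass(frozen=True)
class PhysioParams:
    """Physiological summary of one ROI or voxel.

    Units: cbf and k1 in mL min^-1 (100 mL)^-1, e unitless, mtt seconds,
    vd in mL (100 mL)^-1 (NaN when undefined, e.g. trapped tracers),
    delta_t seconds.
    """

    cbf: float
    e: float
    k1: float
    mtt: float
    vd: float
    delta_t: float = 0.0
    clipped_fraction: float = 0.0
    tailfit: Optional[TailFit] = None

    def as_dict(self) -> dict[str, float]:
        return {
            "cbf": self.cbf, "e": self.e, "k1": self.k1,
            "mtt": self.mtt, "vd": self.vd, "delta_t": self.delta_t,
            "clipped_fraction": self.clipped_fraction,
        }


def k1_from_extraction(e: float, cbf: float) -> float:
    """Unidirectional influx constant K1 = E x f (both in reported units)."""
    return e * cbf


def discrete_convolve(aif: TimeActivityCurve, kernel: ResidueFunction) -> TimeActivityCurve:
    """Causal discrete convolution C_tis[i] = dt * sum_{j<=i} C_a[i-j] R[j].

    This is the forward model: tissue activity from the arterial input and
    the perfusion-scaled residue function, both on the same uniform grid.
    """
    if len(aif) != kernel.t.size or not np.allclose(aif.t, kernel.t, atol=1e-9):
        raise GridMismatchError("AIF and kernel must share the time grid")
    full = scipy.signal.fftconvolve(aif.c, kernel.r)[: len(aif)]
    return aif.with_values(aif.dt * full)


def build_toeplitz(aif: TimeActivityCurve) -> np.ndarray:
    """Lower-triangular Toeplitz matrix A with A[i, j] = C_a[i-j] for j <= i.

    The grid-spacing factor dt is *not* folded into A; the forward model is
    ``C = dt A R``.  Keeping dt explicit means a change of time units cannot
    silently rescale the regularization weight downstream.
    """
    if len(aif) < 3:
        raise TooShortSeriesError("need at least 3 samples to build the system")
    return scipy.linalg.toeplitz(aif.c, np.zeros(len(aif)))


def _fit_tail_line(t: np.ndarray, rif: np.ndarray, t_start: float,
                   t_stop: float, floor: float = 0.0) -> TailFit:
    sel = (t >= t_start) & (t <= t_stop) & (rif > floor)
    if np.count_nonzero(sel) < 5:
        raise InsufficientTailError(
            f"fewer than 5 strictly positive residue samples in "
            f"[{t_start:.0f}, {t_stop:.0f}] s")
    tt, yy = t[sel], np.log(rif[sel])
    slope, intercept = np.polyfit(tt, yy, 1)
    return TailFit(float(slope), float(intercept), float(t_start),
                   float(t_stop), int(np.count_nonzero(sel)))


def default_tail_window(res: ResidueFunction,
                        config: DeconvolutionConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    """Default extraction tail window.

    Starts at the later of (peak time + ``tail_start_after_peak_s``) and
    ``tail_min_fraction`` of the measured window, and runs to the end of the
    scan.  Sixty seconds past the peak the vascular washout phase (time
    constant a few seconds) has decayed by many orders of magnitude, so the
    fit sees only the slow parenchymal component; samples below
    ``tail_floor`` of the peak are additionally excluded from the fit
    because a back-extrapolation over hundreds of seconds amplifies any
    slope error contributed by near-zero, smoothing-dominated samples.
    """
    t0, t1 = float(res.t[0]), float(res.t[-1])
    start = max(res.peak_time + config.tail_start_after_peak_s,
                t0 + config.tail_min_fraction * (t1 - t0))
    return start, t1


def estimate_extraction(res: ResidueFunction,
                        window: Optional[tuple[float, float]] = None,
                        config: DeconvolutionConfig = DEFAULT_CONFIG,
                        ) -> tuple[float, TailFit]:
    """Extraction fraction from the slow tail of the residue function.

    Fits a line to ln(RIF) over the tail window (semilogarithmic plot) and
    reads E as the fitted line evaluated at the time of the RIF peak: the
    back-extrapolated amplitude of the slow (parenchymal) component.  A
    mono-exponential RIF therefore gives E = 1; a bi-phasic RIF with a fast
    vascular washout gives the amplitude of the extracted component.
    E is clamped to [0, 1.05] (values slightly above 1 tolerate noise).
    """
    rif = np.maximum(res.r, 0.0)
    peak = rif.max()
    if peak <= 0:
        raise NonPhysicalSolutionError("residue function has non-positive peak")
    rif = rif / peak
    if window is None:
        window = default_tail_window(res, config)
    fit = _fit_tail_line(res.t, rif, window[0], window[1], config.tail_floor)
    e = math.exp(fit.intercept + fit.slope * res.peak_time)
    return float(np.clip(e, 0.0, 1.05)), fit


def rif_mtt(res: ResidueFunction, tail: Optional[TailFit] = None,
            config: DeconvolutionConfig = DEFAULT_CONFIG) -> float:
    """Mean transit time: area under the unit-peak residue function, seconds.

    The trapezoidal integral over the measured window is extended by the
    analytic integral of the fitted mono-exponential tail beyond the end of
    the scan.  If no tail fit is supplied one is computed over the default
    window.  When the tail decay rate is below the trapping threshold the
    integral diverges (trapped tracer, e.g. FDG) and ``inf`` is returned;
    downstream the distribution volume is then undefined.
    """
    rif = np.maximum(res.r, 0.0)
    peak = rif.max()
    if peak <= 0:
        raise NonPhysicalSolutionError("residue function has non-positive peak")
    rif = rif / peak
    if tail is None:
        start, stop = default_tail_window(res, config)
        tail = _fit_tail_line(res.t, rif, start, stop, config.tail_floor)
    if tail.decay_rate < config.trapping_threshold:
        return math.inf
    area = float(np.trapezoid(rif, res.t))
    t_end = float(res.t[-1])
    tail_value = math.exp(tail.intercept + tail.slope * t_end)
    return area + tail_value / tail.decay_rate


def derive_physiology(res: ResidueFunction, aif: TimeActivityCurve,
                      tis: TimeActivityCurve, delta_t: float = 0.0,
                      config: DeconvolutionConfig = DEFAULT_CONFIG) -> PhysioParams:
    """All per-voxel physiology from a recovered residue function.

    CBF is the peak of R (converted to mL min^-1 100 mL^-1); E and the tail
    fit come from :func:`estimate_extraction`; K1 = E x CBF; MTT from
    :func:`rif_mtt`.  The distribution volume uses the integral ratio
    vd = int C_tis / int C_a when the tissue curve has decayed below
    ``vd_return_fraction`` of its peak by the end of the scan, and
    CBF x MTT otherwise; it is NaN when the MTT diverges and the integral
    rule does not apply.

    Negative samples of R (allowed by the unconstrained solver) are clipped
    to zero for these derivations; the clipped fraction is recorded.
    """
    clipped_fraction = res.clipped_fraction()
    res_pos = res.clipped()
    f = res_pos.f
    if f <= 0:
        raise NonPhysicalSolutionError("non-positive perfusion estimate")
    cbf = f * PER_SECOND_TO_ML_MIN_100ML
    e, tail = estimate_extraction(res_pos, config=config)
    k1 = k1_from_extraction(e, cbf)
    mtt = rif_mtt(res_pos, tail, config=config)

    tis_returned = tis.c[-1] <= config.vd_return_fraction * tis.c.max()
    if tis_returned:
        denom = aif.integral()
        if denom <= 0:
            raise NonPhysicalSolutionError("AIF integral is non-positive")
        vd = 100.0 * tis.integral() / denom
    elif math.isfinite(mtt):
        # cbf [mL/min/100mL] x mtt [s] / 60 [s/min] -> mL/100mL
        vd = cbf * mtt / 60.0
    else:
        vd = math.nan
    return PhysioParams(cbf=cbf, e=e, k1=k1, mtt=mtt, vd=vd, delta_t=delta_t,
                        clipped_fraction=clipped_fraction, tailfit=tail)
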