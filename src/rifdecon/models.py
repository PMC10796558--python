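"""Model/Results objects: the high-level fitting interface.

Two estimators share the statsmodels idiom — construct a model from data,
call ``fit()``, inspect the returned results object:

* :class:`TikhonovDeconvolution` — the model-free route: regularized
  deconvolution of a tissue curve against the AIF, returning the residue
  function and the physiology derived from it (CBF, E, K1, MTT, vd).
* :class:`TwoTissueCompartment` — the conventional comparison model with
  constrained rate constants and a fitted blood-volume fraction.

Both accept a framed curve plus schedule or an already-resampled 1-s
:class:`~rifdecon.timecourse.TimeActivityCurve`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .aifproc import FramedCurve, resample_to_1s
from .compartment import CompartmentParams, fit_2tc, model_2tc_tissue
from .config import DEFAULT_CONFIG, DeconvolutionConfig
from .delay import DelayFit, estimate_delay, shift_series
from .kinetics import PhysioParams, ResidueFunction, derive_physiology
from .tikhonov import RegularizationResult, deconvolve
from .timecourse import TimeActivityCurve

__all__ = ["TikhonovDeconvolution", "TikhonovDeconvolutionResults",
           "TwoTissueCompartment", "TwoTissueCompartmentResults"]


def _as_1s_tac(data, schedule=None) -> TimeActivityCurve:
    if isinstance(data, TimeActivityCurve):
        return data
    if isinstance(data, FramedCurve):
        return resample_to_1s(data)
    if schedule is not None:
        return resample_to_1s(FramedCurve(schedule.mid_times,
                                          np.asarray(data, float)))
    raise TypeError("expected a TimeActivityCurve, a FramedCurve, or framed "
                    "values plus a schedule")


class TikhonovDeconvolution:
    """Model-free perfusion estimation for one ROI or voxel curve.

    Parameters
    ----------
    tissue, aif : TimeActivityCurve or FramedCurve
        Tissue and arterial curves; framed input is upsampled to 1 s.
    schedule : FrameSchedule, optional
        Needed only when raw framed value arrays are passed.
    correct_delay : bool
        Estimate the arterial arrival delay from the early tissue upslope
        and align the AIF before deconvolving (default True).
    config : DeconvolutionConfig
        Solver and physiology settings.
    """

    def __init__(self, tissue, aif, schedule=None, correct_delay: bool = True,
                 config: DeconvolutionConfig = DEFAULT_CONFIG):
        tissue = _as_1s_tac(tissue, schedule)
        aif = _as_1s_tac(aif, schedule)
        n = min(len(tissue), len(aif))
        self.tissue = TimeActivityCurve(tissue.t[:n], tissue.c[:n])
        self.aif = TimeActivityCurve(aif.t[:n], aif.c[:n])
        self.correct_delay = correct_delay
        self.config = config

    def fit(self) -> "TikhonovDeconvolutionResults":
        delay_fit: Optional[DelayFit] = None
        aif = self.aif
        if self.correct_delay:
            delay_fit = estimate_delay(aif, self.tissue, self.config)
            aif = shift_series(aif, delay_fit.delta_t)
        residue, regularization = deconvolve(aif, self.tissue, self.config)
        physio = derive_physiology(
            residue, aif, self.tissue,
            delay_fit.delta_t if delay_fit else 0.0, self.config)
        return TikhonovDeconvolutionResults(
            model=self, aif_aligned=aif, residue=residue,
            regularization=regularization, physio=physio,
            delay_fit=delay_fit)


@dataclass(frozen=True)
class TikhonovDeconvolutionResults:
    """Residue function, regularization diagnostics and derived physiology."""

    model: TikhonovDeconvolution
    aif_aligned: TimeActivityCurve
    residue: ResidueFunction
    regularization: RegularizationResult
    physio: PhysioParams
    delay_fit: Optional[DelayFit]

    @property
    def fitted_tissue(self) -> TimeActivityCurve:
        from .kinetics import discrete_convolve
        return discrete_convolve(self.aif_aligned, self.residue)

    def summary(self) -> str:
        p = self.physio
        lines = [
            "Tikhonov model-free deconvolution",
            "=" * 46,
            f"{'CBF':<28}{p.cbf:10.1f}  mL/min/100mL",
            f"{'Extraction fraction E':<28}{p.e:10.3f}",
            f"{'K1 = E x CBF':<28}{p.k1:10.1f}  mL/min/100mL",
            f"{'MTT':<28}{p.mtt:10.1f}  s",
            f"{'vd':<28}{p.vd:10.1f}  mL/100mL",
            f"{'Arterial delay dT':<28}{p.delta_t:10.1f}  s",
            "-" * 46,
            f"{'lambda (L-curve corner)':<28}"
            f"{self.regularization.lambda_star:10.3g}",
            f"{'negative-R fraction':<28}{p.clipped_fraction:10.3f}",
            f"{'n time points':<28}{len(self.model.tissue):10d}",
        ]
        return "\n".join(lines)

    def plot_lcurve(self, ax=None):
        """Log-log residual norm vs seminorm with the selected corner."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        reg = self.regularization
        ax.loglog(reg.residual_norms, reg.seminorms, "o-", ms=3)
        i = reg.corner_index
        ax.loglog(reg.residual_norms[i], reg.seminorms[i], "rs", ms=8,
                  label=f"corner, lambda={reg.lambda_star:.3g}")
        ax.set_xlabel("residual norm ||DV - y||")
        ax.set_ylabel("seminorm ||L R||")
        ax.legend()
        return ax

    def plot_fit(self, ax=None):
        """Tissue data, model fit and (inset-scaled) residue function."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.tissue.t, self.model.tissue.c, "k.", ms=3,
                label="tissue TAC")
        ax.plot(self.fitted_tissue.t, self.fitted_tissue.c, "g-",
                label="deconvolution fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("activity (kBq/mL)")
        ax.legend()
        return ax


class TwoTissueCompartment:
    """Conventional 2-tissue compartment model with fixed-parameter flags.

    ``fixed`` pins parameters, e.g. ``{"k4": 0.0}`` (irreversible default)
    or ``{"k3": 0.0, "k4": 0.0}`` for water.
    """

    def __init__(self, tissue, aif, schedule=None,
                 fixed: dict[str, float] | None = None,
                 weights: np.ndarray | None = None):
        tissue = _as_1s_tac(tissue, schedule)
        aif = _as_1s_tac(aif, schedule)
        n = min(len(tissue), len(aif))
        self.tissue = TimeActivityCurve(tissue.t[:n], tissue.c[:n])
        self.aif = TimeActivityCurve(aif.t[:n], aif.c[:n])
        self.fixed = dict(fixed) if fixed is not None else {"k4": 0.0}
        self.weights = weights

    def fit(self) -> "TwoTissueCompartmentResults":
        params = fit_2tc(self.aif, self.tissue, fixed=self.fixed,
                         weights=self.weights)
        return TwoTissueCompartmentResults(model=self, params=params)


@dataclass(frozen=True)
class TwoTissueCompartmentResults:
    model: TwoTissueCompartment
    params: CompartmentParams

    @property
    def fitted_tissue(self) -> TimeActivityCurve:
        return model_2tc_tissue(self.params, self.model.aif)

    def summary(self) -> str:
        p = self.params
        def mark(name: str) -> str:
            return " (fixed)" if name in p.fixed else ""
        lines = [
            "Two-tissue compartment model",
            "=" * 46,
            f"{'K1':<28}{p.k1_influx:10.2f}  mL/min/100mL{mark('k1_influx')}",
            f"{'k2':<28}{p.k2:10.4f}  1/min{mark('k2')}",
            f"{'k3':<28}{p.k3:10.4f}  1/min{mark('k3')}",
            f"{'k4':<28}{p.k4:10.4f}  1/min{mark('k4')}",
            f"{'Va':<28}{p.va:10.4f}  fraction{mark('va')}",
            "-" * 46,
            f"{'SSE':<28}{p.sse:10.4g}",
            f"{'starts converged':<28}{p.n_starts_converged:10d}",
        ]
        return "\n".join(lines)
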