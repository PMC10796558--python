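"""Synthetic dynamic-PET generator: AIFs, residue functions, TACs, phantoms.

Everything the estimation pipeline consumes can be generated here with
known ground truth, so each stage is testable without any acquired data.

* :func:`gamma_variate_aif` emulates an aorta image-derived input: a sharp
  gamma-variate first-pass peak, a dispersed recirculation copy and a slow
  equilibrium washout tail.
* :func:`ground_truth_rif` builds residue functions of the three tracer
  classes: flow-limited mono-exponential washout (water, the Kety kernel
  exp(-f t / vd)); diffusion-limited bi-exponential (fast vascular washout
  of the unextracted fraction plus slow parenchymal clearance of the
  extracted fraction); and trapping (the extracted fraction plateaus, FDG).
* :func:`simulate_tissue_tac` runs the forward convolution with a chosen
  arrival delay, averages over a realistic frame schedule and adds
  activity- and frame-duration-scaled Gaussian noise (a Poisson surrogate:
  count variance grows with activity and shrinks with frame duration).
* :func:`build_phantom` assembles a small 4-D volume with one region per
  tracer-class spec and an aorta surrogate region carrying the pure AIF.

Tracer presets encode the five study tracers: their published frame
schedules and thalamus-level truth values (CBF, E, vd).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.signal

from .config import PER_SECOND_TO_ML_MIN_100ML
from .delay import shift_series
from .exceptions import SchemaError
from .kinetics import ResidueFunction
from .timecourse import FrameSchedule, TimeActivityCurve
from .aifproc import FramedCurve

__all__ = [
    "TracerClassSpec",
    "TracerPreset",
    "PhantomTruth",
    "RegionSpec",
    "TRACER_PRESETS",
    "gamma_variate_aif",
    "default_aif",
    "ground_truth_rif",
    "simulate_tissue_tac",
    "build_phantom",
]


@dataclass(frozen=True)
class TracerClassSpec:
    """Kinetic class and truth parameters of a simulated tracer.

    tracer_class: ``flow_limited`` (mono-exponential, rate f/vd),
    ``diffusion_limited`` (bi-exponential: vascular washout + extraction) or
    ``trapping`` (extracted fraction never leaves).
    e_true: extraction fraction in [0, 1].
    vascular_tau: vascular washout time constant, seconds.
    washout: parenchymal clearance rate of the extracted fraction, s^-1
    (0 for trapping).
    vd_true: distribution volume, mL per 100 mL tissue (NaN when undefined).
    """

    tracer_class: str
    e_true: float
    vascular_tau: float = 4.0
    washout: float = 0.0
    vd_true: float = float("nan")

    def __post_init__(self) -> None:
        if self.tracer_class not in ("flow_limited", "diffusion_limited",
                                     "trapping"):
            raise ValueError(f"unknown tracer class {self.tracer_class!r}")
        if not 0.0 <= self.e_true <= 1.0:
            raise ValueError("e_true must lie in [0, 1]")
        if not 0.5 <= self.vascular_tau <= 10.0:
            raise ValueError("vascular_tau must lie in [0.5, 10] s")
        if self.tracer_class == "trapping" and self.washout != 0.0:
            raise ValueError("trapping implies washout = 0")


def washout_rate(e: float, vascular_tau: float, vd_frac: float,
                 cbf_s: float) -> float:
    """Parenchymal washout rate making CBF x MTT equal the target vd.

    Solves (1-e) tau_v + e / w = vd_frac / cbf_s for w, so the analytic
    area under the residue function reproduces the intended distribution
    volume exactly.
    """
    target_mtt = vd_frac / cbf_s
    tail_area = target_mtt - (1.0 - e) * vascular_tau
    if tail_area <= 0:
        raise ValueError("vd too small for the requested vascular tau")
    return e / tail_area


@dataclass(frozen=True)
class TracerPreset:
    """One study tracer: schedule, phantom truth and reported reference means."""

    name: str
    spec: TracerClassSpec
    cbf: float                      # truth CBF, mL/min/100mL
    schedule_blocks: tuple[tuple[int, float], ...]
    reported: dict = field(default_factory=dict)

    @property
    def schedule(self) -> FrameSchedule:
        return FrameSchedule.from_blocks(list(self.schedule_blocks))

    @property
    def cbf_per_s(self) -> float:
        return self.cbf / PER_SECOND_TO_ML_MIN_100ML


def _diffusion_preset(name: str, e: float, cbf: float, vd: float,
                      blocks: tuple, reported: dict,
                      tracer_class: str = "diffusion_limited",
                      vascular_tau: float = 4.0) -> TracerPreset:
    cbf_s = cbf / PER_SECOND_TO_ML_MIN_100ML
    if tracer_class == "trapping":
        w = 0.0
        vd_field = float("nan")
    else:
        w = washout_rate(e, vascular_tau, vd / 100.0, cbf_s)
        vd_field = vd
    spec = TracerClassSpec(tracer_class=tracer_class, e_true=e,
                           vascular_tau=vascular_tau, washout=w,
                           vd_true=vd_field)
    return TracerPreset(name=name, spec=spec, cbf=cbf,
                        schedule_blocks=blocks, reported=reported)


_SHORT = ((40, 1.0), (5, 4.0), (6, 10.0), (3, 20.0), (2, 30.0), (8, 60.0))
_MEDIUM = ((40, 1.0), (10, 5.0), (15, 10.0), (6, 60.0), (10, 120.0), (2, 300.0))
_LONG = ((40, 1.0), (10, 5.0), (15, 10.0), (6, 60.0), (10, 120.0), (6, 300.0))

#: The five study tracers.  ``reported`` carries the published thalamus
#: means (CBF mL/min/100mL, E, K1 mL/min/100mL, vd mL/100mL) used as
#: reference constants; phantom truths are chosen to match them.
TRACER_PRESETS: dict[str, TracerPreset] = {
    "water": TracerPreset(
        name="water",
        # freely diffusible: mono-exponential Kety kernel, full extraction
        spec=TracerClassSpec(tracer_class="flow_limited", e_true=1.0,
                             vd_true=90.0),
        cbf=69.0,
        schedule_blocks=_SHORT,
        reported={"cbf": 69.0, "e": 0.94, "k1": float("nan"), "vd": 90.0,
                  "e_abstract": 0.95},
    ),
    "fe_pe2i": _diffusion_preset(
        "fe_pe2i", e=0.78, cbf=58.0, vd=383.0, blocks=_MEDIUM,
        reported={"cbf": 58.0, "e": 0.78, "k1": 45.0, "vd": 383.0}),
    "pib": _diffusion_preset(
        "pib", e=0.62, cbf=50.0, vd=288.0, blocks=_LONG,
        reported={"cbf": 50.0, "e": 0.62, "k1": 31.0, "vd": 288.0}),
    "fdg": _diffusion_preset(
        "fdg", e=0.19, cbf=37.0, vd=float("nan"), blocks=_LONG,
        reported={"cbf": 37.0, "e": 0.19, "k1": 5.5, "vd": float("nan")},
        tracer_class="trapping"),
    "fet": _diffusion_preset(
        "fet", e=0.032, cbf=53.0, vd=48.0, blocks=_MEDIUM,
        reported={"cbf": 53.0, "e": 0.032, "k1": 1.7, "vd": 48.0}),
}


def gamma_variate_aif(tgrid: np.ndarray, amp: float = 1.0, t0: float = 10.0,
                      shape: float = 3.0, scale: float = 4.0,
                      recirc_frac: float = 0.15,
                      washout_tau: float = 600.0) -> TimeActivityCurve:
    """Arterial input: gamma-variate first pass + recirculation + slow tail.

    First pass ``amp (t-t0)^shape exp(-(t-t0)/scale)`` (zero before t0,
    mode at t0 + shape*scale); a recirculation copy equal to ``recirc_frac``
    times the first pass dispersed through a 20-s exponential kernel; and an
    equilibrium tail that rises over ~30 s and decays with ``washout_tau``
    (whole-body clearance).  Both extra components vanish when
    ``recirc_frac`` is zero.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    if not 0.0 <= recirc_frac < 0.5:
        raise ValueError("recirc_frac must lie in [0, 0.5)")
    t = np.asarray(tgrid, dtype=float)
    dt = t[1] - t[0]
    tau = np.maximum(t - t0, 0.0)
    fp = amp * tau ** shape * np.exp(-tau / scale)
    fp[t <= t0] = 0.0
    if recirc_frac > 0:
        disp = np.exp(-(t - t[0]) / 20.0) / 20.0
        recirc = recirc_frac * dt * scipy.signal.fftconvolve(fp, disp)[: t.size]
        peak = fp.max()
        tail = (recirc_frac * 0.08 * peak * (1.0 - np.exp(-tau / 30.0))
                * np.exp(-tau / washout_tau))
        c = fp + recirc + tail
    else:
        c = fp
    return TimeActivityCurve(t, c)


def default_aif(tgrid: np.ndarray, peak_kbq_ml: float = 100.0,
                **kwargs) -> TimeActivityCurve:
    """Gamma-variate AIF scaled to a given first-pass peak (kBq/mL)."""
    shape = kwargs.get("shape", 3.0)
    scale = kwargs.get("scale", 4.0)
    mode_value = (shape * scale) ** shape * math.exp(-shape)
    return gamma_variate_aif(tgrid, amp=peak_kbq_ml / mode_value, **kwargs)


def ground_truth_rif(spec: TracerClassSpec, tgrid: np.ndarray,
                     cbf_s: Optional[float] = None) -> ResidueFunction:
    """Unit-peak residue function of a tracer class on a time grid.

    Flow-limited tracers need ``cbf_s`` (s^-1) to set the Kety rate
    f / vd; the other classes are fully specified by the spec.
    """
    t = np.asarray(tgrid, dtype=float)
    t = t - t[0]
    if spec.tracer_class == "flow_limited":
        if cbf_s is None:
            raise ValueError("flow_limited needs cbf_s to set the Kety rate")
        tau = (spec.vd_true / 100.0) / cbf_s
        rif = np.exp(-t / tau)
    else:
        rif = ((1.0 - spec.e_true) * np.exp(-t / spec.vascular_tau)
               + spec.e_true * np.exp(-spec.washout * t))
    return ResidueFunction(np.asarray(tgrid, dtype=float), rif)


def simulate_tissue_tac(aif: TimeActivityCurve, cbf: float,
                        rif: ResidueFunction, delta_t: float,
                        schedule: FrameSchedule, noise_sd0: float = 0.0,
                        seed: int | None = None,
                        c_floor: float = 0.1) -> FramedCurve:
    """Forward-simulate a framed, noisy tissue curve.

    ``C = cbf * (AIF shifted by delta_t) (x) rif`` on the fine grid, frame
    averaged over the schedule, then Gaussian noise with per-frame standard
    deviation ``noise_sd0 * sqrt(max(C,0) + c_floor) / sqrt(duration)`` —
    count noise grows with activity and integrates down with frame length.
    ``cbf`` is in reported units (mL/min/100 mL).
    """
    if schedule.ends[-1] > aif.t[-1] + aif.dt + 1e-9:
        raise SchemaError("frame schedule extends past the simulated window")
    cbf_s = cbf / PER_SECOND_TO_ML_MIN_100ML
    aif_sh = shift_series(aif, delta_t) if delta_t else aif
    c_fine = aif.dt * scipy.signal.fftconvolve(
        aif_sh.c, cbf_s * rif.rif)[: len(aif)]
    framed = schedule.frame_average(aif.t, c_fine)
    if noise_sd0 > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd0 * np.sqrt(np.maximum(framed, 0.0) + c_floor)
        sd = sd / np.sqrt(schedule.durations)
        framed = framed + rng.normal(0.0, 1.0, framed.size) * sd
    return FramedCurve(schedule.mid_times, framed)


@dataclass(frozen=True)
class RegionSpec:
    """One phantom region: a label, its truth kinetics and arrival delay."""

    name: str
    label: int
    cbf: float
    spec: TracerClassSpec
    delta_t: float = 0.0


@dataclass(frozen=True)
class PhantomTruth:
    """Complete description of a synthetic phantom (serializable)."""

    shape: tuple[int, int, int]
    regions: tuple[RegionSpec, ...]
    schedule_blocks: tuple[tuple[int, float], ...]
    seed: int
    noise_sd0: float = 0.0
    aif_peak: float = 100.0

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise SchemaError("region labels must be disjoint")

    @property
    def schedule(self) -> FrameSchedule:
        return FrameSchedule.from_blocks(list(self.schedule_blocks))

    def to_json(self, path: str) -> None:
        payload = {
            "shape": list(self.shape),
            "seed": self.seed,
            "noise_sd0": self.noise_sd0,
            "aif_peak": self.aif_peak,
            "schedule_blocks": [list(b) for b in self.schedule_blocks],
            "regions": [
                {"name": r.name, "label": r.label, "cbf": r.cbf,
                 "delta_t": r.delta_t,
                 "spec": {"tracer_class": r.spec.tracer_class,
                          "e_true": r.spec.e_true,
                          "vascular_tau": r.spec.vascular_tau,
                          "washout": r.spec.washout,
                          "vd_true": r.spec.vd_true}}
                for r in self.regions],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "PhantomTruth":
        with open(path) as fh:
            payload = json.load(fh)
        regions = tuple(
            RegionSpec(name=r["name"], label=r["label"], cbf=r["cbf"],
                       delta_t=r["delta_t"],
                       spec=TracerClassSpec(**r["spec"]))
            for r in payload["regions"])
        return cls(shape=tuple(payload["shape"]), regions=regions,
                   schedule_blocks=tuple(tuple(b) for b in
                                         payload["schedule_blocks"]),
                   seed=payload["seed"], noise_sd0=payload["noise_sd0"],
                   aif_peak=payload["aif_peak"])

    @classmethod
    def from_preset(cls, preset_name: str, shape=(16, 16, 4), seed: int = 0,
                    noise_sd0: float = 0.0,
                    delta_t: float = 0.0) -> "PhantomTruth":
        preset = TRACER_PRESETS[preset_name]
        region = RegionSpec(name=preset.name, label=2, cbf=preset.cbf,
                            spec=preset.spec, delta_t=delta_t)
        return cls(shape=shape, regions=(region,),
                   schedule_blocks=preset.schedule_blocks, seed=seed,
                   noise_sd0=noise_sd0)


#: label value reserved for the aorta surrogate region
AORTA_LABEL = 1


def build_phantom(truth: PhantomTruth
                  ) -> tuple[np.ndarray, np.ndarray, TimeActivityCurve]:
    """Assemble a 4-D phantom: (volume, label mask, fine-grid AIF).

    The volume is laid out in x-slabs: slab 0 is the aorta surrogate
    (label 1, carries the framed AIF itself), one further slab per region in
    order, the remainder background (label 0, zero signal).  Voxel noise is
    independent per voxel and reproducible from the truth seed.
    """
    nx, ny, nz = truth.shape
    n_slabs = len(truth.regions) + 1
    if nx < n_slabs + 1:
        raise SchemaError("phantom x-extent too small for the regions")
    schedule = truth.schedule
    tgrid = np.arange(0.0, schedule.total_duration, 1.0)
    aif = default_aif(tgrid, peak_kbq_ml=truth.aif_peak)

    labels = np.zeros(truth.shape, dtype=np.int16)
    slab = nx // (n_slabs + 1)
    labels[:slab] = AORTA_LABEL
    for i, region in enumerate(truth.regions, start=1):
        labels[i * slab:(i + 1) * slab] = region.label

    volume = np.zeros(truth.shape + (schedule.n_frames,), dtype=float)
    rng = np.random.default_rng(truth.seed)
    aif_framed = schedule.frame_average(tgrid, aif.c)

    def fill(mask: np.ndarray, mean_curve: np.ndarray) -> None:
        idx = np.argwhere(mask)
        for ix, iy, iz in idx:
            if truth.noise_sd0 > 0:
                sd = (truth.noise_sd0
                      * np.sqrt(np.maximum(mean_curve, 0.0) + 0.1)
                      / np.sqrt(schedule.durations))
                volume[ix, iy, iz] = mean_curve + rng.normal(
                    0.0, 1.0, mean_curve.size) * sd
            else:
                volume[ix, iy, iz] = mean_curve

    fill(labels == AORTA_LABEL, aif_framed)
    for region in truth.regions:
        cbf_s = region.cbf / PER_SECOND_TO_ML_MIN_100ML
        rif = ground_truth_rif(region.spec, tgrid, cbf_s=cbf_s)
        framed = simulate_tissue_tac(aif, region.cbf, rif, region.delta_t,
                                     schedule, noise_sd0=0.0)
        fill(labels == region.label, framed.values)
    return volume, labels, aif
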