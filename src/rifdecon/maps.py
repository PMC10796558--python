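"""Voxelwise orchestration: parameter maps from a dynamic image and an AIF.

For every voxel that passes the signal mask, the pipeline resamples the
framed curve to the 1-s grid, estimates the arterial arrival delay, aligns
the AIF, deconvolves, and derives CBF, E, K1, MTT, vd plus diagnostics.
Failed voxels become NaN (never crash the run, never bias downstream
statistics toward zero).  Results are independent of processing order and
of serial vs parallel execution.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import nibabel as nib
from joblib import Parallel, delayed

from .aifproc import FramedCurve, resample_to_1s
from .config import DEFAULT_CONFIG, DeconvolutionConfig
from .delay import estimate_delay, shift_series
from .exceptions import RifdeconError, SchemaError
from .kinetics import derive_physiology
from .timecourse import FrameSchedule, TimeActivityCurve
from .tikhonov import deconvolve, prepare_system

__all__ = ["DynamicImage", "ParamMaps", "run_voxelwise", "read_dynamic",
           "write_maps", "region_summary"]

logger = logging.getLogger("rifdecon")

_PARAM_NAMES = ("cbf", "mtt", "delay", "vd", "e", "k1", "lambda_star",
                "clipped_fraction")


@dataclass(frozen=True)
class DynamicImage:
    """4-D dynamic PET volume (x, y, z, frame) with affine and timing."""

    voxels: np.ndarray
    affine: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        if self.voxels.ndim != 4:
            raise SchemaError("dynamic image must be 4-D")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise SchemaError(
                f"{self.voxels.shape[3]} frames in image vs "
                f"{self.schedule.n_frames} in schedule")
        if abs(np.linalg.det(np.asarray(self.affine)[:3, :3])) < 1e-12:
            raise SchemaError("affine must be invertible")


@dataclass(frozen=True)
class ParamMaps:
    """3-D parameter volumes sharing the input affine; NaN where masked out."""

    volumes: dict[str, np.ndarray]
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.volumes[name]


def auto_mask(img: DynamicImage,
              config: DeconvolutionConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Voxel inclusion mask: frame-peak above 3x the robust background MAD.

    The background reference is the lowest quartile of the frame-peak
    volume (air and empty space), so the rule stays valid when signal
    voxels make up a large share of the field of view.
    """
    peak = img.voxels.max(axis=3)
    bg = peak[peak <= np.percentile(peak, 25)]
    level = float(np.median(bg))
    mad = 1.4826 * float(np.median(np.abs(bg - level)))
    threshold = level + config.mask_mad_factor * max(mad, 1e-12)
    return peak > threshold


def _process_voxel(framed_values: np.ndarray, mids: np.ndarray,
                   aif: TimeActivityCurve, config: DeconvolutionConfig,
                   estimate_voxel_delay: bool, system_cache: dict):
    """One voxel: resample, delay-align, deconvolve, derive physiology."""
    try:
        tac = resample_to_1s(FramedCurve(mids, framed_values))
        n = min(len(tac), len(aif))
        tac = TimeActivityCurve(tac.t[:n], tac.c[:n])
        aif_c = TimeActivityCurve(aif.t[:n], aif.c[:n])
        if estimate_voxel_delay:
            fit = estimate_delay(aif_c, tac, config)
            delta = fit.delta_t
        else:
            delta = 0.0
        # quantize so voxels sharing a delay reuse one factorization
        delta_q = round(delta / config.refine_step_s) * config.refine_step_s
        aif_aligned = shift_series(aif_c, delta_q) if delta_q else aif_c
        key = round(delta_q, 6)
        if key not in system_cache:
            system_cache[key] = prepare_system(aif_aligned, config)
        res, reg = deconvolve(aif_aligned, tac, config,
                              factorization=system_cache[key])
        physio = derive_physiology(res, aif_aligned, tac, delta_q, config)
        return {"cbf": physio.cbf, "mtt": physio.mtt, "delay": delta_q,
                "vd": physio.vd, "e": physio.e, "k1": physio.k1,
                "lambda_star": reg.lambda_star,
                "clipped_fraction": physio.clipped_fraction}
    except RifdeconError as exc:
        logger.debug("voxel failed: %s", exc)
        return None


def run_voxelwise(img: DynamicImage, aif: TimeActivityCurve,
                  config: DeconvolutionConfig = DEFAULT_CONFIG,
                  mask: np.ndarray | None = None,
                  estimate_voxel_delay: bool = True,
                  n_jobs: int = 1) -> ParamMaps:
    """Produce CBF/MTT/delay/vd/E maps for a dynamic image.

    The AIF must already be on the 1-s grid (see
    :func:`rifdecon.aifproc.resample_to_1s`).  ``mask`` restricts
    processing; by default an automatic signal mask is used.  Parallel and
    serial runs are bitwise identical: each voxel is an independent pure
    computation.
    """
    if mask is None:
        mask = auto_mask(img, config)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.voxels.shape[:3]:
        raise SchemaError("mask shape does not match image")
    mids = img.schedule.mid_times
    coords = np.argwhere(mask)
    logger.info("processing %d voxels", len(coords))

    if n_jobs == 1:
        cache: dict = {}
        results = [_process_voxel(img.voxels[x, y, z], mids, aif, config,
                                  estimate_voxel_delay, cache)
                   for x, y, z in coords]
    else:
        # per-worker caches; results identical since voxels are independent
        results = Parallel(n_jobs=n_jobs, batch_size=max(1, len(coords) // (4 * n_jobs) or 1))(
            delayed(_process_voxel)(img.voxels[x, y, z], mids, aif, config,
                                    estimate_voxel_delay, {})
            for x, y, z in coords)

    volumes = {name: np.full(img.voxels.shape[:3], np.nan)
               for name in _PARAM_NAMES}
    n_failed = 0
    for (x, y, z), result in zip(coords, results):
        if result is None:
            n_failed += 1
            continue
        for name in _PARAM_NAMES:
            volumes[name][x, y, z] = result[name]
    if n_failed:
        logger.warning("%d of %d voxels failed and were set to NaN",
                       n_failed, len(coords))
    provenance = {"config_hash": config.config_hash(),
                  "config": config.to_dict(),
                  "n_voxels": int(len(coords)), "n_failed": int(n_failed),
                  "estimate_voxel_delay": bool(estimate_voxel_delay)}
    return ParamMaps(volumes=volumes, affine=np.asarray(img.affine),
                     provenance=provenance)


def read_dynamic(pet_path: str, schedule_path: str) -> DynamicImage:
    """Load a 4-D NIfTI plus its frame-timing sidecar JSON."""
    img = nib.load(pet_path)
    schedule = FrameSchedule.from_json(schedule_path)
    data = np.asarray(img.dataobj, dtype=float)
    return DynamicImage(voxels=data, affine=img.affine, schedule=schedule)


def write_dynamic(img: DynamicImage, pet_path: str,
                  schedule_path: str) -> None:
    nib.save(nib.Nifti1Image(img.voxels.astype(np.float64), img.affine),
             pet_path)
    img.schedule.to_json(schedule_path)


def write_maps(maps: ParamMaps, outdir: str) -> None:
    """One NIfTI per parameter plus a provenance sidecar."""
    import os
    os.makedirs(outdir, exist_ok=True)
    for name, volume in maps.volumes.items():
        nib.save(nib.Nifti1Image(volume, maps.affine),
                 os.path.join(outdir, f"{name}.nii"))
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(maps.provenance, fh, indent=1)


def read_maps(outdir: str) -> ParamMaps:
    import os
    volumes = {}
    affine = None
    for name in _PARAM_NAMES:
        path = os.path.join(outdir, f"{name}.nii")
        if os.path.exists(path):
            img = nib.load(path)
            volumes[name] = np.asarray(img.dataobj, dtype=float)
            affine = img.affine
    with open(os.path.join(outdir, "provenance.json")) as fh:
        provenance = json.load(fh)
    return ParamMaps(volumes=volumes, affine=affine, provenance=provenance)


def region_summary(maps: ParamMaps, labels: np.ndarray,
                   path: str | None = None) -> pd.DataFrame:
    """Per-region means of every parameter map (NaN-aware); optional TSV."""
    labels = np.asarray(labels)
    rows = []
    for label in np.unique(labels):
        if label == 0:
            continue
        sel = labels == label
        row: dict[str, float] = {"label": int(label),
                                 "n_voxels": int(sel.sum())}
        for name, volume in maps.volumes.items():
            values = volume[sel]
            row[f"{name}_mean"] = float(np.nanmean(values)) if np.any(
                np.isfinite(values)) else float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
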