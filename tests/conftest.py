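"""Shared fixtures: synthetic rigs built once per session.

Everything is generated programmatically from the tracer presets; no stored
data.  The "rig" bundles the pieces a test needs to exercise one tracer:
the fine-grid AIF, the ground-truth residue function, and the framed AIF
resampled to 1 s exactly as the pipeline would produce it from an aorta
region.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import rifdecon as rd
from rifdecon.aifproc import FramedCurve


@dataclass(frozen=True)
class TracerRig:
    preset: rd.TracerPreset
    tgrid: np.ndarray
    aif_fine: rd.TimeActivityCurve
    rif_true: rd.ResidueFunction
    aif_1s: rd.TimeActivityCurve  # framed through the schedule then resampled

    def tissue_framed(self, delta_t: float = 0.0, noise_sd0: float = 0.0,
                      seed: int | None = None) -> FramedCurve:
        return rd.simulate_tissue_tac(self.aif_fine, self.preset.cbf,
                                      self.rif_true, delta_t,
                                      self.preset.schedule,
                                      noise_sd0=noise_sd0, seed=seed)

    def tissue_1s(self, **kwargs) -> rd.TimeActivityCurve:
        return rd.resample_to_1s(self.tissue_framed(**kwargs))


def make_rig(name: str) -> TracerRig:
    preset = rd.TRACER_PRESETS[name]
    sched = preset.schedule
    t = np.arange(0.0, sched.total_duration, 1.0)
    aif = rd.default_aif(t)
    rif = rd.ground_truth_rif(preset.spec, t, cbf_s=preset.cbf_per_s)
    framed_aif = FramedCurve(sched.mid_times, sched.frame_average(t, aif.c))
    return TracerRig(preset=preset, tgrid=t, aif_fine=aif, rif_true=rif,
                     aif_1s=rd.resample_to_1s(framed_aif))


@pytest.fixture(scope="session")
def water_rig() -> TracerRig:
    return make_rig("water")


@pytest.fixture(scope="session")
def fdg_rig() -> TracerRig:
    return make_rig("fdg")


@pytest.fixture(scope="session")
def water_phantom_maps():
    """Noiseless water phantom with an 8-s arterial delay, run end to end."""
    import warnings
    truth = rd.PhantomTruth.from_preset("water", shape=(9, 6, 2), seed=5,
                                        noise_sd0=0.0, delta_t=8.0)
    volume, labels, _ = rd.build_phantom(truth)
    img = rd.DynamicImage(voxels=volume, affine=np.eye(4),
                          schedule=truth.schedule)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aif = rd.resample_to_1s(rd.extract_aif(volume, labels == 1,
                                               truth.schedule))
        maps = rd.run_voxelwise(img, aif, estimate_voxel_delay=True)
    return truth, volume, labels, img, aif, maps
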