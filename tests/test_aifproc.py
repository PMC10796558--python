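"""AIF extraction, 1-s resampling and blood/metabolite corrections."""
import numpy as np
import pytest

import rifdecon as rd
from rifdecon.aifproc import FramedCurve
from rifdecon.exceptions import PartialVolumeWarning, SchemaError


@pytest.fixture()
def framed_schedule():
    return rd.FrameSchedule.from_blocks([(10, 1.0), (5, 4.0), (3, 10.0)])


class TestExtractAif:
    def _phantom(self, schedule, n=(6, 5, 4), noise=0.0, seed=0):
        t = np.arange(0.0, schedule.total_duration, 1.0)
        aif = rd.default_aif(t)
        framed = schedule.frame_average(t, aif.c)
        rng = np.random.default_rng(seed)
        vox = np.zeros(n + (schedule.n_frames,))
        vox[:] = framed
        if noise:
            vox += rng.normal(0.0, noise, vox.shape)
        return vox, framed

    def test_noiseless_extraction_equals_truth(self, framed_schedule):
        vox, framed = self._phantom(framed_schedule)
        mask = np.zeros(vox.shape[:3], bool)
        mask[2:4, 2:4, 1:3] = True
        out = rd.extract_aif(vox, mask, framed_schedule)
        np.testing.assert_allclose(out.values, framed, atol=1e-10)
        np.testing.assert_allclose(out.mid_times, framed_schedule.mid_times)

    def test_single_voxel_mask_returns_that_series(self, framed_schedule):
        vox, _ = self._phantom(framed_schedule, noise=0.5)
        mask = np.zeros(vox.shape[:3], bool)
        mask[3, 2, 1] = True
        with pytest.warns(PartialVolumeWarning):
            # mask away from the border would not warn; use border voxel to
            # exercise the warning path in the same test
            mask2 = mask.copy()
            mask2[0, 0, 0] = True
            rd.extract_aif(vox, mask2, framed_schedule)
        out = rd.extract_aif(vox, mask, framed_schedule)
        np.testing.assert_array_equal(out.values, vox[3, 2, 1])

    def test_empty_mask_rejected(self, framed_schedule):
        vox, _ = self._phantom(framed_schedule)
        with pytest.raises(SchemaError):
            rd.extract_aif(vox, np.zeros(vox.shape[:3], bool),
                           framed_schedule)

    def test_noise_shrinks_with_mask_size(self, framed_schedule):
        """Extraction SD scales roughly as 1/sqrt(n_voxels)."""
        sds = {}
        for size in (1, 16):
            errs = []
            for seed in range(40):
                vox, framed = self._phantom(framed_schedule, noise=1.0,
                                            seed=seed)
                mask = np.zeros(vox.shape[:3], bool)
                if size == 1:
                    mask[2, 2, 1] = True
                else:
                    mask[1:5, 1:5, 1] = True
                out = rd.extract_aif(vox, mask, framed_schedule)
                errs.append(out.values[0] - framed[0])
            sds[size] = np.std(errs)
        ratio = sds[1] / sds[16]
        assert ratio == pytest.approx(4.0, rel=0.5)


class TestResampleTo1s:
    def test_identity_on_one_second_grid(self):
        mids = np.arange(0.0, 30.0, 1.0)
        values = np.sin(mids / 5.0) + 2.0
        out = rd.resample_to_1s(FramedCurve(mids, values))
        np.testing.assert_allclose(out.c, values, atol=1e-12)

    def test_linear_ramp_reproduced_exactly(self):
        mids = np.array([0.5, 2.0, 5.0, 9.0, 14.0])
        out = rd.resample_to_1s(FramedCurve(mids, 3.0 * mids))
        inside = out.t >= mids[0]
        np.testing.assert_allclose(out.c[inside], 3.0 * out.t[inside],
                                   atol=1e-10)

    def test_zero_fill_before_first_mid_time(self):
        mids = np.array([5.5, 8.0, 12.0, 20.0])
        out = rd.resample_to_1s(FramedCurve(mids, np.ones(4)))
        np.testing.assert_array_equal(out.c[out.t < 5.5], 0.0)

    def test_monotone_interpolation_never_overshoots(self):
        """Across 100 random framed curves the upsampled maximum never
        exceeds the framed maximum (a naive cubic would overshoot)."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            mids = np.sort(rng.uniform(0, 100, 12))
            mids += np.arange(12) * 1e-3  # ensure strictly increasing
            values = rng.random(12) * 10
            out = rd.resample_to_1s(FramedCurve(mids, values))
            assert out.c.max() <= values.max() + 1e-12

    def test_duplicate_mid_times_rejected(self):
        with pytest.raises(SchemaError):
            FramedCurve(np.array([1.0, 1.0, 3.0]), np.zeros(3))

    def test_frame_average_consistency(self, water_rig):
        """Frame-averaging the resampled AIF over the original multi-second
        windows reproduces the framed values within 2% of the peak.  The
        1-s bolus frames are excluded: a 1-s window holds a single grid
        sample, so re-averaging there measures quadrature, not the
        interpolant."""
        sched = water_rig.preset.schedule
        framed = sched.frame_average(water_rig.tgrid, water_rig.aif_fine.c)
        resampled = water_rig.aif_1s
        back = sched.frame_average(resampled.t, resampled.c)
        sel = sched.durations >= 4.0
        sel[-1] = False  # resampled grid ends at the final mid-time
        np.testing.assert_allclose(back[sel], framed[sel],
                                   atol=0.02 * framed.max())


class TestBloodCorrections:
    def _aif(self):
        t = np.arange(0.0, 300.0, 1.0)
        return rd.default_aif(t)

    def test_identity_curves_leave_aif_unchanged(self):
        aif = self._aif()
        out = rd.apply_blood_corrections(aif)
        np.testing.assert_array_equal(out.c, aif.c)

    def test_constant_parent_fraction_scales_pointwise(self):
        aif = self._aif()
        half = rd.CorrectionCurve(np.array([0.0, 300.0]),
                                  np.array([0.5, 0.5]))
        out = rd.apply_blood_corrections(aif, parent=half)
        np.testing.assert_allclose(out.c, 0.5 * aif.c)

    def test_late_corrections_preserve_first_pass_peak(self):
        """Correction curves equal to 1 before 60 s leave the first-pass
        peak amplitude within 1%."""
        aif = self._aif()
        parent = rd.CorrectionCurve(np.array([0.0, 60.0, 150.0, 300.0]),
                                    np.array([1.0, 1.0, 0.6, 0.4]))
        out = rd.apply_blood_corrections(aif, parent=parent)
        peak_window = aif.t <= 40.0
        assert (np.abs(out.c[peak_window] - aif.c[peak_window]).max()
                <= 0.01 * aif.c.max())

    def test_nonpositive_correction_values_rejected(self):
        with pytest.raises(SchemaError):
            rd.CorrectionCurve(np.array([0.0, 10.0]), np.array([1.0, 0.0]))

    def test_correction_tsv_round_trip(self, tmp_path):
        curve = rd.CorrectionCurve(np.array([0.0, 100.0, 200.0]),
                                   np.array([1.0, 0.8, 0.55]))
        path = tmp_path / "parent.tsv"
        import pandas as pd
        pd.DataFrame({"time_s": curve.t, "value": curve.value}).to_csv(
            path, sep="\t", index=False)
        back = rd.CorrectionCurve.from_tsv(str(path))
        np.testing.assert_allclose(back.value, curve.value)
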