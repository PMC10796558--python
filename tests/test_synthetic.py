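"""Synthetic generator: AIFs, residue functions, TACs, phantoms."""
import math

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

import rifdecon as rd
from rifdecon.exceptions import SchemaError


class TestGammaVariateAif:
    def test_zero_amplitude_gives_zero_curve(self):
        t = np.arange(0.0, 300.0, 1.0)
        out = rd.gamma_variate_aif(t, amp=0.0)
        np.testing.assert_array_equal(out.c, 0.0)

    def test_peak_at_analytic_mode(self):
        """Mode of amp (t-t0)^a e^{-(t-t0)/s} is at t0 + a s."""
        t = np.arange(0.0, 300.0, 0.5)
        out = rd.gamma_variate_aif(t, t0=12.0, shape=3.0, scale=4.0,
                                   recirc_frac=0.0)
        assert out.t[np.argmax(out.c)] == pytest.approx(24.0, abs=0.5)

    def test_integral_matches_gamma_closed_form(self):
        """Without recirculation the area is amp scale^(a+1) Gamma(a+1)
        within 0.5%."""
        t = np.arange(0.0, 2000.0, 0.25)
        amp, shape, scale = 2.0, 3.0, 4.0
        out = rd.gamma_variate_aif(t, amp=amp, t0=10.0, shape=shape,
                                   scale=scale, recirc_frac=0.0)
        closed = amp * scale ** (shape + 1) * gamma_fn(shape + 1)
        assert out.integral() == pytest.approx(closed, rel=0.005)

    def test_default_aif_peak_scaling(self):
        t = np.arange(0.0, 300.0, 1.0)
        out = rd.default_aif(t, peak_kbq_ml=100.0, recirc_frac=0.0)
        assert out.c.max() == pytest.approx(100.0, rel=0.01)


class TestGroundTruthRif:
    def test_flow_limited_is_mono_exponential(self):
        t = np.arange(0.0, 500.0, 1.0)
        spec = rd.TracerClassSpec("flow_limited", e_true=1.0, vd_true=90.0)
        rif = rd.ground_truth_rif(spec, t, cbf_s=0.01)
        np.testing.assert_allclose(rif.rif, np.exp(-t / 90.0), atol=1e-12)

    def test_trapping_plateaus_at_extraction(self):
        """FDG-like residue levels off at the extracted fraction."""
        t = np.arange(0.0, 3600.0, 1.0)
        spec = rd.TRACER_PRESETS["fdg"].spec
        rif = rd.ground_truth_rif(spec, t)
        assert rif.rif[-1] == pytest.approx(0.19, abs=1e-6)
        assert rif.rif[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("name", ["fe_pe2i", "pib", "fdg", "fet"])
    def test_extraction_estimator_closes_the_loop(self, name):
        """estimate_extraction applied to the generated residue function
        returns the spec's own extraction within 0.02."""
        preset = rd.TRACER_PRESETS[name]
        t = np.arange(0.0, preset.schedule.total_duration, 1.0)
        rif = rd.ground_truth_rif(preset.spec, t, cbf_s=preset.cbf_per_s)
        e, _ = rd.estimate_extraction(rif)
        assert e == pytest.approx(preset.spec.e_true, abs=0.02)

    def test_trapping_with_washout_rejected(self):
        with pytest.raises(ValueError):
            rd.TracerClassSpec("trapping", e_true=0.2, washout=0.01)


class TestSimulateTissueTac:
    def test_noiseless_equals_framed_exact_convolution(self, water_rig):
        """noise_sd0 = 0, delta_t = 0: exactly the schedule averages of the
        discrete convolution."""
        preset = water_rig.preset
        framed = water_rig.tissue_framed()
        kernel = rd.ResidueFunction(
            water_rig.tgrid, preset.cbf_per_s * water_rig.rif_true.rif)
        fine = rd.discrete_convolve(water_rig.aif_fine, kernel)
        expected = preset.schedule.frame_average(fine.t, fine.c)
        np.testing.assert_allclose(framed.values, expected, atol=1e-12)

    def test_noise_variance_scales_inversely_with_duration(self, water_rig):
        """Doubling the frame duration halves the noise variance (within
        10% over 200 seeds)."""
        sched1 = rd.FrameSchedule.from_blocks([(720, 1.0)])
        sched2 = rd.FrameSchedule.from_blocks([(360, 2.0)])
        clean1 = rd.simulate_tissue_tac(water_rig.aif_fine, 69.0,
                                        water_rig.rif_true, 0.0, sched1)
        clean2 = rd.simulate_tissue_tac(water_rig.aif_fine, 69.0,
                                        water_rig.rif_true, 0.0, sched2)
        # pool activity-normalized residuals over late frames and seeds so
        # the empirical variance ratio is tight
        sel1 = slice(500, 700)
        sel2 = slice(250, 350)
        pooled = {1: [], 2: []}
        for seed in range(200):
            f1 = rd.simulate_tissue_tac(water_rig.aif_fine, 69.0,
                                        water_rig.rif_true, 0.0, sched1,
                                        noise_sd0=0.5, seed=seed)
            f2 = rd.simulate_tissue_tac(water_rig.aif_fine, 69.0,
                                        water_rig.rif_true, 0.0, sched2,
                                        noise_sd0=0.5, seed=seed + 10_000)
            pooled[1].extend((f1.values - clean1.values)[sel1]
                             / np.sqrt(clean1.values[sel1] + 0.1))
            pooled[2].extend((f2.values - clean2.values)[sel2]
                             / np.sqrt(clean2.values[sel2] + 0.1))
        ratio = np.var(pooled[1]) / np.var(pooled[2])
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_reproducible_under_seed(self, water_rig):
        a = water_rig.tissue_framed(noise_sd0=0.5, seed=9)
        b = water_rig.tissue_framed(noise_sd0=0.5, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_schedule_beyond_window_rejected(self, water_rig):
        long_sched = rd.FrameSchedule.from_blocks([(800, 1.0)])
        with pytest.raises(SchemaError):
            rd.simulate_tissue_tac(water_rig.aif_fine, 69.0,
                                   water_rig.rif_true, 0.0, long_sched)


class TestSchedulePresets:
    def test_presets_reproduce_published_framings(self):
        """Named presets carry the per-tracer frame schedules: 12 min for
        water, 40 min for FE-PE2I and FET, 60 min for PIB and FDG."""
        totals = {name: rd.TRACER_PRESETS[name].schedule.total_duration
                  for name in rd.TRACER_PRESETS}
        assert totals["water"] == 720.0
        assert totals["fe_pe2i"] == totals["fet"] == 2400.0
        assert totals["pib"] == totals["fdg"] == 3600.0
        fdg = rd.TRACER_PRESETS["fdg"].schedule
        assert fdg.n_frames == 40 + 10 + 15 + 6 + 10 + 6
        assert np.all(fdg.durations[:40] == 1.0)
        assert np.all(fdg.durations[-6:] == 300.0)


class TestBuildPhantom:
    def test_aorta_region_carries_the_aif(self):
        truth = rd.PhantomTruth.from_preset("water", shape=(9, 6, 2), seed=0)
        volume, labels, aif = rd.build_phantom(truth)
        framed = truth.schedule.frame_average(aif.t, aif.c)
        one_voxel = volume[labels == 1][0]
        np.testing.assert_allclose(one_voxel, framed, atol=1e-12)

    def test_same_seed_bit_identical(self):
        truth = rd.PhantomTruth.from_preset("water", shape=(9, 6, 2), seed=3,
                                            noise_sd0=0.5)
        v1, l1, _ = rd.build_phantom(truth)
        v2, l2, _ = rd.build_phantom(truth)
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(l1, l2)

    def test_truth_json_round_trip(self, tmp_path):
        truth = rd.PhantomTruth.from_preset("pib", shape=(12, 8, 3), seed=7,
                                            noise_sd0=0.3, delta_t=4.0)
        path = tmp_path / "truth.json"
        truth.to_json(str(path))
        back = rd.PhantomTruth.from_json(str(path))
        assert back == truth

    def test_truth_json_round_trip_with_undefined_vd(self, tmp_path):
        """The trapping preset has no distribution volume; the NaN survives
        serialization."""
        truth = rd.PhantomTruth.from_preset("fdg", shape=(9, 6, 2), seed=1)
        path = tmp_path / "truth.json"
        truth.to_json(str(path))
        back = rd.PhantomTruth.from_json(str(path))
        assert math.isnan(back.regions[0].spec.vd_true)
        assert back.schedule_blocks == truth.schedule_blocks

    def test_duplicate_region_labels_rejected(self):
        spec = rd.TRACER_PRESETS["water"].spec
        regions = (rd.RegionSpec("a", 2, 50.0, spec),
                   rd.RegionSpec("b", 2, 60.0, spec))
        with pytest.raises(SchemaError):
            rd.PhantomTruth(shape=(9, 6, 2), regions=regions,
                            schedule_blocks=((40, 1.0), (8, 85.0)), seed=0)
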