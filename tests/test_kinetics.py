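"""Forward convolution model and residue-function physiology."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rifdecon as rd
from rifdecon.exceptions import (
    GridMismatchError,
    InsufficientTailError,
    TooShortSeriesError,
)
from rifdecon.kinetics import k1_from_extraction


def _tac(c, dt=1.0):
    c = np.asarray(c, dtype=float)
    return rd.TimeActivityCurve(np.arange(c.size) * dt, c)


def _res(r, dt=1.0):
    r = np.asarray(r, dtype=float)
    return rd.ResidueFunction(np.arange(r.size) * dt, r)


class TestDiscreteConvolve:
    def test_unit_pulse_sifts_kernel(self):
        """A discrete delta input (1/dt at t=0) returns the kernel itself."""
        dt = 0.5
        aif = _tac([1.0 / dt] + [0.0] * 19, dt)
        r = np.exp(-0.1 * np.arange(20))
        out = rd.discrete_convolve(aif, _res(r, dt))
        np.testing.assert_allclose(out.c, r, atol=1e-14)

    def test_zero_kernel_gives_zero_tissue(self):
        aif = _tac(np.random.default_rng(0).random(20))
        out = rd.discrete_convolve(aif, _res(np.zeros(20)))
        np.testing.assert_array_equal(out.c, 0.0)

    def test_matches_double_loop_sum(self):
        """Brute-force O(n^2) convolution oracle agreement at 1e-12."""
        rng = np.random.default_rng(42)
        ca, r = rng.random(20), rng.random(20)
        dt = 1.0
        expected = np.array([dt * sum(ca[i - j] * r[j] for j in range(i + 1))
                             for i in range(20)])
        out = rd.discrete_convolve(_tac(ca, dt), _res(r, dt))
        np.testing.assert_allclose(out.c, expected, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(GridMismatchError):
            rd.discrete_convolve(_tac(np.ones(10)), _res(np.ones(12)))


class TestBuildToeplitz:
    def test_matches_printed_definition(self):
        A = rd.build_toeplitz(_tac([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(A, [[1, 0, 0], [2, 1, 0], [3, 2, 1]])

    def test_zero_aif_gives_rank_zero(self):
        A = rd.build_toeplitz(_tac(np.zeros(5)))
        assert np.linalg.matrix_rank(A) == 0

    def test_too_short_series_rejected(self):
        with pytest.raises(TooShortSeriesError):
            rd.build_toeplitz(_tac([1.0, 2.0]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(n=st.integers(3, 200), seed=st.integers(0, 10_000))
    def test_product_equals_convolution(self, n, seed):
        """dt * A @ R reproduces the direct discrete convolution to 1e-12."""
        rng = np.random.default_rng(seed)
        dt = 0.5
        aif = _tac(rng.random(n), dt)
        r = _res(rng.random(n), dt)
        product = dt * rd.build_toeplitz(aif) @ r.r
        out = rd.discrete_convolve(aif, r)
        np.testing.assert_allclose(out.c, product, atol=1e-12)


class TestRifMtt:
    def test_mono_exponential_area(self):
        """Fully sampled exp(-t/tau) integrates to tau within 1%."""
        t = np.arange(0.0, 200.0, 0.2)
        mtt = rd.rif_mtt(rd.ResidueFunction(t, np.exp(-t / 10.0)))
        assert mtt == pytest.approx(10.0, rel=0.01)

    def test_constant_rif_diverges(self):
        """A trapped tracer (flat residue) has no finite transit time."""
        t = np.arange(0.0, 300.0, 1.0)
        assert math.isinf(rd.rif_mtt(rd.ResidueFunction(t, np.ones(t.size))))

    def test_bi_exponential_matches_fine_grid_quadrature(self):
        """Tail-extended area vs dense-grid numeric oracle within 1%."""
        t = np.arange(0.0, 400.0, 1.0)
        rif = 0.3 * np.exp(-t / 5.0) + 0.7 * np.exp(-t / 120.0)
        mtt = rd.rif_mtt(rd.ResidueFunction(t, rif))
        tf = np.arange(0.0, 20000.0, 0.05)
        oracle = np.trapezoid(0.3 * np.exp(-tf / 5.0)
                              + 0.7 * np.exp(-tf / 120.0), tf)
        assert mtt == pytest.approx(oracle, rel=0.01)


class TestEstimateExtraction:
    def test_mono_exponential_gives_unit_extraction(self):
        t = np.arange(0.0, 400.0, 1.0)
        e, fit = rd.estimate_extraction(rd.ResidueFunction(t, np.exp(-t / 80)))
        assert e == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-1 / 80, rel=1e-6)

    def test_bi_exponential_reads_slow_amplitude(self):
        """The line fit on t in [60, 300] s recovers the extracted fraction."""
        t = np.arange(0.0, 400.0, 1.0)
        rif = 0.8 * np.exp(-t / 2.0) + 0.2 * np.exp(-t / 500.0)
        e, _ = rd.estimate_extraction(rd.ResidueFunction(t, rif),
                                      window=(60.0, 300.0))
        assert e == pytest.approx(0.2, rel=0.05)

    def test_too_few_positive_points_rejected(self):
        t = np.arange(0.0, 200.0, 1.0)
        r = np.exp(-t / 10.0)
        r[30:] = 0.0
        with pytest.raises(InsufficientTailError):
            rd.estimate_extraction(rd.ResidueFunction(t, r))


class TestDerivePhysiology:
    def test_k1_is_extraction_times_flow(self):
        assert k1_from_extraction(0.62, 50.0) == pytest.approx(31.0)

    def test_kety_kernel_round_trip_recovers_vd(self):
        """Forward-simulate a flow-limited tracer, invert, vd within 2%."""
        cbf_s = 60.0 / 6000.0
        vd_true = 0.9  # fraction -> 90 mL/100mL
        t = np.arange(0.0, 900.0, 1.0)
        aif = rd.default_aif(t, recirc_frac=0.0)
        res = rd.ResidueFunction(t, cbf_s * np.exp(-cbf_s * t / vd_true))
        tis = rd.discrete_convolve(aif, res)
        physio = rd.derive_physiology(res, aif, tis)
        assert physio.cbf == pytest.approx(60.0, rel=1e-9)
        assert physio.vd == pytest.approx(90.0, rel=0.02)
        assert physio.k1 == pytest.approx(physio.e * physio.cbf, rel=1e-9)

    def test_intravascular_identity_gives_vd_100(self):
        """C_tis identical to a fully decayed C_a: integral ratio is 1."""
        t = np.arange(0.0, 600.0, 1.0)
        aif = rd.default_aif(t, recirc_frac=0.0)
        res = rd.ResidueFunction(t, 0.01 * np.exp(-t / 50.0))
        physio = rd.derive_physiology(res, aif, aif)
        assert physio.vd == pytest.approx(100.0, rel=1e-9)

    def test_vd_rules_agree_on_decayed_mono_exponential(self):
        """Integral-ratio vd and CBF x MTT agree within 3% once the tissue
        curve has fully washed out."""
        cbf_s = 50.0 / 6000.0
        t = np.arange(0.0, 1200.0, 1.0)
        aif = rd.default_aif(t, recirc_frac=0.0)
        res = rd.ResidueFunction(t, cbf_s * np.exp(-cbf_s * t / 0.6))
        tis = rd.discrete_convolve(aif, res)
        physio = rd.derive_physiology(res, aif, tis)
        vd_flow = physio.cbf * physio.mtt / 60.0
        assert physio.vd == pytest.approx(vd_flow, rel=0.03)

    def test_negative_samples_reported_as_clipped_fraction(self):
        t = np.arange(0.0, 300.0, 1.0)
        r = 0.01 * np.exp(-t / 60.0)
        r[250:] = -1e-5
        res = rd.ResidueFunction(t, r)
        aif = rd.default_aif(t, recirc_frac=0.0)
        tis = rd.discrete_convolve(aif, rd.ResidueFunction(t, np.maximum(r, 0)))
        physio = rd.derive_physiology(res, aif, tis)
        assert physio.clipped_fraction == pytest.approx(50 / 300)
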