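"""Forward spectral model: resolution profile, detailed balance, DHO kernel,
resolution convolution and total model evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lipidixs as lx
from lipidixs.constants import KB_MEV_PER_K
from lipidixs.errors import InvalidInputError, InvalidParameterError
from lipidixs.lineshape import ConvolutionEngine, validate_energy_grid

from oracles import lorentzian, model_curve


class TestPseudoVoigt:
    @pytest.mark.parametrize(
        "eta, expected_peak",
        [(1.0, 2.0 / (np.pi * 1.7)),                       # Lorentzian 2/(pi*G)
         (0.0, (2.0 / 1.7) * np.sqrt(np.log(2) / np.pi))],  # Gaussian peak
    )
    def test_peak_value(self, eta, expected_peak):
        assert lx.pseudo_voigt(0.0, lx.ResolutionFunction(1.7, eta)) == pytest.approx(
            expected_peak, rel=1e-12)

    def test_unit_area_within_lorentzian_tails(self, rf):
        w = np.linspace(-50, 50, 200001)
        area = np.trapezoid(lx.pseudo_voigt(w, rf), w)
        assert area == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("eta", [0.0, 0.5, 1.0])
    def test_measured_fwhm_matches_parameter(self, eta):
        """The mixture of equal-FWHM profiles halves exactly at +/-fwhm/2."""
        rf = lx.ResolutionFunction(1.7, eta)
        step = 1e-3
        w = np.arange(0.0, 5.0, step)
        y = lx.pseudo_voigt(w, rf)
        half_crossing = float(np.interp(-0.5 * y[0], -y, w))  # y is decreasing
        assert abs(2 * half_crossing - rf.fwhm) <= 2 * step

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(InvalidParameterError):
            lx.ResolutionFunction(-1.0, 0.5)
        with pytest.raises(InvalidParameterError):
            lx.ResolutionFunction(1.7, 1.5)

    @settings(derandomize=True, max_examples=30)
    @given(omega=st.floats(0.1, 20), fwhm=st.floats(0.1, 5), eta=st.floats(0, 1))
    def test_symmetric_and_positive(self, omega, fwhm, eta):
        rf = lx.ResolutionFunction(fwhm, eta)
        assert lx.pseudo_voigt(omega, rf) == pytest.approx(lx.pseudo_voigt(-omega, rf))
        assert lx.pseudo_voigt(omega, rf) >= 0  # Gaussian tail may underflow
        if omega <= 5 * fwhm or eta > 0:
            assert lx.pseudo_voigt(omega, rf) > 0
        assert lx.pseudo_voigt(omega, rf) < lx.pseudo_voigt(0.0, rf)


class TestDetailedBalance:
    def test_unity_at_zero_energy(self):
        assert lx.detailed_balance_factor(0.0, 293.15) == pytest.approx(1.0)

    def test_stokes_anti_stokes_ratio(self):
        # k_B T at 293.15 K is 25.26 meV, so the 2 meV asymmetry is ~8.2%
        b_pos = lx.detailed_balance_factor(2.0, 293.15)
        b_neg = lx.detailed_balance_factor(-2.0, 293.15)
        assert b_pos / b_neg == pytest.approx(np.exp(2.0 / (KB_MEV_PER_K * 293.15)),
                                              rel=1e-10)
        assert b_pos / b_neg == pytest.approx(1.0823, abs=1e-4)

    def test_linear_asymptote_at_large_energy(self):
        t = 300.0
        w = 500.0
        assert lx.detailed_balance_factor(w, t) == pytest.approx(
            w / (KB_MEV_PER_K * t), rel=1e-6)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(InvalidParameterError):
            lx.detailed_balance_factor(1.0, 0.0)

    @settings(derandomize=True, max_examples=40)
    @given(omega=st.floats(0.01, 30), t=st.floats(100, 500))
    def test_ratio_identity_everywhere(self, omega, t):
        ratio = lx.detailed_balance_factor(omega, t) / lx.detailed_balance_factor(-omega, t)
        assert ratio == pytest.approx(np.exp(omega / (KB_MEV_PER_K * t)), rel=1e-8)


class TestDHOKernel:
    def test_unit_area_classical_limit(self):
        w = np.linspace(-400, 400, 800001)
        area = np.trapezoid(lx.dho_kernel(w, 3.0, 0.5), w)
        assert area == pytest.approx(1.0, abs=1e-4)

    def test_even_symmetry(self):
        w = np.linspace(0.1, 20, 57)
        np.testing.assert_allclose(lx.dho_kernel(w, 3.0, 1.0),
                                   lx.dho_kernel(-w, 3.0, 1.0), rtol=1e-12)

    def test_underdamped_peak_near_omega0(self):
        w = np.linspace(0.0, 10.0, 100001)
        peak = w[np.argmax(lx.dho_kernel(w, 3.0, 0.5))]
        assert abs(peak - 3.0) < 0.1

    def test_profile_carries_integrated_intensity(self):
        mode = lx.DHOMode(3.0, 1.0, 250.0)
        w = np.linspace(-500, 500, 1000001)
        # classical limit: strip the balance weight by evaluating the kernel
        area = np.trapezoid(mode.intensity * lx.dho_kernel(w, mode.omega0, mode.gamma), w)
        assert area == pytest.approx(mode.intensity, rel=1e-4)

    def test_invalid_mode_rejected(self):
        with pytest.raises(InvalidParameterError):
            lx.DHOMode(-1.0, 1.0, 10.0)
        with pytest.raises(InvalidParameterError):
            lx.DHOMode(3.0, 0.0, 10.0)
        with pytest.raises(InvalidParameterError):
            lx.dho_kernel(1.0, 3.0, -1.0)

    def test_detailed_balance_of_two_sided_profile(self):
        """Intensity ratio at +/-omega of the full inelastic density equals
        exp(hbar omega / kB T) -- the kernel is even, so the weight carries
        the whole asymmetry."""
        mode = lx.DHOMode(3.0, 1.0, 100.0)
        t = 318.15
        w = np.linspace(0.25, 14.0, 56)
        ratio = lx.dho_profile(w, mode, t) / lx.dho_profile(-w, mode, t)
        np.testing.assert_allclose(ratio, np.exp(w / (KB_MEV_PER_K * t)), rtol=1e-8)


class TestConvolution:
    def test_quasi_delta_is_identity(self):
        rf = lx.ResolutionFunction(1e-3, 0.5)
        g = np.linspace(-10, 10, 201)
        density = lambda w: np.exp(-0.5 * ((w - 1.0) / 0.8) ** 2)
        out = lx.convolve_with_rf(density, rf, g)
        ref = density(g)
        mask = ref > 0.01 * ref.max()
        assert np.max(np.abs(out - ref)[mask]) < 0.005 * ref.max()

    def test_lorentzian_width_additivity(self):
        """L(a) convolved with a pure-Lorentzian RF of width b is L(a+b)."""
        g = np.linspace(-40, 40, 401)
        rf = lx.ResolutionFunction(1.7, 1.0)
        out = lx.convolve_with_rf(lambda w: lorentzian(w, 2.0), rf, g)
        ref = lorentzian(g, 3.7)
        assert np.max(np.abs(out - ref)) < 0.01 * ref.max()

    def test_zeroth_moment_conserved(self):
        rf = lx.ResolutionFunction(1.7, 0.5)
        g = np.linspace(-60, 60, 961)
        density = lambda w: np.exp(-0.5 * w**2) / np.sqrt(2 * np.pi)
        out = lx.convolve_with_rf(density, rf, g)
        assert np.trapezoid(out, g) == pytest.approx(1.0, abs=0.01)

    def test_short_grid_rejected(self, rf):
        with pytest.raises(InvalidInputError):
            lx.convolve_with_rf(lambda w: w * 0, rf, [0.0, 1.0])

    def test_irregular_grid_supported(self, rf):
        g_reg = np.linspace(-12, 12, 241)
        g_irr = np.sort(np.concatenate([np.linspace(-12, -1, 60),
                                        np.linspace(-0.95, 0.95, 120),
                                        np.linspace(1, 12, 60)]))
        density = lambda w: np.exp(-0.5 * (w / 2.0) ** 2)
        out_irr = lx.convolve_with_rf(density, rf, g_irr)
        out_reg = lx.convolve_with_rf(density, rf, g_reg)
        interp = np.interp(g_irr, g_reg, out_reg)
        assert np.max(np.abs(out_irr - interp)) < 0.01 * out_reg.max()


class TestEvaluateModel:
    def test_elastic_only_is_scaled_rf(self, grid97, rf):
        params = lx.SpectralModelParams(123.0, 0.0, (), 293.15)
        out = lx.evaluate_model(params, grid97, rf)
        np.testing.assert_allclose(out, 123.0 * lx.pseudo_voigt(grid97, rf), rtol=1e-12)

    def test_background_only_is_constant(self, grid97, rf):
        params = lx.SpectralModelParams(0.0, 7.5, (), 293.15)
        np.testing.assert_allclose(lx.evaluate_model(params, grid97, rf), 7.5)

    def test_linearity_in_amplitudes(self, grid97, rf):
        base = lx.SpectralModelParams(1000.0, 5.0, (lx.DHOMode(3.0, 1.0, 100.0),), 318.0)
        scaled = lx.SpectralModelParams(3000.0, 15.0, (lx.DHOMode(3.0, 1.0, 300.0),), 318.0)
        np.testing.assert_allclose(lx.evaluate_model(scaled, grid97, rf),
                                   3.0 * lx.evaluate_model(base, grid97, rf), rtol=1e-12)

    def test_against_independent_quadrature_golden(self, grid97, rf, data_dir):
        """Regression against a frozen evaluation produced by a direct
        scipy.integrate.quad implementation of elastic + DHO (*) RF."""
        golden = np.loadtxt(data_dir / "golden_model_eval.csv", delimiter=",")
        params = lx.SpectralModelParams(1000.0, 5.0, (lx.DHOMode(3.0, 1.0, 100.0),), 318.0)
        out = lx.evaluate_model(params, golden[:, 0], rf)
        assert np.max(np.abs(out - golden[:, 1])) < 0.005 * golden[:, 1].max()

    def test_matches_oracle_for_two_modes(self, rf):
        """Fresh (non-frozen) cross-check on a coarse grid with two modes."""
        g = np.linspace(-12, 12, 25)
        modes = [(2.0, 0.8, 50.0), (6.0, 1.5, 80.0)]
        ref = model_curve(g, 400.0, 2.0, modes, 293.15, 1.7, 0.5)
        params = lx.SpectralModelParams(
            400.0, 2.0, tuple(lx.DHOMode(*m) for m in modes), 293.15)
        out = lx.evaluate_model(params, g, rf)
        assert np.max(np.abs(out - ref)) < 0.005 * ref.max()


class TestGridValidation:
    def test_rejects_descending_and_short_grids(self):
        with pytest.raises(InvalidInputError):
            validate_energy_grid([0.0, 1.0])
        with pytest.raises(InvalidInputError):
            validate_energy_grid([0.0, 2.0, 1.0])
        with pytest.raises(InvalidInputError):
            validate_energy_grid([1.0, 2.0, 3.0], require_both_signs=True)
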