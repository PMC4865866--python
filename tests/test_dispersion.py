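"""Dispersion assembly and derived observables: sound speeds, zone boundary,
area per lipid, damping ratios, transverse band gap and cluster size."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lipidixs as lx
from lipidixs.constants import MEV_NM_TO_M_PER_S
from lipidixs.dispersion import (DispersionBranch, classify_damping,
                                 damping_ratio, detect_phonon_gap, find_q_min)
from lipidixs.errors import (InsufficientDataError, InvalidInputError,
                             InvalidParameterError)
from lipidixs.fitting import FitResult, ModeSelection
from lipidixs.lineshape import DHOMode, SpectralModelParams


def _branch(q, omega, gamma=None, present=None, label="longitudinal",
            omega_err=None, gamma_err=None):
    q = np.asarray(q, dtype=float)
    omega = np.asarray(omega, dtype=float)
    gamma = np.ones_like(q) if gamma is None else np.asarray(gamma, dtype=float)
    present = np.ones_like(q, dtype=bool) if present is None else np.asarray(present)
    omega_err = 0.05 * np.ones_like(q) if omega_err is None else np.asarray(omega_err)
    gamma_err = 0.05 * np.ones_like(q) if gamma_err is None else np.asarray(gamma_err)
    return DispersionBranch(q=q, omega=omega, omega_err=omega_err,
                            gamma=gamma, gamma_err=gamma_err,
                            present=present, label=label)


def _fit_pair(q, modes, n_chosen=None):
    modes = tuple(modes)
    n_chosen = len(modes) if n_chosen is None else n_chosen
    params = SpectralModelParams(1000.0, 5.0, modes, 293.15)
    fit = FitResult(params=params,
                    param_errors=np.full(2 + 3 * len(modes), 0.1),
                    reduced_chi2=1.0, residuals=np.zeros(97),
                    n_free_params=2 + 3 * len(modes), converged=True, q=q)
    sel = ModeSelection(chosen_n_modes=max(n_chosen, 1), chi2_one=2.0,
                        chi2_two=1.0, vanished=False, two_hump_flag=False)
    return fit, sel


class TestAssembleBranches:
    def test_two_mode_fits_populate_both_branches(self):
        pairs = [
            _fit_pair(q, [DHOMode(1.0 + 0.1 * q, 0.5, 100.0, "transverse"),
                          DHOMode(3.0 + 0.2 * q, 0.8, 100.0, "longitudinal")])
            for q in np.linspace(2.47, 27.29, 18)
        ]
        longitudinal, transverse = lx.assemble_branches(pairs)
        assert len(longitudinal) == len(transverse) == 18
        assert longitudinal.present.all() and transverse.present.all()

    def test_gap_encoded_in_present_flags(self):
        qs = np.linspace(2.47, 27.29, 18)
        pairs = []
        for q in qs:
            if q < 5.0:
                pairs.append(_fit_pair(q, [DHOMode(3.0, 0.8, 100.0, "longitudinal")]))
            else:
                pairs.append(_fit_pair(q, [DHOMode(1.5, 0.5, 100.0, "transverse"),
                                           DHOMode(5.0, 0.8, 100.0, "longitudinal")]))
        longitudinal, transverse = lx.assemble_branches(pairs)
        assert longitudinal.present.all()
        np.testing.assert_array_equal(transverse.present, qs >= 5.0)

    def test_single_fit_gives_length_one(self):
        longitudinal, transverse = lx.assemble_branches(
            [_fit_pair(3.0, [DHOMode(2.0, 0.5, 10.0, "longitudinal")])])
        assert len(longitudinal) == 1 and len(transverse) == 1

    def test_duplicates_and_empty_rejected(self):
        pair = _fit_pair(3.0, [DHOMode(2.0, 0.5, 10.0, "longitudinal")])
        with pytest.raises(InvalidInputError):
            lx.assemble_branches([pair, pair])
        with pytest.raises(InvalidInputError):
            lx.assemble_branches([])


class TestSoundSpeed:
    def test_unit_slope_conversion_constant(self):
        q = np.linspace(0.5, 6, 8)
        v, err = lx.sound_speed(_branch(q, 1.0 * q), q_linear_max=8.0)
        assert v == pytest.approx(1519.26, rel=1e-3)

    def test_linearity_in_omega(self):
        q = np.linspace(0.5, 6, 8)
        v1, _ = lx.sound_speed(_branch(q, 1.2 * q), q_linear_max=8.0)
        v2, _ = lx.sound_speed(_branch(q, 2.4 * q), q_linear_max=8.0)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_gel_phase_slope_value(self):
        q = np.linspace(0.5, 6, 8)
        v, _ = lx.sound_speed(_branch(q, 1.667 * q), q_linear_max=8.0)
        assert v == pytest.approx(2532, rel=2e-3)

    def test_invariant_under_subsampling_of_linear_branch(self):
        q = np.linspace(0.5, 8, 16)
        full = _branch(q, 0.9 * q)
        sub = _branch(q[::3], 0.9 * q[::3])
        v_full, _ = lx.sound_speed(full, 8.0)
        v_sub, _ = lx.sound_speed(sub, 8.0)
        assert v_sub == pytest.approx(v_full, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            lx.sound_speed(_branch([1.0, 6.0, 7.0], [1, 6, 7]), q_linear_max=2.0)


class TestFindQMin:
    def test_exact_parabola_recovered(self):
        q = np.array([14.0, 15.0, 16.0, 17.0])
        result = find_q_min(_branch(q, (q - 15.4) ** 2 + 2.0), (12.0, 19.0))
        assert result.q_min == pytest.approx(15.4, abs=0.05)
        assert not result.edge_flag

    def test_monotone_branch_flagged(self):
        q = np.linspace(10, 19, 7)
        result = find_q_min(_branch(q, 0.5 * q), (10.0, 19.0))
        assert result.edge_flag

    def test_noisy_zone_boundary_recovery(self):
        """Parabolic interpolation beats the coarse Q spacing: over seeded
        noise realisations the vertex lands within ~2x its propagated error."""
        rng = np.random.default_rng(42)
        q = np.linspace(2.47, 27.29, 18)
        true_min = 15.4
        hits = 0
        n = 50
        for _ in range(n):
            omega = 8.2 * np.abs(np.sin(np.pi * q / true_min))
            sigma = 0.25 * np.ones_like(q)
            noisy = np.clip(omega + rng.normal(0, sigma), 0.01, None)
            result = find_q_min(_branch(q, noisy, omega_err=sigma), (10.0, 20.0))
            tol = 2.0 * max(result.stderr, 1e-6)
            hits += abs(result.q_min - true_min) <= tol
        assert hits >= 0.8 * n

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            find_q_min(_branch([14.0, 15.0, 16.0], [2, 1, 2],
                               present=[True, True, False]), (10.0, 20.0))


class TestAreaPerLipid:
    @pytest.mark.parametrize("q_min, expected", [
        (15.4, 55.6),   # gel phase
        (14.2, 65.4),   # fluid phase
        (2 * np.pi, 334.125),  # d = 10 Angstrom by construction
    ])
    def test_reference_values(self, q_min, expected):
        assert lx.area_per_lipid(q_min) == pytest.approx(expected, abs=0.1)

    def test_invalid_q_rejected(self):
        with pytest.raises(InvalidParameterError):
            lx.area_per_lipid(0.0)

    @settings(derandomize=True, max_examples=30)
    @given(q=st.floats(5.0, 25.0), dq=st.floats(0.01, 5.0))
    def test_strictly_decreasing_in_q_min(self, q, dq):
        assert lx.area_per_lipid(q) > lx.area_per_lipid(q + dq)


class TestDampingRatio:
    @pytest.mark.parametrize("omega, gamma, expected_r, regime", [
        (2.0, 2.0, 1.0, "critical"),
        (3.0, 0.5, 6.0, "underdamped"),
        (1.0, 4.0, 0.25, "overdamped"),
    ])
    def test_classification(self, omega, gamma, expected_r, regime):
        branch = _branch([1.0], [omega], gamma=[gamma],
                         omega_err=[0.0], gamma_err=[0.0])
        r, r_err = damping_ratio(branch)
        assert r[0] == pytest.approx(expected_r)
        assert classify_damping(r[0], r_err[0]) == regime

    def test_exactly_one_regime_per_point(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            r = rng.uniform(0.05, 5.0)
            err = rng.uniform(0.0, 0.3)
            regimes = [classify_damping(r, err)]
            assert len(set(regimes)) == 1
            assert regimes[0] in ("overdamped", "critical", "underdamped")

    def test_error_propagation(self):
        branch = _branch([1.0], [3.0], gamma=[1.5],
                         omega_err=[0.3], gamma_err=[0.15])
        r, r_err = damping_ratio(branch)
        expected = 2.0 * np.sqrt((0.3 / 3.0) ** 2 + (0.15 / 1.5) ** 2)
        assert r_err[0] == pytest.approx(expected)


class TestPhononGap:
    def test_gap_edge_midpoint_rule(self):
        q = np.array([2.47, 3.89, 5.2, 6.6, 8.0])
        present = np.array([False, False, True, True, True])
        branch = _branch(q, np.where(present, 1.5, np.nan), present=present,
                         label="transverse")
        gap = detect_phonon_gap(branch)
        assert gap.q_gap == pytest.approx((3.89 + 5.2) / 2)

    def test_no_gap_when_present_at_lowest_q(self):
        branch = _branch([2.47, 3.89, 5.2], [1, 1, 1], label="transverse")
        assert detect_phonon_gap(branch) is None

    def test_all_absent_warns_and_returns_none(self):
        q = np.array([2.47, 3.89, 5.2])
        branch = _branch(q, np.full(3, np.nan), present=np.zeros(3, bool),
                         label="transverse")
        with pytest.warns(UserWarning):
            assert detect_phonon_gap(branch) is None


class TestClusterSize:
    @pytest.mark.parametrize("q_gap, expected", [
        (5.0, 1.257),
        (2 * np.pi, 1.0),
        (3.9, 1.611),
    ])
    def test_values(self, q_gap, expected):
        assert lx.cluster_size(q_gap) == pytest.approx(expected, abs=1e-3)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            lx.cluster_size(-1.0)

    @settings(derandomize=True, max_examples=30)
    @given(q=st.floats(1.0, 20.0), dq=st.floats(0.01, 5.0))
    def test_strictly_decreasing(self, q, dq):
        assert lx.cluster_size(q) > lx.cluster_size(q + dq)
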