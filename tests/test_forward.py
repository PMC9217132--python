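"""Forward model: transfer functions, closed-form PSD, time-domain twin."""

import numpy as np
import pytest

from eispec.forward import (
    FrequencyGrid,
    InstabilityError,
    NMMParameters,
    NumericalDegeneracyError,
    _psd_db_fast,
    gamma_transfer,
    is_stable,
    local_transfer,
    model_psd_db,
    simulate_time_domain,
    state_matrices,
)


class TestNMMParameters:
    def test_from_ms_roundtrip(self):
        p = NMMParameters.from_ms(12.5, 17.0, 2.0, 3.0)
        assert p.tau_e == pytest.approx(0.0125)
        assert p.tau_e_ms == pytest.approx(12.5)
        assert NMMParameters.from_dict(p.to_dict()) == p

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            NMMParameters.from_ms(0.0, 15.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            NMMParameters.from_ms(10.0, -1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            NMMParameters.from_ms(10.0, 15.0, -0.5, 1.0)
        with pytest.raises(ValueError):
            NMMParameters.from_ms(10.0, 15.0, 1.0, 1.0, noise_sd=-1.0)

    def test_with_updates_fields(self):
        p = NMMParameters.from_ms(12.0, 15.0, 1.0, 1.0)
        assert p.with_(g_ee=2.0).g_ee == 2.0


class TestFrequencyGrid:
    def test_default_covers_analysis_band(self, grid):
        assert grid.frequencies[0] == 1.0
        assert grid.frequencies[-1] == 35.0
        assert len(grid) == 69
        assert np.allclose(np.diff(grid.frequencies), 0.5)

    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([]))


class TestGammaTransfer:
    def test_dc_value_is_unity(self):
        g = FrequencyGrid(np.array([1e-9]))
        assert gamma_transfer(0.015, g)[0] == pytest.approx(1.0, abs=1e-6)

    def test_magnitude_decays_monotonically(self, grid):
        mag = np.abs(gamma_transfer(0.015, grid))
        assert np.all(np.diff(mag) < 0)
        assert np.all(mag <= 1.0)

    def test_matches_numerical_fourier_transform_of_kernel(self):
        # F(omega) should equal the numerically integrated transform of
        # f(t) = (t / tau^2) exp(-t / tau)
        tau = 0.012
        t = np.linspace(0, 40 * tau, 200_001)
        kernel = (t / tau**2) * np.exp(-t / tau)
        grid = FrequencyGrid(np.array([1.0, 5.0, 17.0, 35.0]))
        analytic = gamma_transfer(tau, grid)
        for k, f in enumerate(grid.frequencies):
            numeric = np.trapezoid(kernel * np.exp(-2j * np.pi * f * t), t)
            assert numeric == pytest.approx(analytic[k], abs=1e-7)

    def test_requires_positive_tau(self, grid):
        with pytest.raises(ValueError):
            gamma_transfer(0.0, grid)


class TestLocalTransfer:
    def test_matches_generic_linear_solver(self, grid, stable_params):
        h_e, h_i = local_transfer(stable_params, grid)
        p = stable_params
        fe = gamma_transfer(p.tau_e, grid)
        fi = gamma_transfer(p.tau_i, grid)
        for k, w in enumerate(grid.omega):
            A = np.array(
                [
                    [1j * w + (fe[k] / p.tau_e) * p.g_ee, -(fe[k] / p.tau_e) * p.g_ei * fi[k]],
                    [(fi[k] / p.tau_i) * p.g_ei * fe[k], 1j * w + (fi[k] / p.tau_i) * p.g_ii],
                ]
            )
            x = np.linalg.solve(A, np.ones(2))
            assert x[0] == pytest.approx(h_e[k], rel=1e-10)
            assert x[1] == pytest.approx(h_i[k], rel=1e-10)

    def test_no_degeneracy_across_bounds_box(self, grid):
        # for one real frequency the complex determinant has two real parts
        # that cannot both vanish at valid parameters, so the degeneracy
        # guard should never fire inside the fitting bounds; transfer values
        # must always be finite there
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = NMMParameters.from_ms(
                rng.uniform(5, 30), rng.uniform(5, 30),
                rng.uniform(0.1, 10), rng.uniform(0.1, 10),
            )
            h_e, h_i = local_transfer(p, grid)
            assert np.all(np.isfinite(h_e)) and np.all(np.isfinite(h_i))

    def test_degeneracy_error_is_a_value_error(self):
        assert issubclass(NumericalDegeneracyError, ValueError)


class TestModelPsd:
    def test_noise_sd_is_additive_db_offset(self, grid, stable_params):
        base = model_psd_db(stable_params, grid).psd_db
        scaled = model_psd_db(stable_params.with_(noise_sd=10.0), grid).psd_db
        assert np.allclose(scaled - base, 20.0, atol=1e-12)

    def test_zero_noise_sd_rejected(self, grid, stable_params):
        with pytest.raises(ValueError):
            model_psd_db(stable_params.with_(noise_sd=0.0), grid)

    def test_independent_mode_differs_from_common(self, grid, stable_params):
        common = model_psd_db(stable_params, grid, "common").psd_db
        indep = model_psd_db(stable_params, grid, "independent").psd_db
        assert not np.allclose(common, indep)
        with pytest.raises(ValueError):
            model_psd_db(stable_params, grid, "bogus")

    def test_fast_path_matches_validated_path(self, grid):
        rng = np.random.default_rng(3)
        for _ in range(10):
            te, ti = rng.uniform(5, 30, 2)
            gee, gii = rng.uniform(0.1, 10, 2)
            ref = model_psd_db(NMMParameters.from_ms(te, ti, gee, gii), grid).psd_db
            fast = _psd_db_fast(te, ti, gee, gii, 1.0, grid.omega, "common")
            assert np.allclose(ref, fast, atol=1e-12)


class TestStateSpace:
    def test_state_matrix_eigenvalues_match_transfer_poles(self, stable_params, grid):
        # the closed-form |He+Hi|^2 evaluated via the state-space resolvent
        # must equal local_transfer: C (jwI - A)^-1 B with C selecting x_e+x_i
        A, B = state_matrices(stable_params)
        h_e, h_i = local_transfer(stable_params, grid)
        C = np.zeros(10)
        C[0] = C[1] = 1.0
        for k in (0, len(grid) // 2, len(grid) - 1):
            w = grid.omega[k]
            resolvent = np.linalg.solve(1j * w * np.eye(10) - A, B[:, 0])
            assert C @ resolvent == pytest.approx(h_e[k] + h_i[k], rel=1e-9)

    def test_noise_mode_column_counts(self, stable_params):
        assert state_matrices(stable_params, "common")[1].shape == (10, 1)
        assert state_matrices(stable_params, "independent")[1].shape == (10, 2)
        with pytest.raises(ValueError):
            state_matrices(stable_params, "bogus")

    def test_default_protocol_parameters_are_unstable(self):
        # the conventional initial point of the fitting protocol is not a
        # stable dynamical system; the closed form is still well-defined there
        p = NMMParameters.from_ms(17.0, 17.0, 0.5, 0.5)
        assert not is_stable(p)
        assert np.all(np.isfinite(model_psd_db(p).psd_db))


class TestSimulation:
    def test_deterministic_per_seed(self, stable_params):
        a = simulate_time_domain(stable_params, 200, 10, seed=5)
        b = simulate_time_domain(stable_params, 200, 10, seed=5)
        c = simulate_time_domain(stable_params, 200, 10, seed=6)
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_signal_is_sum_of_populations(self, stable_params):
        r = simulate_time_domain(stable_params, 200, 10, seed=1)
        assert np.array_equal(r.signal, r.x_e + r.x_i)
        assert len(r.signal) == 2000

    def test_zero_noise_decays_from_initial_state(self, stable_params):
        x0 = np.zeros(10)
        x0[0] = 1.0
        # the E/I feedback creates a slow mode (decay ~0.4/s for this set),
        # so allow enough time for the envelope to collapse
        r = simulate_time_domain(
            stable_params.with_(noise_sd=0.0), 200, 60, seed=0, initial_state=x0
        )
        assert abs(r.signal[-1]) < 1e-6 * abs(r.signal[0])

    def test_unstable_parameters_raise(self):
        p = NMMParameters.from_ms(17.0, 17.0, 0.5, 0.5)
        with pytest.raises(InstabilityError):
            simulate_time_domain(p, 200, 10, seed=0)

    def test_input_validation(self, stable_params):
        with pytest.raises(ValueError):
            simulate_time_domain(stable_params, 100, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_time_domain(stable_params, 200, 5, seed=0)
        with pytest.raises(ValueError):
            simulate_time_domain(stable_params, 200, 10, seed=0, initial_state=np.zeros(3))
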