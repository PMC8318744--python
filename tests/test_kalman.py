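import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kalmix import (
    FilterConfig,
    SensitivityMatrix,
    Spectrum,
    align_to_grid,
    build_sensitivity_matrix,
    cls_oracle,
    component_spectrum,
    innovation_diagnostics,
    kalman_step,
    mixture_spectrum,
    run_filter,
)
from kalmix.errors import (
    GridMismatchError,
    SingularityError,
    UnobservableComponentError,
)
from kalmix.synth import MixtureDesign, NoiseModel


class TestSensitivityMatrix:
    def test_single_point_calibration_divides_by_concentration(self):
        grid = np.array([220.0, 221.0])
        std = Spectrum(grid, np.array([0.5, 1.0]), "drug")
        H = build_sensitivity_matrix(
            align_to_grid([std]), {"drug": 5.0}
        )
        np.testing.assert_allclose(H.values[:, 0], [0.1, 0.2])

    def test_mismatched_grids_rejected(self):
        a = Spectrum(np.array([220.0, 221.0]), np.ones(2), "a")
        b = Spectrum(np.array([220.5, 221.5]), np.ones(2), "b")
        with pytest.raises(GridMismatchError):
            align_to_grid([a, b])

    def test_nonpositive_concentration_rejected(self):
        grid = np.array([220.0, 221.0])
        std = align_to_grid([Spectrum(grid, np.ones(2), "drug")])
        with pytest.raises(ValueError, match="> 0"):
            build_sensitivity_matrix(std, {"drug": 0.0})

    def test_all_zero_column_unobservable(self):
        grid = np.array([220.0, 221.0])
        with pytest.raises(UnobservableComponentError, match="ghost"):
            SensitivityMatrix(grid, ("ghost",), np.zeros((2, 1)))

    def test_preset_standard_peaks_at_band_center(self, preset_sensitivity):
        H = preset_sensitivity
        hct_col = H.values[:, 0]
        assert H.grid[np.argmax(hct_col)] == 272.0


class TestKalmanStep:
    def test_zero_measurement_zero_prior_is_fixed_point(self):
        c, P, e = kalman_step(np.zeros(2), np.eye(2), np.array([1.0, 0.0]), 0.0, 1e-6)
        np.testing.assert_allclose(c, 0.0)
        assert e == 0.0

    def test_diffuse_prior_single_step_approaches_measurement(self):
        # with h=[1] and prior variance >> r, one update lands on A
        c, _, _ = kalman_step(np.zeros(1), np.eye(1) * 1e12, np.ones(1), 0.37, 1e-6)
        assert c[0] == pytest.approx(0.37, rel=1e-9)

    def test_single_step_matches_hand_algebra(self):
        # closed form: g = P h / (h P h + r), c' = g A
        P0, r = 1e6, 1e-6
        h = np.array([1.0, 0.5])
        A = 2.0
        g = P0 * h / (P0 * (h @ h) + r)
        c, P, e = kalman_step(np.zeros(2), np.eye(2) * P0, h, A, r)
        np.testing.assert_allclose(c, g * A, rtol=1e-12)
        assert e == pytest.approx(2.0)
        # covariance update: P' = P - g (h P)
        expected_P = np.eye(2) * P0 - np.outer(g, h * P0)
        np.testing.assert_allclose(P, 0.5 * (expected_P + expected_P.T), rtol=1e-9)

    def test_joseph_form_agrees_with_plain(self):
        rng = np.random.default_rng(7)
        P = np.eye(3) * 10.0
        h = rng.normal(size=3)
        c0 = rng.normal(size=3)
        plain = kalman_step(c0, P, h, 1.0, 1e-3)
        joseph = kalman_step(c0, P, h, 1.0, 1e-3, joseph=True)
        np.testing.assert_allclose(plain[0], joseph[0], rtol=1e-10)
        np.testing.assert_allclose(plain[1], joseph[1], rtol=1e-8, atol=1e-10)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            kalman_step(np.zeros(1), np.eye(1), np.ones(1), np.nan, 1e-6)


class TestRunFilter:
    def test_single_component_proportionality(self, presets):
        hct, _, grid = presets
        std = component_spectrum(hct, 5.0, grid)
        lsp_std = component_spectrum(presets[1], 20.0, grid)
        H = build_sensitivity_matrix(
            align_to_grid([std, lsp_std]), {std.label: 5.0, lsp_std.label: 20.0}
        )
        sample = std.scaled(2.0, "double")
        res = run_filter(H, sample)
        np.testing.assert_allclose(res.estimate, [10.0, 0.0], rtol=1e-6, atol=1e-6)

    def test_exact_linear_system(self, hand_system):
        H, sample, c_true = hand_system
        res = run_filter(H, sample)
        np.testing.assert_allclose(res.estimate, c_true, rtol=1e-6)
        assert res.converged

    def test_noisy_mixture_recovered_within_2pct(self, presets, preset_sensitivity):
        hct, lsp, grid = presets
        sset = mixture_spectrum(
            [hct, lsp],
            MixtureDesign({"HCT": 5.0, "LSP": 20.0}, 1, "M7"),
            NoiseModel(0.002, seed=123),
            grid,
        )
        res = run_filter(preset_sensitivity, sset[0])
        np.testing.assert_allclose(res.estimate, [5.0, 20.0], rtol=0.02)

    def test_grid_mismatch_rejected(self, hand_system):
        H, _, _ = hand_system
        other = Spectrum(np.array([231.0, 251.0, 271.0]), np.ones(3), "off")
        with pytest.raises(GridMismatchError):
            run_filter(H, other)

    def test_negative_estimate_warned_not_clipped(self, hand_system):
        H, _, _ = hand_system
        # sample = -1 x component y only
        sample = Spectrum(H.grid, -H.values[:, 1], "neg")
        with pytest.warns(UserWarning, match="negative"):
            res = run_filter(H, sample)
        assert res.estimate[1] == pytest.approx(-1.0, rel=1e-6)

    def test_innovation_count_matches_steps(self, hand_system):
        H, sample, _ = hand_system
        res = run_filter(H, sample)
        assert len(res.innovations) == len(H.grid) * res.passes_used


class TestClsOracle:
    def test_hand_solved_system(self, hand_system):
        H, sample, c_true = hand_system
        est, cov = cls_oracle(H, sample)
        np.testing.assert_allclose(est, c_true, rtol=1e-12)
        assert cov.shape == (2, 2)

    def test_identical_columns_singular(self):
        grid = np.array([220.0, 221.0, 222.0])
        col = np.array([0.1, 0.2, 0.3])
        H = SensitivityMatrix(grid, ("p", "q"), np.column_stack([col, col]))
        sample = Spectrum(grid, col, "s")
        with pytest.raises(SingularityError, match="'p' and 'q'"):
            cls_oracle(H, sample)

    def test_noiseless_scale_factor_exact(self, presets):
        hct, lsp, grid = presets
        stds = align_to_grid(
            [component_spectrum(hct, 5.0, grid), component_spectrum(lsp, 20.0, grid)]
        )
        H = build_sensitivity_matrix(stds, {stds[0].label: 5.0, stds[1].label: 20.0})
        sample = stds[0].scaled(3.0, "x3")
        est, _ = cls_oracle(H, sample)
        np.testing.assert_allclose(est, [15.0, 0.0], atol=1e-9)


class TestInnovationDiagnostics:
    def test_constant_zero_sequence(self, hand_system):
        H, sample, _ = hand_system
        res = run_filter(H, sample)
        d = innovation_diagnostics(res)
        assert set(d) == {"mean", "variance", "lag1_autocorrelation"}

    def test_alternating_sequence_anticorrelated(self, hand_system):
        H, sample, _ = hand_system
        res = run_filter(H, sample)
        fake = res.__class__(
            estimate=res.estimate,
            covariance=res.covariance,
            innovations=np.array([1.0, -1.0, 1.0, -1.0]),
            trace=res.trace,
            passes_used=res.passes_used,
            components=res.components,
            converged=res.converged,
        )
        d = innovation_diagnostics(fake)
        assert d["mean"] == 0.0
        assert d["lag1_autocorrelation"] == pytest.approx(-1.0)

    def test_converged_noiseless_run_has_tiny_innovation_variance(self, hand_system):
        H, sample, _ = hand_system
        res = run_filter(H, sample)
        last_sweep = res.innovations[-len(H.grid):]
        assert float(np.var(last_sweep)) < 1e-12


class TestFilterProperties:
    @given(
        n_comp=st.integers(min_value=2, max_value=4),
        n_wl=st.integers(min_value=10, max_value=81),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_oracle_equivalence(self, n_comp, n_wl, seed):
        """Converged filter with a diffuse prior matches batch CLS."""
        rng = np.random.default_rng(seed)
        grid = 220.0 + np.arange(n_wl, dtype=float)
        values = rng.uniform(0.01, 1.0, size=(n_wl, n_comp))
        H = SensitivityMatrix(grid, tuple(f"c{i}" for i in range(n_comp)), values)
        c_true = rng.uniform(0.5, 20.0, size=n_comp)
        A = values @ c_true + rng.normal(0.0, 0.002, size=n_wl)
        sample = Spectrum(grid, A, "rand")
        cfg = FilterConfig(prior_variance=1e6, measurement_variance=1e-6)
        res = run_filter(H, sample, cfg)
        est, _ = cls_oracle(H, sample)
        np.testing.assert_allclose(res.estimate, est, rtol=1e-6)

    def test_order_invariance(self, preset_sensitivity, presets):
        hct, lsp, grid = presets
        sset = mixture_spectrum(
            [hct, lsp],
            MixtureDesign({"HCT": 3.0, "LSP": 16.0}, 1, "m"),
            NoiseModel(0.002, seed=5),
            grid,
        )
        up = run_filter(preset_sensitivity, sset[0])
        down = run_filter(preset_sensitivity, sset[0], descending=True)
        np.testing.assert_allclose(up.estimate, down.estimate, rtol=1e-6)

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_linearity_in_sample_scale(self, hand_system, k):
        H, sample, _ = hand_system
        base = run_filter(H, sample)
        scaled = run_filter(H, sample.scaled(k, "scaled"))
        np.testing.assert_allclose(scaled.estimate, k * base.estimate, rtol=1e-9)

    def test_covariance_contraction(self, hand_system):
        """Posterior variance of every component never increases."""
        H, sample, _ = hand_system
        c = np.zeros(2)
        P = np.eye(2) * 1e6
        diags = [np.diag(P).copy()]
        for _ in range(3):
            for kk in range(len(H.grid)):
                c, P, _ = kalman_step(
                    c, P, H.values[kk], sample.absorbances[kk], 1e-6
                )
                diags.append(np.diag(P).copy())
        diags = np.asarray(diags)
        assert np.all(np.diff(diags, axis=0) <= 1e-12)
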