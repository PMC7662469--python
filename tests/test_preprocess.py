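import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soyspec import (
    normalize_2norm100, savgol, mean_center, select_region,
    fit_apply_recipe, PreprocessRecipe,
)
from soyspec.errors import DegenerateInputError, ParameterError
from soyspec.preprocess import regression_recipe

from conftest import make_spectra


def brute_force_savgol(y, window, polyorder, deriv):
    """Independent oracle: explicit least-squares polynomial fit in every
    window, derivative evaluated at the window's target offset. Edge points
    reuse the nearest full window, evaluated off-center."""
    import math
    n = len(y)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        c = min(max(i, half), n - 1 - half)   # center of nearest full window
        idx = np.arange(c - half, c + half + 1)
        # fit y = sum_j a_j (x - c)^j by explicit normal equations
        V = np.vander(idx - c, polyorder + 1, increasing=True)
        a, *_ = np.linalg.lstsq(V, y[idx], rcond=None)
        x0 = i - c
        val = sum(
            a[j] * math.factorial(j) / math.factorial(j - deriv) * x0 ** (j - deriv)
            for j in range(deriv, polyorder + 1)
        )
        out[i] = val
    return out


class TestNormalize:
    def test_3_4_5_triangle(self):
        np.testing.assert_allclose(normalize_2norm100(np.array([3.0, 4.0])),
                                   [60.0, 80.0])

    def test_1_2_2(self):
        np.testing.assert_allclose(
            normalize_2norm100(np.array([1.0, 2.0, 2.0])),
            [100 / 3, 200 / 3, 200 / 3])

    def test_norm_100_fixed_point(self):
        v = np.array([60.0, 80.0])
        np.testing.assert_allclose(normalize_2norm100(v), v)

    def test_zero_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize_2norm100(np.zeros(5))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
           st.floats(1e-3, 1e3))
    def test_idempotent_and_scale_invariant(self, vals, c):
        x = np.asarray(vals)
        if np.linalg.norm(x) < 1e-9 or np.linalg.norm(c * x) == 0:
            return
        f = normalize_2norm100
        np.testing.assert_allclose(np.linalg.norm(f(x)), 100.0, atol=1e-9)
        np.testing.assert_allclose(f(f(x)), f(x), atol=1e-9)
        np.testing.assert_allclose(f(c * x), f(x), atol=1e-7)


class TestSavgol:
    def test_exact_second_derivative_of_quadratic(self):
        s = make_spectra(n_samples=1, n_wavelengths=60, spacing=8.0)
        lam = np.arange(60, dtype=float)  # unit-spaced index
        s = s.with_absorbance(lam[None, :] ** 2)
        out = savgol(s, window=5, polyorder=2, deriv_order=2)
        np.testing.assert_allclose(out.absorbance, 2.0, atol=1e-9)

    def test_linear_input_gives_zero_second_derivative(self):
        s = make_spectra(n_samples=2, n_wavelengths=40)
        lam = np.arange(40, dtype=float)
        s = s.with_absorbance(np.vstack([3 * lam + 1, -2 * lam + 5]))
        out = savgol(s, window=21, polyorder=3, deriv_order=2)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-8)

    def test_matches_brute_force_polyfit_oracle(self):
        rng = np.random.default_rng(7)
        s = make_spectra(n_samples=1, n_wavelengths=60)
        y = rng.normal(0, 1, 60)
        s = s.with_absorbance(y[None, :])
        out = savgol(s, window=21, polyorder=3, deriv_order=2)
        expected = brute_force_savgol(y, 21, 3, 2)
        np.testing.assert_allclose(out.absorbance[0], expected, atol=1e-9)

    @pytest.mark.parametrize("window,polyorder,deriv", [
        (11, 2, 1), (7, 3, 0), (9, 4, 2),
    ])
    def test_oracle_agreement_other_settings(self, window, polyorder, deriv):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, 50)
        s = make_spectra(n_samples=1, n_wavelengths=50).with_absorbance(y[None, :])
        out = savgol(s, window=window, polyorder=polyorder, deriv_order=deriv)
        np.testing.assert_allclose(
            out.absorbance[0], brute_force_savgol(y, window, polyorder, deriv),
            atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 40))
        base = make_spectra(n_samples=1, n_wavelengths=40)
        op = lambda v: savgol(base.with_absorbance(v[None, :]),
                              9, 3, 2).absorbance[0]
        np.testing.assert_allclose(op(2.5 * x - 1.5 * y),
                                   2.5 * op(x) - 1.5 * op(y), atol=1e-9)

    def test_per_nm_scaling(self):
        rng = np.random.default_rng(5)
        s = make_spectra(n_samples=1, n_wavelengths=40, spacing=8.0)
        s = s.with_absorbance(rng.normal(size=(1, 40)))
        per_step = savgol(s, 9, 3, 2).absorbance
        per_nm = savgol(s, 9, 3, 2, per_nm=True).absorbance
        np.testing.assert_allclose(per_nm, per_step / 64.0, atol=1e-12)

    @pytest.mark.parametrize("window,polyorder", [(10, 3), (3, 3)])
    def test_bad_parameters(self, window, polyorder):
        s = make_spectra(n_samples=1, n_wavelengths=40)
        with pytest.raises(ParameterError):
            savgol(s, window=window, polyorder=polyorder, deriv_order=2)


class TestMeanCenter:
    def test_row_mode(self):
        s = make_spectra(n_samples=1, n_wavelengths=8).with_absorbance(
            np.array([[1., 2., 3., 4., 5., 6., 7., 8.]]))
        out = mean_center(s, "row")
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0)
        np.testing.assert_allclose(out.absorbance[0, :3], [-3.5, -2.5, -1.5])

    def test_column_mode(self):
        s = make_spectra(n_samples=2, n_wavelengths=8)
        A = np.tile([[1.], [3.]], (1, 8))
        A[:, 1] = [3, 5]
        out = mean_center(s.with_absorbance(A), "column")
        np.testing.assert_allclose(out.absorbance[:, :2],
                                   [[-1, -1], [1, 1]])

    def test_fitted_means_reused_not_reestimated(self):
        cal = make_spectra(n_samples=4, n_wavelengths=8, seed=1)
        mu = cal.absorbance.mean(axis=0)
        new = make_spectra(n_samples=2, n_wavelengths=8, seed=2)
        out = mean_center(new, "column", fitted_means=mu)
        np.testing.assert_allclose(out.absorbance, new.absorbance - mu)

    def test_fitted_means_in_row_mode_rejected(self):
        s = make_spectra(n_samples=2, n_wavelengths=8)
        with pytest.raises(ParameterError):
            mean_center(s, "row", fitted_means=np.zeros(8))


class TestSelectRegion:
    def test_full_range_is_identity(self, small_spectra):
        g = small_spectra.grid.values
        out = select_region(small_spectra, g[0], g[-1])
        np.testing.assert_array_equal(out.absorbance, small_spectra.absorbance)

    def test_closed_interval_matches_enumeration(self):
        s = make_spectra(n_samples=2, n_wavelengths=152, lo=1350.0, spacing=8.0)
        out = select_region(s, 1680.0, 1859.0)
        expected = [w for w in s.grid.values if 1680.0 <= w <= 1859.0]
        np.testing.assert_array_equal(out.grid.values, expected)
        assert out.absorbance.shape[1] == len(expected)

    def test_empty_region_errors(self):
        s = make_spectra(n_samples=1, n_wavelengths=20)  # 1350-1502 nm
        with pytest.raises(ParameterError):
            select_region(s, 2000.0, 2100.0)

    def test_nested_selection_equals_tighter(self):
        s = make_spectra(n_samples=2, n_wavelengths=100)
        a = select_region(select_region(s, 1400.0, 2000.0), 1500.0, 1800.0)
        b = select_region(s, 1500.0, 1800.0)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)
        assert a.grid == b.grid


class TestRecipe:
    def test_single_step_recipe_equals_normalize(self, small_spectra):
        recipe = PreprocessRecipe([{"step": "normalize_2norm100"}])
        cal, _ = fit_apply_recipe(recipe, small_spectra)
        np.testing.assert_allclose(
            cal.absorbance, normalize_2norm100(small_spectra.absorbance))

    def test_apply_is_stateless_after_fit(self):
        cal = make_spectra(n_samples=8, n_wavelengths=80, seed=1)
        val = make_spectra(n_samples=3, n_wavelengths=80, seed=2)
        recipe = regression_recipe(1450.0, 1900.0, window=11)
        recipe.fit(cal)
        once = recipe.apply(val).absorbance
        twice = recipe.apply(val).absorbance
        np.testing.assert_array_equal(once, twice)

    def test_calibration_columns_centered_after_recipe(self):
        cal = make_spectra(n_samples=10, n_wavelengths=80, seed=3)
        recipe = regression_recipe(1450.0, 1900.0, window=11)
        out, _ = fit_apply_recipe(recipe, cal)
        np.testing.assert_allclose(out.absorbance.mean(axis=0), 0.0, atol=1e-9)

    def test_stored_means_length_matches_subgrid(self):
        cal = make_spectra(n_samples=6, n_wavelengths=152, seed=4)
        recipe = regression_recipe(1876.0, 2294.0)
        recipe.fit(cal)
        (centre_idx,) = [i for i, s in enumerate(recipe.steps)
                         if s["step"] == "mean_center"]
        n_region = np.sum((cal.grid.values >= 1876.0)
                          & (cal.grid.values <= 2294.0))
        assert recipe.fitted_state[centre_idx].size == n_region

    def test_yaml_round_trip(self):
        cal = make_spectra(n_samples=6, n_wavelengths=80, seed=5)
        recipe = regression_recipe(1450.0, 1900.0, window=11)
        recipe.fit(cal)
        back = PreprocessRecipe.from_yaml(recipe.to_yaml())
        val = make_spectra(n_samples=2, n_wavelengths=80, seed=6)
        np.testing.assert_allclose(back.apply(val).absorbance,
                                   recipe.apply(val).absorbance, atol=1e-12)

    def test_unfitted_column_centering_rejected(self, small_spectra):
        recipe = PreprocessRecipe([{"step": "mean_center", "mode": "column"}])
        with pytest.raises(ParameterError, match="unfitted"):
            recipe.apply(small_spectra)
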