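import numpy as np
import pytest

from sersdx import (
    GridSpec,
    PreprocessConfig,
    Spectrum,
    airpls_baseline,
    difference_spectrum,
    group_mean_and_sd,
    normalize_minmax,
    preprocess_dataset,
    savitzky_golay,
    simulate,
)
from sersdx.errors import ConfigError, DegenerateInputError
from sersdx.simulate import PeakSpec, line_profile

from .conftest import make_tiny_dataset, small_cohort_config

# ----------------------------------------------------------------- oracles


def sg_oracle(y: np.ndarray, window: int, order: int) -> np.ndarray:
    """Per-point windowed polynomial least squares by explicit normal
    equations; edges evaluated from the nearest full window's fit."""
    n, half = len(y), window // 2
    out = np.empty(n)
    for i in range(n):
        c = min(max(i, half), n - 1 - half)  # centre of nearest full window
        idx = np.arange(c - half, c + half + 1)
        V = np.vander(idx - c, order + 1, increasing=True)
        coef = np.linalg.solve(V.T @ V, V.T @ y[idx])
        out[i] = np.polynomial.polynomial.polyval(float(i - c), coef)
    return out


def airpls_dense_oracle(y, lam, diff_order, max_iter, tol):
    """Same airPLS reweighting loop, but the weighted penalized system is
    solved densely with numpy.linalg.solve — independent of the banded path."""
    n = len(y)
    D = np.eye(n)
    for _ in range(diff_order):
        D = np.diff(D, axis=0)
    P = lam * (D.T @ D)
    w = np.ones(n)
    abs_y = np.abs(y).sum()
    z = np.zeros(n)
    for t in range(1, max_iter + 1):
        z = np.linalg.solve(np.diag(w) + P, w * y)
        neg = y < z
        d = y[neg] - z[neg]
        d_norm = np.abs(d).sum()
        if d_norm < tol * abs_y or d_norm == 0.0:
            break
        w[:] = 0.0
        w[neg] = np.exp(t * np.abs(d) / d_norm)
    return z


def _spec(y, start=300.0, step=1.0):
    return Spectrum(start + step * np.arange(len(y)), np.asarray(y, dtype=float))


# ------------------------------------------------------------ Savitzky-Golay


class TestSavitzkyGolay:
    def test_constant_unchanged(self):
        out = savitzky_golay(_spec(np.full(50, 3.7)), 5, 3)
        np.testing.assert_allclose(out.intensities, 3.7, rtol=1e-12)

    def test_exact_on_cubic(self):
        x = np.linspace(-1, 1, 60)
        spec = Spectrum(300 + np.arange(60.0), x**3)
        out = savitzky_golay(spec, 5, 3)
        np.testing.assert_allclose(out.intensities, x**3, atol=1e-9 * np.abs(x**3).max() + 1e-15)

    @pytest.mark.parametrize("window,order", [(5, 3), (7, 2), (9, 4)])
    def test_matches_per_window_least_squares_oracle(self, window, order):
        rng = np.random.default_rng(0)
        y = np.sin(np.linspace(0, 6, 80)) + 0.1 * rng.standard_normal(80)
        out = savitzky_golay(_spec(y), window, order)
        np.testing.assert_allclose(out.intensities, sg_oracle(y, window, order), atol=1e-10)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        y1, y2 = rng.random(40), rng.random(40)
        a, b = 2.5, -1.3
        lhs = savitzky_golay(_spec(a * y1 + b * y2), 5, 3).intensities
        rhs = a * savitzky_golay(_spec(y1), 5, 3).intensities + b * savitzky_golay(_spec(y2), 5, 3).intensities
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_window_order_violations(self):
        spec = _spec(np.ones(20))
        with pytest.raises(ConfigError):
            savitzky_golay(spec, 4, 3)  # even window
        with pytest.raises(ConfigError):
            savitzky_golay(spec, 5, 5)  # order >= window


# ------------------------------------------------------------------ airPLS


class TestAirPLS:
    def test_all_zero_spectrum(self):
        baseline, corrected = airpls_baseline(_spec(np.zeros(64)))
        np.testing.assert_array_equal(baseline.intensities, 0.0)
        np.testing.assert_array_equal(corrected.intensities, 0.0)

    def test_linear_ramp_fully_removed(self):
        # a ramp has zero 3rd-difference penalty, so the first weighted
        # solve reproduces it and the correction is < 0.1% of its range
        y = np.linspace(1.0, 2.0, 400)
        _, corrected = airpls_baseline(_spec(y), lam=150.0, diff_order=3)
        assert np.abs(corrected.intensities).max() < 1e-3 * (y.max() - y.min())

    def test_matches_dense_oracle_on_peaky_input(self):
        x = np.arange(512.0)
        rng = np.random.default_rng(4)
        y = (
            1.0 + 0.004 * x + 2e-6 * x**2
            + 3.0 * line_profile(x, 150.0, 8.0)
            + 2.0 * line_profile(x, 320.0, 12.0)
            + 0.01 * rng.standard_normal(512)
        )
        baseline, _ = airpls_baseline(_spec(y), lam=150.0, diff_order=3, max_iter=15, tol=1e-3)
        oracle = airpls_dense_oracle(y, 150.0, 3, 15, 1e-3)
        np.testing.assert_allclose(baseline.intensities, oracle, rtol=1e-8, atol=1e-8 * np.abs(oracle).max())

    @pytest.mark.parametrize("diff_order", [1, 2, 3])
    def test_banded_equals_dense_across_orders(self, diff_order):
        x = np.arange(256.0)
        y = 2.0 + 0.01 * x + 4.0 * line_profile(x, 100.0, 10.0)
        baseline, _ = airpls_baseline(_spec(y), lam=50.0, diff_order=diff_order)
        oracle = airpls_dense_oracle(y, 50.0, diff_order, 15, 1e-3)
        np.testing.assert_allclose(baseline.intensities, oracle, rtol=1e-8, atol=1e-8 * np.abs(oracle).max())

    def test_recovers_known_quadratic_baseline_off_peak(self):
        # generative truth: three Lorentzian peaks on a known smooth baseline
        x = np.arange(300.0, 1801.0)
        u = (x - 300.0) / 1500.0
        true_baseline = 1.0 + 0.8 * u - 0.5 * u**2
        peaks = [(600.0, 7.0, 1.2), (1000.0, 6.0, 1.0), (1400.0, 8.0, 1.5)]
        y = true_baseline + sum(a * line_profile(x, c, w) for c, w, a in peaks)
        recovered, _ = airpls_baseline(Spectrum(x, y), lam=150.0, diff_order=3)
        # off-peak: outside 5 half-widths of any band (Lorentzian tails are
        # fat; channels nearer the cores are dominated by the bands, not
        # the baseline)
        off_peak = np.all(
            np.array([np.abs(x - c) > 5 * w for c, w, _ in peaks]), axis=0
        )
        rmse = np.sqrt(np.mean((recovered.intensities[off_peak] - true_baseline[off_peak]) ** 2))
        assert rmse < 0.05 * (true_baseline.max() - true_baseline.min())

    def test_peak_retention_scales_with_lambda(self):
        # the Whittaker smoothing length is ~ lambda^(1/(2 d)) channels, so
        # a small lambda lets the baseline follow band shapes while a large
        # one cannot bridge a 10-channel-wide peak; either way the apex
        # remains the maximum of the corrected trace and the far field is
        # corrected to ~0
        x = np.arange(300.0)
        y = 1.0 + 3.0 * line_profile(x, 150.0, 10.0)
        apex_region = np.abs(x - 150.0) < 5
        far = np.abs(x - 150.0) > 80
        retained = {}
        for lam in (150.0, 1e6):
            _, corrected = airpls_baseline(_spec(y), lam=lam, diff_order=3)
            assert corrected.intensities.argmax() == np.argmax(y)
            assert np.abs(corrected.intensities[far]).max() < 0.15
            retained[lam] = corrected.intensities[apex_region].max()
        assert retained[1e6] > 2.0  # stiff baseline cannot follow the band
        assert 0.0 < retained[150.0] < retained[1e6]


# -------------------------------------------------------------- normalize


class TestNormalize:
    def test_three_point_example(self):
        out = normalize_minmax(_spec([2.0, 4.0, 6.0, 2.0, 4.0, 6.0, 2.0, 4.0]))
        np.testing.assert_allclose(out.intensities[:3], [0.0, 0.5, 1.0])

    def test_output_spans_unit_interval(self):
        rng = np.random.default_rng(2)
        out = normalize_minmax(_spec(rng.random(30)))
        assert out.intensities.min() == 0.0 and out.intensities.max() == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.random(30)
        a, b = 4.2, -7.0
        np.testing.assert_allclose(
            normalize_minmax(_spec(a * y + b)).intensities,
            normalize_minmax(_spec(y)).intensities,
            atol=1e-12,
        )

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_minmax(_spec(np.full(20, 5.0)))


# --------------------------------------------------------------- pipeline


class TestPreprocessDataset:
    def test_deterministic_and_manifest_preserved(self):
        ds = simulate(small_cohort_config(seed=8))
        a = preprocess_dataset(ds)
        b = preprocess_dataset(ds)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert a.manifest.equals(ds.manifest)
        assert len(a) == len(ds)

    def test_output_spans_crop_window_and_unit_range(self):
        ds = simulate(small_cohort_config(seed=8))
        out = preprocess_dataset(ds, PreprocessConfig(crop_lo=300.0, crop_hi=1800.0))
        assert out.shifts[0] >= 300.0 and out.shifts[-1] <= 1800.0
        assert out.shifts[-1] + (out.shifts[1] - out.shifts[0]) > 1800.0  # nothing kept beyond hi
        np.testing.assert_allclose(out.intensities.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.intensities.max(axis=1), 1.0, atol=1e-12)


# -------------------------------------------------------------- aggregation


def _two_sample_dataset(values_a, values_b, n_channels=10):
    import pandas as pd
    from sersdx import SpectrumDataset

    shifts = 300.0 + np.arange(float(n_channels))
    rows = [np.full(n_channels, v) for v in values_a] + [np.full(n_channels, v) for v in values_b]
    manifest = pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(len(rows))],
        "sample_id": ["A"] * len(values_a) + ["B"] * len(values_b),
        "patient_id": ["p0"] * len(values_a) + ["p1"] * len(values_b),
        "class_label": ["malignant"] * len(rows),
    })
    return SpectrumDataset(shifts, np.vstack(rows), manifest)


class TestGroupAggregation:
    def test_two_constant_samples(self):
        ds = _two_sample_dataset([1.0], [3.0])
        mean, sd = group_mean_and_sd(ds, "malignant")
        np.testing.assert_allclose(mean.intensities, 2.0)
        np.testing.assert_allclose(sd.intensities, np.sqrt(2.0))

    def test_unbalanced_replicates_use_two_stage_mean(self):
        # sample A: 10 replicates at 1, sample B: 1 replicate at 3
        ds = _two_sample_dataset([1.0] * 10, [3.0])
        mean, _ = group_mean_and_sd(ds, "malignant")
        np.testing.assert_allclose(mean.intensities, 2.0)  # not the pooled 13/11

    def test_agrees_with_pooled_mean_when_balanced(self):
        rng = np.random.default_rng(5)
        va, vb = rng.random(4), rng.random(4)
        ds = _two_sample_dataset(list(va), list(vb))
        mean, _ = group_mean_and_sd(ds, "malignant")
        pooled = ds.intensities.mean(axis=0)  # equal replicate counts
        np.testing.assert_allclose(mean.intensities, pooled, atol=1e-12)

    def test_single_sample_sd_undefined(self):
        ds = _two_sample_dataset([1.0], [3.0])
        sub = ds.subset(ds.manifest["sample_id"].eq("A").to_numpy())
        with pytest.raises(DegenerateInputError):
            group_mean_and_sd(sub, "malignant")


class TestDifferenceSpectrum:
    def test_single_delta_band_noise_free(self):
        cfg = small_cohort_config(
            seed=0, n_patients=2, spectra_per_sample=2,
            sigma_patient=0.0, sigma_sample=0.0, sigma_noise=0.0,
            peaks=[PeakSpec(1038.0, 9.0, 0.6, class_delta=0.4)],
            grid=GridSpec(900.0, 1200.0, 1.0),  # 1038 lies on the grid
        )
        ds = simulate(cfg)
        diff = difference_spectrum(ds)
        apex = diff.shifts[np.argmax(diff.intensities)]
        assert abs(apex - 1038.0) <= cfg.grid.step
        np.testing.assert_allclose(diff.intensities.max(), 0.4, rtol=1e-9)
        expected = 0.4 * line_profile(diff.shifts, 1038.0, 9.0)
        np.testing.assert_allclose(diff.intensities, expected, atol=1e-9)

    def test_antisymmetry_under_class_swap(self):
        ds = simulate(small_cohort_config(seed=13, n_patients=3, spectra_per_sample=4))
        swapped = ds.manifest.copy()
        swapped["class_label"] = swapped["class_label"].map(
            {"benign": "malignant", "malignant": "benign"}
        )
        from sersdx import SpectrumDataset

        ds_swapped = SpectrumDataset(ds.shifts, ds.intensities, swapped)
        np.testing.assert_allclose(
            difference_spectrum(ds_swapped).intensities,
            -difference_spectrum(ds).intensities,
            atol=1e-12,
        )

    def test_identical_class_means_give_zero(self):
        import pandas as pd
        from sersdx import SpectrumDataset

        shifts = 300.0 + np.arange(10.0)
        row = np.linspace(1, 2, 10)
        manifest = pd.DataFrame({
            "spectrum_id": ["a", "b"],
            "sample_id": ["A", "B"],
            "patient_id": ["p0", "p1"],
            "class_label": ["benign", "malignant"],
        })
        ds = SpectrumDataset(shifts, np.vstack([row, row]), manifest)
        np.testing.assert_allclose(difference_spectrum(ds).intensities, 0.0, atol=1e-15)
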