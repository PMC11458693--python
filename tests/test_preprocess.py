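import numpy as np
import pytest
from scipy.spatial.distance import pdist

from scftir.preprocess import (
    EMSCMieCorrector,
    PreprocessConfig,
    baseline_linear,
    emsc_mie_correct,
    preprocess_cohort,
    second_derivative,
    smooth,
)
from scftir.simulate import (
    CohortDesign,
    default_grid,
    mie_artifact,
    simulate_cohort,
)
from scftir.spectra import Spectrum, SpectrumSet, default_region_table


def spec_from(values, grid=None, cell_id="c"):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = np.arange(2000.0, 2000.0 - 2.0 * values.size, -2.0)
    return Spectrum(cell_id, grid, values)


class TestPreprocessConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"smooth_points": 8},
            {"smooth_points": 1},
            {"sg_window": 4},
            {"sg_window": 3, "sg_polyorder": 3},
            {"sg_polyorder": 1},
            {"reference_choice": "bogus"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PreprocessConfig(**kwargs)


class TestSmooth:
    def test_constant_spectrum_unchanged(self):
        s = spec_from(np.full(676, 0.7))
        np.testing.assert_allclose(smooth(s, 9).absorbance, 0.7)

    def test_linear_ramp_unchanged_including_edges(self):
        grid = default_grid(2000.0, 650.0)
        s = spec_from(0.1 + 0.002 * grid, grid)
        # symmetric (shrinking) windows average a line back onto itself
        np.testing.assert_allclose(smooth(s, 9).absorbance, s.absorbance, rtol=1e-12)

    def test_white_noise_variance_reduced_ninefold(self, rng):
        n = 10_000
        grid = np.arange(float(n), 0.0, -1.0)
        noise = rng.normal(0.0, 1.0, n)
        sm = smooth(Spectrum("c", grid, noise), 9).absorbance
        interior = sm[50:-50]
        ratio = noise.var() / interior.var()
        assert 8.0 < ratio < 10.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth(spec_from(np.zeros(100)), 8)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            smooth(spec_from(np.zeros(100)), 101)

    def test_provenance_tag_appended(self):
        assert "smooth[9]" in smooth(spec_from(np.zeros(100)), 9).provenance


class TestBaselineLinear:
    def test_pure_line_maps_to_zero(self):
        grid = default_grid(2000.0, 650.0)
        s = spec_from(0.3 - 0.0004 * grid, grid)
        np.testing.assert_allclose(baseline_linear(s).absorbance, 0.0, atol=1e-12)

    def test_band_on_tilted_line_recovered(self):
        grid = default_grid(2000.0, 650.0)
        band = 0.8 * np.exp(-((grid - 1300.0) ** 2) / (2 * 15.0**2))
        tilt = 0.05 + 0.0002 * grid
        corrected = baseline_linear(spec_from(band + tilt, grid)).absorbance
        np.testing.assert_allclose(corrected, band, atol=1e-9)
        # exactly zero at both anchor points
        n_edge = int(np.ceil(0.05 * grid.size))
        assert abs(corrected[np.argmin(corrected[:n_edge])]) < 1e-10
        assert np.min(np.abs(corrected[-n_edge:])) < 1e-10

    def test_idempotent(self):
        grid = default_grid(2000.0, 650.0)
        band = 0.8 * np.exp(-((grid - 1300.0) ** 2) / (2 * 15.0**2))
        once = baseline_linear(spec_from(band + 0.05 + 0.0002 * grid, grid))
        twice = baseline_linear(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-10)


class TestSecondDerivative:
    def test_quadratic_gives_constant_curvature(self):
        grid = default_grid(2000.0, 650.0)
        a = 3.5e-6
        s = spec_from(a * grid**2, grid)
        d2 = second_derivative(s, 9, 3).absorbance
        np.testing.assert_allclose(d2[4:-4], 2 * a, rtol=1e-6)

    def test_gaussian_band_minimum_at_center(self):
        grid = default_grid(2000.0, 650.0)
        s = spec_from(np.exp(-((grid - 1400.0) ** 2) / (2 * 12.0**2)), grid)
        d2 = second_derivative(s).absorbance
        assert grid[np.argmin(d2)] == pytest.approx(1400.0, abs=2.0)

    @pytest.mark.parametrize("window,polyorder", [(9, 2), (9, 3), (13, 4)])
    def test_interior_matches_local_polynomial_fit_oracle(self, rng, window, polyorder):
        # independent oracle: direct least-squares polynomial fit per window,
        # second derivative = 2 * quadratic coefficient / delta^2
        n, delta = 60, 2.0
        grid = np.arange(2000.0, 2000.0 - n * delta, -delta)
        y = rng.normal(size=n)
        d2 = second_derivative(Spectrum("c", grid, y), window, polyorder).absorbance
        h = window // 2
        x = np.arange(-h, h + 1, dtype=float)
        for i in range(h, n - h):
            coefs = np.polynomial.polynomial.polyfit(x, y[i - h : i + h + 1], polyorder)
            expected = 2.0 * coefs[2] / delta**2
            assert d2[i] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_linearity(self, rng):
        grid = default_grid(2000.0, 650.0)
        y1, y2 = rng.normal(size=grid.size), rng.normal(size=grid.size)
        d = lambda y: second_derivative(Spectrum("c", grid, y)).absorbance
        np.testing.assert_allclose(
            d(2.0 * y1 - 3.0 * y2), 2.0 * d(y1) - 3.0 * d(y2), rtol=1e-9, atol=1e-12
        )

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            second_derivative(spec_from(np.zeros(100)), 8, 3)
        with pytest.raises(ValueError):
            second_derivative(spec_from(np.zeros(100)), 9, 1)


class TestEMSC:
    def _reference(self, grid):
        return (
            0.9 * np.exp(-((grid - 1650.0) ** 2) / (2 * 20.0**2))
            + 0.5 * np.exp(-((grid - 1080.0) ** 2) / (2 * 25.0**2))
            + 0.4 * np.exp(-((grid - 2920.0) ** 2) / (2 * 18.0**2))
        )

    def test_reference_input_returned_unchanged(self):
        grid = default_grid()
        ref = self._reference(grid)
        X = np.vstack([ref, ref])
        corr = EMSCMieCorrector(wavenumbers=grid).fit(X).transform(X)
        np.testing.assert_allclose(corr, X, atol=1e-8)

    def test_in_span_mie_contamination_removed(self):
        grid = default_grid()
        ref = self._reference(grid)
        curve = mie_artifact(grid, 0.4, 8.0, 1.3)  # first basis curve of the design
        X = np.vstack([ref + curve, ref])
        corr = (
            EMSCMieCorrector(wavenumbers=grid, reference=ref).fit(X).transform(X)
        )
        np.testing.assert_allclose(corr[0], ref, atol=1e-8)

    def test_degenerate_reference_coefficient_reported(self):
        grid = default_grid()
        ref = self._reference(grid)
        # a pure polynomial baseline carries no reference signal
        X = np.vstack([np.linspace(0, 1, grid.size), ref])
        with pytest.raises(ValueError, match="degenerate"):
            EMSCMieCorrector(wavenumbers=grid, reference=ref).fit(X).transform(X)

    def test_correction_shrinks_within_group_spectral_distances(self):
        design = CohortDesign(
            n_cells_per_group=30,
            group_effects={"u": 1.0},
            cell_cv=0.1,
            noise_sd=0.002,
            mie_amplitude=0.15,
            drift_sd=0.005,
            seed=3,
        )
        cohort = simulate_cohort(design)
        before = pdist(cohort.to_matrix()).mean()
        after = pdist(emsc_mie_correct(cohort).to_matrix()).mean()
        assert after < before

    def test_second_pass_is_small(self):
        cohort = simulate_cohort(CohortDesign(n_cells_per_group=20, seed=5))
        once = emsc_mie_correct(cohort)
        twice = emsc_mie_correct(once)
        x1, x2 = once.to_matrix(), twice.to_matrix()
        rel_rms = np.sqrt(((x2 - x1) ** 2).mean()) / np.sqrt((x1**2).mean())
        assert rel_rms < 0.01


class TestFullChain:
    def test_noise_free_cohort_has_exactly_14_region_minima(self, noise_free_chain):
        from scipy.signal import find_peaks

        _, deriv = noise_free_chain
        grid = deriv.shared_grid
        mean_d2 = deriv.to_matrix().mean(axis=0)
        idx, _ = find_peaks(-mean_d2)
        idx = idx[mean_d2[idx] < 0]
        rt = default_region_table()
        counts: dict[str, int] = {}
        for i in idx:
            r = rt.region_of(grid[i])
            if r is not None:
                counts[r] = counts.get(r, 0) + 1
        assert counts == {"fatty_acid": 4, "protein": 7, "carbohydrate": 3}

    def test_chain_tags_provenance_in_order(self, noise_free_chain):
        processed, deriv = noise_free_chain
        tags = deriv.spectra[0].provenance
        assert [t.split("[")[0] for t in tags] == [
            "simulated",
            "smooth",
            "baseline_linear",
            "second_derivative",
        ]
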