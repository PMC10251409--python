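import numpy as np
import pytest

from spectrop.cwt_features import (
    WaveletFeature,
    coefficients_at,
    cwt_transform,
    fit_wavelet_model,
    mexh,
    scalogram_r2_map,
    select_per_scale_features,
    wavelet_function,
)
from spectrop.index_search import ScoreMap
from spectrop.spectra_io import SpectrumSet

from conftest import direct_cwt


class TestMexh:
    def test_closed_form_at_zero(self):
        assert mexh(0.0) == pytest.approx(2.0 / (np.sqrt(3.0) * np.pi**0.25))
        assert mexh(0.0) == pytest.approx(0.867325, abs=1e-6)

    def test_roots_at_unit_offset(self):
        assert mexh(1.0) == pytest.approx(0.0, abs=1e-15)
        assert mexh(-1.0) == pytest.approx(0.0, abs=1e-15)

    def test_zero_mean_admissibility(self):
        u = np.linspace(-8, 8, 200001)
        assert np.trapezoid(mexh(u), u) == pytest.approx(0.0, abs=1e-8)

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError, match="unknown wavelet"):
            wavelet_function("haar")


def _single(f, grid=None):
    grid = np.arange(350, 350 + len(f)) if grid is None else grid
    return SpectrumSet(grid, np.asarray(f)[None, :])


class TestCwtTransform:
    def test_constant_spectrum_annihilated(self):
        s = _single(np.full(300, 0.4))
        c = cwt_transform(s, "mexh", range(1, 7))
        assert np.abs(c.coefficients).max() < 1e-9

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        grid = np.arange(350, 606)
        f = 0.3 + 0.2 * np.exp(-((grid - 480) ** 2) / (2 * 15.0**2))
        f = np.clip(f + 0.01 * rng.normal(size=grid.size), 0.001, 0.999)
        c = cwt_transform(_single(f, grid), "mexh", [3])
        oracle = direct_cwt(f, mexh, 3)
        np.testing.assert_allclose(c.coefficients[0, 0], oracle, atol=1e-8)

    def test_odd_wavelet_orientation_matches_oracle(self):
        rng = np.random.default_rng(4)
        grid = np.arange(400, 600)
        f = np.clip(0.4 + 0.1 * rng.normal(size=grid.size), 0.01, 0.99)
        c = cwt_transform(_single(f, grid), "gaus1", [2])
        oracle = direct_cwt(f, wavelet_function("gaus1"), 2)
        np.testing.assert_allclose(c.coefficients[0, 0], oracle, atol=1e-8)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        grid = np.arange(350, 550)
        f = rng.uniform(0.1, 0.4, size=grid.size)
        g = rng.uniform(0.05, 0.15, size=grid.size)
        combo = 2 * f + g  # stays within [0, 1]
        cf = cwt_transform(_single(f, grid), "mexh", [2, 4]).coefficients
        cg = cwt_transform(_single(g, grid), "mexh", [2, 4]).coefficients
        cc = cwt_transform(_single(combo, grid), "mexh", [2, 4]).coefficients
        np.testing.assert_allclose(cc, 2 * cf + cg, atol=1e-10)

    def test_linear_ramp_interior_annihilated(self):
        # two vanishing moments: a pure ramp leaves only boundary effects
        ramp = np.linspace(0.1, 0.9, 2151)
        s = _single(ramp, np.arange(350, 2501))
        c = cwt_transform(s, "mexh", range(1, 7))
        for k, a in enumerate(range(1, 7)):
            margin = 16 * 2**a
            assert np.abs(c.coefficients[0, k, margin:-margin]).max() < 1e-6

    def test_shift_covariance(self):
        grid = np.arange(350, 1000)
        bump = lambda c: 0.3 + 0.2 * np.exp(-((grid - c) ** 2) / (2 * 20.0**2))
        c1 = cwt_transform(_single(bump(600), grid), "mexh", [3]).coefficients[0, 0]
        c2 = cwt_transform(_single(bump(610), grid), "mexh", [3]).coefficients[0, 0]
        interior = slice(200, 450)
        np.testing.assert_allclose(
            c2[interior.start + 10 : interior.stop + 10], c1[interior], atol=1e-8
        )

    def test_unknown_name_and_bad_scales(self):
        s = _single(np.full(64, 0.3))
        with pytest.raises(ValueError):
            cwt_transform(s, "nosuch", [1])
        with pytest.raises(ValueError):
            cwt_transform(s, "mexh", [0, 1])

    def test_coefficients_at_matches_full_transform(self):
        rng = np.random.default_rng(9)
        grid = np.arange(350, 700)
        refl = rng.uniform(0.1, 0.9, size=(5, grid.size))
        s = SpectrumSet(grid, refl)
        full = cwt_transform(s, "mexh", [2, 5])
        feats = [WaveletFeature(400, 2), WaveletFeature(523, 5)]
        direct = coefficients_at(s, feats)
        np.testing.assert_allclose(direct[:, 0], full.at(2, 400), atol=1e-10)
        np.testing.assert_allclose(direct[:, 1], full.at(5, 523), atol=1e-10)


class TestScalogram:
    def _coeff_stack(self):
        rng = np.random.default_rng(2)
        n, S, W = 12, 3, 10
        coeffs = rng.normal(size=(n, S, W))
        lpc = rng.uniform(1, 4, size=n)
        from spectrop.cwt_features import WaveletCoefficients

        c = WaveletCoefficients(np.arange(500, 510), np.arange(1, 4), coeffs)
        return c, lpc

    def test_matches_per_cell_regression_oracle(self):
        from scipy import stats

        c, lpc = self._coeff_stack()
        smap = scalogram_r2_map(c, lpc)
        for i in range(3):
            for j in range(10):
                r = stats.linregress(c.coefficients[:, i, j], lpc)
                assert smap.values[i, j] == pytest.approx(r.rvalue**2, abs=1e-10)

    def test_exact_linear_cell_scores_one(self):
        c, lpc = self._coeff_stack()
        c.coefficients[:, 1, 4] = 3.0 * lpc - 1.0
        smap = scalogram_r2_map(c, lpc)
        assert smap.values[1, 4] == pytest.approx(1.0, abs=1e-12)

    def test_sample_permutation_invariance(self):
        c, lpc = self._coeff_stack()
        perm = np.random.default_rng(0).permutation(len(lpc))
        from spectrop.cwt_features import WaveletCoefficients

        cp = WaveletCoefficients(c.wavelengths_nm, c.scale_indices,
                                 c.coefficients[perm])
        np.testing.assert_allclose(
            scalogram_r2_map(c, lpc).values,
            scalogram_r2_map(cp, lpc[perm]).values,
            atol=1e-12,
        )

    def test_constant_cell_flagged_undefined(self):
        c, lpc = self._coeff_stack()
        c.coefficients[:, 0, 0] = 0.25
        smap = scalogram_r2_map(c, lpc)
        assert np.isnan(smap.values[0, 0])

    def test_per_scale_normalization_invariance(self):
        # rescaling one scale's coefficients by a positive constant leaves
        # the correlation map unchanged
        c, lpc = self._coeff_stack()
        from spectrop.cwt_features import WaveletCoefficients

        scaled = c.coefficients.copy()
        scaled[:, 1, :] *= 7.3
        c2 = WaveletCoefficients(c.wavelengths_nm, c.scale_indices, scaled)
        np.testing.assert_allclose(
            scalogram_r2_map(c, lpc).values, scalogram_r2_map(c2, lpc).values,
            atol=1e-12,
        )


class TestPerScaleSelection:
    def test_one_feature_per_scale_and_tiebreak(self):
        vals = np.array([
            [0.2, 0.9, 0.9, 0.1],   # tie at columns 1 and 2 → smaller wavelength
            [0.5, 0.1, 0.2, 0.6],
        ])
        smap = ScoreMap(np.array([1, 2]), np.array([900, 1000, 1200, 1300]),
                        vals, "scalogram", "mexh")
        feats = select_per_scale_features(smap)
        assert len(feats) == 2
        assert feats[0].wavelength_nm == 1000
        assert feats[1].wavelength_nm == 1300

    def test_planted_cell_recovered(self):
        rng = np.random.default_rng(5)
        n = 30
        lpc = rng.uniform(1, 4, size=n)
        coeffs = rng.normal(scale=0.05, size=(n, 4, 20))
        coeffs[:, 3, 7] = 0.5 * lpc  # planted linear signal at scale 4
        from spectrop.cwt_features import WaveletCoefficients

        c = WaveletCoefficients(np.arange(700, 720), np.arange(1, 5), coeffs)
        smap = scalogram_r2_map(c, lpc)
        feats = select_per_scale_features(smap)
        by_scale = {f.scale_index: f for f in feats}
        assert by_scale[4].wavelength_nm == 707

    def test_undefined_scale_omitted(self, caplog):
        vals = np.array([[np.nan, np.nan], [0.3, 0.8]])
        smap = ScoreMap(np.array([1, 2]), np.array([900, 901]), vals,
                        "scalogram", "mexh")
        feats = select_per_scale_features(smap)
        assert [f.scale_index for f in feats] == [2]


def test_fit_wavelet_model_exact():
    rng = np.random.default_rng(6)
    n = 20
    lpc = rng.uniform(1, 4, size=n)
    coeffs = rng.normal(size=(n, 2, 5))
    coeffs[:, 1, 2] = (lpc - 0.15) / 22.74
    from spectrop.cwt_features import WaveletCoefficients

    c = WaveletCoefficients(np.arange(600, 605), np.arange(1, 3), coeffs)
    f = fit_wavelet_model(WaveletFeature(602, 2), c, lpc)
    assert f.slope == pytest.approx(22.74)
    assert f.intercept == pytest.approx(0.15, abs=1e-9)
    assert f.r2_cal == pytest.approx(1.0)
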