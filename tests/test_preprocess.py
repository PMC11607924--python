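"""Band selection and spectral preprocessing transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mixcal
from mixcal.preprocess import (
    ANALYTE_BANDS,
    BandSelection,
    PreprocessorState,
    apply_chain,
    apply_state,
    fit_centering,
    fit_chain,
    msc_apply,
    msc_fit,
    osc_apply,
    osc_fit,
    select_bands,
    snv,
)
from mixcal.simulate import SpectraSet


def _spectra(X, wl=None, ids=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if wl is None:
        wl = 200.0 + 0.5 * np.arange(X.shape[1])
    if ids is None:
        ids = [f"s{i}" for i in range(X.shape[0])]
    return SpectraSet(wl, X, ids)


class TestSelectBands:
    def test_glm_bands_have_190_columns(self, noiseless_dataset):
        spectra, _ = noiseless_dataset
        out = select_bands(spectra, ANALYTE_BANDS["GLM"])
        assert out.absorbance.shape[1] == 190

    def test_alg_pio_bands_have_111_columns(self, noiseless_dataset):
        spectra, _ = noiseless_dataset
        out = select_bands(spectra, ANALYTE_BANDS["ALG"])
        assert out.absorbance.shape[1] == 111
        assert out.absorbance.shape[1] == 30 + 81  # 230.5-245 plus 260-300

    def test_full_span_band_keeps_all_columns(self, noiseless_dataset):
        spectra, _ = noiseless_dataset
        out = select_bands(spectra, BandSelection(((200.0, 400.0),)))
        assert out.absorbance.shape[1] == 401

    def test_point_count_formula(self, noiseless_dataset):
        # count = sum over bands of (stop - start)/0.5 + 1
        spectra, _ = noiseless_dataset
        for sel in ANALYTE_BANDS.values():
            expected = sum(
                int(round((stop - start) / 0.5)) + 1 for start, stop in sel.bands
            )
            out = select_bands(spectra, sel)
            assert out.absorbance.shape[1] == expected

    def test_off_grid_edge_rejected(self, noiseless_dataset):
        spectra, _ = noiseless_dataset
        with pytest.raises(ValueError, match="off-grid"):
            select_bands(spectra, BandSelection(((230.3, 245.0),)))

    def test_outside_span_rejected(self, noiseless_dataset):
        spectra, _ = noiseless_dataset
        with pytest.raises(ValueError, match="span"):
            select_bands(spectra, BandSelection(((150.0, 245.0),)))

    def test_band_validation(self):
        with pytest.raises(ValueError):
            BandSelection(((250.0, 240.0),))
        with pytest.raises(ValueError):
            BandSelection(((230.0, 260.0), (255.0, 280.0)))


class TestCentering:
    def test_mc_zeroes_column_means(self, mild_noise_dataset):
        spectra, _ = mild_noise_dataset
        _, out = fit_centering(spectra, "MC")
        np.testing.assert_allclose(out.absorbance.mean(axis=0), 0, atol=1e-12)

    def test_as_unit_column_sds(self, mild_noise_dataset):
        spectra, _ = mild_noise_dataset
        _, out = fit_centering(spectra, "AS")
        np.testing.assert_allclose(out.absorbance.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_mean_sample_maps_to_zero_row(self, mild_noise_dataset):
        spectra, _ = mild_noise_dataset
        state, _ = fit_centering(spectra, "MC")
        mean_row = _spectra(spectra.absorbance.mean(axis=0), wl=spectra.wavelengths)
        out = apply_state(state, mean_row)
        np.testing.assert_allclose(out.absorbance, 0, atol=1e-12)

    def test_as_zero_variance_column_names_wavelength(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        spectra = _spectra(X, wl=np.array([250.0, 250.5]))
        with pytest.raises(ValueError, match="250"):
            fit_centering(spectra, "AS")

    def test_fit_apply_consistency(self, mild_noise_dataset):
        # apply(fit(X).state, X) == fit(X).transformed
        spectra, _ = mild_noise_dataset
        for method in ("MC", "AS"):
            state, transformed = fit_centering(spectra, method)
            again = apply_state(state, spectra)
            np.testing.assert_array_equal(again.absorbance, transformed.absorbance)


class TestSNV:
    def test_three_point_row(self):
        out = snv(_spectra([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance, [[-1.0, 0.0, 1.0]])

    def test_rows_standardised(self, mild_noise_dataset):
        spectra, _ = mild_noise_dataset
        out = snv(spectra)
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_idempotent(self, mild_noise_dataset):
        spectra, _ = mild_noise_dataset
        once = snv(spectra)
        twice = snv(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(_spectra([[2.0, 2.0, 2.0]]))


class TestMSC:
    def test_affine_transform_of_reference_recovered(self, noiseless_dataset):
        spectra, _ = noiseless_dataset
        state, _ = msc_fit(spectra)
        ref = np.asarray(state.params["reference"])
        warped = _spectra(2.0 * ref + 1.0, wl=spectra.wavelengths)
        out = msc_apply(state, warped)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)

    def test_reference_itself_unchanged(self, noiseless_dataset):
        spectra, _ = noiseless_dataset
        state, _ = msc_fit(spectra)
        ref = np.asarray(state.params["reference"])
        out = msc_apply(state, _spectra(ref, wl=spectra.wavelengths))
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)

    def test_inverts_synthetic_scatter(self, noiseless_dataset, rng):
        # inverse-transform oracle: per-sample a*x+b scatter is removed
        # exactly, i.e. MSC(scatter(x)) == MSC(x)
        spectra, _ = noiseless_dataset
        state, corrected = msc_fit(spectra)
        scattered = spectra.absorbance * rng.normal(1.0, 0.05, (43, 1)) \
            + rng.normal(0.0, 0.02, (43, 1))
        out = msc_apply(state, _spectra(scattered, wl=spectra.wavelengths,
                                        ids=spectra.sample_ids))
        np.testing.assert_allclose(out.absorbance, corrected.absorbance, atol=1e-8)

    def test_single_sample_fit_rejected(self):
        with pytest.raises(ValueError, match="2 calibration samples"):
            msc_fit(_spectra([[1.0, 2.0, 3.0]]))


class TestOSC:
    def _centered_training(self, dataset, analyte="ALG"):
        spectra, conc = dataset
        banded = select_bands(spectra, ANALYTE_BANDS[analyte])
        ids_m = [s for s in spectra.sample_ids if s.startswith("M")]
        _, centered = fit_centering(banded.subset(ids_m), "MC")
        y = conc.loc[ids_m, analyte].to_numpy()
        return centered, y

    def test_removed_scores_orthogonal_to_y(self, mild_noise_dataset):
        centered, y = self._centered_training(mild_noise_dataset)
        X0 = centered.absorbance.copy()
        state, corrected = osc_fit(centered, y, n_components=1)
        w = np.asarray(state.params["weights"])[0]
        t = X0 @ w
        yc = y - y.mean()
        corr = abs(t @ yc) / (np.linalg.norm(t) * np.linalg.norm(yc))
        assert corr < 1e-8

    def test_pure_signal_loses_under_one_percent_variance(self, rng):
        # X = y s^T exactly: no y-orthogonal variation to strip
        y = rng.normal(size=20)
        s = rng.normal(size=40)
        X = np.outer(y - y.mean(), s)
        spectra = _spectra(X)
        _, corrected = osc_fit(spectra, y, n_components=1)
        removed = np.sum(X**2) - np.sum(corrected.absorbance**2)
        assert removed < 0.01 * np.sum(X**2)

    def test_zero_components_is_identity(self, mild_noise_dataset):
        centered, y = self._centered_training(mild_noise_dataset)
        state, corrected = osc_fit(centered, y, n_components=0)
        np.testing.assert_array_equal(corrected.absorbance, centered.absorbance)
        out = osc_apply(state, centered)
        np.testing.assert_array_equal(out.absorbance, centered.absorbance)

    def test_apply_reproduces_training_deflation(self, mild_noise_dataset):
        centered, y = self._centered_training(mild_noise_dataset)
        state, corrected = osc_fit(centered, y, n_components=2)
        again = osc_apply(state, centered)
        np.testing.assert_allclose(
            again.absorbance, corrected.absorbance, atol=1e-10
        )

    def test_zero_matrix_stays_zero(self, mild_noise_dataset):
        centered, y = self._centered_training(mild_noise_dataset)
        state, _ = osc_fit(centered, y, n_components=1)
        zeros = _spectra(np.zeros_like(centered.absorbance),
                         wl=centered.wavelengths, ids=centered.sample_ids)
        out = osc_apply(state, zeros)
        np.testing.assert_array_equal(out.absorbance, 0)

    def test_wavelength_mismatch_rejected(self, mild_noise_dataset):
        centered, y = self._centered_training(mild_noise_dataset)
        state, _ = osc_fit(centered, y, n_components=1)
        other = _spectra(np.zeros((2, 5)))
        with pytest.raises(ValueError, match="grid"):
            osc_apply(state, other)

    def test_osc_improves_pls_rmsecv_under_scatter(self, table1, set_ids):
        """With injected y-orthogonal scatter, OSC lowers PLS RMSECV (sign test).

        Paired over 20 seeds; requires a clear majority of improvements.
        """
        wins = 0
        for seed in range(20):
            cfg = mixcal.DistortionConfig(
                scatter_slope_sd=0.05, scatter_offset_sd=0.02,
                baseline_drift_sd=0.02, noise_sd=0.002, seed=seed,
            )
            spectra, conc = mixcal.simulate_dataset(table1, cfg=cfg)
            banded = select_bands(spectra, ANALYTE_BANDS["ALG"])
            train = banded.subset(set_ids["M"])
            y = conc.loc[set_ids["M"], "ALG"].to_numpy()
            _, centered = fit_centering(train, "MC")
            _, rmsecv_plain = mixcal.loo_rmsecv(centered, y, 6)
            _, osc_train = osc_fit(centered, y, n_components=1)
            _, rmsecv_osc = mixcal.loo_rmsecv(osc_train, y, 6)
            wins += rmsecv_osc.min() <= rmsecv_plain.min()
        assert wins >= 15  # one-sided sign test, p < 0.05 under a fair coin


class TestChainsAndSerialisation:
    def test_chain_inserts_mc_before_osc(self, mild_noise_dataset, set_ids):
        spectra, conc = mild_noise_dataset
        train = select_bands(spectra, ANALYTE_BANDS["ALG"]).subset(set_ids["M"])
        y = conc.loc[set_ids["M"], "ALG"].to_numpy()
        states, _ = fit_chain(train, ["OSC"], y=y)
        assert [s.method for s in states] == ["MC", "OSC"]

    def test_chain_apply_matches_fit_output(self, mild_noise_dataset, set_ids):
        spectra, conc = mild_noise_dataset
        train = select_bands(spectra, ANALYTE_BANDS["GLM"]).subset(set_ids["M"])
        y = conc.loc[set_ids["M"], "GLM"].to_numpy()
        states, transformed = fit_chain(train, ["MC", "OSC"], y=y)
        again = apply_chain(states, train)
        np.testing.assert_allclose(
            again.absorbance, transformed.absorbance, atol=1e-10
        )

    def test_state_json_round_trip(self, mild_noise_dataset):
        spectra, _ = mild_noise_dataset
        state, _ = fit_centering(spectra, "AS")
        back = PreprocessorState.from_json(state.to_json())
        assert back.method == "AS"
        np.testing.assert_allclose(back.params["means"], state.params["means"])
        out_a = apply_state(state, spectra).absorbance
        out_b = apply_state(back, spectra).absorbance
        np.testing.assert_allclose(out_a, out_b, atol=1e-12)


@settings(deadline=None, max_examples=20)
@given(st.integers(min_value=0, max_value=10_000))
def test_snv_output_always_standardised(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(3, 12)) + rng.normal(size=(3, 1))
    out = snv(_spectra(X))
    np.testing.assert_allclose(out.absorbance.mean(axis=1), 0, atol=1e-10)
    np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1, atol=1e-10)
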