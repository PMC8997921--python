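"""Composition simulator and spectra generator."""

import numpy as np
import pytest

import lipidspec as ls
from lipidspec.reference import EPA, DHA
from lipidspec.synthetic import (SALMON_FA_STATS, BandModel, repair_correlation,
                                 raman_band_model)


class TestDrawCompositions:
    def test_zero_sd_gives_exact_means(self):
        spec = ls.CompositionSpec(fa_names=["a", "b"], means=[10.0, 5.0],
                                  sds=[0.0, 0.0], correlation=np.eye(2),
                                  n_samples=5, seed=1)
        table = ls.draw_compositions(spec)
        np.testing.assert_allclose(table.values.to_numpy(),
                                   np.tile([10.0, 5.0], (5, 1)))

    def test_table_means_recovered_at_n618(self):
        table = ls.draw_compositions(ls.salmon_reference_spec(n_samples=618, seed=0))
        for name, (mean, sd) in SALMON_FA_STATS.items():
            se = sd / np.sqrt(618)
            assert abs(table.values[name].mean() - mean) < 3 * se, name
        assert table.values["C18-1 (n-9)"].mean() == pytest.approx(30.5, abs=0.3)

    def test_requested_pairwise_correlation_recovered(self):
        spec = ls.CompositionSpec(fa_names=["a", "b"], means=[30.0, 10.0],
                                  sds=[2.0, 1.0],
                                  correlation=np.array([[1.0, 0.95], [0.95, 1.0]]),
                                  n_samples=10_000, seed=3)
        table = ls.draw_compositions(spec)
        r = np.corrcoef(table.column("a"), table.column("b"))[0, 1]
        assert r == pytest.approx(0.95, abs=0.02)

    def test_full_structure_recovered_within_003(self):
        spec = ls.salmon_reference_spec(n_samples=10_000, seed=5)
        table = ls.draw_compositions(spec)
        emp = np.corrcoef(table.values.to_numpy().T)
        np.testing.assert_allclose(emp, spec.correlation, atol=0.03)

    def test_same_seed_bit_identical(self):
        a = ls.draw_compositions(ls.salmon_reference_spec(n_samples=50, seed=9))
        b = ls.draw_compositions(ls.salmon_reference_spec(n_samples=50, seed=9))
        assert a.values.equals(b.values) and a.fat.equals(b.fat)

    def test_closure_option_fixes_row_sums(self):
        table = ls.draw_compositions(ls.salmon_reference_spec(n_samples=20, seed=2), total=100.0)
        np.testing.assert_allclose(table.values.sum(axis=1), 100.0, rtol=1e-12)

    def test_truncation_keeps_values_nonnegative(self):
        spec = ls.CompositionSpec(fa_names=["a", "b"], means=[1.0, 1.0],
                                  sds=[0.5, 0.5], correlation=np.eye(2),
                                  n_samples=2000, seed=4)
        table = ls.draw_compositions(spec)
        assert (table.values.to_numpy() >= 0).all()

    def test_unrepairable_correlation_names_eigenvalue(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            repair_correlation(bad)

    def test_repaired_matrix_is_psd_unit_diagonal(self):
        mild = np.array([[1.0, 0.8, 0.0], [0.8, 1.0, 0.75], [0.0, 0.75, 1.0]])
        fixed = repair_correlation(mild)
        assert np.linalg.eigvalsh(fixed)[0] >= -1e-10
        np.testing.assert_allclose(np.diag(fixed), 1.0)


class TestComponentSpectra:
    def test_unit_amplitude_band_peaks_at_one(self):
        bands = BandModel([1000.0], [20.0], [1.0])
        axis = np.arange(900.0, 1100.0)
        spectrum = ls.build_component_spectrum(bands, axis)
        assert spectrum[np.where(axis == 1000.0)[0][0]] == pytest.approx(1.0)

    def test_nonoverlapping_bands_integrate_additively(self):
        axis = np.arange(0.0, 2000.0)
        b1 = BandModel([500.0], [10.0], [2.0])
        b2 = BandModel([1500.0], [10.0], [3.0])
        both = BandModel([500.0, 1500.0], [10.0, 10.0], [2.0, 3.0])
        s = ls.build_component_spectrum
        assert np.trapezoid(s(both, axis)) == pytest.approx(
            np.trapezoid(s(b1, axis)) + np.trapezoid(s(b2, axis)), rel=1e-10)

    def test_unsaturation_contrast_at_cc_stretch(self, defs):
        axis = np.arange(500.0, 1801.0)
        epa = ls.build_component_spectrum(raman_band_model(defs[EPA]), axis)
        stearate = ls.build_component_spectrum(raman_band_model(defs["C18-0"]), axis)
        i = np.where(axis == 1665.0)[0][0]
        assert epa[i] / max(stearate[i], 1e-12) > 10

    def test_empty_band_list_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="empty band list"):
            out = ls.build_component_spectrum(BandModel([], [], []), np.arange(10.0))
        np.testing.assert_array_equal(out, 0.0)


class TestSynthesizeSpectra:
    def _clean_kwargs(self):
        return dict(noise_sd=0.0, scatter_sd=0.0, baseline_order=-1,
                    baseline_scale=0.0, background_jitter_sd=0.0,
                    water_shift_sd=0.0, n_replicates=1)

    def test_single_component_identity(self, defs):
        table = ls.CompositionTable.from_arrays([EPA], [[100.0]], [40.0])
        sp = ls.synthesize_spectra(table, modality="raman", seed=0,
                                   include_backgrounds=False, **self._clean_kwargs())
        expected = 0.40 * ls.build_component_spectrum(raman_band_model(defs[EPA]),
                                                      sp.axis)
        np.testing.assert_allclose(sp.intensities[0], expected, atol=1e-12)

    def test_same_seed_bit_identical(self, comps300):
        a = ls.synthesize_spectra(comps300, modality="raman", seed=5, n_replicates=1)
        b = ls.synthesize_spectra(comps300, modality="raman", seed=5, n_replicates=1)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_noiseless_signal_rank_bounded(self, comps300):
        sp = ls.synthesize_spectra(comps300, modality="raman", seed=0,
                                   **self._clean_kwargs())
        s = np.linalg.svd(sp.intensities, compute_uv=False)
        # 13 FA components + protein + water backgrounds
        assert int((s > 1e-10 * s[0]).sum()) <= 15

    def test_negative_composition_rejected(self):
        with pytest.raises(ValueError):
            ls.CompositionTable.from_arrays(["a"], [[-1.0]], [10.0])

    def test_reflectance_roundtrip_through_absorbance(self, comps300):
        sp = ls.synthesize_spectra(comps300, modality="nir_reflectance", seed=1,
                                   n_replicates=1)
        assert (sp.intensities > 0).all()
        absorb = ls.reflectance_to_absorbance(sp)
        assert absorb.modality == "nir_absorbance"

    def test_clean_absolute_content_model_is_exact(self):
        """Distortion-free spectra are a linear map of fat × composition, so a
        PLS model of absolute contents cross-validates to R² = 1."""
        comps = ls.draw_compositions(ls.salmon_reference_spec(n_samples=60, seed=11))
        sp = ls.synthesize_spectra(comps, modality="raman", seed=12,
                                   **self._clean_kwargs())
        X = sp.intensities
        y = comps.column(DHA) * comps.fat.to_numpy() / 100.0
        cv = ls.cross_validate(X, y, 15, 7)
        assert cv.r2cv[cv.best_a - 1] >= 0.995

    def test_missing_band_model_errors(self, comps300):
        with pytest.raises(KeyError, match="band model"):
            ls.synthesize_spectra(comps300, library={}, modality="raman")


def test_spectra_csv_round_trip(tmp_path, comps300):
    sp = ls.synthesize_spectra(comps300, modality="raman", seed=3, n_replicates=2)
    path = tmp_path / "spectra.csv"
    sp.to_csv(path)
    back = ls.SpectraSet.from_csv(path, "raman")
    np.testing.assert_allclose(back.intensities, sp.intensities, rtol=1e-12)
    assert back.sample_ids == sp.sample_ids
    np.testing.assert_allclose(back.axis, sp.axis)
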