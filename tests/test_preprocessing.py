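"""Preprocessing chain: absorbance transform, SNV, trim, baseline, EMSC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import lipidspec as ls
from conftest import make_spectra


class TestAbsorbance:
    @pytest.mark.parametrize("r,expected", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_log_closed_forms(self, r, expected):
        sp = make_spectra([[r, r]], modality="nir_reflectance")
        out = ls.reflectance_to_absorbance(sp)
        np.testing.assert_allclose(out.intensities, expected, atol=1e-12)
        assert out.modality == "nir_absorbance"

    def test_nonpositive_reflectance_lists_channels(self):
        sp = make_spectra([[0.5, 0.0, 0.5]], modality="nir_reflectance")
        with pytest.raises(ValueError, match="channels"):
            ls.reflectance_to_absorbance(sp)

    def test_wrong_modality_rejected(self):
        sp = make_spectra([[1.0, 2.0]], modality="raman")
        with pytest.raises(ValueError):
            ls.reflectance_to_absorbance(sp)


class TestSNV:
    def test_closed_form(self):
        out = ls.snv(make_spectra([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.intensities, [[-1.0, 0.0, 1.0]], atol=1e-12)

    @given(hnp.arrays(np.float64, (3, 8), elements=st.floats(-50, 50)))
    @settings(max_examples=30, deadline=None)
    def test_rows_have_zero_mean_unit_sd(self, x):
        if np.any(x.std(axis=1, ddof=1) < 1e-6):
            return
        out = ls.snv(make_spectra(x)).intensities
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_idempotent(self, rng):
        sp = make_spectra(rng.normal(size=(4, 30)))
        once = ls.snv(sp)
        twice = ls.snv(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=(2, 40))
        a = ls.snv(make_spectra(x)).intensities
        b = ls.snv(make_spectra(3.7 * x)).intensities
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_constant_spectrum_names_sample(self):
        sp = make_spectra([[2.0, 2.0, 2.0]], samples=["fish42"])
        with pytest.raises(ValueError, match="fish42"):
            ls.snv(sp)


class TestTrim:
    def test_acquisition_range_to_analysis_range(self):
        axis = np.arange(300.0, 1890.5, 0.5)
        sp = make_spectra(np.ones((2, len(axis))), axis=axis)
        out = ls.trim(sp, 500.0, 1800.0)
        assert out.axis.min() == 500.0 and out.axis.max() == 1800.0
        assert out.intensities.shape[1] == len(out.axis)

    def test_wider_than_axis_is_identity(self):
        sp = make_spectra(np.ones((1, 5)), axis=[10.0, 20.0, 30.0, 40.0, 50.0])
        out = ls.trim(sp, 0.0, 100.0)
        np.testing.assert_array_equal(out.axis, sp.axis)

    def test_single_point(self):
        sp = make_spectra(np.ones((1, 5)), axis=[10.0, 20.0, 30.0, 40.0, 50.0])
        assert ls.trim(sp, 29.0, 31.0).n_channels == 1

    def test_empty_result_errors(self):
        sp = make_spectra(np.ones((1, 3)), axis=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ls.trim(sp, 10.0, 20.0)


class TestBaselineCorrection:
    def test_annihilates_exact_polynomial(self, rng):
        axis = np.linspace(500.0, 1800.0, 400)
        x01 = (axis - axis[0]) / (axis[-1] - axis[0]) * 2 - 1
        poly = np.polynomial.polynomial.polyval(x01, rng.normal(size=5))
        out = ls.polynomial_baseline_correct(poly, axis, order=4)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_linearity(self, rng):
        axis = np.linspace(0.0, 100.0, 200)
        signal = rng.normal(size=200)
        poly = 3.0 + 0.1 * axis - 0.002 * axis**2
        a = ls.polynomial_baseline_correct(signal + poly, axis, order=4)
        b = ls.polynomial_baseline_correct(signal, axis, order=4)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_order_zero_mean_centers(self, rng):
        axis = np.arange(50.0)
        x = rng.normal(size=50)
        out = ls.polynomial_baseline_correct(x, axis, order=0)
        np.testing.assert_allclose(out, x - x.mean(), atol=1e-10)


class TestEMSC:
    @pytest.fixture()
    def reference(self, rng):
        axis = np.linspace(500.0, 1800.0, 300)
        ref = np.exp(-0.5 * ((axis - 1440.0) / 30.0) ** 2) \
            + 0.6 * np.exp(-0.5 * ((axis - 1665.0) / 20.0) ** 2)
        return axis, ls.polynomial_baseline_correct(ref, axis, 4)

    def test_identity_on_reference(self, reference):
        axis, ref = reference
        sp = make_spectra(ref[None, :], axis=axis)
        out, model = ls.emsc_correct(sp, ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-8)
        assert model.multiplicative[0] == pytest.approx(1.0, abs=1e-8)
        assert model.additive[0] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(model.polynomial[0], 0.0, atol=1e-8)

    def test_affine_distortion_removed(self, reference):
        axis, ref = reference
        sp = make_spectra((3.0 * ref + 5.0)[None, :], axis=axis)
        out, _ = ls.emsc_correct(sp, ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-8)

    def test_polynomial_baseline_absorbed(self, reference):
        axis, ref = reference
        x01 = (axis - axis[0]) / (axis[-1] - axis[0]) * 2 - 1
        quad = 0.5 - 0.8 * x01 + 1.2 * x01**2
        sp = make_spectra((ref + quad)[None, :], axis=axis)
        out, _ = ls.emsc_correct(sp, ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-8)

    def test_positive_scaling_invariance(self, reference, rng):
        axis, ref = reference
        z = ref + 0.1 * rng.normal(size=ref.size)
        a, _ = ls.emsc_correct(make_spectra(z[None, :], axis=axis), ref)
        b, _ = ls.emsc_correct(make_spectra((2.5 * z)[None, :], axis=axis), ref)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-8)

    def test_degenerate_multiplicative_parameter_errors(self, reference):
        axis, ref = reference
        x01 = (axis - axis[0]) / (axis[-1] - axis[0]) * 2 - 1
        sp = make_spectra((0.3 + 0.2 * x01)[None, :], axis=axis, samples=["bad1"])
        with pytest.raises(ValueError, match="bad1"):
            ls.emsc_correct(sp, ref)

    def test_reference_from_identical_spectra(self, rng):
        axis = np.linspace(0.0, 100.0, 120)
        x = rng.normal(size=120)
        sp = make_spectra(np.tile(x, (3, 1)), axis=axis)
        ref = ls.emsc_fit_reference(sp, baseline_order=4)
        np.testing.assert_allclose(ref, ls.polynomial_baseline_correct(x, axis, 4),
                                   atol=1e-10)

    def test_reference_invariant_to_replicate_order(self, rng):
        axis = np.linspace(0.0, 100.0, 80)
        x = rng.normal(size=(4, 80))
        ref1 = ls.emsc_fit_reference(make_spectra(x, axis=axis))
        ref2 = ls.emsc_fit_reference(make_spectra(x[::-1], axis=axis))
        np.testing.assert_allclose(ref1, ref2, atol=1e-12)


class TestAverageReplicates:
    def test_identical_replicates(self, rng):
        x = rng.normal(size=30)
        sp = make_spectra(np.tile(x, (3, 1)), samples=["s1"] * 3,
                          reps=["r1", "r2", "r3"])
        out = ls.average_replicates(sp)
        assert out.n_spectra == 1
        np.testing.assert_allclose(out.intensities[0], x, atol=1e-12)

    def test_two_replicates_mean(self, rng):
        x, y = rng.normal(size=(2, 20))
        sp = make_spectra(np.stack([x, y]), samples=["s1", "s1"], reps=["r1", "r2"])
        np.testing.assert_allclose(ls.average_replicates(sp).intensities[0],
                                   (x + y) / 2, atol=1e-12)

    def test_commutes_with_trim(self, rng):
        axis = np.arange(100.0)
        x = rng.normal(size=(6, 100))
        sp = make_spectra(x, axis=axis, samples=["a", "a", "a", "b", "b", "b"],
                          reps=["r1", "r2", "r3"] * 2)
        a = ls.trim(ls.average_replicates(sp), 20.0, 60.0)
        b = ls.average_replicates(ls.trim(sp, 20.0, 60.0))
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-12)
        assert a.sample_ids == b.sample_ids


class TestChains:
    def test_nir_chain_order_recorded(self, comps300):
        sp = ls.synthesize_spectra(comps300, modality="nir_reflectance", seed=1,
                                   n_replicates=2)
        out = ls.nir_chain(sp)
        steps = [s.split("(")[0] for s in out.provenance if not s.startswith("synth")]
        assert steps == ["to_absorbance", "average_replicates", "snv", "trim"]

    def test_raman_chain_order_recorded(self, comps300):
        sp = ls.synthesize_spectra(comps300, modality="raman", seed=1, n_replicates=2)
        out, model = ls.raman_chain(sp)
        steps = [s.split("(")[0] for s in out.provenance if not s.startswith("synth")]
        assert steps == ["trim", "emsc", "average_replicates"]
        assert model.polynomial_order == 6
        assert out.n_spectra == comps300.n_samples
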