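"""Spectral preprocessing: absorbance transform, SNV, trimming, EMSC.

Two fixed chains are provided, mirroring standard practice for the two
modalities:

* NIR:   reflectance → absorbance (A = log₁₀(1/R)) → replicate average →
         SNV → trim to 1150–2500 nm.
* Raman: trim to 500–1800 cm⁻¹ → EMSC against a common baseline-corrected
         mean reference (sixth-order polynomial extension) → replicate
         average.

Every step appends to the :class:`~lipidspec.containers.SpectraSet`
provenance list so the applied chain is recorded with the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SpectraSet


def reflectance_to_absorbance(spectra: SpectraSet) -> SpectraSet:
    """A = log₁₀(1/R), elementwise; modality becomes ``nir_absorbance``."""
    if spectra.modality != "nir_reflectance":
        raise ValueError(f"expected nir_reflectance spectra, got {spectra.modality}")
    r = spectra.intensities
    if np.any(r <= 0):
        bad = np.unique(np.where(r <= 0)[1])
        raise ValueError(f"nonpositive reflectance at channels {bad[:10].tolist()}")
    return spectra.with_intensities(np.log10(1.0 / r), modality="nir_absorbance",
                                    step="to_absorbance")


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard Normal Variate: each spectrum centered and scaled to unit SD.

    Uses the sample (n−1) standard deviation.
    """
    x = spectra.intensities
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 channels")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = np.where(sd[:, 0] == 0)[0]
    if len(zero):
        names = [spectra.sample_ids[i] for i in zero[:5]]
        raise ValueError(f"constant spectrum (zero SD) for samples {names}")
    return spectra.with_intensities((x - mu) / sd, step="snv")


def trim(spectra: SpectraSet, low: float, high: float) -> SpectraSet:
    """Keep channels with low ≤ axis ≤ high, preserving order."""
    if low >= high:
        raise ValueError("trim requires low < high")
    keep = (spectra.axis >= low) & (spectra.axis <= high)
    if not keep.any():
        raise ValueError(f"trim({low}, {high}) leaves no channels")
    out = SpectraSet(
        intensities=spectra.intensities[:, keep],
        axis=spectra.axis[keep],
        modality=spectra.modality,
        sample_ids=list(spectra.sample_ids),
        replicate_ids=list(spectra.replicate_ids),
        provenance=list(spectra.provenance) + [f"trim({low:g}, {high:g})"],
    )
    return out


def _poly_basis(axis: np.ndarray, order: int) -> np.ndarray:
    """Vandermonde of plain powers on the axis affinely mapped to [−1, 1]."""
    lo, hi = axis[0], axis[-1]
    x = (2.0 * (axis - lo) / (hi - lo) - 1.0) if hi > lo else np.zeros_like(axis)
    return np.vander(x, order + 1, increasing=True)


def polynomial_baseline_correct(spectrum: np.ndarray, axis: np.ndarray,
                                order: int = 4) -> np.ndarray:
    """Subtract the least-squares polynomial of the given order."""
    spectrum = np.asarray(spectrum, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if order < 0:
        raise ValueError("order must be ≥ 0")
    if len(spectrum) <= order + 1:
        raise ValueError("need more channels than polynomial coefficients")
    basis = _poly_basis(axis, order)
    coef, *_ = np.linalg.lstsq(basis, spectrum, rcond=None)
    return spectrum - basis @ coef


def emsc_fit_reference(spectra: SpectraSet, baseline_order: int = 4) -> np.ndarray:
    """EMSC reference: the grand mean over all replicate spectra, baseline-corrected.

    The mean is taken over every spectrum in the set (a common reference
    frame for the whole dataset), then a polynomial baseline of
    ``baseline_order`` is removed.
    """
    if spectra.n_spectra < 2:
        raise ValueError("need at least 2 spectra to fit a reference")
    mean = spectra.intensities.mean(axis=0)
    return polynomial_baseline_correct(mean, spectra.axis, baseline_order)


@dataclass
class EMSCModel:
    """Fitted EMSC decomposition: per-spectrum additive (a), multiplicative (b)
    and polynomial (d₁..d_P) parameters against a common reference."""

    reference: np.ndarray
    polynomial_order: int
    basis: np.ndarray            # columns: 1, x, x², … on axis mapped to [−1, 1]
    additive: np.ndarray         # a, per spectrum
    multiplicative: np.ndarray   # b, per spectrum
    polynomial: np.ndarray       # d, per spectrum × order


def emsc_correct(spectra: SpectraSet, reference: np.ndarray,
                 polynomial_order: int = 6) -> tuple[SpectraSet, EMSCModel]:
    """Extended multiplicative signal correction against a common reference.

    Each spectrum z is decomposed by least squares as

        z ≈ a·1 + b·reference + Σⱼ dⱼ·xʲ        (j = 1..P)

    and the corrected spectrum is (z − a·1 − Σⱼ dⱼ·xʲ)/b, i.e. the additive,
    baseline and multiplicative distortions are removed and all spectra are
    expressed on the reference's intensity scale.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != spectra.axis.shape:
        raise ValueError("reference length must match channel count")
    basis = _poly_basis(spectra.axis, polynomial_order)
    design = np.column_stack([basis[:, :1], reference, basis[:, 1:]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("reference is collinear with the polynomial basis")
    params, *_ = np.linalg.lstsq(design, spectra.intensities.T, rcond=None)
    a = params[0]
    b = params[1]
    d = params[2:].T
    small = np.where(np.abs(b) < 1e-8)[0]
    if len(small):
        names = [spectra.sample_ids[i] for i in small[:5]]
        raise ValueError(f"EMSC multiplicative parameter ≈ 0 for samples {names}")
    poly_part = d @ basis[:, 1:].T
    corrected = (spectra.intensities - a[:, None] - poly_part) / b[:, None]
    model = EMSCModel(reference=reference, polynomial_order=polynomial_order,
                      basis=basis, additive=a, multiplicative=b, polynomial=d)
    out = spectra.with_intensities(corrected, step=f"emsc(order={polynomial_order})")
    return out, model


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """One spectrum per sample id: the arithmetic mean of its replicates.

    Sample order follows first appearance in the replicate set.
    """
    samples = spectra.unique_samples()
    ids = np.asarray(spectra.sample_ids)
    means = np.stack([spectra.intensities[ids == s].mean(axis=0) for s in samples])
    return SpectraSet(intensities=means, axis=spectra.axis, modality=spectra.modality,
                      sample_ids=samples, replicate_ids=["mean"] * len(samples),
                      provenance=list(spectra.provenance) + ["average_replicates"])


def nir_chain(spectra: SpectraSet, low: float = 1150.0, high: float = 2500.0) -> SpectraSet:
    """Full NIR chain: to-absorbance → replicate average → SNV → trim."""
    if spectra.modality == "nir_reflectance":
        spectra = reflectance_to_absorbance(spectra)
    elif spectra.modality != "nir_absorbance":
        raise ValueError("NIR chain expects NIR spectra")
    return trim(snv(average_replicates(spectra)), low, high)


def raman_chain(spectra: SpectraSet, low: float = 500.0, high: float = 1800.0,
                baseline_order: int = 4, polynomial_order: int = 6
                ) -> tuple[SpectraSet, EMSCModel]:
    """Full Raman chain: trim → EMSC (common reference) → replicate average."""
    if spectra.modality != "raman":
        raise ValueError("Raman chain expects raman spectra")
    trimmed = trim(spectra, low, high)
    reference = emsc_fit_reference(trimmed, baseline_order)
    corrected, model = emsc_correct(trimmed, reference, polynomial_order)
    return average_replicates(corrected), model
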