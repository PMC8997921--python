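"""Shared fixtures: canonical synthetic datasets built once per session.

The "study" fixtures use the default generator conditions (13 FAs with the
standard means/SDs/correlations, n=300 samples, triplicate spectra) at a
fixed seed, so every test sees the same reproducible dataset.
"""

from __future__ import annotations

import numpy as np
import pytest

import lipidspec as ls
from lipidspec.preprocessing import average_replicates, reflectance_to_absorbance, trim

STUDY_SEED = 7


@pytest.fixture(scope="session")
def defs():
    return ls.builtin_definitions()


@pytest.fixture(scope="session")
def comps300():
    """Canonical composition table: 13 FAs, n=300, default structure."""
    return ls.draw_compositions(ls.salmon_reference_spec(n_samples=300, seed=STUDY_SEED))


@pytest.fixture(scope="session")
def raman_study(comps300):
    """Raman-like study data: processed matrix, axis, raw replicate-averaged block."""
    spectra = ls.synthesize_spectra(comps300, modality="raman", seed=STUDY_SEED + 200)
    processed, _ = ls.raman_chain(spectra)
    order = [processed.sample_ids.index(s) for s in comps300.sample_ids]
    raw = average_replicates(trim(spectra, 500.0, 1800.0))
    raw_x = raw.intensities[[raw.sample_ids.index(s) for s in comps300.sample_ids]]
    return {"X": processed.intensities[order], "axis": processed.axis,
            "raw": raw_x, "comps": comps300}


@pytest.fixture(scope="session")
def nir_study(comps300):
    """NIR-like study data: SNV-processed matrix, axis, raw absorbance block."""
    spectra = ls.synthesize_spectra(comps300, modality="nir_reflectance",
                                    seed=STUDY_SEED + 100)
    processed = ls.nir_chain(spectra)
    order = [processed.sample_ids.index(s) for s in comps300.sample_ids]
    raw = average_replicates(reflectance_to_absorbance(spectra))
    raw_x = raw.intensities[[raw.sample_ids.index(s) for s in comps300.sample_ids]]
    return {"X": processed.intensities[order], "axis": processed.axis,
            "raw": raw_x, "comps": comps300}


@pytest.fixture()
def rng():
    return np.random.default_rng(STUDY_SEED)


def make_spectra(intensities, axis=None, modality="raman", samples=None, reps=None):
    """Small helper to build a SpectraSet from a plain matrix."""
    intensities = np.asarray(intensities, dtype=float)
    n, p = intensities.shape
    if axis is None:
        axis = np.arange(p, dtype=float)
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    if reps is None:
        reps = ["r1"] * n
    return ls.SpectraSet(intensities=intensities, axis=np.asarray(axis, float),
                         modality=modality, sample_ids=samples, replicate_ids=reps)
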