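"""Synthetic salmon-muscle compositions and Raman/NIR-like spectra.

The generator emulates the statistical structure a muscle-spectroscopy
calibration study rests on: fatty-acid compositions with realistic means,
spreads and a strong co-variation structure (a plant-oil pole of C18
unsaturates against a marine pole of long-chain n-3 FAs, as produced by
feed-oil blending); fat-content variation that drives absolute contents;
Raman-like spectra built from narrow chemically-assigned bands; NIR-like
spectra dominated by broad water/protein bands, multiplicative scatter and
polynomial baselines.

All randomness flows through a single integer seed, so identical calls are
bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import CompositionTable, SpectraSet
from .reference import DHA, EPA, FattyAcidDefinition, builtin_definitions

# ---------------------------------------------------------------------------
# Composition simulation
# ---------------------------------------------------------------------------

# Proportional contents (% of total FA), mean and SD, for the 13 FAs the
# analysis models (those above ~2% of total FA in farmed Atlantic salmon).
SALMON_FA_STATS: dict[str, tuple[float, float]] = {
    "C14-0": (3.4, 0.3),
    "C16-0": (11.7, 0.6),
    "C18-0": (2.7, 0.2),
    "C16-1 (n-7)": (4.0, 0.3),
    "C18-1 (n-9)": (30.5, 1.8),
    "C18-1 (n-7)": (3.0, 0.3),
    "C20-1 (n-9)": (3.7, 0.3),
    "C22-1 (n-11)": (3.1, 0.5),
    "C18-2 (n-6)": (9.6, 0.7),
    "C18-3 (n-3)": (3.4, 0.2),
    EPA: (5.1, 0.5),
    "C22-5 (n-3)": (2.3, 0.2),
    DHA: (6.8, 0.5),
}

# Pairwise correlations reported for this kind of sample set.
CITED_CORRELATIONS: dict[tuple[str, str], float] = {
    ("C18-1 (n-9)", "C18-2 (n-6)"): 0.95,
    ("C18-2 (n-6)", "C18-3 (n-3)"): 0.88,
    (EPA, DHA): 0.51,
}

_PLANT = ["C18-1 (n-9)", "C18-1 (n-7)", "C18-2 (n-6)", "C18-3 (n-3)"]
_MARINE = ["C14-0", "C16-0", "C16-1 (n-7)", "C20-1 (n-9)", "C22-1 (n-11)",
           EPA, "C22-5 (n-3)", DHA]


def default_correlation(fa_names: Sequence[str] | None = None) -> np.ndarray:
    """Default FA correlation matrix: cited pairs plus a two-pole feed axis.

    Uncited entries are filled from group membership (plant-oil FAs mutually
    high-positive, marine FAs moderately positive, plant vs marine negative)
    and then the matrix is repaired to the nearest unit-diagonal PSD matrix.
    """
    names = list(fa_names) if fa_names is not None else list(SALMON_FA_STATS)
    n = len(names)
    corr = np.full((n, n), 0.1)
    idx = {name: i for i, name in enumerate(names)}

    def put(a: str, b: str, r: float) -> None:
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r

    for a in names:
        for b in names:
            if a == b:
                continue
            in_p = (a in _PLANT) + (b in _PLANT)
            in_m = (a in _MARINE) + (b in _MARINE)
            if in_p == 2:
                put(a, b, 0.82)
            elif in_m == 2:
                put(a, b, 0.45)
            elif in_p == 1 and in_m == 1:
                put(a, b, -0.45)
    # long-chain n-3 cluster a little tighter
    put(EPA, "C22-5 (n-3)", 0.55)
    put(DHA, "C22-5 (n-3)", 0.45)
    put("C20-1 (n-9)", "C22-1 (n-11)", 0.70)
    put("C14-0", "C16-0", 0.60)
    # the marine–plant antagonism is strongest for the majors
    put("C18-1 (n-9)", EPA, -0.60)
    put("C18-1 (n-9)", DHA, -0.60)
    for (a, b), r in CITED_CORRELATIONS.items():
        put(a, b, r)
    np.fill_diagonal(corr, 1.0)
    return repair_correlation(corr)


def repair_correlation(corr: np.ndarray, min_eig_allowed: float = -0.15) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal.

    Raises if the matrix is too indefinite to be an honest correlation
    target (smallest eigenvalue below ``min_eig_allowed``).
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation must be symmetric")
    w, v = np.linalg.eigh(corr)
    if w[0] < min_eig_allowed:
        raise ValueError(
            f"correlation matrix is not repairable to PSD: smallest eigenvalue {w[0]:.4f}"
        )
    if w[0] >= -1e-8:
        out = corr.copy()
    else:
        w = np.clip(w, 0.0, None)
        out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class CompositionSpec:
    """Target marginal statistics and correlation for simulated compositions.

    ``fat_correlation`` optionally couples fat (% of sample) to the FAs; by
    default fat is drawn independently, truncated at ``fat_min``.
    """

    fa_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    correlation: np.ndarray
    fat_mean: float = 18.0
    fat_sd: float = 3.0
    fat_min: float = 5.0
    fat_correlation: np.ndarray | None = None
    n_samples: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = len(self.fa_names)
        if self.means.shape != (k,) or self.sds.shape != (k,):
            raise ValueError("means/sds must match fa_names length")
        if np.any(self.means <= 0):
            raise ValueError("means must be positive")
        if np.any(self.sds < 0):
            raise ValueError("sds must be nonnegative")
        if self.n_samples < 2:
            raise ValueError("n_samples must be ≥ 2")
        self.correlation = repair_correlation(np.asarray(self.correlation, dtype=float))
        if self.correlation.shape != (k, k):
            raise ValueError("correlation must be fa_names × fa_names")
        if self.fat_correlation is not None:
            self.fat_correlation = np.asarray(self.fat_correlation, dtype=float)
            if self.fat_correlation.shape != (k,):
                raise ValueError("fat_correlation must have one entry per FA")


def salmon_reference_spec(n_samples: int = 618, seed: int = 0) -> CompositionSpec:
    """The default 13-FA study conditions (means/SDs and correlation structure)."""
    names = list(SALMON_FA_STATS)
    means = np.array([SALMON_FA_STATS[n][0] for n in names])
    sds = np.array([SALMON_FA_STATS[n][1] for n in names])
    return CompositionSpec(fa_names=names, means=means, sds=sds,
                           correlation=default_correlation(names),
                           n_samples=n_samples, seed=seed)


def _truncated_mvn(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray,
                   n: int, max_tries: int = 200) -> np.ndarray:
    """Draw MVN rows, redrawing any row with a negative entry (truncation at 0)."""
    out = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    for _ in range(max_tries):
        bad = np.any(out < 0, axis=1)
        if not bad.any():
            return out
        out[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()),
                                           method="cholesky")
    raise RuntimeError("truncated MVN rejection did not converge; means too close to 0")


def draw_compositions(spec: CompositionSpec, total: float | None = None) -> CompositionTable:
    """Draw per-sample FA compositions and fat contents with known ground truth.

    FA vectors come from a zero-truncated multivariate normal with the
    requested means, SDs and correlations.  If ``total`` is given, each
    sample is additionally rescaled so its modelled FAs sum to that constant
    (compositional closure); the default leaves the draws unclosed so the
    requested correlation structure is preserved exactly.

    Fat (% of sample) is drawn from a truncated normal, independently of the
    FAs unless ``spec.fat_correlation`` is set.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.fa_names)
    if spec.fat_correlation is None:
        cov = spec.correlation * np.outer(spec.sds, spec.sds)
        v = _truncated_mvn(rng, spec.means, cov, spec.n_samples) if np.any(spec.sds > 0) \
            else np.tile(spec.means, (spec.n_samples, 1))
        fat = _truncated_fat(rng, spec)
    else:
        corr = np.zeros((k + 1, k + 1))
        corr[:k, :k] = spec.correlation
        corr[k, :k] = corr[:k, k] = spec.fat_correlation
        corr[k, k] = 1.0
        corr = repair_correlation(corr)
        sds = np.append(spec.sds, spec.fat_sd)
        means = np.append(spec.means, spec.fat_mean)
        joint = _truncated_mvn(rng, means, corr * np.outer(sds, sds), spec.n_samples)
        v, fat = joint[:, :k], joint[:, k]
        fat = np.clip(fat, spec.fat_min, None)
    if total is not None:
        rowsum = v.sum(axis=1)
        if np.any(rowsum <= 0):
            raise ValueError("cannot close compositions with zero row sum")
        v = v * (total / rowsum[:, None])
    return CompositionTable.from_arrays(spec.fa_names, v, fat)


def _truncated_fat(rng: np.random.Generator, spec: CompositionSpec) -> np.ndarray:
    if spec.fat_sd == 0:
        return np.full(spec.n_samples, spec.fat_mean)
    fat = rng.normal(spec.fat_mean, spec.fat_sd, size=spec.n_samples)
    for _ in range(200):
        bad = fat < spec.fat_min
        if not bad.any():
            return fat
        fat[bad] = rng.normal(spec.fat_mean, spec.fat_sd, size=int(bad.sum()))
    return np.clip(fat, spec.fat_min, None)


# ---------------------------------------------------------------------------
# Band models and component spectra
# ---------------------------------------------------------------------------

@dataclass
class BandModel:
    """A set of spectral bands (positions, FWHMs, amplitudes) of one shape."""

    positions: np.ndarray
    widths: np.ndarray        # full width at half maximum, axis units
    amplitudes: np.ndarray
    shape: str = "gaussian"   # or "lorentzian"

    def __post_init__(self) -> None:
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if not (len(self.positions) == len(self.widths) == len(self.amplitudes)):
            raise ValueError("positions, widths, amplitudes must have equal length")
        if len(self.widths) and np.any(self.widths <= 0):
            raise ValueError("all widths must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")


def build_component_spectrum(bands: BandModel, axis: np.ndarray) -> np.ndarray:
    """Sum of band profiles on ``axis``; each band has unit height at its center."""
    axis = np.asarray(axis, dtype=float)
    if len(bands.positions) == 0:
        warnings.warn("empty band list: returning a zero spectrum", stacklevel=2)
        return np.zeros_like(axis)
    out = np.zeros_like(axis)
    for pos, fwhm, amp in zip(bands.positions, bands.widths, bands.amplitudes):
        if bands.shape == "gaussian":
            sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            out += amp * np.exp(-0.5 * ((axis - pos) / sigma) ** 2)
        else:
            hw = fwhm / 2.0
            out += amp * hw**2 / ((axis - pos) ** 2 + hw**2)
    return out


# Raman shift (cm⁻¹) of the C=C stretch moves up with the unsaturation level.
_CC_STRETCH_POS = {1: 1655.0, 2: 1657.0, 3: 1659.0, 4: 1662.0, 5: 1665.0, 6: 1666.0}


def raman_band_model(fa: FattyAcidDefinition) -> BandModel:
    """Narrow-band Raman model of one fatty acid, tied to its chemistry.

    Unsaturation bands (C=C stretch, =C–H rock, alkene C–H deformation)
    scale with the double-bond count; CH₂ bands (scissoring, twist) and the
    skeletal C–C / C–O stretches scale with a methylene-count proxy
    (chain length − 2·#DB − 2).  The C=C stretch position shifts from
    ~1655 cm⁻¹ (monounsaturated) to 1666 cm⁻¹ (DHA).
    """
    d = fa.n_double_bonds
    m = max(fa.n_carbons - 2 * d - 2, 0)
    dx = 0.3 * (fa.n_carbons - 18)  # slight chain-length shift of CH₂ bands
    positions, widths, amps = [], [], []
    if d > 0:
        positions += [_CC_STRETCH_POS.get(d, 1666.0), 1266.0, 935.0]
        widths += [16.0, 20.0, 18.0]
        amp935 = 0.30 * d * (1.5 if d == 6 else 1.0)  # DHA relatively stronger at 935
        amps += [1.0 * d, 0.55 * d, amp935]
    if m > 0:
        positions += [1440.0 + dx, 1300.0 + dx, 1122.0 + dx, 1066.0 + dx]
        widths += [22.0, 22.0, 16.0, 16.0]
        amps += [0.16 * m, 0.09 * m, 0.055 * m, 0.055 * m]
    return BandModel(np.array(positions), np.array(widths), np.array(amps))


def nir_band_model(fa: FattyAcidDefinition) -> BandModel:
    """Broad-band NIR model of one fatty acid (CH overtone/combination bands).

    Band centers shift by a few nm with chain length and unsaturation level,
    as they do physically; against FWHMs of 80–95 nm these shifts are the
    only FA-specific information beyond gross CH₂/C=C amplitudes, which is
    what makes NIR calibration demand many latent components.
    """
    d = fa.n_double_bonds
    m = max(fa.n_carbons - 2 * d - 2, 0)
    dc = fa.n_carbons - 18
    positions = [1210.0 + 4.0 * dc, 1725.0 + 5.0 * dc - 3.0 * d, 1765.0 + 4.0 * dc,
                 2310.0 + 4.0 * dc - 2.5 * d, 2350.0 + 3.0 * dc]
    widths = [90.0, 80.0, 80.0, 85.0, 85.0]
    amps = [0.045 * m, 0.11 * m, 0.075 * m, 0.13 * m, 0.09 * m]
    if d > 0:
        positions += [1160.0 + 6.0 * d, 2170.0 + 7.5 * d + 2.5 * dc]
        widths += [85.0, 95.0]
        amps += [0.16 * d, 0.22 * d]
    return BandModel(np.array(positions), np.array(widths), np.array(amps))


def default_band_library(modality: str,
                         defs: Mapping[str, FattyAcidDefinition] | None = None
                         ) -> dict[str, BandModel]:
    defs = defs or builtin_definitions()
    if modality == "raman":
        return {name: raman_band_model(d) for name, d in defs.items()}
    return {name: nir_band_model(d) for name, d in defs.items()}


def default_backgrounds(modality: str) -> tuple[BandModel, BandModel]:
    """(protein, water) background band models for a modality.

    Raman backgrounds are weak (muscle protein amide/CH bands plus the broad
    water bend); NIR backgrounds are dominant, as water O–H and protein N–H
    combination bands swamp the lipid signal in reflectance spectra.
    """
    if modality == "raman":
        protein = BandModel(np.array([1003.0, 1250.0, 1450.0, 1660.0]),
                            np.array([12.0, 55.0, 40.0, 45.0]),
                            np.array([0.30, 0.35, 0.45, 0.55]))
        water = BandModel(np.array([1640.0]), np.array([90.0]), np.array([0.20]))
    else:
        protein = BandModel(np.array([2055.0, 2180.0]),
                            np.array([95.0, 100.0]),
                            np.array([0.55, 0.70]))
        water = BandModel(np.array([1450.0, 1790.0, 1940.0]),
                          np.array([110.0, 120.0, 140.0]),
                          np.array([1.00, 0.25, 1.40]))
    return protein, water


DEFAULT_RAMAN_AXIS = np.arange(500.0, 1800.0 + 1e-9, 1.0)   # cm⁻¹
DEFAULT_NIR_AXIS = np.arange(1150.0, 2500.0 + 1e-9, 2.0)    # nm

# Generator defaults per modality.  Raman noise is set so calibration models
# are good but imperfect at n of a few hundred; its baselines include broad
# non-polynomial fluorescence humps (fluor_scale) that EMSC cannot fully
# remove.  NIR carries little detector noise but strong scatter and baseline
# variation, and its water band dominates.
MODALITY_DEFAULTS = {
    "raman": dict(noise_sd=0.0005, scatter_sd=0.03, baseline_order=4,
                  baseline_scale=0.05, fluor_scale=0.0, background_jitter_sd=0.01,
                  water_shift_sd=0.0),
    "nir_reflectance": dict(noise_sd=0.002, scatter_sd=0.30, baseline_order=2,
                            baseline_scale=0.06, fluor_scale=0.0,
                            background_jitter_sd=0.04, water_shift_sd=1.5),
    "nir_absorbance": dict(noise_sd=0.002, scatter_sd=0.30, baseline_order=2,
                           baseline_scale=0.06, fluor_scale=0.0,
                           background_jitter_sd=0.04, water_shift_sd=1.5),
}

# Muscle water content falls roughly linearly as fat rises; the water
# background is scaled per sample by water%/water%(mean fat).
_WATER_INTERCEPT, _WATER_SLOPE = 74.0, 0.8


def synthesize_spectra(comps: CompositionTable,
                       library: Mapping[str, BandModel] | None = None,
                       modality: str = "raman",
                       axis: np.ndarray | None = None,
                       noise_sd: float | None = None,
                       baseline_order: int | None = None,
                       baseline_scale: float | None = None,
                       scatter_sd: float | None = None,
                       fluor_scale: float | None = None,
                       background_jitter_sd: float | None = None,
                       water_shift_sd: float | None = None,
                       include_backgrounds: bool = True,
                       n_replicates: int = 3,
                       seed: int = 0) -> SpectraSet:
    """Render replicate spectra from compositions and a band library.

    Per replicate the noiseless signal is

        signal = fat/100 · Σᵢ Vᵢ/100 · component_spectrumᵢ
                 + protein_background · (1 − fat/100) + water_background,

    with the water background scaled per sample by the (fat-dependent)
    muscle water content.  Then a multiplicative scatter factor
    (1 + N(0, scatter_sd²)), a random polynomial baseline of the given
    order, broad random fluorescence humps of height ~``fluor_scale``
    (Raman only by default; not exactly polynomial, so EMSC removes them
    only partially), and iid N(0, noise_sd²) noise are applied.  For
    ``nir_reflectance`` the returned intensities are R = 10^(−signal), so
    the log₁₀(1/R) transform of the preprocessing chain is exercised.
    """
    if modality not in MODALITY_DEFAULTS:
        raise ValueError(f"unknown modality {modality!r}")
    d = MODALITY_DEFAULTS[modality]
    noise_sd = d["noise_sd"] if noise_sd is None else noise_sd
    scatter_sd = d["scatter_sd"] if scatter_sd is None else scatter_sd
    baseline_order = d["baseline_order"] if baseline_order is None else baseline_order
    baseline_scale = d["baseline_scale"] if baseline_scale is None else baseline_scale
    fluor_scale = d["fluor_scale"] if fluor_scale is None else fluor_scale
    background_jitter_sd = (d["background_jitter_sd"] if background_jitter_sd is None
                            else background_jitter_sd)
    water_shift_sd = d["water_shift_sd"] if water_shift_sd is None else water_shift_sd
    if axis is None:
        axis = DEFAULT_RAMAN_AXIS if modality == "raman" else DEFAULT_NIR_AXIS
    axis = np.asarray(axis, dtype=float)
    band_modality = "raman" if modality == "raman" else "nir"
    if library is None:
        library = default_band_library(band_modality)
    missing = [n for n in comps.fa_names if n not in library]
    if missing:
        raise KeyError(f"no band model for: {missing}")

    v = comps.values.to_numpy()
    fat = comps.fat.to_numpy()
    if np.any(v < 0) or np.any(fat < 0):
        raise ValueError("negative composition or fat content")

    comp_spectra = np.stack([build_component_spectrum(library[n], axis)
                             for n in comps.fa_names])
    protein_bands, water_bands = default_backgrounds(band_modality if band_modality == "raman"
                                                     else "nir")
    protein = build_component_spectrum(protein_bands, axis)
    water = build_component_spectrum(water_bands, axis)
    if not include_backgrounds:
        protein = np.zeros_like(protein)
        water = np.zeros_like(water)
        water_shift_sd = 0.0

    rng = np.random.default_rng(seed)

    # fat/100 · Σ V/100 · component + protein·(1−fat/100) + water·(water%/water%̄),
    # with independent per-sample jitter on the two backgrounds
    # (homogenization/sampling variability of the bulk composition).
    fa_signal = (v / 100.0) @ comp_spectra
    water_scale = (_WATER_INTERCEPT - _WATER_SLOPE * fat) / (
        _WATER_INTERCEPT - _WATER_SLOPE * float(np.mean(fat)))
    n_samp = len(fat)
    if background_jitter_sd > 0:
        protein_jit = 1.0 + rng.normal(0.0, background_jitter_sd, size=n_samp)
        water_jit = 1.0 + rng.normal(0.0, background_jitter_sd, size=n_samp)
    else:
        protein_jit = water_jit = np.ones(n_samp)
    if water_shift_sd > 0:
        # per-sample shift of the water bands (temperature/hydration state);
        # a shifting dominant band is a nonlinear, multi-component interferent
        shifts = rng.normal(0.0, water_shift_sd, size=n_samp)
        water_rows = np.stack([
            build_component_spectrum(
                BandModel(water_bands.positions + s, water_bands.widths,
                          water_bands.amplitudes), axis)
            for s in shifts])
    else:
        water_rows = np.tile(water, (n_samp, 1))
    base = ((fat[:, None] / 100.0) * fa_signal
            + np.outer((1.0 - fat / 100.0) * protein_jit, protein)
            + (water_scale * water_jit)[:, None] * water_rows)
    n, p = base.shape
    x01 = np.linspace(-1.0, 1.0, p)
    rows, sample_ids, replicate_ids = [], [], []
    for i in range(n):
        for r in range(n_replicates):
            y = base[i].copy()
            if scatter_sd > 0:
                y = y * (1.0 + rng.normal(0.0, scatter_sd))
            if baseline_order is not None and baseline_order >= 0 and baseline_scale > 0:
                coef = rng.normal(0.0, baseline_scale, size=baseline_order + 1)
                y = y + np.polynomial.polynomial.polyval(x01, coef)
            if fluor_scale > 0:
                # broad, non-polynomial fluorescence humps
                span = axis[-1] - axis[0]
                for _ in range(2):
                    c = rng.uniform(axis[0], axis[-1])
                    w = rng.uniform(0.10, 0.30) * span
                    amp = abs(rng.normal(0.0, fluor_scale))
                    y = y + amp * np.exp(-0.5 * ((axis - c) / w) ** 2)
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, size=p)
            rows.append(y)
            sample_ids.append(comps.sample_ids[i])
            replicate_ids.append(f"r{r+1}")
    intens = np.array(rows)
    if modality == "nir_reflectance":
        intens = 10.0 ** (-intens)
    return SpectraSet(intensities=intens, axis=axis, modality=modality,
                      sample_ids=sample_ids, replicate_ids=replicate_ids,
                      provenance=[f"synthesize(modality={modality}, seed={seed}, "
                                  f"noise_sd={noise_sd}, scatter_sd={scatter_sd}, "
                                  f"baseline_order={baseline_order}, "
                                  f"n_replicates={n_replicates})"])
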