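# Methods

## The problem being modelled

A calibration study relates vibrational spectra of homogenized muscle
samples to per-sample fatty-acid (FA) compositions measured by gas
chromatography. Compositions are *proportional* contents V(i) in % of total
FA; multiplying by the fat content (% of sample) gives *absolute* contents.
The scientific question the diagnostics address is identifiability: FAs
co-vary strongly in any one population, their spectra overlap, and fat
content scales every lipid signal, so a model with a high R² may be
measuring fat or a correlated FA rather than its nominal analyte.

## Composition simulator

Compositions are drawn from a multivariate normal with user-specified
marginal means and SDs and a target correlation matrix, truncated at zero by
rejection (negligible rejection rates at the default conditions, where means
sit 5–17 SDs above zero). The default conditions are thirteen FAs — the ones
abundant enough (>2% of total FA) to plausibly leave a spectral signature in
farmed Atlantic salmon — with means from 2.3 to 30.5% and SDs 0.2–1.8%.

The default correlation matrix fixes the cited anchor pairs
(18:1 n-9 ↔ 18:2 n-6 at 0.95, 18:2 n-6 ↔ 18:3 n-3 at 0.88, EPA ↔ DHA at
0.51, EPA/DHA ↔ 18:1 n-9 at −0.60) and fills the rest from a two-pole
structure: plant-oil FAs (C18 unsaturates) mutually high-positive, marine
FAs (14:0, 16:0, 16:1, 20:1, 22:1, EPA, DPA, DHA) moderately positive, and
the two groups negatively coupled — the single feed-blend axis that
dominates FA variation in farmed fish. The assembled matrix is repaired to
the nearest unit-diagonal PSD matrix by eigenvalue clipping; matrices with
an eigenvalue below −0.15 are rejected as incoherent rather than repaired.

Per-sample closure ("FAs sum to 100%") is available via `total=` but off by
default: closing a composition deforms the requested correlations (two
closed FAs are correlated −1 by construction), and the thirteen modelled FAs
are only ~89% of total FA anyway. Fat content is N(18, 3²)% truncated at 5%,
drawn independently of the FAs unless a fat–FA correlation vector is given.
Because the modelled FAs exclude the ~17 minor GC-detected species, the
simulated iodine-value mean (~122 g I₂/100 g) sits below the full-profile
value (~135) by construction; tests assert this rather than hide it.

## Spectra generator

The noiseless signal per sample is a bilinear mixture:

    signal = fat/100 · Σᵢ V(i)/100 · sᵢ(ν)
             + protein(ν) · (1 − fat/100) · (1 + ε_p)
             + water(ν) · w(fat)/w̄ · (1 + ε_w)

where sᵢ is FA i's component spectrum (sum of Gaussian or Lorentzian bands),
w(fat) = 74 − 0.8·fat approximates the % water of muscle, and ε_p, ε_w are
per-sample background jitters. Each replicate then receives a multiplicative
scatter factor (1 + N(0, σ_scatter²)), a random polynomial baseline, and iid
channel noise. NIR reflectance is emitted as R = 10^(−signal) so the
log₁₀(1/R) step of the preprocessing chain is exercised.

**Raman band chemistry** (axis 500–1800 cm⁻¹ at 1 cm⁻¹, FWHM 16–22 cm⁻¹):
unsaturation bands — C=C stretch (1655 cm⁻¹ for monounsaturates rising to
1665/1666 cm⁻¹ for EPA/DHA), =C–H rock at 1266 cm⁻¹, alkene C–H deformation
at 935 cm⁻¹ (relatively enhanced for DHA) — scale with the double-bond
count; CH₂ scissoring (1440), twist (1300) and skeletal C–C/C–O stretches
(1122/1066 cm⁻¹) scale with a methylene proxy (chain length − 2·#DB − 2) and
shift slightly with chain length. This makes unsaturation-driven
separability (EPA vs DHA vs 18:1) emerge from chemistry, not from labels.

**NIR bands** (axis 1150–2500 nm at 2 nm, FWHM 80–95 nm): CH overtone and
combination bands at 1210/1725/1765/2310/2350 nm scaling with the methylene
proxy, unsaturation bands at 1160/2170 nm scaling with #DB. Band centers
shift a few nm per carbon and per double bond. These shifts are deliberately
larger than physical NIR shifts: against 80–95 nm widths they are still
subtle (recoverable only after the bulk variance is modelled out), and they
are what gives the NIR-like data any single-FA information at all. The
dominant NIR terms are the water bands (1450/1790/1940 nm, amplitudes up to
1.4 absorbance) and protein combination bands (2055/2180 nm); water band
*positions* additionally jitter per sample (σ = 1.5 nm), a nonlinear
interferent — as a dominant band slides, its difference spectrum spans
several principal directions — which is the main reason the NIR models need
many latent components, mirroring real NIR behaviour.

### Default distortion levels (the study conditions)

| parameter | Raman | NIR | meaning |
|---|---|---|---|
| noise_sd | 0.0005 | 0.002 | iid channel noise (signal units / absorbance) |
| scatter_sd | 0.03 | 0.30 | multiplicative intensity factor SD |
| baseline order / scale | 4 / 0.05 | 2 / 0.06 | random polynomial per replicate |
| background_jitter_sd | 0.01 | 0.04 | per-sample protein/water amplitude jitter |
| water_shift_sd | 0 | 1.5 nm | per-sample water band position jitter |
| fluor_scale | 0 | — | optional non-polynomial fluorescence humps |

The Raman noise level was calibrated once, by scanning signal-to-noise at
n = 300, to the intended regime of *good but imperfect* models
(cross-validated R² ≈ 0.82–0.88 for 18:1 n-9, EPA and DHA) and then frozen;
the NIR levels encode the modality's character (high photometric SNR, strong
scatter, bulk-dominated variance). With every distortion switched off the
spectra are an exact linear map of fat × composition and a PLS model of any
absolute content cross-validates to R² = 1, which the tests verify.

## Preprocessing

*NIR*: reflectance → absorbance A = log₁₀(1/R); replicate averaging (the
triplicate mean is the analysis unit); SNV (row-center, scale to unit
sample SD, ddof = 1 — stated because the ddof choice rescales all values);
trim to 1150–2500 nm. Whether SNV precedes or follows trimming is a genuine
free choice; this chain fixes SNV-before-trim and records the order in the
data's provenance list.

*Raman*: trim to 500–1800 cm⁻¹; EMSC against a common reference — the grand
mean of **all** replicate spectra in the dataset, baseline-corrected with a
4th-order polynomial — using a 6th-order polynomial extension; replicate
averaging last, so each replicate is corrected individually. Using one
global reference (rather than per-sample references) corrects every spectrum
into a common frame, which any model-transfer use requires. The polynomial
basis is plain powers of the axis affinely mapped to [−1, 1]: adequate
conditioning at order 6 without changing the fitted subspace. EMSC applied
to its own reference is the identity; |b| < 1e−8 (a spectrum indistinguishable
from a polynomial) is an error naming the sample.

## PLS, cross-validation, selection

PLS is single-response NIPALS on column-centered X and centered y: per
component w = X'y/‖X'y‖, t = Xw, p = X't/t't, q = y't/t't, then deflation of
both X and y. For one response no inner iteration is needed, so every
component is a closed-form pass and the implementation is testable
per-component. Coefficient vectors B_a = W(P'W)⁻¹q are stored for every
component count a ≤ A_max (default 20, headroom above the counts the
procedures actually select). Models are fit FA-by-FA; multi-response PLS2 is
out of scope.

Cross-validation uses venetian blinds: sample i (dataset order) in fold
i mod 7. The samples are generated in random order, so interleaved folds
are unbiased; an optional explicit fold vector supports seeded shuffling.
R²_cv uses the full-data mean in its denominator (conventions differ; this
one keeps R² comparable across folds). Component selection is the global
RMSECV minimum by default, with a "parsimonious" alternative (smallest a
within (1+tol) of the minimum, tol = 0.01); ties go to fewer components.
Both rules are exposed because no single convention is canonical.

Variable selection implements two procedures. *Region retraining* refits on
user-supplied axis windows and keeps the restricted model only if its best
RMSECV strictly improves on the full-spectrum baseline (ties keep the
baseline). *Bottom-up selection* partitions channels into consecutive blocks
of 100 (last block partial), keeps the best single block by CV, then
repeatedly adds the best remaining block while the minimum RMSECV improves
by more than tol (default 0: strict improvement). "Performance" is minimum
RMSECV over component counts — re-optimized for every candidate, since
candidate sets differ in dimensionality — with the R²_cv trace logged
alongside. Candidate ties break to the lower block index, so runs are
deterministic given the fold assignment.

## Diagnostics

*Explained variance*: cumulative percent variance from the singular values
of mean-centered blocks. The pipeline computes it for the reference
composition block, the fully processed spectra, and the replicate-averaged
*minimally processed* spectra (absorbance before SNV; trimmed Raman before
EMSC). The modality contrast — NIR concentrating variance in 1–2 bulk
components where Raman spreads it — lives in the minimally processed
blocks, because scatter and baseline structure are precisely what SNV and
EMSC remove.

*Covariance inflation*: mean absolute off-diagonal Pearson correlation
among predictions divided by the same statistic among references; 1.08
means predictions inter-correlate 8% more than the references do. Defined
on correlations to remove scale effects; a covariance-based variant is also
computed and logged. Identical tables give exactly 1.

*Coefficient profiles*: the coefficient vector at the chosen component
count, Euclidean-normalized for cross-model comparison, indexed by the
axis. On the default Raman conditions the EPA model weights the C=C stretch
(1665 cm⁻¹) positively and CH₂ scissoring (1440 cm⁻¹) negatively.

*Cage analysis*: per FA, four cross-validated quantities — R² of the model
trained on absolute contents; R² trained on proportional contents; R² of
absolute predictions ÷ fat against the proportional reference; R² of
proportional predictions × fat against the absolute reference — plus each
prediction vector's correlation with fat. The signature of the covariance
cage is high fat-correlation for absolute models (≈0.86 here) and ≈0 for
proportional models, with proportional×fat beating absolute÷fat.

## Pipeline and reproducibility

`RunConfig` (YAML) fixes modality, sample count, targets, folds, A_max,
selection method and one global seed; per-stage seeds derive from it by
hashing, so stages re-run in isolation reproduce the full run bit for bit.
Every run writes a manifest with the config, its hash, the stage seeds and
the artifact list. Problem sizes used by the acceptance script — n = 618
for the reference population, n = 300 for the calibration study, n = 10⁴
for correlation recovery — are desk-scale choices that keep a full run in
seconds while leaving Monte-Carlo error well inside the asserted
tolerances.

## What the synthetic conditions do and do not show

Passing tests establish that the *procedures* behave as specified on data
with known ground truth and the documented covariance structure: the
preprocessing identities are exact, PLS matches OLS at full rank and an
independent CV oracle bitwise, selection recovers planted structure, and
the cage pattern emerges whenever spectra are generated as fat ×
composition. They do not establish instrument-level realism: no
radiative-transfer or fluorescence physics, no detector nonlinearity, no
temperature drift beyond the water-shift proxy, NIR band shifts larger than
physical, and a correlation structure that is an educated reconstruction
beyond its cited anchor pairs. Absolute R² values on real spectra will
differ; the qualitative contrasts (Raman fewer components than NIR,
proportional-vs-absolute cage behaviour, localization of unsaturation
information at the C=C band) are the transferable content.
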