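# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## RF model and B-mode reconstruction

An RF frame is a 2-D array of signed echo amplitudes (rows = axial
fast-time samples at fs = 32 MHz by default, columns = A-lines), with
an assumed sound speed c = 1540 m/s; one sample spans c/(2fs) = 24 µm
of depth.  The envelope is the magnitude of the per-column analytic
signal (Hilbert transform).  B-mode reconstruction — used only by the
grayscale (GM) model variant — is: per-line moving-average smoothing
(odd length, default 5, chosen as the simplest unit-DC-gain
anti-spike smoother), envelope, 20·log₁₀ compression normalised to the
frame maximum, clipping to a configurable dynamic range (default
60 dB), an affine map to [0, 1], and nearest-neighbour scan conversion
for sector geometry (identity for linear arrays; geometry defaults to
linear since probe-specific sector parameters are inputs, not
constants).

## Feature-map estimators

All three estimators slide with unit axial stride and evaluate only
placements whose windows lie fully inside the ROI mask — no padding,
so no values are fabricated at lesion borders.  Per A-line, on a
rectangular ROI of H rows, DEA yields H−143 values per column, SSD
H−167, and NRD (H−36)(W−7) placements over W columns.

* **DEA.**  "Window interval" is read as the gap between the two gated
  windows (span 64+16+64 = 144), which makes the assignment point
  (64+16)/2 = 40 land mid-gap; the log is log₁₀ (dB convention).  The
  average spectral energy of a window, mean|DFT|², equals the sum of
  squared samples (Parseval), so the map is computed with sliding
  cumulative sums; tests verify equality with direct FFT evaluation.
  A placement with zero window energy is flagged invalid, not an
  error.  The estimator is exactly invariant to global amplitude
  scaling.
* **SSD.**  The subtraction acts on magnitude spectra (top − bottom);
  complex subtraction would feed complex values into a real skewness.
  Skewness uses population (1/n) moments.  A zero-variance difference
  (e.g. a 104-sample-periodic signal) invalidates the placement.
* **NRD.**  The block input is the envelope of the RF (the Rician law
  has positive support; raw RF is signed); |RF| is available as a
  config alternative.  The block slides laterally as well as axially;
  strides are configurable (the pipeline default uses axial stride 2
  purely as a resolution/speed trade — estimates at neighbouring
  placements share most of their samples).

## Rician maximum likelihood

The per-block MLE of (s, σ) solves the score equations

    s  = mean(x · I₁/I₀(x·s/σ²)),   σ² = (mean(x²) − s²)/2,

iterated as a fixed point with Steffensen (Aitken Δ²) acceleration —
plain iteration has contraction factor → 1 in the Rayleigh basin
(s → 0).  Bessel ratios use exponentially scaled I₀/I₁ for stability;
convergence is declared when the map residual falls below 10⁻⁹ of the
RMS amplitude, and the iteration is vectorised across all blocks of a
map.  Tests confirm agreement with `scipy.stats.rice.fit` and with
direct Nelder–Mead minimisation of the same likelihood to ~10⁻⁵.

A finite-sample caveat documented deliberately: on Rayleigh (s = 0)
data the exact MLE has a boundary pile-up, and at the 296 samples of
one 37×8 block the median ŝ/σ̂ is ≈ 0.5, not 0.  The Rayleigh limit is
therefore asserted on pooled fits (10⁴ lesion envelope samples per
phantom), where ŝ/σ̂ < 0.2 holds robustly, while per-block NRD maps on
pure speckle are only required to sit far below planted coherent
levels.

## Radiomics

Matrix features operate on an equal-width quantisation of the valid
values into Ng = 64 levels (configurable; the max maps to level Ng).
Equal-width binning is invariant under positive affine rescaling, so
all matrix-family features are too.  The per-family feature lists are
the classical, citable sets that reproduce the printed counts: 16
first-order features; the 13 Haralick GLCM features (distance 1,
directions 0°/45°/90°/135°, symmetric, direction-averaged; sum
variance centred on the sum average; entropies in bits); 11 GLRLM base
features reported as mean and range over the four directions (22); 13
GLSZM features with 8-connected zones; the 5 Amadasun–King NGTDM
features (3×3 neighbourhood, coarseness capped at 10⁶ on uniform
input).  Wavelet features repeat the 69 on the four subbands of a
single-level 2-D DWT (Haar by default) of the bounding-box crop, with
invalid cells nearest-neighbour filled before the transform and a
subband coefficient trusted only when its 2×2 support was fully valid.
Degenerate (constant) inputs produce defined sentinel values (0 where
a definition becomes 0/0) with a warning instead of aborting a cohort
extraction.

Counts are structural: 16+13+22+13+5 = 69 per band, ×5 bands = 345 per
map, 1035 for DEA+SSD+NRD.

## SRC ranking

Feature columns are z-scored (population sd; zero-variance columns
become dead atoms) and unit-normalised; labels are encoded ±1.  OMP
selects at most n_patients atoms (residual tolerance 10⁻⁶, ties to the
lowest index, rank-deficient refits stop the pursuit).  The ranking
lists the OMP support by descending |β| and then extends by descending
absolute target correlation, so a feature-count sweep can run past the
support.  Note a regime property: run to its n-atom cap, OMP fills the
support with residual-fitting atoms, so weakly informative off-support
features rank behind them; in sparse settings (small max_atoms) the
correlation extension places planted informative features immediately
after the support.

## Classification and evaluation

SVM with RBF kernel at the fixed hyperparameters C = 0.8, γ = 1
(libsvm via scikit-learn; default solver tolerance 10⁻³, configurable).
LOOCV re-standardises features inside each training fold, but the SRC
ranking is computed once on the full table.  This single-ranking
protocol — the one the package evaluates — is a deliberate, documented
source of optimism: on null cohorts (no class difference) the per-cohort LOOCV
AUC averages ≈ 0.7, not 0.5, because the ranking has seen the held-out
patient.  The null-calibration check therefore pools scores across 20
independent cohorts, where cross-cohort pairs dilute the
selection-induced association and the pooled AUC sits near 0.5.

The sweep evaluates k = 1…K (default K = 15) and picks the best k by
AUC, ties broken by higher ACC then smaller k (the tie-break is a
package choice).  AUC is the Mann–Whitney statistic (ties count ½);
its 95% CI is a stratified bootstrap (2000 resamples, seeded).  The
PRC break-even point interpolates linearly between the two adjacent
threshold points where precision−recall changes sign; with a single
threshold point (constant scores) it degenerates to the prevalence.
Class comparison uses one-way ANOVA (with two groups this equals the
pooled t-test, F = t²; Tukey's HSD is reported alongside and reduces
to the same comparison).  The decision threshold is 0 (SVM
convention).

## Synthetic phantoms

Each A-line is sparse Gaussian scatterers (density 0.15 per sample)
convolved with a Gaussian-envelope pulse at 3.5 MHz (fractional
bandwidth 0.6 — inside a 1–5 MHz curved-probe band), normalised so the
diffuse RF has unit variance; depth attenuation multiplies the summed
signal by 10^(−α·f₀·z/20) with α in dB/(m·MHz) and z the one-way
depth; a coherent carrier of amplitude a (units of diffuse RMS) is
added inside the lesion before the decay.  The default frame is
320×24 samples with a centred rectangular 200×14 lesion — the minimum
comfortable geometry for all three window schemes.  There is no
lateral point-spread function and no spectral downshift with depth:
columns are independent, and attenuation acts at the centre frequency
only, which is exactly what the DEA estimator measures.  Consequently
the phantoms validate estimator correctness and end-to-end behaviour,
not clinical realism: passing tests show the pipeline recovers what
was planted, not that the maps separate real tumour classes.

Default two-class cohort (the study condition for the end-to-end
experiments): 20 patients per class, attenuation 50 vs 60 dB/(m·MHz)
(0.5 vs 0.6 dB/(cm·MHz), a subtle, realistic tissue difference) and
coherent amplitude 0 vs 0.8.  These were fixed once by a design-phase
power analysis: the attenuation delta is deliberately near the DEA
map's noise floor at this ROI size (single-map AUC ≈ 0.9), while the
coherent delta is decisive for the Rician map, so model performance
improves with map count without every variant saturating at 100%.

Recovery experiments use stronger, well-identified plants: attenuation
70 dB/(m·MHz) on tall 2000×48 phantoms (the DEA map median over 10
seeds falls within a few percent of the estimator's value on the
noiseless decay profile — note the estimator's window-separation
scaling means that value is (win+gap)/win times α·f₀), and coherent
amplitude 2.0 (the NRD map median recovers it within a few percent;
weaker coherent components sink into the per-block boundary pile-up
described above).

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen as the package's
default experimental design: 40-patient cohorts, 320×24 frames, 20
replicates for trend/null checks, 10 seeds for recovery medians.
Every random quantity (phantoms, bootstrap, permutations) flows from
explicit integer seeds; reruns with the same config are bit-identical,
and every pipeline artifact records the SHA-256 hash of its resolved
config.

## Known limitations

* The per-family feature identities reproduce the printed counts, but
  other classical choices exist (e.g. log base in entropies, biased vs
  unbiased moments); these change feature values, not counts or
  invariances.
* The single global SRC ranking leaks label information into LOOCV, as
  discussed; nested selection would remove the optimism at the cost of
  evaluating a different protocol.
* The phantom's lack of lateral PSF makes per-block envelope samples
  more independent laterally than in real speckle; real NRD maps would
  be noisier per block.
* Scan conversion is nearest-neighbour and the sector path is lightly
  exercised; linear geometry is the default throughout.
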