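# Methods

This note documents what `lwcspec` computes, the assumptions behind the
synthetic data it is exercised on, and the numerical choices that were
genuinely open.

## Preprocessing

Input reflectance spectra are resampled (linear interpolation) to an
integer 1 nm grid, after which four windows are removed: the noisy
instrument edges 350–399 nm and 2401–2500 nm, and the atmospheric
water-vapour bands 1355–1444 nm and 1777–1949 nm (all inclusive;
wavelengths are band centres). On a full 350–2500 nm grid this retains
1738 bands in three contiguous segments (400–1354, 1445–1776,
1950–2400 nm). Trimming is idempotent; every subsequent per-band operation
acts segment by segment and never bridges a gap.

Smoothing is morphological: the mean of the grey-scale opening and closing
with a flat structuring element (default width 7 bands, odd, configurable),
edges handled by reflection. This smoother is exactly bounded by the
rolling min/max of the input over the structuring window, halves isolated
single-band spikes, and leaves monotone stretches untouched except within
(width−1)/2 bands of a segment edge. The pipeline order is trim, then
smooth, then differentiate.

Ten-scan averaging during acquisition is assumed already done; a
`mean_by_group` helper is provided for raw scan tables.

## Grünwald–Letnikov fractional derivative

For order v ∈ [0, 2] and step h = 1 band, the derivative of a sampled
signal f is the weighted backward sum Σₘ cₘ f(k−m) with
cₘ = (−1)^m Γ(v+1)/(m! Γ(v−m+1)). The production path generates the
weights by the numerically stable multiplicative recurrence
c₀ = 1, cₘ = cₘ₋₁ (m−1−v)/m; the Gamma closed form serves only as an
independent cross-check in the tests (agreement to 1e−10 for m ≤ 50).
v = 0 returns a verbatim copy; v = 1 and v = 2 reduce exactly to first and
second backward differences.

At the start of each segment the sum is truncated to the available history
(finite lower terminal, no padding), so the first few bands of each
segment are order-dependent warm-up values; band searches can optionally
mask them, but by default do not. The step is fixed at 1 band and is not
configurable in physical units. Riemann–Liouville and Caputo definitions
are out of scope.

The standard scan differentiates at v = 0.0, 0.2, …, 2.0 and summarizes,
per order, the maximum |r| with the trait and the number of bands passing
the significance screen.

## Spectral indices

Twelve fixed moisture indices (WI = R900/R970, WBI = R970/R900,
FWBI = R900/min(R930–980), SRWI-1 = R858/R1240, SRWI-2 = R1070/R1340,
MSI = R1600/R820, MSI-1 = R870/R1350, and the normalized differences
NDI-1(850, 1650), NDVI(858, 648), NDWI(858, 2130), NDWI-Hyp(1070, 1200),
NDMI(1649, 1722)) are always computed from the raw (order-0, trimmed,
smoothed) reflectance — their definitions assume reflectance, not
derivatives.

The optimization forms are the two-band RVI, NDVI, DVI and the three-band
3BI-1 … 3BI-7 (ratios, normalized ratios and the double difference
3BI-7 = R₁ − 2R₂ + R₃). Derivative spectra may be negative; the forms are
evaluated as written. Denominators within ε = 1e−10 of zero flag that
sample invalid rather than dropping it; downstream correlations use
pairwise deletion, and combinations with fewer than 10 usable samples are
excluded — this avoids the spurious correlations zero-filling would create.

## Band optimization

The screen and searches use the product-moment correlation with the trait.
The two-tailed critical value at level α is r_crit = t/√(t² + n − 2) with
t the 1 − α/2 quantile of Student's t on n − 2 df; it is always computed
from the actual n (at α = 0.01: 0.207 for n = 154, 0.200 for n = 165).
No multiple-testing correction is applied by default, matching standard
practice in this literature; the screen is a ranking device, not an
inferential claim.

Two-band searches evaluate every ordered pair on a strided grid (full map
retained); three-band searches evaluate every ordered distinct triple and
only stream the running best, because a 1 nm triple search over ~900 bands
(≈7×10⁸ triples per form) is not desk-scale. The default three-band search
uses a 5 nm coarse grid on 400–1300 nm followed by a 1 nm local re-search
within ±stride of the coarse optimum; for maps as smooth as these the
coarse+refine optimum coincides with the exhaustive one.

Ties: the optimum is the combination maximizing |r|, ties broken by the
lexicographically smallest wavelength tuple. Ties are real, not just
numerical: 3BI-4 and 3BI-7 are affine in themselves under swapping their
outer bands, so the swapped tuple attains exactly the same |r|.
|r| differences below 1e−12 are therefore treated as ties.

## Calibration and evaluation

Samples are split 70/30 (⌈0.7 n⌉ calibration) by a seeded permutation.
**Every selection step — the sensitive-band screen, all band searches, and
hyperparameter tuning — sees only the calibration subset**; a test
corrupts the validation spectra and verifies the selections are unchanged.

The nine feature sets mirror the standard comparison: sensitive raw bands
(α = 0.01 screen inside 769–924 nm), sensitive derivative bands (screen
inside 711–875 nm at order 0.8), the 12 moisture indices, optimized
two-band indices from raw and from derivative spectra, the seven optimized
three-band indices at order 0.8, and FWBI-combined variants. If no band
passes the screen inside a window, the five largest-|r| bands in the
window are used instead. Derivative-based index sets use one configured
order (default 0.8) rather than searching all eleven, for runtime.

Learners: KNN (k ∈ {3, 5, 7, 9} by 5-fold CV on the calibration set,
Euclidean distance in standardized feature space, prediction = mean of the
k neighbours' targets), SVR (RBF kernel, C ∈ {1, 10, 100},
ε ∈ {0.01, 0.1} by the same CV), and a single-hidden-layer ANN (16 units,
≤ 2000 epochs, seeded initialization). Features are median-imputed and
standardized on the calibration set for all three; the ANN's *targets* are
also standardized (fitted on calibration data), without which the default
learning rate cannot reach the ~78 % LWC scale within the epoch budget.

Metrics: R² is the squared Pearson correlation between measured and
predicted values (0 when predictions are constant); RMSE = √(Σ(y−ŷ)²/n) in
% LWC; SEP is the bias-corrected standard deviation of the validation
residuals (the chemometrics convention — SEP is often left undefined in
applications papers); RPD = SD(y)/SEP, classed as > 2.0 good, 1.4–2.0
general, < 1.4 poor. A perfect fit has SEP = 0 and is reported as
RPD = ∞, class "good".

## Synthetic data generator

The generator is phenomenological, not radiative transfer. A parametric
vegetation baseline (visible floor 0.04, green peak at 550 nm, sigmoidal
red edge at 715 nm rising to a 0.46 NIR plateau, declining SWIR) is
multiplied by Gaussian water-absorption factors (1 − depth·g(λ)) at 970,
1200, 1450, 1940 nm whose depths increase linearly with LWC (base depths
0.06/0.08/0.32/0.42; slopes 0.07/0.08/0.12/0.14 across the LWC range), by
a global amplitude that declines 6 % across the LWC range, and by a
per-sample structural amplitude factor (sd 0.15, LWC-independent) standing
in for canopy geometry / leaf-area variability. Additive band-independent
Gaussian noise (sd 0.005 reflectance units) is added and the result
clipped to (0, 1). LWC values are drawn from a truncated normal (mean
78.24 % — the midpoint of the reported range, since the field mean is not
published — CV 4.58 %, bounds 64.94/91.54 %).

The structural factor is what gives the data the regime the method
targets: any single band confounds the LWC signal with amplitude
variability (|r| ≈ 0.15–0.3), while ratio-type indices cancel the common
factor and reach |r| ≈ 0.7–0.95. What the generator does **not** emulate:
real absorption line shapes and their temperature dependence, spectrally
correlated instrument noise, directional (BRDF) effects, or any
leaf-stacking physics. Consequently the benchmark shows band *combinations*
beating single bands, but it does not reproduce the empirical finding that
derivative-based indices beat raw-reflectance indices — differentiation
amplifies the generator's band-independent noise, so the derivative index
sets land mid-pack here. Passing tests demonstrate correctness and
leakage-safety of the machinery, not field-data performance.

An optional smooth-noise component (per-sample Gaussian-filtered noise,
default off) models spectrally correlated baseline wiggles. The
planted-combination fixtures switch it on (sd 0.012, 10 nm correlation
length) and switch the structural factor off: a planted linear index is
otherwise nearly collinear with the global amplitude factor that *every*
band combination shares (unidentifiable, massive ties), whereas smooth
local variability makes the planted bands locally identifiable while
keeping neighbouring bands correlated enough for a strided search to find
them. In planted mode the trait is re-generated as
mean + sd·(√R²·z + √(1−R²)·ε) with z the standardized index values, so the
realized calibration R² fluctuates around the target (≈ ±0.05 at n = 154).

## Problem sizes and determinism

Default analyses run at the study scale (n = 154, 2151 raw bands, 1738
after trimming). The packaged end-to-end runs use a 2 nm stride for the
two-band searches and a 10 nm coarse stride for the three-band searches —
the package's chosen desk-scale operating point; both are configurable
down to 1 nm/5 nm. Every random draw (LWC sampling, noise, splits, learner
initialization) derives from explicit integer seeds, and generated
datasets are bit-for-bit reproducible from (config, seed). Dataset CSV
writers emit 17 significant digits and the readers parse with
correct rounding, so write/read round-trips are exact.

## Known limitations

- The generator's five latent degrees of freedom (LWC, amplitude, smooth
  noise, band noise, absorption depths) are far fewer than real canopy
  spectra; absolute model accuracies on it should not be quoted as
  expected field performance.
- The three-band coarse+refine search can in principle miss a razor-thin
  global optimum between coarse nodes; on smooth correlation landscapes
  this was never observed, and stride 1 recovers the exhaustive search.
- The 0.01-level screen is uncorrected for multiplicity by design (a
  Bonferroni-style correction would be a one-line change in `critical_r`
  usage but would no longer match standard practice).
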