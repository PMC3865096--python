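# Methods

## Signal model and ADC fitting

Diffusion-weighted signal is modeled per voxel as S(b) = S₀·exp(−ADC·b) with
b in s/mm² and ADC in mm²/s. The fit minimizes the unweighted signal-domain
residual sum of squares — a deliberate, literal reading of "nonlinear least
squares" rather than a log-domain or variance-weighted fit. Parameters are
(ln S₀, ADC); a log-linear regression of ln S on b supplies starting values
(exact on noiseless data, since ln S is then affine in b), refined by a
Levenberg-damped Gauss–Newton iteration vectorized over voxels (closed-form
2×2 normal equations, per-voxel damping, step acceptance on cost decrease,
stop when the scaled step falls below 1e-12 or after 100 iterations).

ADC is constrained to [0, 10⁻²] mm²/s. Free water at body temperature is
≈ 3·10⁻³ mm²/s, so the upper bound sits generously above physiology. A voxel
that converges pinned at a bound with the gradient still pulling outside the
box (e.g. a noise-dominated voxel whose unconstrained optimum is a negative
decay rate) is flagged invalid; a flat decay converging *at* ADC = 0 with
zero gradient is valid. Voxels with any non-positive or non-finite sample
are excluded up front rather than clamped — clamping would bias the
log-domain initialization — and are reported as NaN with a count in the log.
No Rician noise-floor correction is applied in the fit (see limitations).

Accuracy: on noiseless mono-exponential input the fit recovers parameters to
machine precision (measured max relative error ~4·10⁻¹⁵ over 10⁴ random
draws); for two b-values it reproduces the closed-form log-ratio estimate
ln(S(b₁)/S(b₂))/(b₂−b₁) exactly, which the tests use as an independent
oracle alongside `scipy.optimize.curve_fit` on single voxels.

## Noise model

Magnitude images carry Rician noise: S_noisy = |(S + n₁) + i·n₂| with
n₁, n₂ ~ N(0, σ²) and σ = S₀_mean / SNR (a Gaussian option exists for
analytic tests; SNR = ∞ disables noise). At channel SNR 50 the mean noisy
4-point signal vector of a tumor voxel (ADC ≈ 10⁻³) deviates from the
noiseless decay by ≈ 0.13% in relative L2 norm. Per b-value the high-SNR
Rician bias is ≈ 1/(2·SNR_local²): negligible at b ≤ 1000, and ≈ 1.1% at
b = 2000 where the decay e⁻² pushes the local SNR down to ~6.8. The bias is
therefore quoted on the signal *vector*, with the most-attenuated point's
analytic value checked separately in the tests.

## Phantom and cohort generator

One phantom is an ellipsoidal tumor centered on a regular grid (defaults:
128×128 in-plane at 136 µm, 1.5 mm slices; the radius default 4.9 mm gives
the ~500 mm³ enrollment volume typical of subcutaneous xenograft studies).
The intra-tumor ADC field is a spatially correlated Gaussian random field
(white noise smoothed with a Gaussian kernel of configurable correlation
length, default 0.5 mm; standardized, scaled to `adc_sd`, shifted to
`adc_mean`, truncated at 0). S₀ varies smoothly by ±5%. Background voxels
get muscle-like constants (1.7·10⁻³ mm²/s, half S₀) and only matter when
fitting outside the VOI. ADC defaults (mean 1.1·10⁻³, sd 1.5·10⁻⁴ mm²/s)
are literature-typical for untreated solid tumors and fully configurable —
tumor ADC magnitude and noise level are free parameters of the study design,
not measured constants.

**Treatment effects** multiply the VOI ADC field by `adc_factor`. Negative
skew injection leaves the lowest `lag_fraction` (default 25%) of voxels
behind with a relative multiplier 1 + skew (skew < 0), mirroring the
biological picture of responding (apoptotic, high-ADC) regions pulling the
bulk of the distribution up while dense viable regions lag; a final uniform
rescale makes the post/pre mean ratio equal `adc_factor` exactly. Shifts
driving more than 1% of voxels above 5·10⁻³ mm²/s log a warning but retain
the values. The default per-arm profiles (Gem elevated days 2–9, Combo
days 2–14, control/MK1775 flat; growth suppressed in Gem and Combo, ~0.11
per day otherwise) are *qualitative mimics* of a cytotoxic response pattern,
clearly surfaced in the config, not measured values.

**Cohort structure.** Four arms × 4 mice × 2 flank tumors, imaging at day 0,
24 h after each treatment (days 1, 3, 8, 10 → imaging days 2, 4, 9, 11) and
day 14. Every (seed, group, mouse, tumor, day) tuple seeds an independent
`numpy` SeedSequence stream; the tumor-level stream fixes between-tumor
biology (baseline mean ADC jitter, CV 5%; radius jitter, CV 8%) so each
tumor is its own longitudinal control. Identical seeds reproduce volumes and
manifests bit for bit. Tumor volume is exactly voxel count × voxel volume;
radii grow as exp(growth·day/3) so volumes follow exp(growth·day).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: k-space acquisition and reconstruction, motion,
eddy currents and distortion; partial-volume and rim effects at the tumor
boundary; perfusion (IVIM) and non-Gaussian diffusion; segmentation error
(masks are exact); day-to-day tumor identity of the spatial texture (the
correlated field is redrawn per imaging day, so only the distribution, not
the voxel-level pattern, persists); and the litter/flank clustering of real
mice (tumors are generated independently).

## Fixed analysis constants

All histogram-derived statistics share one analysis range, [3·10⁻⁵, 5·10⁻³]
mm²/s. The pixel-fraction curve uses 512 uniformly spaced, endpoint-
inclusive thresholds on this range ("512 increments" is read as 512 grid
points, not 513 edges) and counts voxels strictly above each threshold; ties
are measure-zero for continuous fits. Voxels outside the range stay in the
sample — they saturate the curve at 1 or 0 rather than being dropped. The
difference AUC integrates post − pre fractions by the trapezoid rule over
the *physical* threshold axis (units mm²/s, full-shift maximum 4.97·10⁻³),
which makes the statistic independent of grid resolution; integration over
bin index would not be. Skewness is adjusted Fisher–Pearson sample skewness
and kurtosis is sample excess kurtosis (both 0 by convention for a
zero-variance sample; NaN and flagged below 3 resp. 4 voxels).

## Entropy

Global entropy uses 4 equal-width bins over the fixed analysis range, log
base 2, so H ∈ [0, 2] bits with 0 iff one bin is occupied and 2 iff
occupancy is exactly uniform. Fixed bin edges (rather than per-VOI min–max
binning) keep coefficients comparable across timepoints and animals. The
local filter computes the same 4-bin entropy per pixel over a 9×9 in-plane
window intersected with the VOI, center pixel included, reusing the global
edges; windows are 2D because maps are read slice-wise. It is implemented
with exact integer box-sum bin counts per slice and agrees with a per-pixel
brute-force loop bit for bit. Relative entropy change is
((H_post − H_pre)/H_pre) × 100; a zero pre-treatment coefficient is rejected
with guidance to report the absolute change.

## Group statistics

For every metric × imaging day: one-way ANOVA across arms, then
Tukey(–Kramer, for unequal n) HSD pairwise comparisons at α = 0.05, emitted
in the fixed pair order C–M, C–G, C–X, M–G, M–X, G–X. Each tumor is one
independent observation (n = 8 per arm); the two-tumors-per-mouse clustering
is deliberately ignored — a known limitation shared with common practice in
flank-tumor studies, and the reason the p-values should be read as
descriptive. An unadjusted companion p-value is reported per pair in the
Fisher-LSD form (same pooled all-groups error variance the Tukey statistic
studentizes), which guarantees adjusted ≥ unadjusted; no correction is
applied across metrics or days. Degenerate cells are resolved explicitly:
all observations identical → F = 0, p = 1 (no evidence); zero within-group
variance with distinct means → p = 0; cells with any arm below 2
observations are skipped and logged. Null calibration: with four identical
arms of n = 8 the ANOVA rejects at 5.2% over 1000 replicates.

## Problem sizes in the verification experiments

The Monte-Carlo experiments (noise recovery, day-2 effect recovery) run on
reduced 32×32×8 or 48×48×8 grids with 1.5–1.9 mm tumors (~500–1000 VOI
voxels) — the package's own choice to keep 100-seed experiments fast on one
CPU; voxel geometry, b-values, SNR and the 4×8 statistical design are the
full study conditions. The `analysis/` cohort uses 64×64×10 grids with
2.2 mm tumors (~1600 voxels) for the same reason.

## Known limitations

- **Per-voxel ADC precision at SNR 25.** With four b-values and S₀ free,
  the Cramér–Rao bound puts the per-voxel relative ADC standard deviation at
  ≈ 9% for ADC ≈ 10⁻³ mm²/s and σ = S₀/25; the measured median *magnitude*
  of the relative error is ≈ 6.7%, while the median signed error (recovery
  bias, dominated by the uncorrected Rician floor at b = 2000) is ≈ −1%.
  Per-voxel maps at this SNR are therefore noisy by construction; VOI-level
  means, which average over hundreds of voxels, are tight. Both medians are
  reported by `scripts/acceptance.py`.
- No Rician-floor correction or weighting in the fit; at lower SNR or higher
  ADC the downward bias grows.
- Mono-exponential only: no IVIM, kurtosis or stretched-exponential models;
  no diffusion directionality.
- Statistics ignore repeated measures across days and mouse-level
  clustering; no mixed-effects modeling.
- The entropy bin edges, log base and window convention are explicit package
  defaults for an analysis whose original conventions are not uniquely
  determined; results are comparable within this package, not across
  implementations with other binning rules.
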