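# adctexture

Quantitative diffusion-MRI analysis of tumor therapy response: voxelwise
apparent-diffusion-coefficient (ADC) mapping, ADC-histogram descriptors,
pixel-fraction/AUC shift statistics, Shannon-entropy texture, and four-arm
cohort statistics — together with a fully seeded synthetic DWI phantom
cohort generator so the entire pipeline can be exercised, tested and
benchmarked without any scanner data.

It is written for preclinical imaging scientists who monitor treatment
response in subcutaneous tumor models (e.g. osteosarcoma xenografts treated
with gemcitabine and/or a Wee-1 checkpoint inhibitor) with multi-b-value
diffusion-weighted MRI, and for anyone who wants a tested reference
implementation of these ADC descriptors.

## The quantities computed

**ADC mapping.** Each voxel's signal decay over the b-value schedule
(default b = 50, 500, 1000, 2000 s/mm²) is fitted with the mono-exponential
model

```
S(b) = S(0) · exp(−ADC · b)
```

by unweighted nonlinear least squares in the signal domain (log-linear
initialization, vectorized Levenberg-damped Gauss–Newton, ADC constrained to
[0, 10⁻²] mm²/s). Voxels with non-positive signal or out-of-bound
convergence are flagged invalid, never raised on.

**Histogram descriptors.** Over the tumor VOI: mean ADC, adjusted
Fisher–Pearson sample skewness, sample excess kurtosis; longitudinal change
as ΔADC [%] = (ADC_t / ADC₀) × 100 and ΔV [%] = (V_t / V₀) × 100 (no change
reports 100).

**Pixel-fraction curve and AUC.** For 512 uniformly spaced thresholds on
the fixed analysis range [3·10⁻⁵, 5·10⁻³] mm²/s, the fraction of VOI voxels
with ADC above each threshold; subtracting the pre-treatment curve from the
post-treatment curve and integrating over the threshold axis gives a single
shift statistic (positive when ADC moves up).

**Entropy texture.** VOI ADC values are placed in 4 equal-width bins over
the same fixed range; the global coefficient is H = −Σ p_k log₂ p_k ∈ [0, 2]
bits, and a local 9×9 in-plane entropy filter (restricted to the VOI) maps
intra-tumor heterogeneity.

**Group statistics.** Per metric and imaging day: one-way ANOVA across the
four arms followed by Tukey(–Kramer) pairwise comparisons at α = 0.05, each
tumor treated as one observation.

**Synthetic cohort.** Seeded phantoms with spatially correlated intra-tumor
ADC fields, Rician magnitude noise at a configurable SNR, four-arm design
(4 mice × 2 flank tumors per arm; imaging at baseline, 24 h after each of
four treatments, and day 14), multiplicative treatment-induced ADC shifts
with negative-skew injection, and per-arm exponential volume growth.

## Worked example

```python
import numpy as np
from adctexture import (PhantomSpec, TumorVOI, TreatmentEffect, difference_auc,
                        fit_adc_map, generate_phantom, global_entropy,
                        histogram_summary, pixel_fraction_curve,
                        percent_change_adc, simulate_treatment_effect)
from adctexture.phantom import synthesize_signal

spec = PhantomSpec(grid_shape=(64, 64, 8), tumor_radius=2.0, snr=25.0, seed=7)
series, truth = generate_phantom(spec)
voi = TumorVOI(truth.voi_mask, spec.voxel_size)

pre_map = fit_adc_map(series, voi)
pre = histogram_summary(pre_map, voi)

treated = simulate_treatment_effect(truth, TreatmentEffect(adc_factor=1.3, skew=-0.3))
post_series = synthesize_signal(treated, spec.bvalues, spec.sigma,
                                np.random.default_rng(8))
post_map = fit_adc_map(post_series, voi)
post = histogram_summary(post_map, voi)

auc = difference_auc(pixel_fraction_curve(pre_map, voi),
                     pixel_fraction_curve(post_map, voi))
```

prints (via the obvious f-strings):

```
baseline: 1168 voxels, mean ADC 1.106e-03 mm^2/s, skewness +0.50
post-rx:  mean ADC 1.429e-03 mm^2/s, skewness -0.28, relative ADC 129.2%
difference AUC +3.226e-04 mm^2/s, entropy 0.56 -> 0.84 bits
```

i.e. a 1.3× treatment effect with a lagging low-ADC subpopulation elevates
the mean ADC by ~30%, flips the VOI skewness negative, produces a positive
pixel-fraction AUC, and raises the entropy of the ADC histogram — the
signature of an early cytotoxic response.

## The cohort analysis

The numbered drivers under `analysis/` run the full study on a simulated
cohort (configuration in `analysis/config.yaml`):

```
python analysis/01_simulate.py     # 32 tumors x 6 imaging days -> NIfTI volumes
python analysis/02_fit_adc.py     # voxelwise ADC maps
python analysis/03_metrics.py     # per-tumor descriptors -> results/metrics.csv
python analysis/04_group_stats.py # ANOVA + Tukey grid -> results/comparisons.csv
python analysis/05_figures.py     # trajectories + entropy maps -> results/figures/
```

Large intermediates (volumes, maps) go under `scratch/`; tables and figures
under `results/`. The same stages are available as a CLI
(`adctexture simulate|fit-adc|metrics|entropy|stats|run-all`).

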