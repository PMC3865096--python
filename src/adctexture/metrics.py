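"""Per-tumor volumetric and ADC-histogram descriptors.

Volume is voxel count times voxel volume.  Percent changes follow the ratio
convention ``(x_t / x_0) * 100`` (no change reports 100).  The pixel-fraction
curve sweeps 512 uniformly spaced ADC thresholds over the fixed analysis range
[3e-5, 5e-3] mm^2/s and records, at each threshold, the fraction of valid VOI
voxels strictly above it; subtracting a pre-treatment curve from a
post-treatment curve and integrating over the threshold axis (trapezoid, units
mm^2/s) yields the shift statistic, positive when ADC values move up.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import ADCMap, TumorVOI

logger = logging.getLogger(__name__)

#: Fixed ADC analysis range, mm^2/s, and threshold count.
ADC_RANGE = (3.0e-5, 5.0e-3)
N_THRESHOLDS = 512


@dataclass
class HistogramSummary:
    """Moments of the VOI ADC distribution.

    Skewness is adjusted Fisher-Pearson sample skewness; kurtosis is sample
    excess (Fisher) kurtosis.  Both are 0 by convention for a zero-variance
    sample and NaN (flagged) when too few voxels define them.
    """

    n_voxels: int
    mean_adc: float
    skewness: float
    kurtosis: float
    n_excluded: int = 0
    moments_defined: bool = True


@dataclass
class PixelFractionCurve:
    thresholds: np.ndarray
    fractions: np.ndarray
    tumor_id: str = ""
    day: int | None = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.thresholds.shape != self.fractions.shape:
            raise ValueError("thresholds and fractions must have equal length")


@dataclass
class DifferenceAUC:
    value: float
    pre_day: int | None = None
    post_day: int | None = None


def threshold_grid(
    lo: float = ADC_RANGE[0], hi: float = ADC_RANGE[1], n: int = N_THRESHOLDS
) -> np.ndarray:
    """The uniform, endpoint-inclusive threshold grid."""
    return np.linspace(lo, hi, n)


def tumor_volume(voi: TumorVOI) -> float:
    """Tumor volume in mm^3 (0 for an empty mask)."""
    return voi.n_voxels * voi.voxel_volume_mm3


def percent_change_volume(v_t: float, v_0: float) -> float:
    """``(V_t / V_0) * 100``; no change reports 100."""
    if not v_0 > 0:
        raise ValueError(f"baseline volume must be > 0; got {v_0}")
    return v_t / v_0 * 100.0


def percent_change_adc(mean_t: float, mean_0: float, delta: bool = False) -> float:
    """``(ADC_t / ADC_0) * 100``; ``delta=True`` gives ``(ratio - 1) * 100``."""
    if not mean_0 > 0:
        raise ValueError(f"baseline mean ADC must be > 0; got {mean_0}")
    ratio = mean_t / mean_0
    return (ratio - 1.0) * 100.0 if delta else ratio * 100.0


def _valid_values(adc_map: ADCMap, voi: TumorVOI) -> tuple[np.ndarray, int]:
    if adc_map.adc.shape != voi.mask.shape:
        raise ValueError(
            f"VOI shape {voi.mask.shape} does not match map shape {adc_map.adc.shape}"
        )
    sel = voi.mask & adc_map.valid_mask & np.isfinite(adc_map.adc)
    n_excluded = int(voi.mask.sum() - sel.sum())
    return adc_map.adc[sel], n_excluded


def histogram_summary(adc_map: ADCMap, voi: TumorVOI) -> HistogramSummary:
    """Mean, skewness and excess kurtosis of the valid VOI ADC values."""
    values, n_excluded = _valid_values(adc_map, voi)
    n = values.size
    if n == 0:
        raise ValueError("no valid voxels in VOI")
    if n_excluded:
        logger.info("histogram_summary: %d VOI voxels excluded (invalid fit)", n_excluded)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        skew = 0.0 if n >= 3 else np.nan
        kurt = 0.0 if n >= 4 else np.nan
    else:
        skew = float(sps.skew(values, bias=False)) if n >= 3 else np.nan
        kurt = float(sps.kurtosis(values, fisher=True, bias=False)) if n >= 4 else np.nan
    defined = n >= 4
    if not defined:
        logger.warning("histogram_summary: only %d voxels; higher moments flagged", n)
    return HistogramSummary(n, mean, skew, kurt, n_excluded, defined)


def pixel_fraction_curve(
    adc_map: ADCMap,
    voi: TumorVOI,
    lo: float = ADC_RANGE[0],
    hi: float = ADC_RANGE[1],
    n: int = N_THRESHOLDS,
) -> PixelFractionCurve:
    """Fraction of valid VOI voxels with ADC strictly above each threshold.

    Voxels outside the analysis range still count: values above the top
    threshold contribute 1 everywhere, values below the bottom contribute 0 —
    the range clips the curve, not the sample.
    """
    values, _ = _valid_values(adc_map, voi)
    if values.size == 0:
        raise ValueError("no valid voxels in VOI")
    thr = threshold_grid(lo, hi, n)
    v = np.sort(values)
    # count of values > t  ==  n - (index of first element > t)
    above = values.size - np.searchsorted(v, thr, side="right")
    frac = above / values.size
    return PixelFractionCurve(thr, frac, tumor_id=voi.tumor_id, day=voi.day)


def difference_auc(pre: PixelFractionCurve, post: PixelFractionCurve) -> DifferenceAUC:
    """Trapezoidal integral of (post - pre) fraction over the threshold axis."""
    if pre.thresholds.shape != post.thresholds.shape or not np.array_equal(
        pre.thresholds, post.thresholds
    ):
        raise ValueError("pre and post curves use different threshold grids")
    diff = post.fractions - pre.fractions
    value = float(np.trapezoid(diff, post.thresholds))
    return DifferenceAUC(value, pre_day=pre.day, post_day=post.day)
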