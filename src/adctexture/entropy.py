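"""Shannon-entropy texture of ADC maps.

A VOI's ADC values are assigned to 4 equal-width bins over the fixed analysis
range [3e-5, 5e-3] mm^2/s (values outside the range fall into the end bins so
the binning is total); the global coefficient is the base-2 Shannon entropy of
the bin occupancy, bounded by log2(4) = 2 bits.  The local filter computes the
same 4-bin entropy per pixel from the in-plane 9x9 neighborhood restricted to
the VOI (center included), using the same fixed bin edges so maps are
comparable across timepoints and animals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .containers import ADCMap, TumorVOI
from .metrics import ADC_RANGE

N_BINS = 4


@dataclass
class EntropyResult:
    global_entropy: float          # bits
    bin_edges: np.ndarray          # 5 values, mm^2/s
    bin_counts: np.ndarray         # 4 counts, sum to n_voxels
    n_voxels: int


@dataclass
class LocalEntropyMap:
    map: np.ndarray                # bits; NaN outside the VOI
    window: int = 9


def bin_edges(
    lo: float = ADC_RANGE[0], hi: float = ADC_RANGE[1], n_bins: int = N_BINS
) -> np.ndarray:
    return np.linspace(lo, hi, n_bins + 1)


def _bin_index(values: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Total bin assignment: out-of-range values are clipped into end bins."""
    width = (hi - lo) / n_bins
    idx = np.floor((np.asarray(values, dtype=float) - lo) / width).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def shannon_entropy_bits(counts: np.ndarray) -> float:
    """``-sum p log2 p`` over occupied bins (0 log 0 == 0)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty histogram")
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _voi_values(adc_map: ADCMap, voi: TumorVOI) -> np.ndarray:
    if adc_map.adc.shape != voi.mask.shape:
        raise ValueError(
            f"VOI shape {voi.mask.shape} does not match map shape {adc_map.adc.shape}"
        )
    sel = voi.mask & adc_map.valid_mask & np.isfinite(adc_map.adc)
    return adc_map.adc[sel]


def global_entropy(
    adc_map: ADCMap,
    voi: TumorVOI,
    lo: float = ADC_RANGE[0],
    hi: float = ADC_RANGE[1],
    n_bins: int = N_BINS,
) -> EntropyResult:
    """One entropy coefficient for the whole VOI."""
    values = _voi_values(adc_map, voi)
    if values.size == 0:
        raise ValueError("no valid voxels in VOI")
    idx = _bin_index(values, lo, hi, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return EntropyResult(
        global_entropy=shannon_entropy_bits(counts),
        bin_edges=bin_edges(lo, hi, n_bins),
        bin_counts=counts,
        n_voxels=int(values.size),
    )


def local_entropy_map(
    adc_map: ADCMap,
    voi: TumorVOI,
    window: int = 9,
    lo: float = ADC_RANGE[0],
    hi: float = ADC_RANGE[1],
    n_bins: int = N_BINS,
) -> LocalEntropyMap:
    """Per-pixel 4-bin entropy over the in-plane ``window x window``
    neighborhood intersected with the VOI.

    Implemented slice by slice with exact integer box-sum counts per bin, so
    it agrees with a brute-force per-pixel loop bit for bit.  Pixels whose
    in-VOI fit is invalid are excluded from every neighborhood; the output is
    NaN outside the usable VOI.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3; got {window}")
    if adc_map.adc.shape != voi.mask.shape:
        raise ValueError(
            f"VOI shape {voi.mask.shape} does not match map shape {adc_map.adc.shape}"
        )
    usable = voi.mask & adc_map.valid_mask & np.isfinite(adc_map.adc)
    out = np.full(adc_map.adc.shape, np.nan)
    kernel = np.ones((window, window), dtype=np.int64)
    for z in range(adc_map.adc.shape[2]):
        m = usable[:, :, z]
        if not m.any():
            continue
        idx = _bin_index(np.where(m, adc_map.adc[:, :, z], lo), lo, hi, n_bins)
        counts = np.empty((n_bins,) + m.shape, dtype=np.int64)
        for k in range(n_bins):
            ind = ((idx == k) & m).astype(np.int64)
            counts[k] = correlate(ind, kernel, mode="constant", cval=0)
        total = counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / total
            plogp = np.where(counts > 0, p * np.log2(p), 0.0)
        h = -plogp.sum(axis=0)
        out[:, :, z] = np.where(m & (total > 0), h, np.nan)
    # clamp tiny negative round-off
    np.clip(out, 0.0, None, out=out)
    return LocalEntropyMap(map=out, window=window)


def percent_change_entropy(h_pre: float, h_post: float) -> float:
    """Relative change ``((h_post - h_pre) / h_pre) * 100``."""
    if not h_pre > 0:
        raise ValueError(
            f"pre-treatment entropy must be > 0 (got {h_pre}); "
            "report the absolute change instead"
        )
    return (h_post - h_pre) / h_pre * 100.0
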