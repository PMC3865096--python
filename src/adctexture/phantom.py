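"""Synthetic DWI phantoms and longitudinal treatment cohorts.

The generator emulates a subcutaneous-xenograft DWI study: ellipsoidal tumors
on a regular grid (136 um in-plane, 1.5 mm slices), a spatially correlated
intra-tumor ADC field, mono-exponential signal decay over a multi-b schedule,
and Rician magnitude noise.  Treatment response is injected as a multiplicative
shift of the tumor ADC field with an optional low-ADC "lagging" subpopulation
that drives the post-treatment distribution negatively skewed, plus per-group
exponential volume growth.  Everything is seeded: identical (spec, design,
seed) reproduces volumes and manifests bit for bit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import DWISeries, TumorVOI

logger = logging.getLogger(__name__)

DEFAULT_BVALUES = (50.0, 500.0, 1000.0, 2000.0)
DEFAULT_VOXEL_SIZE = (0.136, 0.136, 1.5)


@dataclass
class PhantomSpec:
    """Parameters of a single synthetic tumor acquisition.

    ADC defaults are literature-typical for untreated solid tumors (the mean
    sits near 1.1e-3 mm^2/s, well below free water at ~3e-3); the acquisition
    constants (b-values, voxel geometry, 128x128 in-plane grid) follow the
    study protocol being emulated.  ``snr`` is the ratio of ``s0_mean`` to the
    Gaussian channel noise sigma; ``np.inf`` disables noise.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 12)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    tumor_radius: float = 4.9          # mm; ~500 mm^3 at enrollment
    adc_mean: float = 1.1e-3           # mm^2/s
    adc_sd: float = 1.5e-4             # mm^2/s intra-tumor spread
    adc_skew_target: float = 0.0
    s0_mean: float = 1000.0
    snr: float = 25.0
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    correlation_length: float = 0.5    # mm, of the intra-tumor ADC texture
    noise_model: str = "rician"
    seed: int = 0

    def validate(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        if b.size < 2 or np.any(np.diff(b) <= 0):
            raise ValueError(f"bvalues must be strictly increasing, length >= 2: {b}")
        for name in ("tumor_radius", "adc_mean", "adc_sd", "s0_mean",
                     "correlation_length"):
            if getattr(self, name) < 0 or (name != "adc_sd" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive; got {getattr(self, name)}")
        if not self.snr > 0:
            raise ValueError(f"snr must be positive (np.inf for noiseless); got {self.snr}")
        if not 1e-4 < self.adc_mean < 5e-3:
            raise ValueError(
                f"adc_mean must lie in (1e-4, 5e-3) mm^2/s; got {self.adc_mean}"
            )
        if any(v <= 0 for v in self.voxel_size) or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape and voxel_size must be positive")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"noise_model must be 'rician' or 'gaussian'; got {self.noise_model!r}")

    @property
    def sigma(self) -> float:
        """Gaussian channel noise standard deviation, signal units."""
        return 0.0 if np.isinf(self.snr) else self.s0_mean / self.snr


@dataclass
class GroundTruth:
    """Noise-free truth behind a phantom; the oracle for parameter recovery."""

    true_adc_map: np.ndarray
    true_s0_map: np.ndarray
    voi_mask: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.voi_mask = np.asarray(self.voi_mask).astype(bool)
        if np.any(self.true_adc_map < 0):
            raise ValueError("true_adc_map must be non-negative everywhere")
        if not self.voi_mask.any():
            raise ValueError("voi_mask is empty")

    @property
    def true_mean_adc(self) -> float:
        return float(self.true_adc_map[self.voi_mask].mean())

    @property
    def true_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return float(self.voi_mask.sum()) * dx * dy * dz


@dataclass
class TreatmentEffect:
    """Per-day response injection.

    ``adc_factor`` multiplies the tumor ADC field (post/pre mean ratio is made
    exact by a final rescale).  ``skew`` < 0 leaves the lowest ``lag_fraction``
    of voxels behind (relative multiplier ``1 + skew``), producing the low-ADC
    tail that skews the treated distribution negative; ``skew`` > 0 boosts the
    top fraction instead.
    """

    adc_factor: float = 1.0
    skew: float = 0.0
    lag_fraction: float = 0.25

    def validate(self) -> None:
        if not self.adc_factor > 0:
            raise ValueError(f"adc_factor must be > 0; got {self.adc_factor}")
        if not 0.0 <= self.lag_fraction < 1.0:
            raise ValueError(f"lag_fraction must be in [0, 1); got {self.lag_fraction}")
        if self.skew <= -1.0:
            raise ValueError(f"skew must be > -1; got {self.skew}")


def _ellipsoid_mask(grid_shape, voxel_size, radius_mm, center=None) -> np.ndarray:
    nx, ny, nz = grid_shape
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    ax = (np.arange(nx) - center[0]) * voxel_size[0]
    ay = (np.arange(ny) - center[1]) * voxel_size[1]
    az = (np.arange(nz) - center[2]) * voxel_size[2]
    d2 = (ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2)
    return d2 <= radius_mm ** 2


def _correlated_field(rng, shape, sigma_vox) -> np.ndarray:
    """Zero-mean unit-variance spatially correlated Gaussian field."""
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


# ADC/S0 assigned to non-tumor background voxels (muscle-like, only relevant
# when fitting outside the VOI)
_BACKGROUND_ADC = 1.7e-3
_BACKGROUND_S0_FRACTION = 0.5


def make_ground_truth(spec: PhantomSpec, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the noise-free ADC/S0 fields and VOI mask for one phantom."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.grid_shape, spec.voxel_size, spec.tumor_radius)
    if not mask.any():
        raise ValueError(
            f"tumor_radius {spec.tumor_radius} mm produces an empty tumor on "
            f"grid {spec.grid_shape} at voxel size {spec.voxel_size}"
        )
    sigma_vox = [spec.correlation_length / v for v in spec.voxel_size]
    adc = np.full(spec.grid_shape, _BACKGROUND_ADC)
    field = _correlated_field(rng, spec.grid_shape, sigma_vox)
    tumor_field = spec.adc_mean + spec.adc_sd * field
    if spec.adc_skew_target != 0.0:
        # mix in an offset subpopulation on the appropriate side
        frac = 0.15
        pick = rng.random(spec.grid_shape) < frac
        offset = np.sign(spec.adc_skew_target) * 2.0 * max(spec.adc_sd, 1e-5)
        tumor_field = np.where(pick, tumor_field + abs(spec.adc_skew_target) * offset,
                               tumor_field)
    adc[mask] = tumor_field[mask]
    np.clip(adc, 0.0, None, out=adc)

    s0 = np.full(spec.grid_shape, _BACKGROUND_S0_FRACTION * spec.s0_mean)
    s0_field = spec.s0_mean * (1.0 + 0.05 * _correlated_field(rng, spec.grid_shape, sigma_vox))
    s0[mask] = s0_field[mask]
    np.clip(s0, 1e-6 * spec.s0_mean, None, out=s0)
    return GroundTruth(adc, s0, mask, spec.voxel_size)


def synthesize_signal(
    ground: GroundTruth,
    bvalues,
    sigma: float,
    rng: np.random.Generator,
    noise_model: str = "rician",
    series_id: str = "",
) -> DWISeries:
    """Mono-exponential decay of the truth fields plus magnitude noise."""
    b = np.asarray(bvalues, dtype=float).ravel()
    clean = ground.true_s0_map[..., None] * np.exp(-ground.true_adc_map[..., None] * b)
    if sigma == 0.0:
        noisy = clean
    elif noise_model == "rician":
        n1 = rng.standard_normal(clean.shape) * sigma
        n2 = rng.standard_normal(clean.shape) * sigma
        noisy = np.sqrt((clean + n1) ** 2 + n2 ** 2)
    elif noise_model == "gaussian":
        noisy = clean + rng.standard_normal(clean.shape) * sigma
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    return DWISeries(noisy, b, ground.voxel_size, series_id=series_id)


def generate_phantom(spec: PhantomSpec) -> tuple[DWISeries, GroundTruth]:
    """Generate one seeded phantom acquisition and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ground = make_ground_truth(spec, rng)
    series = synthesize_signal(
        ground, spec.bvalues, spec.sigma, rng, spec.noise_model,
        series_id=f"phantom-seed{spec.seed}",
    )
    return series, ground


def simulate_treatment_effect(ground: GroundTruth, effect: TreatmentEffect) -> GroundTruth:
    """Apply a response profile to the tumor ADC field (VOI only).

    The post/pre VOI mean ratio equals ``effect.adc_factor`` exactly: the
    heterogeneous multipliers are renormalized by a final uniform scale.
    """
    effect.validate()
    if effect.adc_factor == 1.0 and effect.skew == 0.0:
        return ground
    adc = ground.true_adc_map.copy()
    voi = ground.voi_mask
    vals = adc[voi]
    mult = np.full(vals.shape, effect.adc_factor)
    if effect.skew != 0.0 and effect.lag_fraction > 0.0:
        if effect.skew < 0.0:
            q = np.quantile(vals, effect.lag_fraction)
            mult[vals <= q] = effect.adc_factor * (1.0 + effect.skew)
        else:
            q = np.quantile(vals, 1.0 - effect.lag_fraction)
            mult[vals >= q] = effect.adc_factor * (1.0 + effect.skew)
    new_vals = vals * mult
    mean_new = new_vals.mean()
    if mean_new > 0:
        new_vals *= effect.adc_factor * vals.mean() / mean_new
    n_high = int((new_vals > 5e-3).sum())
    if n_high > 0.01 * new_vals.size:
        logger.warning(
            "treatment effect pushed %d/%d VOI voxels above 5e-3 mm^2/s; values retained",
            n_high, new_vals.size,
        )
    adc[voi] = new_vals
    return GroundTruth(adc, ground.true_s0_map, voi, ground.voxel_size)


def _default_effect_profiles() -> dict:
    """Qualitative response mimics: Gem elevated days 2-9, Combo days 2-14,
    control/MK1775 flat.  Invented defaults, not measured values."""
    gem = {2: TreatmentEffect(1.30, -0.30), 4: TreatmentEffect(1.35, -0.30),
           9: TreatmentEffect(1.30, -0.20), 11: TreatmentEffect(1.10, -0.10)}
    combo = {2: TreatmentEffect(1.30, -0.35), 4: TreatmentEffect(1.35, -0.35),
             9: TreatmentEffect(1.35, -0.30), 11: TreatmentEffect(1.30, -0.20),
             14: TreatmentEffect(1.25, -0.20)}
    return {"control": {}, "MK1775": {}, "Gem": gem, "Combo": combo}


def _default_growth_rates() -> dict:
    # per-day exponential volume growth; Gem/Combo growth suppressed
    return {"control": 0.11, "MK1775": 0.11, "Gem": 0.03, "Combo": 0.015}


@dataclass
class CohortDesign:
    """Four-arm longitudinal design: imaging at baseline, 24 h after each of
    four treatments (days 1, 3, 8, 10) and on day 14; 4 mice x 2 flank tumors
    per group."""

    groups: tuple[str, ...] = ("control", "MK1775", "Gem", "Combo")
    mice_per_group: int = 4
    tumors_per_mouse: int = 2
    imaging_days: tuple[int, ...] = (0, 2, 4, 9, 11, 14)
    treatment_days: tuple[int, ...] = (1, 3, 8, 10)
    effect_profiles: dict = field(default_factory=_default_effect_profiles)
    growth_rates: dict = field(default_factory=_default_growth_rates)
    adc_jitter_cv: float = 0.05    # between-tumor spread of baseline mean ADC
    radius_jitter_cv: float = 0.08

    def validate(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError(f"duplicate group labels: {self.groups}")
        if self.mice_per_group < 1 or self.tumors_per_mouse < 1:
            raise ValueError("mice_per_group and tumors_per_mouse must be >= 1")
        days = list(self.imaging_days)
        if days != sorted(days) or days[0] != 0:
            raise ValueError(
                f"imaging_days must be sorted ascending starting at 0: {days}"
            )

    @property
    def tumors_per_group(self) -> int:
        return self.mice_per_group * self.tumors_per_mouse


@dataclass
class CohortRecord:
    subject_id: str
    tumor_id: str
    group: str
    day: int
    series: DWISeries
    voi: TumorVOI
    ground: GroundTruth


def simulate_cohort(
    design: CohortDesign, spec: PhantomSpec
) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Simulate every tumor at every imaging day.

    One independent seeded stream per (seed, group, mouse, tumor, day); the
    tumor-level stream fixes between-tumor biology (baseline mean ADC and
    radius jitter) so a tumor is its own control across days.  Control-group
    truth is day-stationary up to field redraw noise; volumes follow the
    per-group exponential growth rates.
    """
    design.validate()
    spec.validate()
    records: list[CohortRecord] = []
    rows = []
    subject_ids = set()
    for gi, group in enumerate(design.groups):
        profile = design.effect_profiles.get(group, {})
        growth = design.growth_rates.get(group, 0.0)
        for mi in range(design.mice_per_group):
            subject = f"{group}_m{mi + 1}"
            if subject in subject_ids:
                raise ValueError(f"duplicate subject identifier {subject!r}")
            subject_ids.add(subject)
            for tj in range(design.tumors_per_mouse):
                tumor = f"{subject}_t{tj + 1}"
                t_rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, gi, mi, tj])
                )
                adc0 = spec.adc_mean * (1.0 + design.adc_jitter_cv * t_rng.standard_normal())
                adc0 = float(np.clip(adc0, 2e-4, 4.9e-3))
                r0 = spec.tumor_radius * (1.0 + design.radius_jitter_cv * t_rng.standard_normal())
                # keep jittered tumors a few in-plane voxels wide
                r0 = float(max(r0, 3.0 * min(spec.voxel_size)))
                for di, day in enumerate(design.imaging_days):
                    day_rng = np.random.default_rng(
                        np.random.SeedSequence([spec.seed, gi, mi, tj, di])
                    )
                    radius = r0 * float(np.exp(growth * day / 3.0))
                    day_spec = replace(spec, adc_mean=adc0, tumor_radius=radius)
                    ground = make_ground_truth(day_spec, day_rng)
                    effect = profile.get(day)
                    if effect is not None:
                        ground = simulate_treatment_effect(ground, effect)
                    series = synthesize_signal(
                        ground, spec.bvalues, spec.sigma, day_rng,
                        spec.noise_model, series_id=f"{tumor}_d{day}",
                    )
                    voi = TumorVOI(ground.voi_mask, spec.voxel_size,
                                   tumor_id=tumor, day=day)
                    records.append(CohortRecord(subject, tumor, group, day,
                                                series, voi, ground))
                    rows.append({
                        "subject_id": subject, "tumor_id": tumor,
                        "group": group, "day": day,
                        "dwi_path": "", "mask_path": "",
                        "true_mean_adc": ground.true_mean_adc,
                        "true_volume_mm3": ground.true_volume_mm3,
                    })
    manifest = pd.DataFrame(rows)
    return records, manifest
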