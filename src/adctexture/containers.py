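"""Core array containers shared by every pipeline stage.

Conventions: volumes are indexed ``(x, y, z)`` with the fourth axis of a DWI
series running over the b-value schedule; all ADC quantities are in mm^2/s,
b-values in s/mm^2, voxel sizes in mm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DWISeries:
    """A 4D diffusion-weighted acquisition with its b-value schedule.

    Parameters
    ----------
    signal
        Non-negative 4D array ``(x, y, z, b)`` in arbitrary signal units.
    bvalues
        Strictly increasing diffusion sensitization factors, s/mm^2, one per
        volume on the last axis.  At least two are required for an ADC fit.
    voxel_size
        Voxel edge lengths in mm, ``(dx, dy, dz)``.
    series_id
        Opaque label carried through to outputs.
    """

    signal: np.ndarray
    bvalues: np.ndarray
    voxel_size: tuple[float, float, float] = (0.136, 0.136, 1.5)
    series_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        if self.signal.ndim != 4:
            raise ValueError(
                f"signal must be 4D (x, y, z, b); got shape {self.signal.shape}"
            )
        if self.signal.shape[3] != self.bvalues.size:
            raise ValueError(
                f"signal has {self.signal.shape[3]} b-volumes but "
                f"{self.bvalues.size} b-values were given"
            )
        if self.bvalues.size < 2:
            raise ValueError("at least 2 b-values are required")
        if np.any(np.diff(self.bvalues) <= 0):
            raise ValueError(f"bvalues must be strictly increasing: {self.bvalues}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths: {self.voxel_size}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class TumorVOI:
    """Binary tumor mask defining the volume of interest for all statistics."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (0.136, 0.136, 1.5)
    tumor_id: str = ""
    day: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D; got shape {self.mask.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths: {self.voxel_size}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class ADCMap:
    """Voxelwise mono-exponential fit results.

    ``adc`` and ``s0`` are NaN wherever ``valid_mask`` is False; ``rss`` is the
    residual sum of squares of the signal-domain fit.
    """

    adc: np.ndarray
    s0: np.ndarray
    valid_mask: np.ndarray
    rss: np.ndarray
    voxel_size: tuple[float, float, float] = (0.136, 0.136, 1.5)
    series_id: str = ""

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.rss = np.asarray(self.rss, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask).astype(bool)
        shapes = {a.shape for a in (self.adc, self.s0, self.rss, self.valid_mask)}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent map shapes: {shapes}")
        if self.adc.ndim != 3:
            raise ValueError(f"maps must be 3D; got shape {self.adc.shape}")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())
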