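"""NIfTI-1 input/output with b-value sidecar JSON and cohort manifests.

Volumes carry a diagonal affine encoding the voxel sizes; each DWI series gets
a sidecar ``<stem>.bvals.json`` with field ``bvalues`` in s/mm^2.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import ADCMap, DWISeries, TumorVOI


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def _voxel_size_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return (float(z[0]), float(z[1]), float(z[2]))


def sidecar_path(dwi_path: str | Path) -> Path:
    p = Path(dwi_path)
    stem = p.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return p.parent / f"{stem}.bvals.json"


def save_series(series: DWISeries, path: str | Path) -> Path:
    """Write a 4D series plus its b-value sidecar; returns the volume path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.signal.astype(np.float32), _affine(series.voxel_size))
    img.header.set_zooms(series.voxel_size + (1.0,))
    nib.save(img, path)
    with open(sidecar_path(path), "w") as fh:
        json.dump({"bvalues": list(map(float, series.bvalues)),
                   "series_id": series.series_id}, fh, indent=1)
    return path


def load_series(path: str | Path) -> DWISeries:
    path = Path(path)
    img = nib.load(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing b-value sidecar {side} for {path}")
    with open(side) as fh:
        meta = json.load(fh)
    return DWISeries(
        np.asarray(img.dataobj, dtype=float),
        np.asarray(meta["bvalues"], dtype=float),
        _voxel_size_from(img),
        series_id=meta.get("series_id", path.stem),
    )


def save_mask(voi: TumorVOI, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(voi.mask.astype(np.uint8), _affine(voi.voxel_size))
    nib.save(img, path)
    return path


def load_mask(path: str | Path, tumor_id: str = "", day: int | None = None) -> TumorVOI:
    img = nib.load(path)
    return TumorVOI(
        np.asarray(img.dataobj) > 0, _voxel_size_from(img), tumor_id=tumor_id, day=day
    )


def save_adc_map(adc_map: ADCMap, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write adc/s0/rss/valid volumes as ``<stem>_{adc,s0,rss,valid}.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(adc_map.voxel_size)
    paths = {}
    for name, arr, dtype in (
        ("adc", adc_map.adc, np.float32),
        ("s0", adc_map.s0, np.float32),
        ("rss", adc_map.rss, np.float32),
        ("valid", adc_map.valid_mask.astype(np.uint8), np.uint8),
    ):
        p = out_dir / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), p)
        paths[name] = p
    return paths


def load_adc_map(out_dir: str | Path, stem: str, series_id: str = "") -> ADCMap:
    out_dir = Path(out_dir)

    def arr(name):
        return np.asarray(nib.load(out_dir / f"{stem}_{name}.nii.gz").dataobj, dtype=float)

    img = nib.load(out_dir / f"{stem}_adc.nii.gz")
    return ADCMap(
        adc=arr("adc"), s0=arr("s0"), rss=arr("rss"),
        valid_mask=arr("valid") > 0,
        voxel_size=_voxel_size_from(img), series_id=series_id or stem,
    )


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)
    return path


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_curve(curve, path: str | Path) -> Path:
    """2-column CSV (threshold, fraction)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"threshold": curve.thresholds, "fraction": curve.fractions}
    ).to_csv(path, index=False)
    return path
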