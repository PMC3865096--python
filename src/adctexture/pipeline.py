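"""End-to-end orchestration: simulate -> fit -> metrics -> entropy -> stats.

Each stage writes immutable artifacts into its own subdirectory of the run
directory; re-running with the same config and seed byte-reproduces every CSV.
A run manifest records the package version, a hash of the resolved config and
per-stage row counts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import TumorVOI
from .entropy import global_entropy, local_entropy_map, percent_change_entropy
from .fitting import fit_adc_map
from .io import (load_adc_map, load_mask, load_series, save_adc_map, save_manifest,
                 save_mask, save_series)
from .metrics import (ADC_RANGE, N_THRESHOLDS, difference_auc, histogram_summary,
                      percent_change_adc, percent_change_volume,
                      pixel_fraction_curve, tumor_volume)
from .phantom import CohortDesign, PhantomSpec, TreatmentEffect, simulate_cohort
from .stats import build_comparison_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    The analysis constants default to the fixed values every metric assumes:
    threshold range [3e-5, 5e-3] mm^2/s with 512 increments, 4 entropy bins,
    a 9x9 local window, alpha 0.05.  Everything is overridable from YAML.
    """

    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    design: CohortDesign = field(default_factory=CohortDesign)
    adc_range: tuple[float, float] = ADC_RANGE
    n_thresholds: int = N_THRESHOLDS
    entropy_bins: int = 4
    entropy_window: int = 9
    alpha: float = 0.05
    figures: bool = False
    write_local_entropy: bool = False

    def validate(self) -> None:
        self.phantom.validate()
        self.design.validate()
        lo, hi = self.adc_range
        if not 0 < lo < hi:
            raise ValueError(f"adc_range must satisfy 0 < lo < hi; got {self.adc_range}")
        if self.n_thresholds < 2:
            raise ValueError("n_thresholds must be >= 2")
        if self.entropy_window % 2 == 0 or self.entropy_window < 3:
            raise ValueError("entropy_window must be odd and >= 3")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["snr"] = (
            "inf" if np.isinf(self.phantom.snr) else float(self.phantom.snr)
        )
        d["design"]["effect_profiles"] = {
            g: {int(day): dataclasses.asdict(eff) for day, eff in prof.items()}
            for g, prof in self.design.effect_profiles.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        ph = dict(d.pop("phantom", {}))
        if ph.get("snr") == "inf":
            ph["snr"] = np.inf
        for key in ("grid_shape", "voxel_size", "bvalues"):
            if key in ph:
                ph[key] = tuple(ph[key])
        de = dict(d.pop("design", {}))
        for key in ("groups", "imaging_days", "treatment_days"):
            if key in de:
                de[key] = tuple(de[key])
        if "effect_profiles" in de:
            de["effect_profiles"] = {
                g: {int(day): TreatmentEffect(**eff) for day, eff in prof.items()}
                for g, prof in de["effect_profiles"].items()
            }
        for key in ("adc_range",):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(phantom=PhantomSpec(**ph), design=CohortDesign(**de), **d)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("adctexture")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def simulate_stage(config: RunConfig, out_dir: Path) -> pd.DataFrame:
    """Generate the cohort and write volumes, masks and the manifest."""
    spec = dataclasses.replace(config.phantom, seed=config.seed)
    records, manifest = simulate_cohort(config.design, spec)
    vol_dir = out_dir / "volumes"
    for rec, (_, row) in zip(records, manifest.iterrows()):
        stem = f"{rec.tumor_id}_d{rec.day:02d}"
        dwi_path = save_series(rec.series, vol_dir / f"{stem}_dwi.nii.gz")
        mask_path = save_mask(rec.voi, vol_dir / f"{stem}_mask.nii.gz")
        manifest.loc[row.name, "dwi_path"] = str(dwi_path.relative_to(out_dir))
        manifest.loc[row.name, "mask_path"] = str(mask_path.relative_to(out_dir))
    save_manifest(manifest, out_dir / "manifest.csv")
    logger.info("simulate: %d series written", len(records))
    return manifest


def fit_stage(config: RunConfig, out_dir: Path, manifest: pd.DataFrame) -> None:
    """Fit an ADC map per series (VOI-restricted)."""
    adc_dir = out_dir / "adc"
    for _, row in manifest.iterrows():
        series = load_series(out_dir / row.dwi_path)
        voi = load_mask(out_dir / row.mask_path, row.tumor_id, int(row.day))
        amap = fit_adc_map(series, voi)
        save_adc_map(amap, adc_dir, f"{row.tumor_id}_d{int(row.day):02d}")
    logger.info("fit: %d maps written", len(manifest))


def metrics_stage(config: RunConfig, out_dir: Path, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor, per-day descriptors referenced to each tumor's baseline."""
    lo, hi = config.adc_range
    rows = []
    baseline: dict[str, dict] = {}
    entropy_dir = out_dir / "entropy"
    for _, row in manifest.sort_values(["tumor_id", "day"]).iterrows():
        day = int(row.day)
        stem = f"{row.tumor_id}_d{day:02d}"
        amap = load_adc_map(out_dir / "adc", stem)
        voi = load_mask(out_dir / row.mask_path, row.tumor_id, day)
        vol = tumor_volume(voi)
        summ = histogram_summary(amap, voi)
        curve = pixel_fraction_curve(amap, voi, lo, hi, config.n_thresholds)
        ent = global_entropy(amap, voi, lo, hi, config.entropy_bins)
        if config.write_local_entropy:
            lmap = local_entropy_map(amap, voi, config.entropy_window, lo, hi,
                                     config.entropy_bins)
            import nibabel as nib
            entropy_dir.mkdir(parents=True, exist_ok=True)
            nib.save(
                nib.Nifti1Image(lmap.map.astype(np.float32),
                                np.diag(list(voi.voxel_size) + [1.0])),
                entropy_dir / f"{stem}_local_entropy.nii.gz",
            )
        if row.tumor_id not in baseline:
            baseline[row.tumor_id] = {
                "volume": vol, "mean_adc": summ.mean_adc,
                "curve": curve, "entropy": ent.global_entropy,
            }
        base = baseline[row.tumor_id]
        rows.append({
            "subject_id": row.subject_id, "tumor_id": row.tumor_id,
            "group": row.group, "day": day,
            "volume_mm3": vol,
            "pct_volume": percent_change_volume(vol, base["volume"]),
            "mean_adc": summ.mean_adc,
            "pct_adc": percent_change_adc(summ.mean_adc, base["mean_adc"]),
            "skewness": summ.skewness, "kurtosis": summ.kurtosis,
            "auc_vs_baseline": difference_auc(base["curve"], curve).value,
            "entropy_bits": ent.global_entropy,
            "pct_entropy": (
                percent_change_entropy(base["entropy"], ent.global_entropy)
                if base["entropy"] > 0 else np.nan
            ),
            "n_voxels": summ.n_voxels, "n_excluded": summ.n_excluded,
        })
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "metrics.csv", index=False)
    logger.info("metrics: %d rows", len(table))
    return table


METRIC_COLUMNS = ["volume_mm3", "pct_volume", "mean_adc", "pct_adc", "skewness",
                  "kurtosis", "auc_vs_baseline", "entropy_bits", "pct_entropy"]


def melt_metrics(table: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Wide per-tumor metrics -> long (group, day, metric, value) table."""
    metrics = metrics or METRIC_COLUMNS
    long = table.melt(
        id_vars=["subject_id", "tumor_id", "group", "day"],
        value_vars=[m for m in metrics if m in table.columns],
        var_name="metric", value_name="value",
    )
    return long.dropna(subset=["value"])


def stats_stage(config: RunConfig, out_dir: Path, table: pd.DataFrame) -> pd.DataFrame:
    long = melt_metrics(table)
    grid = build_comparison_report(long, group_order=list(config.design.groups),
                                   alpha=config.alpha)
    grid.to_csv(out_dir / "comparisons.csv", index=False)
    logger.info("stats: %d comparison rows", len(grid))
    return grid


def figures_stage(config: RunConfig, out_dir: Path, table: pd.DataFrame) -> None:
    """Visual smoke tests: growth and ADC-change trajectories per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    for col, fname, ylabel in (
        ("pct_volume", "growth.png", "relative tumor volume [%]"),
        ("pct_adc", "delta_adc.png", "relative mean ADC [%]"),
        ("auc_vs_baseline", "auc.png", "difference AUC [mm$^2$/s]"),
        ("entropy_bits", "entropy.png", "global entropy [bits]"),
    ):
        fig, ax = plt.subplots(figsize=(5, 3.4))
        for group, sub in table.groupby("group", sort=False):
            m = sub.groupby("day")[col].mean()
            s = sub.groupby("day")[col].std()
            ax.errorbar(m.index, m.values, yerr=s.values, marker="o",
                        capsize=2, label=group)
        ax.set_xlabel("study day")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(fig_dir / fname, dpi=120)
        plt.close(fig)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run all stages; returns the run directory."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir)
    try:
        stage = "simulate"
        manifest = simulate_stage(config, out_dir)
        stage = "fit"
        fit_stage(config, out_dir, manifest)
        stage = "metrics"
        table = metrics_stage(config, out_dir, manifest)
        stage = "stats"
        grid = stats_stage(config, out_dir, table)
        if config.figures:
            stage = "figures"
            figures_stage(config, out_dir, table)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("adctexture").removeHandler(handler)
        handler.close()
    run_manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "rows": {"manifest": len(manifest), "metrics": len(table),
                 "comparisons": len(grid)},
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return out_dir
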