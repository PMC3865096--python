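"""Per-tumor descriptors: volume and relative volume, mean ADC and relative
ADC, skewness/kurtosis, pixel-fraction-difference AUC vs baseline, and global
entropy.  Writes the long-format cohort table to results/metrics.csv and
prints the group-mean trajectories.
"""
import logging

from common import RESULTS, RUN_DIR, load_config

from adctexture.io import load_manifest
from adctexture.pipeline import metrics_stage

logging.basicConfig(level=logging.WARNING)


def main() -> None:
    cfg = load_config()
    manifest = load_manifest(RUN_DIR / "manifest.csv")
    table = metrics_stage(cfg, RUN_DIR, manifest)
    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "metrics.csv", index=False)
    print(f"wrote {len(table)} metric rows to results/metrics.csv\n")
    for col, label in (("pct_adc", "relative mean ADC [%]"),
                       ("pct_volume", "relative volume [%]"),
                       ("entropy_bits", "global entropy [bits]")):
        print(f"group-mean {label} by day:")
        print(table.pivot_table(values=col, index="group", columns="day",
                                sort=False).round(2).to_string(), "\n")


if __name__ == "__main__":
    main()
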