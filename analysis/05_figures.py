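"""Visual summaries: group growth curves, relative-ADC trajectories, AUC and
entropy time courses (results/figures/*.png), plus one local-entropy slice
rendering for a treated and a control tumor at day 2.
"""
import logging

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from common import RESULTS, RUN_DIR, load_config

from adctexture.entropy import local_entropy_map
from adctexture.io import load_adc_map, load_manifest, load_mask
from adctexture.pipeline import figures_stage

logging.basicConfig(level=logging.WARNING)


def entropy_slice_figure(cfg) -> None:
    manifest = load_manifest(RUN_DIR / "manifest.csv")
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
    for ax, group in zip(axes, ("control", "Gem")):
        row = manifest[(manifest.group == group) & (manifest.day == 2)].iloc[0]
        stem = f"{row.tumor_id}_d02"
        amap = load_adc_map(RUN_DIR / "adc", stem)
        voi = load_mask(RUN_DIR / row.mask_path, row.tumor_id, 2)
        lmap = local_entropy_map(amap, voi, cfg.entropy_window).map
        z = int(np.argmax(voi.mask.sum(axis=(0, 1))))
        im = ax.imshow(lmap[:, :, z].T, origin="lower", vmin=0, vmax=2,
                       cmap="turbo")
        ax.set_title(f"{group}, day 2", fontsize=9)
        ax.axis("off")
    fig.colorbar(im, ax=axes, shrink=0.8, label="local entropy [bits]")
    fig.savefig(RESULTS / "figures" / "local_entropy_day2.png", dpi=130)
    plt.close(fig)


def main() -> None:
    cfg = load_config()
    table = pd.read_csv(RESULTS / "metrics.csv")
    figures_stage(cfg, RESULTS, table)   # writes results/figures/*.png
    entropy_slice_figure(cfg)
    print("wrote figures to results/figures/")


if __name__ == "__main__":
    main()
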