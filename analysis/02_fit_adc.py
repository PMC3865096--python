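"""Fit voxelwise mono-exponential ADC maps for every simulated series.

Reads scratch/cohort_run/manifest.csv, writes <tumor>_<day>_{adc,s0,rss,valid}
volumes under scratch/cohort_run/adc.
"""
import logging
import time

from common import RUN_DIR, load_config

from adctexture.io import load_manifest
from adctexture.pipeline import fit_stage

logging.basicConfig(level=logging.WARNING)


def main() -> None:
    cfg = load_config()
    manifest = load_manifest(RUN_DIR / "manifest.csv")
    t0 = time.time()
    fit_stage(cfg, RUN_DIR, manifest)
    print(f"fitted {len(manifest)} ADC maps in {time.time() - t0:.1f} s")


if __name__ == "__main__":
    main()
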