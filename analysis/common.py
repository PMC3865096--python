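"""Shared paths and config loading for the numbered analysis drivers."""
from pathlib import Path

from adctexture.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "cohort_run"     # volumes and maps (large, scratch)
RESULTS = ROOT / "results"                    # tables and figures (small, kept)


def load_config() -> RunConfig:
    cfg = RunConfig.from_yaml(ROOT / "analysis" / "config.yaml")
    cfg.validate()
    return cfg
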