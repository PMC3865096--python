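"""Cohort statistics: one-way ANOVA + Tukey pairwise grid for every metric and
imaging day, written to results/comparisons.csv; prints the day-2 and day-4
mean-ADC comparisons (the earliest treatment-response readout).
"""
import logging

import pandas as pd

from common import RESULTS, load_config

from adctexture.pipeline import melt_metrics
from adctexture.stats import build_comparison_report

logging.basicConfig(level=logging.WARNING)


def main() -> None:
    cfg = load_config()
    table = pd.read_csv(RESULTS / "metrics.csv")
    grid = build_comparison_report(melt_metrics(table),
                                   group_order=list(cfg.design.groups),
                                   alpha=cfg.alpha)
    grid.to_csv(RESULTS / "comparisons.csv", index=False)
    print(f"wrote {len(grid)} comparison rows to results/comparisons.csv\n")
    early = grid[(grid.metric == "mean_adc") & grid.day.isin([2, 4])]
    cols = ["day", "group_a", "group_b", "p_tukey", "significant"]
    print("mean-ADC Tukey comparisons, days 2 and 4:")
    print(early[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
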