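"""Condition statistics: mean ± SEM across cases and Welch t-tests.

Aggregates the per-field measurements from 02_measure_fields.py to case
means, compares vehicle vs M-CSF for every metric, and writes summary.csv
and report.txt.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from gliaquant.config import ExperimentConfig
from gliaquant.stats import aggregate, report, summarize_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results/experiment"))
    parser.add_argument("--paired", action="store_true",
                        help="pair vehicle/M-CSF by donor case")
    args = parser.parse_args()

    cfg = ExperimentConfig(paired=args.paired)
    per_field = pd.read_csv(args.results / "per_field.csv")
    per_case = aggregate(per_field)
    summaries = summarize_experiment(per_case, paired=cfg.paired, alpha=cfg.alpha)
    text, table = report(summaries, cfg)
    (args.results / "summary.csv").write_text(table.to_csv(index=False))
    (args.results / "report.txt").write_text(text)
    print(text)


if __name__ == "__main__":
    sys.exit(main())
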