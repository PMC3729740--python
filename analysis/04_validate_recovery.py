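"""Score the measurements against the generator's exact ground truth.

Reports count recovery, per-cell mask IoU and shape recovery for the
simulated experiment, writing validation.json.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

from gliaquant.io import read_fixture_set
from gliaquant.segmentation import segment_microglia
from gliaquant.validation import cell_iou_table, count_recovery


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--images", type=Path, default=Path("results/experiment"))
    args = parser.parse_args()

    fields, layout, truth = read_fixture_set(args.images)
    per_field = pd.read_csv(args.images / "per_field.csv")
    truths = [truth[truth.field_id == f.field_id] for f in fields]
    metrics = count_recovery(per_field, truths)
    ious = pd.concat(
        [cell_iou_table(segment_microglia(f), t) for f, t in zip(fields, truths)],
        ignore_index=True,
    )
    metrics["median_cell_iou"] = float(ious.iou.median())
    metrics["frac_cells_iou_ge_0.8"] = float((ious.iou >= 0.8).mean())

    # shape recovery: measured field-mean EFF vs true mean axis ratio
    mg = truth[truth.is_microglia]
    true_eff = mg.groupby("field_id").true_axis_ratio.mean()
    got_eff = per_field.set_index("field_id").mean_eff
    rel = ((got_eff - true_eff).abs() / true_eff).dropna()
    metrics["eff_mean_abs_rel_error"] = float(rel.mean())

    out = args.images / "validation.json"
    out.write_text(json.dumps(metrics, indent=2, default=float))
    print(json.dumps(metrics, indent=2, default=float))


if __name__ == "__main__":
    sys.exit(main())
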