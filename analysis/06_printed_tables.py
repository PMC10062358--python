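"""Recompute the published summary statistics from the printed count
tables: the chronic-heart-failure Fisher test, confusion-matrix row
percentages and rough-categorization accuracies, and the segment
bookkeeping proportions.

These are arithmetic reproductions on the study's own printed numbers —
independent of any simulation. Writes results/printed_checks.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from afpulse.agreement import ConfusionMatrix, fisher_exact_2x2
from afpulse.fixtures import (
    ACCOUNTING,
    TABLE1_CHF_2X2,
    TABLE2_DAY,
    TABLE2_NIGHT,
    TABLE3_MOTION,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    day = ConfusionMatrix.from_counts(TABLE2_DAY)
    night = ConfusionMatrix.from_counts(TABLE2_NIGHT)
    checks = {
        "chf_fisher_p": round(fisher_exact_2x2(TABLE1_CHF_2X2), 4),
        "day_le80_diag_pct": round(day.row_percentages()[0, 0], 1),
        "night_le80_diag_pct": round(night.row_percentages()[0, 0], 1),
        "day_gt110_diag_pct": round(day.row_percentages()[2, 2], 1),
        "day_rough_accuracy_pct": round(day.rough_accuracy(), 1),
        "night_rough_accuracy_pct": round(night.rough_accuracy(), 1),
        "motion_rough_accuracy_pct": {
            g: round(ConfusionMatrix.from_counts(m).rough_accuracy(), 1)
            for g, m in TABLE3_MOTION.items()
        },
        "included_pct": round(
            100 * ACCOUNTING["included"] / ACCOUNTING["total_simultaneous_minutes"], 1
        ),
        "le80_share_pct": round(100 * ACCOUNTING["ecg_le80"] / ACCOUNTING["included"], 1),
    }
    for k, v in checks.items():
        print(f"{k}: {v}")
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "printed_checks.json").write_text(json.dumps(checks, indent=2))
    print(f"wrote {out/'printed_checks.json'}")


if __name__ == "__main__":
    main()
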