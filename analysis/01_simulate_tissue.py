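"""Simulate the synthetic cohorts and summarize what was planted.

Generates three early-stage (9 planted region archetypes) and three
late-stage (7 archetypes) samples with vessels and ground truth, and writes
per-sample summaries: cell counts, planted phenotype mix, phenotype-gating
accuracy against the planted labels.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import RESULTS, get_cohort

RESULTS.mkdir(exist_ok=True)

rows = []
for stage in ("early", "late"):
    for cells, truth in get_cohort(stage):
        acc = (cells["phenotype"] == cells["true_phenotype"]).mean()
        rows.append({
            "sample_id": cells["sample_id"].iloc[0],
            "stage": stage,
            "n_cells": len(cells),
            "k_planted": truth.k_true,
            "n_vessels": len(truth.vessels),
            "pct_unclassified": 100 * (cells["phenotype"] == "unclassified").mean(),
            "gating_accuracy_pct": 100 * acc,
        })

summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "01_cohort_summary.csv", index=False)
print(summary.to_string(index=False))
print(f"\nSimulated {len(summary)} samples "
      f"({summary.n_cells.sum():,} cells); phenotype gating recovers planted "
      f"labels at {summary.gating_accuracy_pct.mean():.2f}% mean accuracy.")
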