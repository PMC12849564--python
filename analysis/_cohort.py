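"""Shared cohort builder for the analysis scripts.

Simulates a small deterministic cohort per stage (seeds are fixed so every
script sees the same samples) and runs phenotype gating.  Results tables
land under results/.
"""

from pathlib import Path

from cafmap.phenotype import calibrate_thresholds, classify_cells
from cafmap.simulate import reference_architecture

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_SEEDS = {"early": [101, 102, 103, 104], "late": [201, 202, 203, 204]}


def get_cohort(stage: str):
    """List of (classified cell table, ground truth) for one stage."""
    out = []
    for seed in COHORT_SEEDS[stage]:
        cells, truth = reference_architecture(stage, seed=seed)
        cells = classify_cells(cells, calls=calibrate_thresholds(cells))
        out.append((cells, truth))
    return out
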