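"""Raster neighborhoods and SOM region clustering with model selection.

For every cohort sample: 50-µm-radius neighborhoods on a 50-µm lattice,
SOM clustering of the composition vectors, Davies-Bouldin curve over
k = 2..15, and the selected region count.  The planted counts are 9 (early)
and 7 (late).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import COHORT_SEEDS, RESULTS, get_cohort

from cafmap.geometry import make_grid
from cafmap.neighborhoods import compute_neighborhoods
from cafmap.regions import cluster_regions

RESULTS.mkdir(exist_ok=True)

rows, curves = [], []
for stage in ("early", "late"):
    for (cells, truth), seed in zip(get_cohort(stage), COHORT_SEEDS[stage]):
        grid = make_grid(cells)
        comp = compute_neighborhoods(cells, grid)
        model = cluster_regions(comp, k_range=range(2, 16), seed=seed)
        sid = cells["sample_id"].iloc[0]
        rows.append({"sample_id": sid, "stage": stage,
                     "n_neighborhoods": int((~comp.empty_mask).sum()),
                     "k_planted": truth.k_true,
                     "k_selected": model.selected_k})
        for k, score in model.db_scores.items():
            curves.append({"sample_id": sid, "stage": stage,
                           "k": k, "davies_bouldin": score})

summary = pd.DataFrame(rows)
pd.DataFrame(curves).to_csv(RESULTS / "03_davies_bouldin_curves.csv",
                            index=False)
summary.to_csv(RESULTS / "03_region_selection.csv", index=False)
print(summary.to_string(index=False))
hits = (summary.k_selected == summary.k_planted).sum()
print(f"\nDavies-Bouldin argmin recovered the planted region count in "
      f"{hits}/{len(summary)} samples.")
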