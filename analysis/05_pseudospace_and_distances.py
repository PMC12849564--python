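"""Pseudo-space CAF gradients and CAF-to-target distance analysis.

Orders late-stage neighborhoods along the immune-minus-tumor composition
axis and compares CAF substate abundance at the two ends, then measures
nearest distances from each CAF substate to vessel tiles, immune and tumor
cells, testing whether vCAFs sit closer to vessels than mCAFs.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import RESULTS, get_cohort

from cafmap.geometry import VesselGeometry, make_grid, tile_vessels
from cafmap.neighborhoods import compute_neighborhoods, normalize
from cafmap.stats import nearest_distances, pseudospace, wilcoxon_compare

RESULTS.mkdir(exist_ok=True)

decile_rows, dist_frames = [], []
for cells, truth in get_cohort("late"):
    sid = cells["sample_id"].iloc[0]
    comp = normalize(compute_neighborhoods(cells, make_grid(cells)),
                     "fraction")
    ps = pseudospace(comp)
    d = max(1, len(ps.curves) // 10)
    for end, block in (("immune_rich", ps.curves.iloc[:d]),
                       ("tumor_rich", ps.curves.iloc[-d:])):
        decile_rows.append({"sample_id": sid, "end": end,
                            **block[["mCAF1", "mCAF2", "vCAF1", "vCAF2"]]
                            .mean().to_dict()})

    tiles = tile_vessels(VesselGeometry(truth.vessels, source="synthetic"))
    ds = nearest_distances(cells, ["mCAF1", "mCAF2", "vCAF1", "vCAF2"],
                           tiles=tiles)
    dist_frames.append(ds.per_sample)

deciles = pd.DataFrame(decile_rows)
deciles.to_csv(RESULTS / "05_pseudospace_deciles.csv", index=False)
dist = pd.concat(dist_frames, ignore_index=True)
dist.to_csv(RESULTS / "05_distances_per_sample.csv", index=False)

print(deciles.round(3).to_string(index=False))
v = dist[(dist.target == "vessel")
         & dist.phenotype.str.startswith("vCAF")]
m = dist[(dist.target == "vessel")
         & dist.phenotype.str.startswith("mCAF")]
vmeans = v.groupby("sample_id").mean_distance_um.mean()
mmeans = m.groupby("sample_id").mean_distance_um.mean()
t = wilcoxon_compare(vmeans, mmeans)
print(f"\nvCAF->vessel {vmeans.mean():.0f} um vs mCAF->vessel "
      f"{mmeans.mean():.0f} um per sample; rank-sum p = {t.p_value:.3g} "
      f"{t.stars}")
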