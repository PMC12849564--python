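"""Stromal composition and aSMA intensity across tumor stages.

Writes per-sample phenotype percentages and per-phenotype mean aSMA
intensity, then tests the two planted contrasts: the immune-cell percentage
rises from early to late stage, and the myofibroblastic substates (mCAF1,
vCAF1) stain brighter for aSMA than their immunomodulatory partners
(mCAF2, vCAF2).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import RESULTS, get_cohort

from cafmap.phenotype import intensity_by_phenotype
from cafmap.stats import composition_summary, wilcoxon_compare

RESULTS.mkdir(exist_ok=True)

frames, intens = [], []
for stage in ("early", "late"):
    for cells, _ in get_cohort(stage):
        frames.append(composition_summary(cells))
        intens.append(intensity_by_phenotype(cells, "aSMA"))
comp = pd.concat(frames, ignore_index=True)
asma = pd.concat(intens, ignore_index=True)
comp.to_csv(RESULTS / "02_composition_per_sample.csv", index=False)
asma.to_csv(RESULTS / "02_asma_intensity_per_sample.csv", index=False)

imm = comp[comp.phenotype == "immune"]
early_pct = imm.loc[imm.stage == "early", "percent"]
late_pct = imm.loc[imm.stage == "late", "percent"]
test = wilcoxon_compare(early_pct, late_pct)
print(f"Immune cells: {early_pct.mean():.1f}% (early) vs "
      f"{late_pct.mean():.1f}% (late); rank-sum p = {test.p_value:.3g} "
      f"{test.stars}")

for hi, lo in (("mCAF1", "mCAF2"), ("vCAF1", "vCAF2")):
    a = asma.loc[asma.phenotype == hi, "mean_intensity"]
    b = asma.loc[asma.phenotype == lo, "mean_intensity"]
    t = wilcoxon_compare(a, b)
    print(f"aSMA intensity {hi} {a.mean():.1f} vs {lo} {b.mean():.1f}; "
          f"p = {t.p_value:.3g} {t.stars}")
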