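# cafmap

Spatial niche analysis of cancer-associated fibroblasts (CAFs) in the tumor
microenvironment, built for per-cell tables exported from multiplex
immunofluorescence imaging (e.g. QuPath measurement exports with marker mean
intensities and µm centroids).

Matrix-type CAFs (mCAF, PDGFRα+) and vascular-type CAFs (vCAF, MCAM+) each
split into a myofibroblastic, α-SMA+ substate (mCAF1/vCAF1) and an
immunomodulatory, α-SMA− substate (mCAF2/vCAF2).  Where these substates sit
in the tissue — shielding the tumor core, mixing with immune infiltrate, or
hugging vessels — is the question this package quantifies.

## The pipeline

1. **Phenotype gating** (`cafmap.phenotype`): per-marker positivity
   thresholds (2-component Gaussian mixture on log intensity, threshold at
   the equal-posterior point), applied in a fixed hierarchy: MCAM and PDGFRα
   jointly (double-positive → intermediate CAF; single-positive → vCAF/mCAF
   branch split by α-SMA), then sequentially CD31 → CD45 → PanCK → α-SMA
   alone.  Unclassified cells are excluded downstream.
2. **Raster neighborhoods** (`cafmap.geometry`, `cafmap.neighborhoods`):
   a lattice of sample points (50 µm pitch) over the tissue; each point's
   neighborhood is the per-phenotype count of cells within a closed 50-µm
   ball.
3. **Region clustering** (`cafmap.regions`): neighborhood compositions in
   the Hellinger embedding (√fractions) are quantized by a self-organizing
   map (10×10), the codebook is merged by Ward linkage into k regions for
   each k in 2..15, and the Davies–Bouldin index
   `DB = mean_i max_j (σ_i + σ_j) / d(c_i, c_j)` selects k (argmin; full
   curve retained for inspection).
4. **Region interactions** (`cafmap.interactions`): on the region label
   raster, the percentage of each region's 8-connected boundary edges shared
   with every other region; edges with `max(P[A,B], P[B,A]) ≥ 10%` form the
   niche-adjacency graph.
5. **Spatial statistics** (`cafmap.stats`): pseudo-space ordering of
   neighborhoods along the immune-minus-tumor composition axis with smoothed
   abundance curves; nearest-distance analysis from CAF substates to vessel
   tiles (10-µm square subdivisions of vessel annotations), immune and tumor
   cells; Wilcoxon rank-sum comparisons with conventional star bands.
6. **Synthetic tissue** (`cafmap.simulate`): a generator that plants the
   full niche architecture — region archetypes with known compositions and
   densities, a concentric layout (tumor core, mCAF1/myofibroblast shield
   ring, immune/mCAF2/endothelial territories outside it), log-normal marker
   intensities, vessel ribbons with perivascular vCAF enrichment — with
   complete ground truth for every downstream stage.

## Worked example

```python
from cafmap import (reference_architecture, calibrate_thresholds,
                    classify_cells, make_grid, compute_neighborhoods,
                    cluster_regions)

cells, truth = reference_architecture("late", seed=0)   # ~66,000 cells, 3x3 mm
cells = classify_cells(cells, calls=calibrate_thresholds(cells))
print((cells.phenotype == cells.true_phenotype).mean())  # 0.9997

comp = compute_neighborhoods(cells, make_grid(cells))    # 3844 neighborhoods
model = cluster_regions(comp, k_range=range(2, 16), seed=0)
print(truth.k_true, model.selected_k)                    # 7 7
print(model.db_scores[7], model.db_scores[4])            # 0.820 1.220
```

The late-stage architecture plants seven region archetypes; the
Davies–Bouldin curve over candidate k bottoms out at the planted count, and
the recovered labels match the planted layout (adjusted Rand index ≈ 0.88).

The same flow runs from the shell:

```sh
cafmap simulate --stage late --seed 0 --out run/
cafmap report --stage late --seed 0 --out run/      # full pipeline + tables
```

The numbered scripts under `analysis/` run the study end to end on small
synthetic cohorts (simulation and gating accuracy, composition shifts and
α-SMA intensity contrasts, region-count selection, interaction topology,
pseudo-space and distance orderings) and write their tables under
`results/`.

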