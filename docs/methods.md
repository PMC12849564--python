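# Methods

## Scope and data model

The package analyzes segmented-cell tables from multiplex immunofluorescence
imaging of tumors: one row per cell with µm centroids (image convention,
origin top-left, y down), sample and stage metadata, and mean intensities
for PDGFRα, MCAM, α-SMA, CD31, CD45, PanCK and DAPI.  Vessel annotations
arrive as GeoJSON polygons.  Everything downstream — gating, neighborhoods,
regions, interactions, distances — operates on this table, so the package is
agnostic to the upstream segmentation tool as long as a column map is
provided.

## Phenotype gating

Interactively trained per-marker classifiers are not portable, so positivity
is decided by per-marker intensity thresholds with a pluggable calibration:
the default fits a 2-component Gaussian mixture to log intensity and places
the threshold at the equal-posterior crossing (located by bisection between
the component means); a fixed-quantile alternative exists for manual
control.  The decision hierarchy evaluates the two CAF lineage markers
jointly first (MCAM+/PDGFRα+ → intermediate CAF, including triple-positives
with α-SMA; single-positives split by α-SMA into substate 1/2), then tests
the remaining cells sequentially CD31 → CD45 → PanCK → α-SMA-only.  The
sequential order is a fixed, documented choice; multi-positive conflicts
outside the CAF branch resolve to the first positive marker in that order.
Cells failing every test are labelled `unclassified` and excluded from all
downstream statistics.  Labels are a pure function of (intensities,
thresholds): row order cannot affect any call.

## Neighborhoods and regions

Neighborhoods use a raster-scan design: an axis-aligned lattice covering the
cell bounding box padded by the neighborhood radius.  Defaults are radius
50 µm and spacing = radius; membership is the closed ball.  Compositions are
stored as raw per-phenotype counts; empty neighborhoods are flagged,
excluded from clustering, and rendered as background in the label raster
(this prevents a spurious all-zero region).

Region clustering embeds compositions as √fractions (the Hellinger
embedding).  The square root stabilizes multinomial counting variance —
every neighborhood contributes noise of comparable magnitude regardless of
its dominant phenotype — which matters because the Davies–Bouldin index
compares within-cluster dispersions across clusters; in the raw or z-scored
count space, stroma-rich regions are several-fold noisier than tumor-rich
ones and the index degenerates.  A per-feature z-score scheme is retained as
an option (`features="zscore"`).

The SOM is a 10×10 rectangular lattice trained online (Gaussian
neighborhood, linearly decaying radius and learning rate, codebook
initialized from data rows; one iteration = one sample presentation, default
10,000, fully seeded).  Codebook nodes are meta-clustered by Ward linkage —
standard SOM practice, and the route by which neighborhood-clustering tools
reach small region counts — and node labels propagate to neighborhoods via
their best-matching unit.  For each candidate k (default 2..15) the
Davies–Bouldin index of the induced neighborhood partition is computed in
the same feature space; the selected k is the argmin with ties to the
smaller k, and the full curve is exported so the choice can be inspected the
way the original analyses inspected it.  The index can alternatively be
evaluated on the codebook nodes (`db_on="nodes"`).

## Interactions, pseudo-space, distances

A boundary edge is an 8-connected lattice pair with differing
non-background labels (diagonal contacts count as borders at 50-µm pitch;
4-connectivity is available).  The directed matrix P gives the percentage of
a region's boundary edges shared with each other region; every
non-degenerate row sums to 100.  Because the published chord diagrams are
symmetric while the underlying percentage is directional, thresholding uses
`max(P[A,B], P[B,A]) ≥ cutoff` (default 10%).  Per-sample matrices average
element-wise over the label union, with missing-region rows contributing
flagged zeros.

Pseudo-space sorts non-empty neighborhoods by immune fraction minus tumor
fraction (descending; ties by total count then grid index, so the ordering
is invariant to input row order) and smooths each phenotype's fraction along
the ordering with a centered moving average spanning 5% of neighborhoods.

Distance analysis measures each source cell's Euclidean nearest-neighbor
distance per target class (immune cells, tumor cells, vessel-tile
centroids) with a k-d tree.  Vessel annotations are subdivided into square
tiles — read as squares of side 10 µm, the tiling convention of interactive
pathology tools; the literal area-10-µm² reading remains available through
the `tile_side_um` parameter — and edge tiles below 25% of a full tile are
dropped by default.  A reporting radius censors (never zeroes) distances
beyond it; the 10-µm and 100-µm profiles are both exported, and per-sample
means are taken over uncensored values.  Recovery checks of the
vCAF-closer-to-vessels ordering use the uncensored distances, since a 10-µm
censor restricts both groups to sub-10-µm values and erases the contrast.
Group comparisons are two-sided Wilcoxon rank-sum tests (exact null for
untied samples below 50 total, tie-corrected normal approximation
otherwise), reported per sample with no multiple-comparison correction to
match the per-panel star convention; Benjamini–Hochberg can be applied
externally where needed.

## Synthetic tissue generator

The generator is the package's test bed: it plants a known niche
architecture and full ground truth so every stage can be scored.  It
emulates:

- **Region archetypes.**  9 early-stage and 7 late-stage archetypes with
  the qualitative enrichment pattern of murine mammary tumors: three
  tumor-enriched regions, an immune-exclusive region, a mCAF2-exclusive
  region, a mixed immune+mCAF2 region, endothelial-enriched regions (two
  early, one late), and a myofibroblast-dominated region early only.  No
  numeric per-region compositions are published (heatmaps only), so the
  fractions are this package's own encodings.  Within the qualitative
  constraints they were chosen by a maximin design: maximize the smallest
  pairwise Hellinger distance between archetype compositions (achieved
  ≈ 0.7).  Near-uniform pairwise separation is what makes the planted
  region count identifiable to a Davies–Bouldin argmin — if archetypes form
  super-clusters, merging an isolated tight pair always lowers the index
  and the selector under-splits, a property of the index rather than an
  implementation artifact.
- **Geometry.**  A concentric layout in a 3×3 mm field: tumor core
  (plus a corridor through the second tumor annulus so core and shield
  share a border), a shield ring enriched for myofibroblasts/mCAF1/vCAF1,
  and immune / mixed / mCAF2 / endothelial sectors outside the shield.
  Immune-role regions never border tumor-role regions by construction; the
  planted adjacency is recorded in the ground truth.  In the late-stage
  enumeration the shield is also the third tumor-containing archetype
  (tumor fraction ≈ 0.08), since the seven late archetypes leave no
  separate slot; topology checks therefore count only the `tumor_core` and
  `tumor` roles as "tumor regions".
- **Cell placement.**  Per region, a Poisson count with mean density ×
  area (so count tests have a stated noise model), multinomial phenotypes,
  uniform positions by rejection sampling.  Densities are 6,000–9,000
  cells/mm² — dense carcinoma tissue; ≈ 55 cells per 50-µm neighborhood.
  This occupancy is what keeps multinomial composition noise (σ ≈ 0.2 in
  the Hellinger embedding) below half the minimum archetype separation,
  the regime in which the planted k is recoverable.
- **Intensities.**  Log-normal per (phenotype, marker): positive markers at
  location 3.2 (log scale), background at 1.0, scale 0.3 — strictly
  positive and right-skewed like fluorescence means, with non-overlapping
  interquartile ranges (≈ 5σ separation), yielding ≥ 99.9% gating accuracy.
- **Vessels.**  Buffered random ribbons, extra ones seeded in
  endothelial-role regions; endothelial cells are pulled onto vessels and
  60% of vCAF cells into a 15-µm perivascular band of their own region
  (relocation stays within the region so planted compositions are
  preserved), and vCAF MCAM intensity gets a distance-decay boost within
  20 µm of a vessel.

What the generator does **not** emulate: segmentation errors and doublets,
spatially varying staining background, autofluorescence, irregular tissue
boundaries, folds and necrosis, cell-size variation, or continuous
phenotype gradients.  Passing recovery tests therefore demonstrates that
the pipeline's inference chain is correct and well-calibrated on clean,
planted architecture — not that real tissue meets these assumptions.

## Numerical choices and degenerate inputs

- Ties in Davies–Bouldin model selection go to the smaller k (parsimony).
- Constant intensity columns abort calibration with the marker named;
  tables under 100 cells are rejected.
- A clustering candidate whose meta-clusters collapse to fewer than two
  non-empty clusters scores +∞ and can never be selected.
- The DB index raises on all-singleton/coincident degenerate clusterings.
- Empty vessel lists yield an empty TileSet (not an error); invalid
  polygons are rejected by feature index.
- Grid construction with one cell yields a 3×3 lattice at default
  spacing; non-finite coordinates are rejected.
- All randomness (placement, intensities, SOM initialization and
  presentation order) flows through numpy Generators seeded per run;
  identical seeds reproduce byte-identical tables.

## Problem sizes

Default synthetic samples are 3×3 mm at full density (≈ 66,000 cells, 3,721
neighborhoods); recovery studies in the tests and the acceptance script use
20 samples per stage, and the analysis scripts 4 per stage.  These sizes
give stable modal statistics (the region-count mode is reproducible across
seed offsets) while a full cohort runs in minutes on a single core.

## Known limitations

- The Davies–Bouldin argmin is an automated stand-in for human inspection
  of the curve; on real tissue with hierarchically similar niches it will
  tend to under-split, and the exported curve should be inspected.
- Region recovery is assessed against hard planted labels; neighborhoods
  straddling region borders are intrinsically ambiguous and cap the
  achievable agreement (ARI ≈ 0.9 at these settings).
- The shared-border normalization convention (by each region's own border
  length) is one of several in circulation; the directional matrix is
  exported so alternatives can be derived.
- Distances are 2-D; tissue sections are thin 3-D slabs.
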