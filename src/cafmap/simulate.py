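"""Synthetic tumor-microenvironment generator with planted ground truth.

Generates labeled point patterns that emulate early- and late-stage mammary
tumors: a set of region *archetypes* (expected phenotype composition +
cell density), a geometric layout placing each archetype in the field with a
planned adjacency structure, log-normal marker intensities per phenotype,
and vessel ribbons with perivascular vCAF enrichment.  Every downstream
stage of the pipeline (phenotyping, neighborhoods, region clustering,
interactions, distances) can be scored against the planted truth.

Late-stage tissue is organized concentrically: a tumor core, a second
tumor-enriched annulus, a myofibroblastic mCAF1/vCAF1 shield ring around
them, and immune / mCAF2 / mixed / endothelial territories outside the
shield, so that immune-rich regions never share a border with tumor-rich
regions.  Early-stage tissue uses the same concentric plan with nine
archetypes, including a myofibroblast-dominated shield and two distinct
endothelial territories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

from cafmap.core import MARKERS, PHENOTYPES, POSITIVITY, STAGES

__all__ = [
    "ArchetypeProfile",
    "LayoutSpec",
    "IntensityModel",
    "GroundTruth",
    "VesselPlan",
    "builtin_archetypes",
    "default_intensity_model",
    "generate_tissue",
    "reference_architecture",
]


@dataclass(frozen=True)
class ArchetypeProfile:
    """Expected cellular makeup of one region archetype.

    Parameters
    ----------
    name
        Short label ("E1".."E9" for early stage, "L1".."L7" for late).
    composition
        Map phenotype -> expected fraction; non-negative, sums to 1.
    density
        Expected cells per mm^2; must be positive.
    role
        Functional role used by recovery checks: one of ``tumor_core``,
        ``tumor``, ``shield``, ``immune``, ``mcaf2``, ``immune_mixed``,
        ``endothelial``.
    """

    name: str
    composition: dict[str, float]
    density: float
    role: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"archetype {self.name}: density must be > 0")
        fracs = np.asarray(list(self.composition.values()), dtype=float)
        if (fracs < 0).any():
            raise ValueError(f"archetype {self.name}: negative fraction")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"archetype {self.name}: fractions sum to {fracs.sum():.12f}, not 1"
            )
        unknown = set(self.composition) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"archetype {self.name}: unknown phenotypes {unknown}")


@dataclass(frozen=True)
class VesselPlan:
    """How many vessel ribbons to draw and how they recruit cells."""

    n_vessels: int = 30
    n_extra_endothelial: int = 12  # additional vessels seeded in endothelial regions
    length_range: tuple[float, float] = (80.0, 250.0)
    width_range: tuple[float, float] = (8.0, 16.0)
    perivascular_radius_um: float = 15.0
    vcaf_attach_prob: float = 0.6
    endo_attach_prob: float = 0.8
    intensity_decay_radius_um: float = 20.0


@dataclass
class LayoutSpec:
    """Geometric plan of a synthetic sample.

    ``regions`` maps archetype names to shapely polygons that jointly cover
    the field; ``adjacency_plan`` lists the unordered archetype pairs meant
    to share a border.
    """

    field_size: tuple[float, float]
    regions: list[tuple[str, Polygon]]
    adjacency_plan: set[frozenset[str]]
    vessel_plan: VesselPlan = field(default_factory=VesselPlan)
    seed: int = 0

    def validate(self, archetype_names: set[str]) -> None:
        placed = {name for name, _ in self.regions}
        missing = archetype_names - placed
        if missing:
            raise ValueError(f"archetypes never placed in layout: {sorted(missing)}")
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError("field_size must be positive")
        field_area = w * h
        covered = sum(poly.area for _, poly in self.regions)
        if covered < 0.98 * field_area:
            raise ValueError(
                f"region polygons cover {covered:.0f} of {field_area:.0f} um^2"
            )


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal marker-intensity model per (phenotype, marker).

    A marker is drawn from ``positive_loc/scale`` when the phenotype is
    positive for it (per ``POSITIVITY``; DAPI always positive), otherwise
    from the background ``negative_loc/scale``.  Locations are on the
    natural-log scale; positive location must exceed negative location for
    every marker so the planted classes are separable.
    """

    positive_loc: float = 3.2
    positive_scale: float = 0.3
    negative_loc: float = 1.0
    negative_scale: float = 0.3

    def __post_init__(self) -> None:
        if not self.positive_loc > self.negative_loc:
            raise ValueError("positive location must exceed negative location")
        if min(self.positive_scale, self.negative_scale) <= 0:
            raise ValueError("scales must be positive")

    def is_positive(self, phenotype: str, marker: str) -> bool:
        return marker == "DAPI" or marker in POSITIVITY[phenotype]

    def draw(self, phenotype: str, marker: str, n: int, rng: np.random.Generator):
        if self.is_positive(phenotype, marker):
            return np.exp(rng.normal(self.positive_loc, self.positive_scale, n))
        return np.exp(rng.normal(self.negative_loc, self.negative_scale, n))


@dataclass
class GroundTruth:
    """Planted truth for one generated sample."""

    k_true: int
    layout: LayoutSpec
    roles: dict[str, str]
    vessels: list[Polygon]
    adjacency: set[frozenset[str]]

    def region_labels(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """True archetype name at each (x, y); first-placed region wins ties."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, "", dtype=object)
        undecided = np.ones(x.shape, dtype=bool)
        for name, poly in self.layout.regions:
            if not undecided.any():
                break
            hit = undecided & shapely.contains_xy(poly, x, y)
            out[hit] = name
            undecided &= ~hit
        if undecided.any():
            # points on shared arcs / numeric slivers: snap to nearest region
            idx = np.flatnonzero(undecided)
            pts = shapely.points(x[idx], y[idx])
            for j, pt in zip(idx, pts):
                dists = [poly.distance(pt) for _, poly in self.layout.regions]
                out[j] = self.layout.regions[int(np.argmin(dists))][0]
        return out.astype(str)


# --------------------------------------------------------------------------
# Built-in archetypes
#
# The composition values are qualitative encodings of the enrichment
# patterns reported for murine mammary tumors (three tumor-enriched regions;
# an immune-exclusive, a mCAF2-exclusive and a mixed immune+mCAF2 region;
# two endothelial regions early vs one late; a myofibroblast shield early
# only), not measured numbers.  Densities are in cells/mm^2, in the range
# typical of segmented mammary carcinoma sections.
# --------------------------------------------------------------------------

_EARLY_ARCHETYPES = [
    ("E1", "tumor_core", 9000, {
        "tumor": 0.750, "immune": 0.020, "endothelial": 0.040, "mCAF1": 0.004, "mCAF2": 0.014, "vCAF1": 0.004, "vCAF2": 0.014, "intCAF": 0.150, "myofibroblast": 0.004}),
    ("E2", "tumor", 7000, {
        "tumor": 0.340, "immune": 0.004, "endothelial": 0.004, "mCAF1": 0.150, "mCAF2": 0.350, "vCAF1": 0.004, "vCAF2": 0.014, "intCAF": 0.081, "myofibroblast": 0.053}),
    ("E3", "tumor", 8000, {
        "tumor": 0.376, "immune": 0.040, "endothelial": 0.040, "mCAF1": 0.030, "mCAF2": 0.080, "vCAF1": 0.040, "vCAF2": 0.350, "intCAF": 0.004, "myofibroblast": 0.040}),
    ("E4", "shield", 7500, {
        "tumor": 0.021, "immune": 0.040, "endothelial": 0.028, "mCAF1": 0.217, "mCAF2": 0.040, "vCAF1": 0.035, "vCAF2": 0.040, "intCAF": 0.013, "myofibroblast": 0.566}),
    ("E5", "immune", 8000, {
        "tumor": 0.040, "immune": 0.652, "endothelial": 0.038, "mCAF1": 0.004, "mCAF2": 0.024, "vCAF1": 0.160, "vCAF2": 0.040, "intCAF": 0.004, "myofibroblast": 0.038}),
    ("E6", "mcaf2", 6000, {
        "tumor": 0.023, "immune": 0.019, "endothelial": 0.040, "mCAF1": 0.036, "mCAF2": 0.684, "vCAF1": 0.040, "vCAF2": 0.150, "intCAF": 0.004, "myofibroblast": 0.004}),
    ("E7", "immune_mixed", 7000, {
        "tumor": 0.004, "immune": 0.358, "endothelial": 0.037, "mCAF1": 0.040, "mCAF2": 0.383, "vCAF1": 0.015, "vCAF2": 0.004, "intCAF": 0.120, "myofibroblast": 0.039}),
    ("E8", "endothelial", 6500, {
        "tumor": 0.040, "immune": 0.040, "endothelial": 0.384, "mCAF1": 0.150, "mCAF2": 0.032, "vCAF1": 0.248, "vCAF2": 0.004, "intCAF": 0.098, "myofibroblast": 0.004}),
    ("E9", "endothelial", 6000, {
        "tumor": 0.004, "immune": 0.040, "endothelial": 0.294, "mCAF1": 0.024, "mCAF2": 0.100, "vCAF1": 0.021, "vCAF2": 0.277, "intCAF": 0.200, "myofibroblast": 0.040}),
]

_LATE_ARCHETYPES = [
    ("L1", "tumor_core", 9000, {
        "tumor": 0.734, "immune": 0.040, "endothelial": 0.040, "mCAF1": 0.120, "mCAF2": 0.040, "vCAF1": 0.014, "vCAF2": 0.004, "intCAF": 0.004, "myofibroblast": 0.004}),
    ("L2", "tumor", 7000, {
        "tumor": 0.394, "immune": 0.004, "endothelial": 0.004, "mCAF1": 0.024, "mCAF2": 0.004, "vCAF1": 0.300, "vCAF2": 0.040, "intCAF": 0.150, "myofibroblast": 0.080}),
    ("L3", "shield", 7500, {
        "tumor": 0.081, "immune": 0.038, "endothelial": 0.039, "mCAF1": 0.369, "mCAF2": 0.038, "vCAF1": 0.121, "vCAF2": 0.039, "intCAF": 0.011, "myofibroblast": 0.264}),
    ("L4", "immune", 8000, {
        "tumor": 0.037, "immune": 0.730, "endothelial": 0.004, "mCAF1": 0.004, "mCAF2": 0.024, "vCAF1": 0.040, "vCAF2": 0.119, "intCAF": 0.005, "myofibroblast": 0.037}),
    ("L5", "mcaf2", 6000, {
        "tumor": 0.037, "immune": 0.008, "endothelial": 0.004, "mCAF1": 0.027, "mCAF2": 0.700, "vCAF1": 0.004, "vCAF2": 0.178, "intCAF": 0.005, "myofibroblast": 0.037}),
    ("L6", "immune_mixed", 7000, {
        "tumor": 0.004, "immune": 0.373, "endothelial": 0.040, "mCAF1": 0.039, "mCAF2": 0.426, "vCAF1": 0.004, "vCAF2": 0.014, "intCAF": 0.096, "myofibroblast": 0.004}),
    ("L7", "endothelial", 6500, {
        "tumor": 0.038, "immune": 0.038, "endothelial": 0.467, "mCAF1": 0.040, "mCAF2": 0.038, "vCAF1": 0.099, "vCAF2": 0.064, "intCAF": 0.178, "myofibroblast": 0.038}),
]


def builtin_archetypes(stage: str) -> list[ArchetypeProfile]:
    """Region archetypes for a tumor stage: 9 for "early", 7 for "late"."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    raw = _EARLY_ARCHETYPES if stage == "early" else _LATE_ARCHETYPES
    profiles = []
    for name, role, density, comp in raw:
        total = sum(comp.values())
        comp = {p: comp.get(p, 0.0) / total for p in PHENOTYPES}
        profiles.append(
            ArchetypeProfile(name=name, composition=comp, density=density, role=role)
        )
    return profiles


def default_intensity_model() -> IntensityModel:
    return IntensityModel()


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def _wedge(cx, cy, r0, r1, a0_deg, a1_deg, n=90) -> Polygon:
    """Annular sector centred at (cx, cy) between radii r0<r1 and angles a0<a1."""
    a0, a1 = math.radians(a0_deg), math.radians(a1_deg)
    ang = np.linspace(a0, a1, n)
    outer = np.column_stack([cx + r1 * np.cos(ang), cy + r1 * np.sin(ang)])
    if r0 <= 0:
        pts = np.vstack([outer, [[cx, cy]]])
    else:
        inner = np.column_stack([cx + r0 * np.cos(ang[::-1]), cy + r0 * np.sin(ang[::-1])])
        pts = np.vstack([outer, inner])
    return Polygon(pts)


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    got: list[np.ndarray] = []
    remaining = n
    frac = max(poly.area / max((maxx - minx) * (maxy - miny), 1e-12), 1e-3)
    for _ in range(200):
        m = int(remaining / frac * 1.3) + 16
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(poly, xs, ys)
        pts = np.column_stack([xs[keep], ys[keep]])
        got.append(pts[:remaining])
        remaining -= min(len(pts), remaining)
        if remaining == 0:
            return np.vstack(got)
    raise RuntimeError("rejection sampling failed to converge (degenerate polygon?)")


def _make_vessels(layout: LayoutSpec, roles: dict[str, str],
                  rng: np.random.Generator) -> list[Polygon]:
    """Buffered random segments; extra ones seeded inside endothelial regions."""
    plan = layout.vessel_plan
    w, h = layout.field_size
    fieldbox = box(0, 0, w, h)
    endo_polys = [poly for name, poly in layout.regions
                  if roles.get(name) == "endothelial"]
    vessels: list[Polygon] = []

    def ribbon(cx, cy):
        length = rng.uniform(*plan.length_range)
        width = rng.uniform(*plan.width_range)
        theta = rng.uniform(0, 2 * np.pi)
        dx, dy = 0.5 * length * np.cos(theta), 0.5 * length * np.sin(theta)
        seg = shapely.LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)])
        v = seg.buffer(width / 2, quad_segs=8).intersection(fieldbox)
        return v if (not v.is_empty and v.area > 0) else None

    for _ in range(plan.n_vessels):
        v = ribbon(rng.uniform(0, w), rng.uniform(0, h))
        if v is not None:
            vessels.append(v)
    for poly in endo_polys:
        for _ in range(plan.n_extra_endothelial):
            (pt,) = _sample_in_polygon(poly, 1, rng)
            v = ribbon(*pt)
            if v is not None:
                vessels.append(v)
    return vessels


def _relocate_near_vessels(xy: np.ndarray, move_mask: np.ndarray,
                           region_poly: Polygon, vessels: list[Polygon],
                           band_um: float, rng: np.random.Generator) -> np.ndarray:
    """Move masked cells to random points in (vessel band) ∩ region."""
    if not move_mask.any() or not vessels:
        return xy
    union = shapely.unary_union(
        [v.buffer(band_um, quad_segs=4) for v in vessels]
    ).intersection(region_poly)
    if union.is_empty or union.area <= 0:
        return xy
    pts = _sample_in_polygon(union, int(move_mask.sum()), rng)
    xy = xy.copy()
    xy[move_mask] = pts
    return xy


# --------------------------------------------------------------------------
# Generator
# --------------------------------------------------------------------------

def generate_tissue(
    layout: LayoutSpec,
    archetypes: list[ArchetypeProfile],
    intensity_model: IntensityModel | None = None,
    seed: int = 0,
    sample_id: str = "sample_0",
    stage: str = "late",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one tissue sample from a layout and its archetypes.

    Per region, the cell count is Poisson with mean density × area; phenotype
    labels are multinomial draws from the archetype composition; marker
    intensities come from the phenotype's positive/negative log-normal
    distributions.  Vessels are buffered ribbons; endothelial cells are
    pulled onto vessels and a fraction of vCAF cells into the perivascular
    band of their own region, and vCAF MCAM intensity receives a
    distance-decay boost within the decay radius of a vessel.
    """
    if intensity_model is None:
        intensity_model = default_intensity_model()
    by_name = {a.name: a for a in archetypes}
    layout.validate(set(by_name))
    if all(a.density <= 0 for a in archetypes):
        raise ValueError("all archetype densities are zero")
    rng = np.random.default_rng(seed)
    roles = {a.name: a.role for a in archetypes}
    vessels = _make_vessels(layout, roles, rng)
    plan = layout.vessel_plan

    rows_xy, rows_phen, rows_region = [], [], []
    for name, poly in layout.regions:
        arch = by_name[name]
        mean_n = arch.density * poly.area / 1e6  # density is per mm^2
        n = int(rng.poisson(mean_n))
        if n == 0:
            continue
        phen_idx = rng.choice(len(PHENOTYPES), size=n,
                              p=[arch.composition.get(p, 0.0) for p in PHENOTYPES])
        phens = np.asarray(PHENOTYPES, dtype=object)[phen_idx]
        xy = _sample_in_polygon(poly, n, rng)
        region_vessels = [v for v in vessels if v.intersects(poly)]
        if region_vessels:
            is_endo = phens == "endothelial"
            move = is_endo & (rng.uniform(size=n) < plan.endo_attach_prob)
            xy = _relocate_near_vessels(xy, move, poly, region_vessels, 1.0, rng)
            is_vcaf = (phens == "vCAF1") | (phens == "vCAF2")
            move = is_vcaf & (rng.uniform(size=n) < plan.vcaf_attach_prob)
            xy = _relocate_near_vessels(
                xy, move, poly, region_vessels, plan.perivascular_radius_um, rng
            )
        rows_xy.append(xy)
        rows_phen.append(phens)
        rows_region.append(np.full(n, name, dtype=object))

    if not rows_xy:
        raise ValueError("simulation produced zero cells (empty field?)")
    xy = np.vstack(rows_xy)
    phens = np.concatenate(rows_phen)
    regions_per_cell = np.concatenate(rows_region)
    n_total = len(phens)

    intens = {m: np.empty(n_total) for m in MARKERS}
    for p in PHENOTYPES:
        mask = phens == p
        k = int(mask.sum())
        if k == 0:
            continue
        for m in MARKERS:
            intens[m][mask] = intensity_model.draw(p, m, k, rng)

    # perivascular distance-decay boost on vCAF MCAM intensity
    vcaf_mask = (phens == "vCAF1") | (phens == "vCAF2")
    if vcaf_mask.any() and vessels:
        vunion = shapely.unary_union(vessels)
        pts = shapely.points(xy[vcaf_mask, 0], xy[vcaf_mask, 1])
        d = shapely.distance(vunion, pts)
        r = plan.intensity_decay_radius_um
        boost = 1.0 + 0.5 * np.clip(1.0 - d / r, 0.0, None)
        intens["MCAM"][vcaf_mask] *= boost

    cells = pd.DataFrame({
        "cell_id": [f"c{i:06d}" for i in range(n_total)],
        "sample_id": sample_id,
        "stage": stage,
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        **{m: intens[m] for m in MARKERS},
        "true_phenotype": phens.astype(str),
        "true_region": regions_per_cell.astype(str),
    })
    truth = GroundTruth(
        k_true=len({name for name, _ in layout.regions}),
        layout=layout,
        roles=roles,
        vessels=vessels,
        adjacency=set(layout.adjacency_plan),
    )
    return cells, truth


# --------------------------------------------------------------------------
# Reference architecture (concentric tumor + shield + outer territories)
# --------------------------------------------------------------------------

def _concentric_layout(stage: str, field_um: float, seed: int) -> tuple[
        list[tuple[str, Polygon]], set[frozenset[str]]]:
    L = field_um
    cx = cy = L / 2
    s = L / 3000.0  # radii were designed on a 3 mm field
    r_core, r_ann, r_shield = 650 * s, 950 * s, 1200 * s
    far = 2.5 * L
    fieldbox = box(0, 0, L, L)
    corridor = (-45, 45)  # degrees; lets the core reach the shield

    if stage == "late":
        names = ["L1", "L2", "L3", "L4", "L6", "L5", "L7"]
        # outer cyclic order: immune, mixed, mcaf2, endothelial
        outer = ["L4", "L6", "L5", "L7"]
        ann_sectors = {"L2": (corridor[1], 360 + corridor[0])}
        core, t2, shield = "L1", None, "L3"
    else:
        outer = ["E5", "E7", "E6", "E8", "E9"]
        ann_sectors = {"E2": (corridor[1], 180), "E3": (180, 360 + corridor[0])}
        core, shield = "E1", "E4"

    regions: list[tuple[str, Polygon]] = []
    core_poly = Point(cx, cy).buffer(r_core, quad_segs=90).union(
        _wedge(cx, cy, r_core, r_ann, *corridor))
    regions.append((core, core_poly))
    for name, (a0, a1) in ann_sectors.items():
        regions.append((name, _wedge(cx, cy, r_core, r_ann, a0, a1)))
    shield_poly = Point(cx, cy).buffer(r_shield, quad_segs=120).difference(
        Point(cx, cy).buffer(r_ann, quad_segs=120))
    regions.append((shield, shield_poly))

    n_out = len(outer)
    offset = 37.0  # keep sector borders off the lattice axes
    for i, name in enumerate(outer):
        a0 = offset + 360.0 * i / n_out
        a1 = offset + 360.0 * (i + 1) / n_out
        sector = _wedge(cx, cy, r_shield, far, a0, a1).intersection(fieldbox)
        regions.append((name, sector))

    adjacency: set[frozenset[str]] = set()
    ann_names = list(ann_sectors)
    for name in ann_names:
        adjacency.add(frozenset({core, name}))
        adjacency.add(frozenset({name, shield}))
    if len(ann_names) == 2:
        adjacency.add(frozenset(ann_names))
    adjacency.add(frozenset({core, shield}))  # via the corridor
    for i, name in enumerate(outer):
        adjacency.add(frozenset({shield, name}))
        adjacency.add(frozenset({name, outer[(i + 1) % n_out]}))
    return regions, adjacency


def reference_architecture(
    stage: str,
    seed: int = 0,
    field_um: float = 3000.0,
    density_scale: float = 1.0,
    sample_id: str | None = None,
    vessel_plan: VesselPlan | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one sample with the packaged concentric niche architecture.

    Late stage: tumor core (L1) + tumor annulus (L2) wrapped by the
    mCAF1/vCAF1 shield ring (L3); immune (L4), mixed immune+mCAF2 (L6),
    mCAF2 (L5) and endothelial (L7) territories outside the shield.  Early
    stage adds a second tumor annulus sector, a myofibroblast shield (E4)
    and a second endothelial territory (9 archetypes total).  The planted
    adjacency (recorded in the ground truth) keeps every immune-role region
    away from every tumor-role region.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    archetypes = builtin_archetypes(stage)
    if density_scale != 1.0:
        archetypes = [
            ArchetypeProfile(a.name, a.composition, a.density * density_scale, a.role)
            for a in archetypes
        ]
    regions, adjacency = _concentric_layout(stage, field_um, seed)
    layout = LayoutSpec(
        field_size=(field_um, field_um),
        regions=regions,
        adjacency_plan=adjacency,
        vessel_plan=vessel_plan or VesselPlan(),
        seed=seed,
    )
    if sample_id is None:
        sample_id = f"{stage}_s{seed}"
    return generate_tissue(
        layout, archetypes, default_intensity_model(), seed=seed,
        sample_id=sample_id, stage=stage,
    )
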