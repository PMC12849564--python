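"""Shared vocabulary: marker panel, phenotype label set, gating patterns.

Coordinates are micrometres throughout, image convention (origin top-left,
y increasing downward).  A cell table is a pandas DataFrame with at least
``cell_id``, ``sample_id``, ``x_um``, ``y_um`` and one intensity column per
marker; ``stage`` ("early"/"late"), ``phenotype`` and ``true_phenotype``
columns are added by the stages that produce them.
"""

from __future__ import annotations

MARKERS = ["PDGFRa", "MCAM", "aSMA", "CD31", "CD45", "PanCK", "DAPI"]
"""Marker panel in staining-cycle order; DAPI is the nuclear counterstain."""

PHENOTYPES = [
    "tumor",
    "immune",
    "endothelial",
    "mCAF1",
    "mCAF2",
    "vCAF1",
    "vCAF2",
    "intCAF",
    "myofibroblast",
]
"""Closed phenotype label set (excluding the 'unclassified' sink).

CAF nomenclature: mCAF = matrix-type (PDGFRa+), vCAF = vascular-type
(MCAM+); substate 1 is myofibroblastic (aSMA+), substate 2
immunomodulatory (aSMA-); intCAF is the MCAM+/PDGFRa+ intermediate state.
"""

UNCLASSIFIED = "unclassified"

POSITIVITY: dict[str, frozenset[str]] = {
    "tumor": frozenset({"PanCK"}),
    "immune": frozenset({"CD45"}),
    "endothelial": frozenset({"CD31"}),
    "mCAF1": frozenset({"PDGFRa", "aSMA"}),
    "mCAF2": frozenset({"PDGFRa"}),
    "vCAF1": frozenset({"MCAM", "aSMA"}),
    "vCAF2": frozenset({"MCAM"}),
    "intCAF": frozenset({"MCAM", "PDGFRa"}),
    "myofibroblast": frozenset({"aSMA"}),
}
"""Markers each phenotype is positive for (DAPI positive in all)."""

REQUIRED_COLUMNS = ["cell_id", "sample_id", "x_um", "y_um"]

STAGES = ("early", "late")
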