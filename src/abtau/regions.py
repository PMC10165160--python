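"""Cortical parcellation vocabulary and tracer-composite region sets.

The package works with a Desikan-Killiany-style parcellation: 34 gyral/sulcal
regions per hemisphere (68 cortical regions in total).  Composite regions of
interest are expressed as lists of parcel *names*; both hemispheres'
homologues are pooled when a composite is evaluated.

The amyloid composite expands the conventional lobar targets (frontal,
parietal, lateral temporal, anterior/posterior cingulate, precuneus) into
explicit parcel names.  The tau composite covers the temporal-lobe regions
where tangle pathology appears first; the medial-temporal (MTL) composite is
the early-abnormality subset (entorhinal + parahippocampal).  The amygdala
belongs to the conventional tau meta-ROI but is subcortical; it is included
automatically whenever the geometry's region table contains it.
"""

from __future__ import annotations

DESIKAN_KILLIANY_34 = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

# Lobar expansion used by the default amyloid composite.
FRONTAL = (
    "superiorfrontal",
    "rostralmiddlefrontal",
    "caudalmiddlefrontal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "lateralorbitofrontal",
    "medialorbitofrontal",
    "frontalpole",
)
PARIETAL = ("superiorparietal", "inferiorparietal", "supramarginal")
LATERAL_TEMPORAL = ("superiortemporal", "middletemporal", "inferiortemporal")
CINGULATE = ("rostralanteriorcingulate", "caudalanteriorcingulate", "posteriorcingulate")

ABETA_COMPOSITE = FRONTAL + PARIETAL + LATERAL_TEMPORAL + CINGULATE + ("precuneus",)

TAU_COMPOSITE = (
    "fusiform",
    "parahippocampal",
    "entorhinal",
    "inferiortemporal",
    "middletemporal",
    "amygdala",  # subcortical; used only when present in the region table
)

MTL_COMPOSITE = ("entorhinal", "parahippocampal")

#: Optional subcortical parcels a geometry may carry in addition to the 34
#: cortical parcels (e.g. for 76-region cross-correlograms).
SUBCORTICAL_OPTIONAL = ("amygdala", "hippocampus", "thalamus", "caudate")


def default_composite_definitions() -> dict[str, tuple[str, ...]]:
    """Composite name -> parcel names, as shipped by default."""
    return {
        "global_abeta": ABETA_COMPOSITE,
        "global_tau": TAU_COMPOSITE,
        "mtl_tau": MTL_COMPOSITE,
    }
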