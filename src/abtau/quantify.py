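"""SUVR normalization, region tables, and composite SUVR panels.

Uptake maps are normalized to a cerebellar gray-matter reference value
(supplied as a precomputed per-subject scalar; the pipeline does not segment
the cerebellum) to give the standardized uptake value ratio (SUVR).  Regional
means over the parcellation feed the three composite markers used throughout
the analysis: global amyloid, global tau, and medial-temporal (MTL) tau.
Left/right homologues are pooled within a composite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .cohort import SurfaceGeometry, VertexOverlay, region_means
from .regions import default_composite_definitions


class QuantifyError(Exception):
    pass


def compute_suvr(suv_overlay: VertexOverlay, reference_value: float) -> VertexOverlay:
    """Divide an uptake overlay by the cerebellar gray reference value."""
    if not reference_value > 0:
        raise QuantifyError(f"reference value must be positive, got {reference_value}")
    return VertexOverlay(subject_id=suv_overlay.subject_id,
                         modality=suv_overlay.modality,
                         values=suv_overlay.values / float(reference_value))


@dataclass(frozen=True)
class CompositeDefinition:
    """A named composite region of interest: a list of parcel names."""

    name: str
    regions: tuple[str, ...]

    def resolve_ids(self, geometry: SurfaceGeometry,
                    strict: bool = True) -> list[int]:
        """Parcel ids (both hemispheres) contributing to the composite.

        With ``strict`` every named parcel must exist in the region table;
        with ``strict=False`` parcels absent from the parcellation (e.g.
        optional subcortical structures) are skipped.
        """
        ids: list[int] = []
        for name in self.regions:
            found = geometry.ids_for_name(name)
            if not found and strict:
                raise QuantifyError(
                    f"composite {self.name!r}: region {name!r} not in parcellation")
            ids.extend(found)
        if not ids:
            raise QuantifyError(f"composite {self.name!r} resolves to no regions")
        return ids


def default_definitions(optional_subcortical: bool = True) -> dict[str, CompositeDefinition]:
    """The shipped composite definitions (amyloid / tau / MTL-tau)."""
    defs = {}
    for name, regions in default_composite_definitions().items():
        defs[name] = CompositeDefinition(name=name, regions=tuple(regions))
    return defs


def load_definitions(path) -> dict[str, CompositeDefinition]:
    raw = yaml.safe_load(open(path))
    return {k: CompositeDefinition(name=k, regions=tuple(v)) for k, v in raw.items()}


def save_definitions(defs: dict[str, CompositeDefinition], path) -> None:
    yaml.safe_dump({k: list(d.regions) for k, d in defs.items()},
                   open(path, "w"), sort_keys=True)


def composite_suvr(region_row: pd.Series, definition: CompositeDefinition,
                   geometry: SurfaceGeometry, strict: bool = False) -> float:
    """Unweighted mean of the composite's regional mean SUVRs.

    ``region_row`` is indexed by parcel id (one subject's row of a region
    table).  Missing or NaN entries for a resolved region raise an error
    naming the region.
    """
    ids = definition.resolve_ids(geometry, strict=strict)
    vals = []
    for rid in ids:
        if rid not in region_row.index or not np.isfinite(region_row.loc[rid]):
            raise QuantifyError(
                f"composite {definition.name!r}: region "
                f"{geometry.region_name(rid)!r} (id {rid}) missing from table")
        vals.append(float(region_row.loc[rid]))
    return float(np.mean(vals))


def build_region_table(overlays: dict[str, VertexOverlay],
                       geometry: SurfaceGeometry) -> pd.DataFrame:
    """Subjects x regions table of per-region mean values for one modality."""
    rows = {sid: region_means(ov, geometry) for sid, ov in overlays.items()}
    return pd.DataFrame(rows).T


def build_panel(subject_frame: pd.DataFrame,
                abeta_regions: pd.DataFrame, tau_regions: pd.DataFrame,
                geometry: SurfaceGeometry,
                definitions: dict[str, CompositeDefinition] | None = None) -> pd.DataFrame:
    """Per-subject composite panel joined with covariates.

    Returns a DataFrame indexed by subject id with columns ``global_abeta``,
    ``global_tau``, ``mtl_tau`` (NaN where the subject lacks the modality)
    plus ``age, sex, icv, diagnosis, cohort``.
    """
    defs = definitions or default_definitions()
    panel = subject_frame[["age", "sex", "icv", "diagnosis", "cohort"]].copy()
    for col, table, dname in (("global_abeta", abeta_regions, "global_abeta"),
                              ("global_tau", tau_regions, "global_tau"),
                              ("mtl_tau", tau_regions, "mtl_tau")):
        out = pd.Series(np.nan, index=panel.index, dtype=float)
        for sid in panel.index:
            if sid in table.index:
                out.loc[sid] = composite_suvr(table.loc[sid], defs[dname], geometry)
        panel[col] = out
    return panel
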