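"""Core domain objects: surface geometry, vertex overlays, subjects, region tables.

All overlays of a geometry share a single 0-based vertex indexing.  Tissue
labels partition the surface into gray matter (analyzed), white matter and
meninges (spill-in sources), and excluded vertices.  Region labels are
defined on gray vertices only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("gray", "white", "meninges", "excluded")
MODALITIES = ("abeta", "tau", "thickness")
SEXES = ("M", "F")
DIAGNOSES = ("HC", "MCI")
COHORTS = ("young", "old")


class CohortError(Exception):
    """Base class for cohort-layer failures."""


class GeometryError(CohortError):
    """Overlay/geometry inconsistency (length, labels, coordinates)."""


class SchemaError(CohortError):
    """Malformed table or unknown enum value."""


class LoadError(CohortError):
    """Missing or unreadable input file."""


@dataclass
class SurfaceGeometry:
    """Shared surface support for all per-subject overlays.

    Parameters
    ----------
    coordinates : (V, 3) float array, mm
    tissue : (V,) str array with values in :data:`TISSUES`
    region : (V,) int array; parcel id for gray vertices, -1 elsewhere
    hemisphere : (V,) str array, 'L'/'R' ('-' for non-cortical vertices)
    region_table : DataFrame indexed by parcel id with columns name, hemisphere
    """

    coordinates: np.ndarray
    tissue: np.ndarray
    region: np.ndarray
    hemisphere: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.tissue = np.asarray(self.tissue, dtype="U8")
        self.region = np.asarray(self.region, dtype=int)
        self.hemisphere = np.asarray(self.hemisphere, dtype="U1")
        v = self.n_vertices
        if self.coordinates.shape != (v, 3):
            raise GeometryError(f"coordinates must be (V, 3); got {self.coordinates.shape}")
        if not np.all(np.isfinite(self.coordinates)):
            raise GeometryError("coordinates must be finite")
        for arr, name in ((self.tissue, "tissue"), (self.region, "region"),
                          (self.hemisphere, "hemisphere")):
            if arr.shape != (v,):
                raise GeometryError(f"{name} must have one entry per vertex")
        bad = set(np.unique(self.tissue)) - set(TISSUES)
        if bad:
            raise SchemaError(f"unknown tissue labels: {sorted(bad)}")
        gray = self.tissue == "gray"
        if np.any(self.region[gray] < 0):
            raise GeometryError("every gray vertex needs a region label")
        known = set(self.region_table.index)
        referenced = set(np.unique(self.region[gray]))
        missing = referenced - known
        if missing:
            raise GeometryError(f"region ids absent from region_table: {sorted(missing)}")

    @property
    def n_vertices(self) -> int:
        return int(self.tissue.shape[0])

    @property
    def gray_mask(self) -> np.ndarray:
        return self.tissue == "gray"

    @property
    def source_mask(self) -> np.ndarray:
        """White-matter and meningeal vertices: the spill-in sources."""
        return (self.tissue == "white") | (self.tissue == "meninges")

    @property
    def gray_indices(self) -> np.ndarray:
        return np.flatnonzero(self.gray_mask)

    def region_ids(self) -> np.ndarray:
        return np.asarray(self.region_table.index)

    def region_name(self, region_id: int) -> str:
        return str(self.region_table.loc[region_id, "name"])

    def ids_for_name(self, name: str) -> list[int]:
        """All parcel ids (both hemispheres) with the given parcel name."""
        tab = self.region_table
        return [int(i) for i in tab.index[tab["name"] == name]]

    def region_label_strings(self) -> list[str]:
        """'hemisphere_name' labels in region-table order (e.g. 'L_entorhinal')."""
        return [f"{h}_{n}" for n, h in
                zip(self.region_table["name"], self.region_table["hemisphere"])]


@dataclass
class VertexOverlay:
    """One per-vertex scalar map (SUVR or cortical thickness) for one subject."""

    subject_id: str
    modality: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise SchemaError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise GeometryError("overlay values must be a 1-D vector")

    def validate(self, geometry: SurfaceGeometry) -> None:
        if self.values.shape[0] != geometry.n_vertices:
            raise GeometryError(
                f"overlay {self.subject_id}/{self.modality} has "
                f"{self.values.shape[0]} values for a geometry of "
                f"{geometry.n_vertices} vertices")
        live = geometry.tissue != "excluded"
        if not np.all(np.isfinite(self.values[live])):
            raise GeometryError(
                f"overlay {self.subject_id}/{self.modality} has non-finite "
                "values on non-excluded vertices")
        if self.modality == "thickness" and np.any(self.values[geometry.gray_mask] < 0):
            raise GeometryError(
                f"thickness overlay {self.subject_id} has negative values")

    def gray_values(self, geometry: SurfaceGeometry) -> np.ndarray:
        return self.values[geometry.gray_mask]


@dataclass
class Subject:
    id: str
    age: float
    sex: str
    icv: float
    diagnosis: str
    cohort: str
    modalities: tuple[str, ...] = field(default_factory=lambda: MODALITIES)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SchemaError(f"subject {self.id}: unknown sex {self.sex!r}")
        if self.diagnosis not in DIAGNOSES:
            raise SchemaError(f"subject {self.id}: unknown diagnosis {self.diagnosis!r}")
        if self.cohort not in COHORTS:
            raise SchemaError(f"subject {self.id}: unknown cohort {self.cohort!r}")
        if self.cohort == "young" and not (20.0 <= self.age <= 40.0):
            raise SchemaError(f"subject {self.id}: young cohort requires age in [20, 40]")
        if self.cohort == "old" and self.age < 55.0:
            raise SchemaError(f"subject {self.id}: old cohort requires age >= 55")
        if not self.icv > 0:
            raise SchemaError(f"subject {self.id}: ICV must be positive")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise SchemaError(f"subject {self.id}: unknown modalities {sorted(unknown)}")


def subjects_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "icv": [s.icv for s in subjects],
            "diagnosis": [s.diagnosis for s in subjects],
            "cohort": [s.cohort for s in subjects],
            "modalities": ["+".join(s.modalities) for s in subjects],
        }
    ).set_index("id", drop=False)


def region_means(overlay: VertexOverlay, geometry: SurfaceGeometry,
                 weights: np.ndarray | None = None) -> pd.Series:
    """Per-region mean of the overlay over each region's gray vertices.

    Returns a Series indexed by parcel id.  Regions without gray vertices are
    flagged absent as NaN (never silently zero).  ``weights`` enables an
    optional per-vertex (e.g. surface-area) weighted mean; the default is the
    unweighted vertex mean.
    """
    overlay.validate(geometry)
    gray = geometry.gray_mask
    ids = geometry.region_ids()
    labels = geometry.region[gray]
    vals = overlay.values[gray]
    w = np.ones_like(vals) if weights is None else np.asarray(weights, float)[gray]
    nmax = int(labels.max()) + 1 if labels.size else 0
    wsum = np.bincount(labels, weights=w, minlength=nmax)
    vsum = np.bincount(labels, weights=w * vals, minlength=nmax)
    out = pd.Series(np.nan, index=ids, dtype=float, name=overlay.modality)
    for rid in ids:
        if rid < nmax and wsum[rid] > 0:
            out.loc[rid] = vsum[rid] / wsum[rid]
    return out
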