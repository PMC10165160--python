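"""Readers and writers for the pipeline's plain-text interchange formats.

Canonical formats
-----------------
subject table
    CSV with columns ``id, age, sex, icv, diagnosis, cohort, modalities``
    (modalities ``+``-joined, e.g. ``abeta+thickness``).
geometry
    a directory containing ``vertices.csv`` (vertex_id, x, y, z, tissue,
    region, hemisphere) and ``regions.csv`` (region_id, name, hemisphere).
vertex overlay
    a flat text file, one value per vertex ordered by 0-based vertex id,
    with ``#``-prefixed header lines.  Values are written with 17 significant
    digits so that write/read round-trips are exact for float64.

Adapters for FreeSurfer MGH and GIFTI functional overlays are provided for
reading real surface data into the same in-memory type.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (MODALITIES, LoadError, SchemaError, Subject, SurfaceGeometry,
                     VertexOverlay, subjects_to_frame)

SUBJECT_COLUMNS = ["id", "age", "sex", "icv", "diagnosis", "cohort", "modalities"]


# ---------------------------------------------------------------- geometry

def save_geometry(geometry: SurfaceGeometry, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    v = pd.DataFrame(
        {
            "vertex_id": np.arange(geometry.n_vertices),
            "x": geometry.coordinates[:, 0],
            "y": geometry.coordinates[:, 1],
            "z": geometry.coordinates[:, 2],
            "tissue": geometry.tissue,
            "region": geometry.region,
            "hemisphere": geometry.hemisphere,
        }
    )
    v.to_csv(path / "vertices.csv", index=False, float_format="%.17g")
    r = geometry.region_table.reset_index()
    r.columns = ["region_id", "name", "hemisphere"]
    r.to_csv(path / "regions.csv", index=False)


def load_geometry(path: str | Path) -> SurfaceGeometry:
    path = Path(path)
    vf, rf = path / "vertices.csv", path / "regions.csv"
    for f in (vf, rf):
        if not f.exists():
            raise LoadError(f"geometry file missing: {f}")
    v = pd.read_csv(vf, float_precision="round_trip")
    r = pd.read_csv(rf).set_index("region_id")
    order = np.argsort(v["vertex_id"].to_numpy())
    v = v.iloc[order]
    return SurfaceGeometry(
        coordinates=v[["x", "y", "z"]].to_numpy(),
        tissue=v["tissue"].to_numpy(dtype="U8"),
        region=v["region"].to_numpy(dtype=int),
        hemisphere=v["hemisphere"].to_numpy(dtype="U1"),
        region_table=r,
    )


# ---------------------------------------------------------------- overlays

def overlay_filename(subject_id: str, modality: str) -> str:
    return f"{subject_id}_{modality}.overlay.txt"


def save_overlay(overlay: VertexOverlay, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# abtau overlay subject={overlay.subject_id} "
                 f"modality={overlay.modality} n={overlay.values.shape[0]}\n")
        np.savetxt(fh, overlay.values, fmt="%.17g")


def load_overlay(path: str | Path, subject_id: str | None = None,
                 modality: str | None = None) -> VertexOverlay:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"overlay file missing: {path}")
    header = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    header[k] = v
            body = fh.read()
        else:
            body = first + fh.read()
    values = pd.read_csv(_io.StringIO(body), header=None, comment="#",
                         dtype=float,
                         float_precision="round_trip").to_numpy().ravel()
    return VertexOverlay(
        subject_id=subject_id or header.get("subject", path.stem),
        modality=modality or header.get("modality", "abeta"),
        values=values,
    )


def read_overlay_mgh(path: str | Path, subject_id: str, modality: str) -> VertexOverlay:
    """Read a FreeSurfer .mgh/.mgz functional overlay (one value per vertex)."""
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asarray(img.get_fdata()).ravel()
    return VertexOverlay(subject_id=subject_id, modality=modality, values=values)


def read_overlay_gifti(path: str | Path, subject_id: str, modality: str) -> VertexOverlay:
    """Read a GIFTI functional overlay (first data array)."""
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asarray(img.darrays[0].data, dtype=float).ravel()
    return VertexOverlay(subject_id=subject_id, modality=modality, values=values)


# ---------------------------------------------------------------- subjects

def save_subject_table(subjects: list[Subject], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False, float_format="%.17g")


def load_subject_table(path: str | Path) -> list[Subject]:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"subject table missing: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"subject table lacks columns: {sorted(missing)}")
    subjects = []
    for _, row in df.iterrows():
        subjects.append(Subject(
            id=str(row["id"]), age=float(row["age"]), sex=str(row["sex"]),
            icv=float(row["icv"]), diagnosis=str(row["diagnosis"]),
            cohort=str(row["cohort"]),
            modalities=tuple(str(row["modalities"]).split("+")),
        ))
    return subjects


# ---------------------------------------------------------------- cohorts

def load_cohort(subject_table_path: str | Path, overlay_dir: str | Path,
                geometry_path: str | Path):
    """Load and cross-validate a full cohort.

    Returns ``(subjects, overlays, geometry)`` where ``overlays`` maps
    subject id -> modality -> :class:`VertexOverlay`.  Subjects missing a
    declared overlay are reported collectively in the raised
    :class:`LoadError`, never silently dropped.
    """
    geometry = load_geometry(geometry_path)
    subjects = load_subject_table(subject_table_path)
    overlay_dir = Path(overlay_dir)
    overlays: dict[str, dict[str, VertexOverlay]] = {}
    missing: list[str] = []
    for s in subjects:
        overlays[s.id] = {}
        for m in s.modalities:
            f = overlay_dir / overlay_filename(s.id, m)
            if not f.exists():
                missing.append(f"{s.id}/{m}")
                continue
            ov = load_overlay(f, subject_id=s.id, modality=m)
            ov.validate(geometry)
            overlays[s.id][m] = ov
    if missing:
        raise LoadError("missing overlays for: " + ", ".join(missing))
    return subjects, overlays, geometry


def save_cohort(subjects: list[Subject],
                overlays: dict[str, dict[str, VertexOverlay]],
                geometry: SurfaceGeometry, path: str | Path) -> None:
    """Write a cohort in the canonical layout understood by :func:`load_cohort`."""
    path = Path(path)
    (path / "overlays").mkdir(parents=True, exist_ok=True)
    save_geometry(geometry, path / "geometry")
    save_subject_table(subjects, path / "subjects.csv")
    for s in subjects:
        for m, ov in overlays[s.id].items():
            save_overlay(ov, path / "overlays" / overlay_filename(s.id, m))
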