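"""Anatomy-driven partial-volume correction of surface-sampled PET uptake.

At PET resolution a gray-matter vertex's apparent uptake mixes true cortical
binding with spill-in from non-specific white-matter and meningeal binding.
In a young normative group (no cortical pathology expected) all gray uptake
can be attributed to spill-in, which lets us *learn* the contamination:

1. For each subject, the white/meninges uptake field is convolved with the
   scanner point spread function (PSF) to synthesize the spill-in reaching
   each gray vertex (:func:`synthesize_spillin`).
2. Per gray vertex, observed young gray uptake is regressed on the
   synthesized spill-in across young subjects (:func:`fit_spillin_model`).
3. For a test subject, the fitted model predicts that subject's spill-in
   from their own white/meninges field, and the prediction is subtracted
   from the observed uptake (:func:`apply_pvc`).

The PSF is an isotropic Gaussian in Euclidean coordinate space, truncated at
a configurable number of sigmas, and normalized per source vertex so that
each source's activity is conserved over its local support.  Gray-to-gray
spread is not modelled (only white/meninges vertices act as sources).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .cohort import GeometryError, SurfaceGeometry, VertexOverlay

GAUSSIAN_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


class PVCError(Exception):
    pass


@dataclass(frozen=True)
class PSFModel:
    """Scanner point spread function. Only the Gaussian kind is supported."""

    kind: str = "gaussian"
    fwhm_mm: float = 6.0
    cutoff_sigmas: float = 3.5

    def __post_init__(self) -> None:
        if self.kind != "gaussian":
            raise PVCError(f"unsupported PSF kind {self.kind!r}")
        if not self.fwhm_mm > 0:
            raise PVCError("PSF FWHM must be positive")

    @property
    def sigma_mm(self) -> float:
        return self.fwhm_mm / GAUSSIAN_FWHM_TO_SIGMA


class SpillinOperator:
    """Sparse linear map from white/meninges uptake to gray-vertex spill-in.

    Building the operator is the expensive step (neighbor search over the
    geometry); it is reusable across subjects and modalities that share the
    geometry and PSF.
    """

    def __init__(self, geometry: SurfaceGeometry, psf: PSFModel):
        self.geometry = geometry
        self.psf = psf
        src = np.flatnonzero(geometry.source_mask)
        if src.size == 0:
            raise PVCError("geometry has no white/meninges vertices")
        self.source_indices = src
        live = geometry.tissue != "excluded"
        live_idx = np.flatnonzero(live)
        coords = geometry.coordinates
        sigma = psf.sigma_mm
        radius = psf.cutoff_sigmas * sigma

        tree_live = cKDTree(coords[live_idx])
        tree_src = cKDTree(coords[src])
        # neighbor lists: for every source vertex, all live vertices in range
        neigh = tree_src.query_ball_tree(tree_live, radius)
        cols, rows = [], []
        for j, lst in enumerate(neigh):
            rows.extend(lst)
            cols.extend([j] * len(lst))
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        d2 = np.sum((coords[live_idx[rows]] - coords[src[cols]]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * sigma * sigma))
        big = sparse.coo_matrix((w, (rows, cols)),
                                shape=(live_idx.size, src.size)).tocsc()
        # conserve each source's activity over its truncated local support
        colsum = np.asarray(big.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        big = big @ sparse.diags(1.0 / colsum)
        gray_rows = np.searchsorted(live_idx, geometry.gray_indices)
        self.kernel = big.tocsr()[gray_rows, :]

    def synthesize(self, values: np.ndarray) -> np.ndarray:
        """Spill-in at each gray vertex from a full-length overlay vector."""
        return self.kernel @ np.asarray(values, dtype=float)[self.source_indices]


def synthesize_spillin(overlay: VertexOverlay, geometry: SurfaceGeometry,
                       psf: PSFModel,
                       operator: SpillinOperator | None = None) -> np.ndarray:
    """PSF-weighted spill-in from white/meninges uptake at each gray vertex."""
    overlay.validate(geometry)
    op = operator if operator is not None else SpillinOperator(geometry, psf)
    return op.synthesize(overlay.values)


@dataclass
class SpillInModel:
    """Per-gray-vertex linear spill-in model (intercept + slope * synthesized)."""

    intercept: np.ndarray
    slope: np.ndarray
    degenerate: np.ndarray  # True where the regressor had no variance
    n_train: int
    psf: PSFModel

    def predict(self, synthesized: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * synthesized

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "gray_index": np.arange(self.intercept.size),
            "intercept": self.intercept,
            "slope": self.slope,
            "degenerate": self.degenerate.astype(int),
        }).to_csv(path / "coefficients.csv", index=False, float_format="%.17g")
        meta = {"n_train": self.n_train, "psf_kind": self.psf.kind,
                "psf_fwhm_mm": self.psf.fwhm_mm,
                "psf_cutoff_sigmas": self.psf.cutoff_sigmas}
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SpillInModel":
        path = Path(path)
        df = pd.read_csv(path / "coefficients.csv",
                         float_precision="round_trip")
        meta = json.loads((path / "meta.json").read_text())
        return cls(intercept=df["intercept"].to_numpy(),
                   slope=df["slope"].to_numpy(),
                   degenerate=df["degenerate"].to_numpy().astype(bool),
                   n_train=int(meta["n_train"]),
                   psf=PSFModel(kind=meta["psf_kind"], fwhm_mm=meta["psf_fwhm_mm"],
                                cutoff_sigmas=meta["psf_cutoff_sigmas"]))


def fit_spillin_model(young_overlays: list[VertexOverlay],
                      geometry: SurfaceGeometry, psf: PSFModel,
                      operator: SpillinOperator | None = None) -> SpillInModel:
    """Per-vertex OLS of observed young gray uptake on synthesized spill-in.

    Requires at least 3 normative subjects.  Vertices whose regressor is
    constant across subjects are flagged degenerate and fall back to an
    intercept-only model (slope 0, intercept = mean observed uptake).
    """
    n = len(young_overlays)
    if n < 3:
        raise PVCError(f"need >= 3 normative subjects, got {n}")
    op = operator if operator is not None else SpillinOperator(geometry, psf)
    gray = geometry.gray_mask
    X = np.empty((n, int(gray.sum())))
    Y = np.empty_like(X)
    for i, ov in enumerate(young_overlays):
        ov.validate(geometry)
        X[i] = op.synthesize(ov.values)
        Y[i] = ov.values[gray]
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    xc, yc = X - xm, Y - ym
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = np.einsum("ij,ij->j", xc, yc)
    scale = np.maximum(np.einsum("ij,ij->j", X, X), 1.0)
    degenerate = sxx <= 1e-14 * scale
    slope = np.where(degenerate, 0.0, sxy / np.where(degenerate, 1.0, sxx))
    intercept = ym - slope * xm
    return SpillInModel(intercept=intercept, slope=slope, degenerate=degenerate,
                        n_train=n, psf=psf)


def apply_pvc(overlay: VertexOverlay, model: SpillInModel,
              geometry: SurfaceGeometry, psf: PSFModel | None = None,
              operator: SpillinOperator | None = None,
              clamp_at_zero: bool = False) -> VertexOverlay:
    """Subtract the modelled spill-in from gray vertices.

    Non-gray vertices pass through unchanged.  Negative corrected values are
    retained by default (flooring at zero would bias group means); set
    ``clamp_at_zero=True`` to floor them.
    """
    overlay.validate(geometry)
    gray = geometry.gray_mask
    if model.intercept.size != int(gray.sum()):
        raise GeometryError("spill-in model does not match geometry gray count")
    op = operator if operator is not None else SpillinOperator(
        geometry, psf if psf is not None else model.psf)
    synthesized = op.synthesize(overlay.values)
    corrected = overlay.values.copy()
    corrected[gray] = overlay.values[gray] - model.predict(synthesized)
    if clamp_at_zero:
        corrected[gray] = np.maximum(corrected[gray], 0.0)
    return VertexOverlay(subject_id=overlay.subject_id,
                         modality=overlay.modality, values=corrected)
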