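"""Per-subject amyloid-tau spatial resonance and its thickness association.

Resonance is the Pearson correlation between a subject's amyloid and tau
SUVR maps across gray-matter vertices: one number per subject describing how
spatially overlapping the two pathologies are.  Amyloid and tau typically
start accumulating in different cortical territories, so resonance is low
early and rises as both pathologies spread across the cortex.

The association model adds resonance to the vertex-wise GLM while
controlling global amyloid, global tau, age, sex, and ICV, isolating the
joint (spatial-overlap) effect beyond the two linear global effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import StatMap, vertexwise_association
from .cohort import SurfaceGeometry, VertexOverlay


class ResonanceError(Exception):
    pass


@dataclass(frozen=True)
class ResonanceScore:
    subject_id: str
    r: float
    n_vertices: int
    flagged: bool = False  # zero variance in one of the maps


def resonance_score(abeta: VertexOverlay, tau: VertexOverlay,
                    geometry: SurfaceGeometry) -> ResonanceScore:
    """Pearson correlation of amyloid and tau over gray-matter vertices."""
    abeta.validate(geometry)
    tau.validate(geometry)
    a = abeta.gray_values(geometry)
    t = tau.gray_values(geometry)
    n = a.size
    if n < 3:
        raise ResonanceError("need >= 3 gray vertices")
    ac, tc = a - a.mean(), t - t.mean()
    sa = np.sqrt(float(ac @ ac))
    st = np.sqrt(float(tc @ tc))
    if sa == 0 or st == 0:
        return ResonanceScore(subject_id=abeta.subject_id, r=np.nan,
                              n_vertices=n, flagged=True)
    r = float(np.clip(float(ac @ tc) / (sa * st), -1.0, 1.0))
    return ResonanceScore(subject_id=abeta.subject_id, r=r, n_vertices=n)


def resonance_scores(overlays: dict[str, dict[str, VertexOverlay]],
                     geometry: SurfaceGeometry,
                     subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Resonance for every subject that has both PET modalities."""
    rows = []
    ids = subject_ids if subject_ids is not None else list(overlays)
    for sid in ids:
        mods = overlays[sid]
        if "abeta" in mods and "tau" in mods:
            s = resonance_score(mods["abeta"], mods["tau"], geometry)
            rows.append({"id": sid, "resonance": s.r,
                         "n_vertices": s.n_vertices, "flagged": s.flagged})
    return pd.DataFrame(rows).set_index("id")


def resonance_association(thickness: np.ndarray, panel: pd.DataFrame,
                          q: float = 0.05) -> StatMap:
    """Vertex-wise thickness ~ resonance model, controlling global amyloid,
    global tau, age, sex, and ICV.  ``panel`` must carry a ``resonance``
    column defined (finite) for all its subjects."""
    if "resonance" not in panel.columns:
        raise ResonanceError("panel lacks a resonance column")
    if not np.all(np.isfinite(panel["resonance"].to_numpy(dtype=float))):
        raise ResonanceError("resonance undefined for some subjects")
    maps = vertexwise_association(
        thickness, panel, coefficients=["resonance"],
        covariates=["global_abeta", "global_tau", "age", "sex", "icv"], q=q)
    return maps["resonance"]
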