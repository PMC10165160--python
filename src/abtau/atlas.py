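"""Probabilistic abnormality atlases and inter-regional cross-correlograms.

The probabilistic atlas answers "at this vertex, what fraction of the
group's subjects exceed the global abnormality cut-point?": per-subject maps
are binarized at the *global* cut-points (1 iff value > cut; equality is
normal) and averaged vertex-wise.  The cross-correlogram relates regional
amyloid to regional tau across subjects: entry (i, j) is the subject-wise
Pearson correlation between region i's amyloid SUVR and region j's tau SUVR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class AtlasError(Exception):
    pass


def binarize_overlay(values: np.ndarray, cut: float) -> np.ndarray:
    """1 where value strictly exceeds the cut-point, else 0."""
    if not np.isfinite(cut):
        raise AtlasError("cut-point must be finite")
    return (np.asarray(values, dtype=float) > cut).astype(np.uint8)


@dataclass
class ProbAtlas:
    group: str
    modality: str
    probability: np.ndarray
    n_subjects: int


def probabilistic_atlas(binarized_maps: list[np.ndarray], group: str = "",
                        modality: str = "") -> ProbAtlas:
    """Vertex-wise fraction of subjects with abnormal (binarized = 1) uptake."""
    if len(binarized_maps) == 0:
        raise AtlasError("probabilistic atlas of an empty group")
    stack = np.asarray(binarized_maps, dtype=float)
    return ProbAtlas(group=group, modality=modality,
                     probability=stack.mean(axis=0),
                     n_subjects=stack.shape[0])


@dataclass
class CrossCorrelogram:
    group: str
    matrix: pd.DataFrame  # rows: amyloid regions, columns: tau regions
    n_subjects: int


def _rank(a: np.ndarray) -> np.ndarray:
    return pd.DataFrame(a).rank(axis=0).to_numpy()


def cross_correlogram(abeta_regions: pd.DataFrame, tau_regions: pd.DataFrame,
                      subjects: list[str], group: str = "",
                      method: str = "pearson") -> CrossCorrelogram:
    """Subject-wise correlation of every (amyloid region, tau region) pair.

    Requires >= 3 subjects.  Zero-variance regions yield NaN entries
    (undefined, never coerced to 0).  ``method`` is ``pearson`` (default) or
    ``spearman``.
    """
    if len(subjects) < 3:
        raise AtlasError(f"need >= 3 subjects for a correlogram, got {len(subjects)}")
    A = abeta_regions.loc[subjects].to_numpy(dtype=float)
    T = tau_regions.loc[subjects].to_numpy(dtype=float)
    if method == "spearman":
        A, T = _rank(A), _rank(T)
    elif method != "pearson":
        raise AtlasError(f"unknown correlation method {method!r}")
    n = A.shape[0]
    Ac = A - A.mean(axis=0)
    Tc = T - T.mean(axis=0)
    sa = np.sqrt((Ac ** 2).sum(axis=0))
    st = np.sqrt((Tc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Ac.T @ Tc) / np.outer(sa, st)
    corr[np.outer(sa == 0, np.ones(st.size, bool))] = np.nan
    corr[np.outer(np.ones(sa.size, bool), st == 0)] = np.nan
    mat = pd.DataFrame(corr, index=abeta_regions.columns, columns=tau_regions.columns)
    return CrossCorrelogram(group=group, matrix=mat, n_subjects=n)
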