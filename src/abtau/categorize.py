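"""Normative cut-points and four-group amyloid/tau categorization.

A normal distribution is fitted (moment matching: sample mean and SD) to the
young cohort's composite SUVRs; the abnormality cut-point is a percentile of
that fitted normal (default: the 96th, z = 1.7507).  An old subject is
amyloid-abnormal when global amyloid SUVR strictly exceeds its cut-point, and
tau-abnormal when *either* global tau or MTL tau exceeds its cut-point (the
MTL composite catches early, spatially confined tangle pathology).  The cross
of the two binary flags yields four groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("nAb/nTau", "aAb/nTau", "nAb/aTau", "aAb/aTau")
MARKERS = ("global_abeta", "global_tau", "mtl_tau")


class CategorizeError(Exception):
    pass


@dataclass(frozen=True)
class ReferenceDistribution:
    """Fitted young-cohort normal for one composite marker."""

    marker: str
    mu: float
    sigma: float
    n_young: int
    normality_p: float


@dataclass(frozen=True)
class CutPoints:
    """Abnormality thresholds with the reference fits that produced them."""

    abeta_global: float
    tau_global: float
    tau_mtl: float
    percentile: float = 96.0
    provenance: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CutPoints":
        return cls(**json.loads(Path(path).read_text()))


#: Published thresholds for users reproducing the original categorization
#: without access to young normative data.
PUBLISHED_CUTPOINTS = CutPoints(abeta_global=1.256, tau_global=1.150,
                                tau_mtl=1.110, percentile=96.0,
                                provenance={"source": "published"})


def fit_reference(young_values, alpha: float = 0.05,
                  marker: str = "global_abeta") -> ReferenceDistribution:
    """Moment-matched normal fit to young composite values.

    Emits a warning (does not fail) when a Shapiro-Wilk test rejects
    normality at ``alpha``.  Requires at least 10 values.
    """
    values = np.asarray(young_values, dtype=float)
    if values.size < 10:
        raise CategorizeError(f"need >= 10 young values, got {values.size}")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    if sigma > 0:
        p = float(stats.shapiro(values).pvalue)
    else:
        p = 1.0
    if p <= alpha:
        warnings.warn(
            f"young {marker} values fail normality (Shapiro-Wilk p={p:.3g}); "
            "the percentile cut-point assumes a normal reference",
            UserWarning, stacklevel=2)
    return ReferenceDistribution(marker=marker, mu=mu, sigma=sigma,
                                 n_young=int(values.size), normality_p=p)


def derive_cutpoint(ref: ReferenceDistribution, percentile: float = 96.0) -> float:
    """mu + z(percentile/100) * sigma of the fitted reference."""
    if not 0.0 < percentile < 100.0:
        raise CategorizeError("percentile must be in (0, 100)")
    return ref.mu + float(stats.norm.ppf(percentile / 100.0)) * ref.sigma


def derive_cutpoints(abeta_ref: ReferenceDistribution,
                     tau_ref: ReferenceDistribution,
                     mtl_ref: ReferenceDistribution,
                     percentile: float = 96.0) -> CutPoints:
    prov = {r.marker: asdict(r) for r in (abeta_ref, tau_ref, mtl_ref)}
    return CutPoints(
        abeta_global=derive_cutpoint(abeta_ref, percentile),
        tau_global=derive_cutpoint(tau_ref, percentile),
        tau_mtl=derive_cutpoint(mtl_ref, percentile),
        percentile=percentile, provenance=prov)


def assign_group(global_abeta: float, global_tau: float, mtl_tau: float,
                 cuts: CutPoints) -> str:
    """Four-group label from the three composites (strict '>' at cut-points)."""
    for name, v in (("global_abeta", global_abeta), ("global_tau", global_tau),
                    ("mtl_tau", mtl_tau)):
        if v is None or not np.isfinite(v):
            raise CategorizeError(f"missing composite {name}")
    abeta_abn = global_abeta > cuts.abeta_global
    tau_abn = (global_tau > cuts.tau_global) or (mtl_tau > cuts.tau_mtl)
    return GROUPS[int(abeta_abn) + 2 * int(tau_abn)]


def assign_groups(panel: pd.DataFrame, cuts: CutPoints) -> pd.Series:
    """Vectorized group labels for a composite panel (old subjects)."""
    labels = [assign_group(row["global_abeta"], row["global_tau"],
                           row["mtl_tau"], cuts)
              for _, row in panel.iterrows()]
    return pd.Series(labels, index=panel.index, name="group")


def group_share_report(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentage bookkeeping over the four-group x diagnosis cross-table.

    ``counts`` is indexed by group label with integer columns ``HC`` and
    ``MCI``.  Returns per-group totals plus each group's share of all old
    subjects, of HC subjects, and of MCI subjects, in percent.
    """
    out = counts.copy().astype(float)
    out["n"] = out["HC"] + out["MCI"]
    total, hc, mci = out["n"].sum(), out["HC"].sum(), out["MCI"].sum()
    out["pct_of_all"] = 100.0 * out["n"] / total
    out["pct_of_hc"] = 100.0 * out["HC"] / hc
    out["pct_of_mci"] = 100.0 * out["MCI"] / mci
    return out
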