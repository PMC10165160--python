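"""Mass-univariate association models with FDR and permutation-based FWE.

Three layers:

* :func:`fit_glm` / :func:`fit_glm_batch` — ordinary least squares with
  per-coefficient t statistics and two-sided p-values from the t
  distribution with the design's residual degrees of freedom.  The batch
  variant fits every vertex at once against a shared design matrix (standard
  mass-univariate practice).
* :func:`vertexwise_association` — the vertex-wise model
  ``thickness ~ global_abeta + global_tau (+ resonance) + age + sex + icv``
  with Benjamini-Hochberg FDR over gray vertices.
* :func:`residualize` / :func:`regional_association` /
  :func:`permutation_fwe` — the two-step regional analysis: thickness is
  first residualized on nuisance covariates (and the non-target pathology),
  then regressed on the target regional uptake; family-wise error control
  comes from an empirical t null built by shuffling the regressor, with a
  normal fitted to the null sample and thresholds taken at its 5th and 95th
  percentiles (a stricter 2.5/97.5 option is available).

Sex enters design matrices coded M=0, F=1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _all_permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SEX_CODES = {"M": 0.0, "F": 1.0}


class AssociationError(Exception):
    pass


def build_design(panel: pd.DataFrame, columns: list[str],
                 add_intercept: bool = True) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix from panel columns (sex coded M=0, F=1)."""
    cols, names = [], []
    if add_intercept:
        cols.append(np.ones(len(panel)))
        names.append("intercept")
    for c in columns:
        v = panel[c]
        if c == "sex":
            v = v.map(SEX_CODES)
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise AssociationError(f"design column {c!r} has missing values")
        cols.append(arr)
        names.append(c)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    n, k = X.shape
    if n <= k + 2:
        raise AssociationError(f"need n > k + 2 subjects (n={n}, k={k})")
    r = np.linalg.matrix_rank(X)
    if r < k:
        # name the offending columns via QR pivoting on correlations
        _, Rq = np.linalg.qr(X)
        bad = [names[j] for j in range(k)
               if abs(Rq[j, j]) < 1e-8 * max(1.0, abs(Rq[0, 0]))]
        raise AssociationError(f"design matrix rank deficient; collinear "
                               f"columns: {bad or names}")


@dataclass
class GLMResult:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    zero_residual: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "se": self.se,
                             "t": self.t, "p": self.p}, index=self.names)


def fit_glm(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> GLMResult:
    """OLS of a single response on a full-rank design.

    t = beta / SE(beta); p two-sided from t(n - k).  Zero residual variance
    (exact fit) reports t = +/-inf with the ``zero_residual`` flag set.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = names or [f"x{j}" for j in range(X.shape[1])]
    _check_rank(X, names)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    ss = float(resid @ resid)
    scale = max(float(y @ y), 1.0)
    zero_resid = ss <= 1e-24 * scale
    sigma2 = ss / df
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.where(beta > 0, np.inf, np.where(beta < 0, -np.inf, 0.0)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return GLMResult(names=names, beta=beta, se=se, t=t, p=p,
                     df_resid=df, zero_residual=zero_resid)


def fit_glm_batch(Y: np.ndarray, X: np.ndarray,
                  names: list[str] | None = None) -> dict:
    """OLS of many responses (columns of Y, n x V) on one shared design.

    Returns dict with ``beta, t, p`` of shape (k, V), ``df_resid``, and a
    ``degenerate`` (V,) mask where the residual variance was (numerically)
    zero, making t ill-defined.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = names or [f"x{j}" for j in range(X.shape[1])]
    _check_rank(X, names)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)                       # (k, V)
    resid = Y - X @ beta
    df = n - k
    ss = np.einsum("ij,ij->j", resid, resid)
    scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
    degenerate = ss <= 1e-24 * scale
    sigma2 = ss / df
    var = np.outer(np.diag(XtX_inv), sigma2)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.sign(beta) * np.inf)
        t = np.where(np.isnan(t), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return {"names": names, "beta": beta, "t": t, "p": p,
            "df_resid": df, "degenerate": degenerate}


def fdr_correct(p_values: np.ndarray, q: float = 0.05,
                method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q.

    ``method='fdr_by'`` switches to Benjamini-Yekutieli.  NaN entries (for
    excluded vertices) are never rejected and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    if valid.any():
        mask[valid] = multipletests(p[valid], alpha=q, method=method)[0]
    return mask


@dataclass
class StatMap:
    """Per-vertex coefficient map with its multiplicity correction."""

    name: str
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    sig_mask: np.ndarray
    valid_mask: np.ndarray
    q: float
    method: str = "fdr_bh"

    @property
    def n_sig_pos(self) -> int:
        return int(np.sum(self.sig_mask & (self.t > 0)))

    @property
    def n_sig_neg(self) -> int:
        return int(np.sum(self.sig_mask & (self.t < 0)))


def vertexwise_association(thickness: np.ndarray, panel: pd.DataFrame,
                           coefficients: list[str],
                           covariates: list[str] = ("age", "sex", "icv"),
                           q: float = 0.05, method: str = "fdr_bh") -> dict[str, StatMap]:
    """Vertex-wise GLM of thickness on the listed predictors plus covariates.

    ``thickness`` is (n_subjects, n_gray_vertices) in panel row order.  One
    FDR-corrected :class:`StatMap` is returned per coefficient of interest.
    Vertices with degenerate fits are excluded from the multiple-testing
    count m and never flagged significant.
    """
    X, names = build_design(panel, list(coefficients) + list(covariates))
    fit = fit_glm_batch(thickness, X, names)
    valid = ~fit["degenerate"]
    out = {}
    for name in coefficients:
        j = names.index(name)
        p = np.where(valid, fit["p"][j], np.nan)
        mask = fdr_correct(p, q=q, method=method)
        out[name] = StatMap(name=name, beta=fit["beta"][j], t=fit["t"][j],
                            p=fit["p"][j], df_resid=fit["df_resid"],
                            sig_mask=mask, valid_mask=valid, q=q, method=method)
    return out


def residualize(values: np.ndarray, nuisance: np.ndarray,
                names: list[str] | None = None) -> np.ndarray:
    """OLS residuals of values (vector or n x V matrix) on a nuisance design."""
    X = np.asarray(nuisance, dtype=float)
    names = names or [f"x{j}" for j in range(X.shape[1])]
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        raise AssociationError("nuisance design is rank deficient")
    v = np.asarray(values, dtype=float)
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def _slope_t(x: np.ndarray, y: np.ndarray) -> float:
    """t of the slope in simple regression y ~ 1 + x, via the correlation."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0:
        raise AssociationError("zero-variance regressor")
    if sy == 0:
        return 0.0
    r = float(xc @ yc) / (sx * sy)
    r = min(1.0, max(-1.0, r))
    df = n - 2
    if abs(r) >= 1.0:
        return math.inf if r > 0 else -math.inf
    return r * math.sqrt(df / (1.0 - r * r))


@dataclass(frozen=True)
class PermThresholds:
    t_low: float
    t_high: float
    null_mean: float
    null_sd: float
    n_perm: int


def permutation_fwe(x: np.ndarray, y: np.ndarray, n_perm: int = 10000,
                    seed: int | None = None,
                    percentiles: tuple[float, float] = (5.0, 95.0),
                    exact: bool = False) -> PermThresholds:
    """Empirical-null t thresholds by shuffling the independent variable.

    Only ``x`` is permuted (the response and any upstream residualization
    stay fixed).  A normal distribution is fitted to the null t sample and
    the thresholds are its 5th and 95th percentiles by default (note this
    convention spends ~5% in each tail; pass ``percentiles=(2.5, 97.5)`` for
    a strict two-sided 5% family-wise level).  ``exact=True`` enumerates all
    n! permutations instead of Monte-Carlo sampling (tiny n only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.allclose(y, y[0]):
        raise AssociationError("degenerate (constant) response")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0:
        raise AssociationError("zero-variance regressor")
    df = n - 2

    def t_from_r(r: np.ndarray) -> np.ndarray:
        r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
        return r * np.sqrt(df / (1.0 - r * r))

    if exact:
        perms = np.array(list(_all_permutations(range(n))))
    else:
        if n_perm < 100:
            raise AssociationError("need n_perm >= 100")
        rng = np.random.default_rng(seed)
        perms = rng.random((n_perm, n)).argsort(axis=1)
    r_null = (xc[perms] @ yc) / (sx * sy)
    t_null = t_from_r(r_null)
    mu, sd = float(t_null.mean()), float(t_null.std(ddof=1))
    lo = float(stats.norm.ppf(percentiles[0] / 100.0, loc=mu, scale=sd))
    hi = float(stats.norm.ppf(percentiles[1] / 100.0, loc=mu, scale=sd))
    return PermThresholds(t_low=lo, t_high=hi, null_mean=mu, null_sd=sd,
                          n_perm=len(perms))


@dataclass
class RegionalStat:
    region: str
    t: float
    p: float
    t_low: float
    t_high: float
    survived: bool
    flagged: bool = False  # degenerate regressor or exact fit


def regional_association(residual_thickness: np.ndarray, regional_uptake: np.ndarray,
                         n_perm: int = 10000, seed: int | None = None,
                         region: str = "",
                         percentiles: tuple[float, float] = (5.0, 95.0)) -> RegionalStat:
    """Simple regression of residualized thickness on regional uptake, with
    permutation FWE thresholds.  Requires >= 10 subjects."""
    y = np.asarray(residual_thickness, dtype=float)
    x = np.asarray(regional_uptake, dtype=float)
    if y.size < 10:
        raise AssociationError(f"need >= 10 subjects, got {y.size}")
    if np.allclose(x, x[0]):
        return RegionalStat(region=region, t=np.nan, p=np.nan, t_low=np.nan,
                            t_high=np.nan, survived=False, flagged=True)
    t = _slope_t(x, y)
    df = y.size - 2
    if math.isinf(t):
        return RegionalStat(region=region, t=t, p=0.0, t_low=np.nan,
                            t_high=np.nan, survived=True, flagged=True)
    p = float(2.0 * stats.t.sf(abs(t), df))
    thr = permutation_fwe(x, y, n_perm=n_perm, seed=seed, percentiles=percentiles)
    survived = bool(t < thr.t_low or t > thr.t_high)
    return RegionalStat(region=region, t=t, p=p, t_low=thr.t_low,
                        t_high=thr.t_high, survived=survived)
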