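import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abtau.association import (AssociationError, build_design, fdr_correct,
                               fit_glm, fit_glm_batch, permutation_fwe,
                               regional_association, residualize,
                               vertexwise_association)


def test_build_design_codes_sex():
    panel = pd.DataFrame({"age": [60.0, 70.0], "sex": ["M", "F"],
                          "icv": [1.5e6, 1.4e6]})
    X, names = build_design(panel, ["age", "sex", "icv"])
    assert names == ["intercept", "age", "sex", "icv"]
    np.testing.assert_array_equal(X[:, 2], [0.0, 1.0])
    panel.loc[0, "age"] = np.nan
    with pytest.raises(AssociationError):
        build_design(panel, ["age"])


def test_fit_glm_exact_fit():
    x = np.arange(5.0)
    y = 1.0 + 2.0 * x
    X = np.column_stack([np.ones(5), x])
    res = fit_glm(y, X, ["intercept", "x"])
    np.testing.assert_allclose(res.beta, [1.0, 2.0], atol=1e-12)
    assert res.zero_residual
    assert res.df_resid == 3


def test_fit_glm_textbook_oracle():
    """Simple regression coefficients/t from the closed-form formulas."""
    x = np.arange(5.0)
    y = np.array([1.0, 3.1, 4.9, 7.2, 8.8])
    X = np.column_stack([np.ones(5), x])
    res = fit_glm(y, X, ["intercept", "x"])

    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid ** 2).sum() / (5 - 2)
    se_slope = np.sqrt(s2 / sxx)
    np.testing.assert_allclose(res.beta, [intercept, slope], atol=1e-12)
    assert res.t[1] == pytest.approx(slope / se_slope, abs=1e-10)
    lr = stats.linregress(x, y)  # independent implementation
    assert res.beta[1] == pytest.approx(lr.slope, abs=1e-12)
    assert res.p[1] == pytest.approx(lr.pvalue, abs=1e-12)


def test_fit_glm_design_guards():
    X = np.column_stack([np.ones(8), np.arange(8.0), 2 * np.arange(8.0)])
    with pytest.raises(AssociationError, match="rank deficient"):
        fit_glm(np.arange(8.0), X, ["intercept", "x", "x2"])
    with pytest.raises(AssociationError, match="n > k"):
        fit_glm(np.arange(4.0), np.column_stack([np.ones(4), np.arange(4.0)]))


def test_fit_glm_batch_matches_single():
    rng = np.random.default_rng(0)
    n, k, v = 40, 3, 25
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    Y = rng.normal(size=(n, v))
    batch = fit_glm_batch(Y, X)
    for j in rng.choice(v, 8, replace=False):
        single = fit_glm(Y[:, j], X)
        np.testing.assert_allclose(batch["beta"][:, j], single.beta,
                                   atol=1e-10)
        np.testing.assert_allclose(batch["t"][:, j], single.t, atol=1e-8)
        np.testing.assert_allclose(batch["p"][:, j], single.p, atol=1e-10)
    assert batch["df_resid"] == n - k


def test_fdr_hand_case():
    # BH at q=0.05 on [0.01, 0.02, 0.04, 0.20]: thresholds i*q/m =
    # 0.0125, 0.025, 0.0375, 0.05 -> largest k with p(k) <= thr is k=2
    mask = fdr_correct(np.array([0.01, 0.02, 0.04, 0.20]), q=0.05)
    np.testing.assert_array_equal(mask, [True, True, False, False])


def test_fdr_nan_excluded_from_m():
    p = np.array([0.012, np.nan, np.nan])
    # with m=1 effective test, 0.012 < 0.05 rejects; NaN never rejected
    mask = fdr_correct(p, q=0.05)
    np.testing.assert_array_equal(mask, [True, False, False])


def test_fdr_null_rarely_rejects():
    rng = np.random.default_rng(7)
    any_rej = 0
    reps = 200
    for _ in range(reps):
        p = rng.uniform(size=100)
        any_rej += fdr_correct(p, q=0.05).any()
    # under the global null, P(any BH rejection) <= q
    assert any_rej / reps <= 0.10


def test_fdr_by_is_more_conservative():
    rng = np.random.default_rng(8)
    p = np.concatenate([rng.uniform(0, 1e-3, 5), rng.uniform(size=95)])
    bh = fdr_correct(p, q=0.05, method="fdr_bh").sum()
    by = fdr_correct(p, q=0.05, method="fdr_by").sum()
    assert by <= bh


def test_residualize_orthogonality():
    rng = np.random.default_rng(1)
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    y = rng.normal(size=n)
    r = residualize(y, X)
    np.testing.assert_allclose(X.T @ r, 0.0, atol=1e-9)
    Y = rng.normal(size=(n, 5))
    R = residualize(Y, X)
    np.testing.assert_allclose(X.T @ R, 0.0, atol=1e-9)
    with pytest.raises(AssociationError):
        residualize(y, np.column_stack([X, X[:, 1]]))


def test_vertexwise_association_recovers_planted_effect():
    rng = np.random.default_rng(2)
    n, v = 120, 50
    panel = pd.DataFrame({
        "global_abeta": rng.normal(1.2, 0.1, n),
        "global_tau": rng.normal(1.0, 0.1, n),
        "age": rng.normal(70, 5, n),
        "sex": rng.choice(["M", "F"], n),
        "icv": rng.normal(1.5e6, 1e5, n),
    })
    beta_true = 2.0
    thickness = (2.5 - 0.01 * (panel["age"].to_numpy()[:, None] - 70)
                 + rng.normal(0, 0.05, (n, v)))
    thickness[:, :10] += beta_true * (
        panel["global_tau"].to_numpy()[:, None] - 1.0)
    maps = vertexwise_association(thickness, panel,
                                  ["global_abeta", "global_tau"])
    tau_map = maps["global_tau"]
    assert tau_map.sig_mask[:10].all()
    assert (tau_map.t[:10] > 0).all()
    assert tau_map.sig_mask[10:].sum() <= 2  # near-null elsewhere
    assert maps["global_abeta"].sig_mask.sum() <= 2
    np.testing.assert_allclose(tau_map.beta[:10], beta_true, atol=0.3)


def test_permutation_fwe_exact_enumeration_matches_oracle():
    x = np.array([0.1, 0.9, 0.4, 0.7, 0.2, 0.6])
    y = np.array([1.0, 2.2, 1.4, 2.0, 1.1, 1.9])
    thr = permutation_fwe(x, y, exact=True)
    assert thr.n_perm == 720  # 6!

    # independent enumeration of the null t distribution
    from itertools import permutations
    ts = []
    for perm in permutations(range(6)):
        r = stats.pearsonr(x[list(perm)], y)[0]
        ts.append(r * np.sqrt(4 / (1 - r ** 2)))
    ts = np.asarray(ts)
    mu, sd = ts.mean(), ts.std(ddof=1)
    assert thr.null_mean == pytest.approx(mu, abs=1e-10)
    assert thr.null_sd == pytest.approx(sd, abs=1e-10)
    assert thr.t_low == pytest.approx(stats.norm.ppf(0.05, mu, sd), abs=1e-10)
    assert thr.t_high == pytest.approx(stats.norm.ppf(0.95, mu, sd), abs=1e-10)


def test_permutation_fwe_monte_carlo_close_to_exact():
    rng = np.random.default_rng(3)
    x = rng.normal(size=7)
    y = rng.normal(size=7)
    exact = permutation_fwe(x, y, exact=True)
    mc = permutation_fwe(x, y, n_perm=20000, seed=11)
    assert mc.t_low == pytest.approx(exact.t_low, abs=0.15)
    assert mc.t_high == pytest.approx(exact.t_high, abs=0.15)


def test_permutation_fwe_deterministic_given_seed():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=30), rng.normal(size=30)
    a = permutation_fwe(x, y, n_perm=500, seed=9)
    b = permutation_fwe(x, y, n_perm=500, seed=9)
    assert a == b
    c = permutation_fwe(x, y, n_perm=500, seed=10)
    assert c != a


def test_permutation_fwe_guards():
    rng = np.random.default_rng(5)
    y = rng.normal(size=12)
    with pytest.raises(AssociationError):
        permutation_fwe(np.ones(12), y)  # constant x
    with pytest.raises(AssociationError):
        permutation_fwe(rng.normal(size=12), np.full(12, 2.0))  # constant y
    with pytest.raises(AssociationError):
        permutation_fwe(rng.normal(size=12), y, n_perm=50)


def test_permutation_fwe_strict_percentiles_widen_thresholds():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=25), rng.normal(size=25)
    lenient = permutation_fwe(x, y, n_perm=2000, seed=1)
    strict = permutation_fwe(x, y, n_perm=2000, seed=1,
                             percentiles=(2.5, 97.5))
    assert strict.t_low < lenient.t_low
    assert strict.t_high > lenient.t_high


def test_regional_association_detects_planted_slope():
    rng = np.random.default_rng(12)
    n = 80
    x = rng.normal(1.2, 0.2, n)
    y = -0.8 * (x - x.mean()) + rng.normal(0, 0.1, n)
    stat = regional_association(y, x, n_perm=2000, seed=0, region="L_insula")
    assert stat.t < 0 and stat.survived and not stat.flagged
    assert stat.region == "L_insula"
    assert stat.p < 1e-6


def test_regional_association_null_usually_not_survived():
    rng = np.random.default_rng(13)
    survived = 0
    for i in range(30):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        survived += regional_association(y, x, n_perm=1000, seed=i).survived
    assert survived <= 10  # ~10% two-tailed at the 5/95 convention


def test_regional_association_flags():
    rng = np.random.default_rng(14)
    y = rng.normal(size=20)
    flagged = regional_association(y, np.ones(20), n_perm=200, seed=0)
    assert flagged.flagged and not flagged.survived and np.isnan(flagged.t)
    x = np.arange(20.0)
    exact = regional_association(2 * x, x, n_perm=200, seed=0)
    assert exact.flagged and exact.survived and np.isinf(exact.t)
    with pytest.raises(AssociationError):
        regional_association(y[:5], x[:5])
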