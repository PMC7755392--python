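import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import volatility_learner as vl
from volatility_learner import bifactor as bf
from volatility_learner.synth import default_thresholds, make_bifactor_loadings


# ---------------------------------------------------------------------------
# Category collapsing


def test_sparse_extreme_category_merges_inward():
    x = np.array([0] * 50 + [1] * 49 + [2] * 1)
    items = pd.DataFrame({"a": x})
    out = bf.collapse_sparse_categories(items, threshold=0.02)
    freq = out["a"].value_counts(normalize=True).sort_index()
    assert freq.tolist() == [0.5, 0.5]
    assert out["a"].max() == 1


def test_well_endorsed_items_unchanged():
    x = np.array([0] * 30 + [1] * 40 + [2] * 30)
    items = pd.DataFrame({"a": x})
    out = bf.collapse_sparse_categories(items)
    assert (out["a"].to_numpy() == x).all()


def test_degenerate_single_category_item_dropped_with_warning():
    items = pd.DataFrame({"a": [0] * 100, "b": [0] * 50 + [1] * 50})
    with pytest.warns(UserWarning, match="single-category"):
        out = bf.collapse_sparse_categories(items)
    assert list(out.columns) == ["b"]


def test_collapsing_reindexes_contiguously():
    x = np.array([0] * 60 + [2] * 39 + [4] * 1)
    out = bf.collapse_sparse_categories(pd.DataFrame({"a": x}))
    assert sorted(out["a"].unique()) == [0, 1]


# ---------------------------------------------------------------------------
# Polychoric correlation


def _ordinal_pair(rho, n, seed, cuts1, cuts2):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = np.searchsorted(cuts1, z[:, 0])
    y = np.searchsorted(cuts2, z[:, 1])
    return x, y


@pytest.mark.parametrize("rho", [0.5, 0.0, -0.4])
def test_polychoric_recovers_generating_correlation(rho):
    x, y = _ordinal_pair(rho, 50_000, seed=abs(hash(rho)) % 2**31,
                         cuts1=[0.3], cuts2=[-0.2, 0.8])
    est = bf.polychoric_pair(x, y)
    assert est == pytest.approx(rho, abs=0.03)


def test_polychoric_matrix_diagonal_and_symmetry():
    rng = np.random.default_rng(0)
    items = pd.DataFrame(rng.integers(0, 3, size=(300, 4)),
                         columns=list("abcd"))
    R = vl.polychoric_correlation(items)
    np.testing.assert_allclose(np.diag(R), 1.0)
    np.testing.assert_allclose(R, R.T)
    assert (R.to_numpy() <= 1).all() and (R.to_numpy() >= -1).all()


def test_bivariate_normal_cdf_against_scipy():
    from scipy.stats import multivariate_normal

    h = np.array([-1.0, 0.0, 0.7])
    k = np.array([-0.5, 1.2])
    for rho in (-0.6, 0.3, 0.9):
        got = bf._bvn_cdf_grid(h, k, rho)
        mvn = multivariate_normal([0, 0], [[1, rho], [rho, 1]])
        want = np.array([[mvn.cdf([hi, ki]) for ki in k] for hi in h])
        np.testing.assert_allclose(got, want, atol=1e-8)


def test_nearest_psd_smoothing():
    R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    assert np.linalg.eigvalsh(R).min() < 0
    S = bf.nearest_psd_correlation(R)
    assert np.linalg.eigvalsh(S).min() >= 0
    np.testing.assert_allclose(np.diag(S), 1.0)


# ---------------------------------------------------------------------------
# Parallel analysis


def test_identity_correlation_retains_nothing():
    n_ret, _ = vl.parallel_analysis(np.eye(20), n_subjects=500, seed=1)
    assert n_ret == 0


def test_parallel_analysis_deterministic_given_seed():
    R = np.eye(10)
    _, t1 = vl.parallel_analysis(R, 200, seed=3)
    _, t2 = vl.parallel_analysis(R, 200, seed=3)
    pd.testing.assert_frame_equal(t1, t2)


# ---------------------------------------------------------------------------
# Schmid-Leiman on exactly-structured matrices


def _exact_bifactor_R(L):
    uniq = 1.0 - (L**2).sum(axis=1)
    return L @ L.T + np.diag(uniq)


def test_schmid_leiman_recovers_planted_orthogonal_structure():
    L = make_bifactor_loadings(n_items=40, seed=3)
    R = _exact_bifactor_R(L)
    sol = vl.schmid_leiman(R, n_specific=2)
    cong = vl.factor_congruence(sol.loadings, L)
    assert (cong >= 0.98).all()


def test_schmid_leiman_identity_matrix_gives_null_loadings():
    sol = vl.schmid_leiman(np.eye(12), n_specific=2)
    assert np.abs(sol.loadings.to_numpy()).max() < 0.1


def test_schmid_leiman_variance_partition():
    # communality equals the sum of squared orthogonalized loadings (the
    # defining variance-partition identity of the transform)
    L = make_bifactor_loadings(n_items=30, seed=9)
    R = _exact_bifactor_R(L)
    sol = vl.schmid_leiman(R, n_specific=2)
    h2_sl = (sol.loadings**2).sum(axis=1)
    np.testing.assert_allclose(h2_sl, sol.communalities, atol=1e-4)


def test_schmid_leiman_requires_two_specifics():
    with pytest.raises(ValueError):
        vl.schmid_leiman(np.eye(5), n_specific=1)


# ---------------------------------------------------------------------------
# Anderson-Rubin scores


@pytest.fixture(scope="module")
def planted_battery():
    L = make_bifactor_loadings(n_items=48, seed=21)
    obs, lat = vl.simulate_item_responses(
        L, default_thresholds(48, seed=21), n_subjects=500, seed=22
    )
    obs = vl.collapse_sparse_categories(obs)
    R = vl.polychoric_correlation(obs)
    sol = vl.schmid_leiman(R, n_specific=2)
    return L, obs, lat, R, sol


def test_scores_are_orthonormal_on_estimation_sample(planted_battery):
    _, obs, _, R, sol = planted_battery
    scores = vl.anderson_rubin_scores(obs, R, sol)
    C = np.cov(scores.frame.to_numpy(), rowvar=False, ddof=0)
    np.testing.assert_allclose(C, np.eye(3), atol=0.05)


def test_scores_recover_latent_factors(planted_battery):
    _, obs, lat, R, sol = planted_battery
    refined = vl.refine_pattern(R, sol)
    scores = vl.anderson_rubin_scores(obs, R, refined)
    for f in scores.frame.columns:
        r = max(abs(np.corrcoef(scores.frame[f], lat[c])[0, 1])
                for c in lat.columns)
        assert r >= 0.75, f
    # the general factor is the best-measured dimension
    r_gen = max(abs(np.corrcoef(scores.frame["general"], lat[c])[0, 1])
                for c in lat.columns)
    assert r_gen >= 0.85


def test_scoring_is_linear_in_responses(planted_battery):
    _, obs, _, R, sol = planted_battery
    scores = vl.anderson_rubin_scores(obs, R, sol)
    # a subject moved one SD up on every item moves monotonically on the
    # general factor (all-positive general weights)
    W = bf._ar_weights(
        bf.scoring_loadings(sol).to_numpy(),
        np.clip(sol.uniquenesses.to_numpy(), 1e-3, None),
        np.corrcoef(((obs - obs.mean()) / obs.std(ddof=0)).to_numpy(),
                    rowvar=False),
    )
    shift = W.sum(axis=0)[0]
    assert shift > 0


def test_subset_scoring_consistency(planted_battery):
    _, obs, _, R, sol = planted_battery
    full = vl.anderson_rubin_scores(obs, R, sol)
    # identical item set: same scores up to the whitening sample
    same = vl.score_with_item_subset(sol, obs)
    r = np.corrcoef(full.frame["general"], same.frame["general"])[0, 1]
    assert r > 0.999
    # a half battery still recovers the general factor well
    half = vl.score_with_item_subset(sol, obs[obs.columns[:30]])
    r_half = np.corrcoef(full.frame["general"], half.frame["general"])[0, 1]
    assert r_half >= 0.9
    with pytest.raises(ValueError):
        vl.score_with_item_subset(sol, obs[[]])


def test_subset_scoring_rejects_unknown_items(planted_battery):
    _, obs, _, _, sol = planted_battery
    bad = obs.copy()
    bad["not_an_item"] = 1
    with pytest.raises(ValueError, match="absent"):
        vl.score_with_item_subset(sol, bad)


# ---------------------------------------------------------------------------
# Congruence


def test_congruence_identity_and_sign_invariance():
    L = make_bifactor_loadings(n_items=20, seed=2)
    assert (vl.factor_congruence(pd.DataFrame(L), L) >= 0.9999).all()
    assert (vl.factor_congruence(pd.DataFrame(L), -L) >= 0.9999).all()


def test_congruence_of_random_loadings_is_low():
    rng = np.random.default_rng(5)
    L = make_bifactor_loadings(n_items=128, seed=4)
    rand = rng.standard_normal(L.shape)
    cong = vl.factor_congruence(pd.DataFrame(L), rand)
    assert cong.mean() < 0.5


def test_congruence_requires_matching_items():
    with pytest.raises(ValueError):
        vl.factor_congruence(np.ones((5, 2)), np.ones((6, 2)))
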