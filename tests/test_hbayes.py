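import warnings

import numpy as np
import pandas as pd
import pytest

import volatility_learner as vl
from volatility_learner import hbayes
from volatility_learner.hbayes import credible, hdi
from volatility_learner.models import LINKS


# ---------------------------------------------------------------------------
# HDI and credibility


def test_uniform_hdi_width():
    rng = np.random.default_rng(0)
    lo, hi = hdi(rng.uniform(0, 1, 40_000), mass=0.95)
    assert hi - lo == pytest.approx(0.95, abs=0.02)


def test_symmetric_hdi_matches_equal_tailed():
    rng = np.random.default_rng(1)
    draws = rng.standard_normal(40_000)
    lo, hi = hdi(draws, 0.95)
    assert lo == pytest.approx(np.quantile(draws, 0.025), abs=0.05)
    assert hi == pytest.approx(np.quantile(draws, 0.975), abs=0.05)


def test_constant_draws_give_zero_width_interval():
    lo, hi = hdi(np.full(500, 1.3))
    assert lo == hi == pytest.approx(1.3)


def test_hdi_rejects_empty_input():
    with pytest.raises(ValueError):
        hdi([])


def test_hdi_agrees_with_arviz():
    import arviz as az

    rng = np.random.default_rng(3)
    draws = rng.gamma(2.0, 1.0, size=20_000)
    lo, hi = hdi(draws, 0.95)
    ref = az.hdi(draws, hdi_prob=0.95)
    assert lo == pytest.approx(ref[0], abs=0.03)
    assert hi == pytest.approx(ref[1], abs=0.03)


@pytest.mark.parametrize("interval,expected", [
    ((0.04, 0.28), True),
    ((-0.05, 0.13), False),
    ((0.0, 1.0), False),      # boundary zero is not credible
    ((-0.9, -0.1), True),
])
def test_credibility_rule(interval, expected):
    assert credible(interval) is expected


# ---------------------------------------------------------------------------
# Model assembly


def _scores(subjects, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((len(subjects), 3)),
                        index=subjects,
                        columns=["general", "depression", "anxiety"])


def test_single_version_drops_version_contrasts():
    spec = vl.get_model_spec("m11")
    pop = vl.default_population(spec)
    truth = vl.simulate_cohort(
        vl.CohortSpec(n_subjects=4, task_versions=("gain",),
                      population=pop, seed=1)
    )
    with pytest.warns(UserWarning, match="does not vary"):
        model = vl.build_model(spec, truth.datasets, truth.scores)
    names = model.component_names()
    assert not any("version" in n for n in names)
    # alpha keeps baseline, block, valence, block*valence
    assert sum(n.startswith("alpha:") for n in names) == 4


def test_missing_scores_rejected():
    spec = vl.get_model_spec("m2")
    pop = vl.default_population(spec)
    truth = vl.simulate_cohort(
        vl.CohortSpec(n_subjects=3, population=pop, seed=2))
    with pytest.raises(ValueError, match="missing factor scores"):
        vl.build_model(spec, truth.datasets, truth.scores.iloc[:2])


def test_empty_cohort_rejected():
    spec = vl.get_model_spec("m2")
    with pytest.raises(ValueError):
        vl.build_model(spec, [], _scores([]))


def test_sampler_loglik_equals_reference_loglik(small_cohort):
    # cross-implementation identity between the compiled cohort likelihood
    # and the sequential reference, at arbitrary component values
    spec = vl.get_model_spec("m11")
    model = vl.build_model(spec, small_cohort.datasets, small_cohort.scores)
    rng = np.random.default_rng(0)
    theta = 0.5 * rng.standard_normal((model.n_subjects, model.n_components))
    ll = model.loglik(theta)
    for s, subj in enumerate(model.subjects):
        params = dict(zip(model.component_names(), theta[s]))
        runs = sorted((d for d in small_cohort.datasets if d.subject == subj),
                      key=lambda d: d.task_version)
        want = sum(vl.run_model(spec, params, ds)["loglik"] for ds in runs)
        assert ll[s] == pytest.approx(want, abs=1e-8)


# ---------------------------------------------------------------------------
# Sampler correctness on a conjugate Normal toy model


class _NormalToyModel(hbayes.HierarchicalModel):
    """One 'component' per subject observed directly through Normal noise.

    Replaces the sequential choice likelihood with y_s ~ N(theta_s, tau^2),
    whose hierarchical posterior has closed-form conditionals, so the
    sampler's output can be checked against analytic shrinkage.
    """

    def __init__(self, y, tau, scores):
        subjects = [f"s{i:02d}" for i in range(len(y))]
        LINKS.setdefault("identity", lambda x: x)
        designs = {
            "alpha": (np.array([0]), np.ones((len(y), 1, 1)), "identity")
        }
        data = {"choice": np.ones((len(y), 1), dtype=np.int64)}
        super().__init__(
            vl.get_model_spec("m2"), subjects, [("alpha", ())],
            scores, data, designs,
        )
        self._y = np.asarray(y, dtype=float)
        self._tau = float(tau)

    def loglik(self, theta, nat=None):
        if nat is not None:
            mu = nat["alpha"][:, 0]
        else:
            mu = np.asarray(theta)[:, 0]
        return -0.5 * ((self._y - mu) / self._tau) ** 2

    def loglik_matrix(self, theta, nat=None):
        return self.loglik(theta, nat)[:, None]


def test_sampler_recovers_conjugate_normal_posterior():
    from scipy.stats import norm

    rng = np.random.default_rng(42)
    n, tau = 60, 1.0
    theta_true = rng.normal(1.2, 0.8, n)
    y = rng.normal(theta_true, tau)
    scores = _scores([f"s{i:02d}" for i in range(n)], seed=3)
    scores[:] = 0.0  # no covariate structure
    model = _NormalToyModel(y, tau, scores)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = vl.fit(model, chains=2, tune=600, draws=1500, seed=5)

    mu_hat = float(res.posterior["mu"].mean())
    sigma_hat = float(res.posterior["sigma"].mean())
    theta_hat = res.posterior["theta"].mean(axis=(0, 1))[:, 0]

    # exact marginal posterior over (mu, sigma) by numerical integration:
    # theta integrates out analytically, y_i ~ N(mu, sigma^2 + tau^2)
    sg = np.linspace(0.01, 3.0, 400)
    mg = np.linspace(-1.0, 3.0, 400)
    lp = np.empty((len(sg), len(mg)))
    for a, s in enumerate(sg):
        sd = np.sqrt(s**2 + tau**2)
        lp[a] = (norm.logpdf(y[:, None], mg[None, :], sd).sum(axis=0)
                 - np.log1p((s / 2.5) ** 2)          # half-Cauchy(2.5)
                 + norm.logpdf(mg, 0.0, 10.0))       # Normal(0, 10)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    mu_exact = float((w.sum(axis=0) * mg).sum())
    sigma_exact = float((w.sum(axis=1) * sg).sum())

    assert mu_hat == pytest.approx(mu_exact, abs=0.05)
    assert sigma_hat == pytest.approx(sigma_exact, abs=0.1)

    # subject-level means follow the precision-weighted shrinkage rule
    shrink = (1 / tau**2) / (1 / tau**2 + 1 / max(sigma_hat, 1e-6) ** 2)
    expected = shrink * y + (1 - shrink) * mu_hat
    np.testing.assert_allclose(theta_hat, expected, atol=0.25)


def test_two_fits_with_same_seed_are_identical(small_cohort):
    spec = vl.get_model_spec("m11")
    model = vl.build_model(spec, small_cohort.datasets, small_cohort.scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = vl.fit(model, chains=1, tune=50, draws=50, seed=7)
        b = vl.fit(model, chains=1, tune=50, draws=50, seed=7)
    np.testing.assert_array_equal(a.posterior["theta"], b.posterior["theta"])
    np.testing.assert_array_equal(a.posterior["mu"], b.posterior["mu"])


def test_rhat_near_one_for_iid_chains():
    import arviz as az
    import xarray as xr

    rng = np.random.default_rng(0)
    draws = rng.standard_normal((4, 2000))
    r = az.rhat(xr.Dataset({"x": (("chain", "draw"), draws)}))
    assert float(r["x"]) < 1.01


def test_fit_result_census_and_summary(small_fit):
    res = small_fit
    assert res.posterior["theta"].shape[-2:] == (12, 26)
    summ = res.summary("mu")
    assert len(summ) == 26
    assert (summ["hdi_95%_lower"] <= summ["hdi_95%_upper"]).all()
    ll = res.pointwise_loglik(max_draws=100)
    assert ll.shape == (12 * 360, 100)
    assert np.all(np.isfinite(ll))
    assert np.all(ll <= 0)
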