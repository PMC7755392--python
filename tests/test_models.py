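import math

import numpy as np
import pytest

import volatility_learner as vl
from volatility_learner import models as m
from volatility_learner.models import (
    ChoiceDataset,
    ConditionCoding,
    beta_bernoulli_step,
    choice_probability,
    coded_outcome,
    decay_probability,
    resolve_parameter,
    risk_adjust,
    run_model,
    signed_power,
    update_choice_kernel,
    update_probability,
    value_additive,
    value_multiplicative,
)

from .conftest import tiny_schedule


def logistic(x):
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# Catalog structure


def test_winning_model_component_census():
    spec = vl.get_model_spec("m11")
    counts = {p: len(c) for p, (c, _l) in spec.parameter_table.items()}
    assert counts == {"alpha": 7, "lambda": 7, "omega": 7,
                      "r": 2, "eta": 1, "omega_k": 2}
    assert spec.n_components == 26


@pytest.mark.parametrize("mid,expected", [("m1", 12), ("m2", 12), ("m5", 21),
                                          ("m7", 23), ("m9", 25), ("m13", 28)])
def test_component_counts_per_model(mid, expected):
    assert vl.get_model_spec(mid).n_components == expected


def test_three_way_variant_adds_one_learning_rate_component():
    spec = vl.get_model_spec("m11", three_way=True)
    assert spec.n_components == 27
    comps, _ = spec.parameter_table["alpha"]
    assert ("block", "version", "valence") in comps
    comps_l, _ = spec.parameter_table["lambda"]
    assert ("block", "version", "valence") not in comps_l


# ---------------------------------------------------------------------------
# Primitive operations against closed-form arithmetic


def test_resolve_parameter_links_and_effect_coding():
    spec = vl.get_model_spec("m2")
    params = spec.zero_parameters()
    cod = ConditionCoding(chi_block=1, chi_version=1)
    assert resolve_parameter(spec, params, cod, "alpha") == 0.5
    params["alpha:block"] = 0.16
    got = resolve_parameter(spec, params, cod, "alpha")
    assert got == pytest.approx(logistic(0.16), abs=1e-10)
    assert got == pytest.approx(0.5399, abs=2e-4)
    # stable trial flips the sign of the block contribution
    cod_stable = ConditionCoding(chi_block=-1, chi_version=1)
    assert resolve_parameter(spec, params, cod_stable, "alpha") == \
        pytest.approx(logistic(-0.16), abs=1e-12)
    spec1 = vl.get_model_spec("m1")
    assert resolve_parameter(spec1, spec1.zero_parameters(), cod, "gamma") == \
        pytest.approx(5.05)
    with pytest.raises(KeyError):
        resolve_parameter(spec, params, cod, "gamma")


@pytest.mark.parametrize("p,o,a,expected", [
    (0.5, 1, 0.2, 0.6),
    (0.3, 0, 0.0, 0.3),
    (0.75, 0, 1.0, 0.0),
])
def test_rescorla_wagner_update(p, o, a, expected):
    assert update_probability(p, o, a) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("p,g,expected", [
    (0.5, 7.3, 0.5),       # fixed point
    (0.8, 2.0, 1.0),       # clipped
    (0.8, 1.0, 0.8),       # identity inside clip range
])
def test_risk_adjustment(p, g, expected):
    assert risk_adjust(p, g) == pytest.approx(expected, abs=1e-12)


def test_multiplicative_value():
    assert value_multiplicative(0.5, 0.3, 0.3) == pytest.approx(0.0)
    assert value_multiplicative(1.0, 0.5, 0.99) == pytest.approx(0.5)
    assert value_multiplicative(0.75, 0.40, 0.60) == pytest.approx(0.15)


def test_additive_value_with_signed_power():
    # pure-probability limit ignores magnitudes
    assert value_additive(0.5, 0.1, 0.9, lam=1.0, r=3.0) == pytest.approx(0.5)
    assert value_additive(0.2, 0.4, 0.4, lam=0.0, r=2.0) == pytest.approx(0.0)
    # signed power: sign removed before exponentiating, then restored
    got = value_additive(0.5, 0.25, 0.50, lam=0.5, r=2.0)
    assert got == pytest.approx(0.5 * 0.5 + 0.5 * (-0.0625), abs=1e-12)
    assert signed_power(-0.25, 2.0) == pytest.approx(-0.0625)


def test_choice_kernel_update():
    assert update_choice_kernel(0.5, 1, 0.1) == pytest.approx(0.55)
    assert update_choice_kernel(0.42, 1, 0.0) == pytest.approx(0.42)
    assert update_choice_kernel(0.0, 1, 1.0) == pytest.approx(1.0)


def test_choice_probability_softmax_kernel_and_lapse():
    assert choice_probability(0.0, 0.5, 2.0, 3.0) == pytest.approx(0.5)
    assert choice_probability(1.0, omega=2.0) == pytest.approx(
        logistic(2.0), abs=1e-12)
    # lapse caps certainty at 1 - eps/2
    assert choice_probability(1e9, 0.5, 1.0, 0.0, epsilon=0.1) == \
        pytest.approx(0.95)
    assert choice_probability(-1e9, 0.5, 1.0, 0.0, epsilon=0.1) == \
        pytest.approx(0.05)


def test_probability_decay_toward_half():
    assert decay_probability(0.37, 0.0) == pytest.approx(0.37)
    assert decay_probability(0.37, 1.0) == pytest.approx(0.5)
    assert decay_probability(0.9, 0.2) == pytest.approx(0.82)


def test_beta_bernoulli_counts():
    counts = (0.0, 0.0, 0.0, 0.0)
    p = (counts[0] + 1) / (counts[0] + counts[1] + 2)
    assert p == 0.5
    # one good outcome for shape 1 with alpha=1, delta=1 (no forgetting)
    counts, p, q = beta_bernoulli_step(counts, 1, True, 1.0, 1.0)
    assert counts == (1.0, 0.0, 0.0, 0.0)
    assert p == pytest.approx(2 / 3)
    assert q == pytest.approx(1 / 2)
    # only the matched count gains mass
    counts, p, q = beta_bernoulli_step(counts, 2, False, 2.0, 1.0)
    assert counts == (1.0, 0.0, 0.0, 2.0)
    # delta = 0 forgets all history each trial
    counts, p, q = beta_bernoulli_step((5.0, 3.0, 2.0, 8.0), 1, True, 1.0, 0.0)
    assert counts == (1.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Outcome coding


@pytest.mark.parametrize("version,event_good", [
    ("gain", True), ("aversive", False), ("loss", False)])
def test_coded_outcome_follows_version_valence_map(version, event_good):
    sched = tiny_schedule(version)
    O = coded_outcome(sched)
    for t, ev in enumerate(sched.event_shape):
        expected = (ev == 1) if event_good else (ev == 2)
        assert O[t] == int(expected)


def test_dataset_rejects_miscoded_outcomes():
    sched = tiny_schedule("gain")
    good_O = coded_outcome(sched)
    bad_O = 1 - good_O
    with pytest.raises(ValueError, match="coding"):
        ChoiceDataset("s", sched, [1] * 5, bad_O)


# ---------------------------------------------------------------------------
# Sequential evaluation against a hand-unrolled oracle


def _unrolled_m11_loglik(params, sched, choices):
    """Independent trial-by-trial unroll of the winning model's equations."""
    O = coded_outcome(sched)
    m1 = sched.trials["M1"].to_numpy() / 100.0
    m2 = sched.trials["M2"].to_numpy() / 100.0
    chi_v = 1  # gain version

    def nat(name, comps, link, chi_b, chi_val):
        chis = {"block": chi_b, "version": chi_v, "valence": chi_val}
        s = 0.0
        for comp in comps:
            key = f"{name}:{'*'.join(comp) if comp else 'baseline'}"
            x = params[key]
            for f in comp:
                x *= chis[f]
            s += x
        if link == "logistic":
            return logistic(s)
        if link == "log":
            return math.exp(s)
        return 0.1 + 9.9 * logistic(s)

    C7 = [(), ("version",), ("block",), ("block", "version"), ("valence",),
          ("block", "valence"), ("version", "valence")]
    C2 = [(), ("version",)]
    p, k = 0.5, 0.5
    total = 0.0
    prev_val = 0
    for t in range(len(choices)):
        chi_b = -1  # tiny fixture is all stable
        if t > 0:
            alpha = nat("alpha", C7, "logistic", chi_b, prev_val)
            p = p + alpha * (O[t - 1] - p)
            eta = nat("eta", [()], "logistic", chi_b, prev_val)
            k = k + eta * ((1 if choices[t - 1] == 1 else 0) - k)
        lam = nat("lambda", C7, "logistic", chi_b, prev_val)
        r = nat("r", C2, "scaled", chi_b, prev_val)
        om = nat("omega", C7, "log", chi_b, prev_val)
        omk = nat("omega_k", C2, "log", chi_b, prev_val)
        dm = m1[t] - m2[t]
        v = lam * (2 * p - 1) + (1 - lam) * math.copysign(abs(dm) ** r, dm)
        pc = logistic(om * v + omk * (2 * k - 1))
        total += math.log(pc if choices[t] == 1 else 1 - pc)
        # valence of the received outcome: good iff the choice matched the
        # coded good option
        prev_val = 1 if (choices[t] == 1) == (O[t] == 1) else -1
    return total


def test_run_model_matches_hand_unrolled_winning_model():
    sched = tiny_schedule("gain")
    spec = vl.get_model_spec("m11")
    rng = np.random.default_rng(8)
    params = {n: float(v) for n, v in
              zip(spec.component_names(),
                  0.5 * rng.standard_normal(spec.n_components))}
    choices = [1, 2, 1, 1, 2]
    ds = ChoiceDataset("s", sched, choices, coded_outcome(sched))
    got = run_model(spec, params, ds)["loglik"]
    want = _unrolled_m11_loglik(params, sched, choices)
    assert got == pytest.approx(want, abs=1e-10)


def test_missing_choices_contribute_nothing_and_freeze_state():
    sched = tiny_schedule("gain")
    spec = vl.get_model_spec("m11")
    params = spec.zero_parameters()
    params["alpha:baseline"] = 1.0
    ds_missing = ChoiceDataset("s", sched, [1, 0, 1, 1, 2],
                               coded_outcome(sched))
    out = run_model(spec, params, ds_missing)
    assert out["pointwise_loglik"][1] == 0.0
    assert out["loglik"] == pytest.approx(
        out["pointwise_loglik"].sum(), abs=1e-12)


def test_total_loglik_is_sum_of_pointwise(small_cohort):
    spec = vl.get_model_spec("m11")
    ds = small_cohort.datasets[0]
    params = small_cohort.parameters.loc[ds.subject].to_dict()
    out = run_model(spec, params, ds)
    assert out["loglik"] == pytest.approx(out["pointwise_loglik"].sum())


# ---------------------------------------------------------------------------
# Model-family equivalences


def test_additive_pure_probability_limit_equals_multiplicative_gamma_one():
    # lambda = 1 in the additive model and gamma = 1, equal magnitudes in
    # the multiplicative model leave only the probability term; the value
    # differs by an affine factor absorbed by omega: v_add = 2p - 1 and
    # v_mult = p*m - (1-p)*m = m*(2p - 1), so with omega_mult = omega/m the
    # likelihoods agree exactly
    sched = tiny_schedule("gain", m1=[50] * 5, m2=[50] * 5)
    choices = [1, 2, 1, 1, 1]
    ds = ChoiceDataset("s", sched, choices, coded_outcome(sched))

    m2spec = vl.get_model_spec("m2")
    p2 = m2spec.zero_parameters()
    p2["alpha:baseline"] = -0.4
    p2["lambda:baseline"] = 40.0      # logistic -> lambda = 1
    p2["omega:baseline"] = 0.3

    m1spec = vl.get_model_spec("m1")
    p1 = m1spec.zero_parameters()
    p1["alpha:baseline"] = -0.4
    frac = (1.0 - 0.1) / 9.9                     # logistic value for gamma=1
    p1["gamma:baseline"] = math.log(frac / (1.0 - frac))
    p1["omega:baseline"] = 0.3 - math.log(0.5)  # omega / m with m = 0.5

    ll2 = run_model(m2spec, p2, ds)["loglik"]
    ll1 = run_model(m1spec, p1, ds)["loglik"]
    assert ll1 == pytest.approx(ll2, abs=1e-9)


def test_winning_model_degenerates_to_m7_without_kernel(small_cohort):
    # eta driven to 0 (kernel frozen at 0.5) and omega_k driven to 0 make
    # the kernel term vanish identically
    ds = small_cohort.datasets[0]
    m7 = vl.get_model_spec("m7")
    rng = np.random.default_rng(3)
    p7 = {n: float(v) for n, v in
          zip(m7.component_names(), 0.4 * rng.standard_normal(m7.n_components))}
    m11 = vl.get_model_spec("m11")
    p11 = {n: p7.get(n, 0.0) for n in m11.component_names()}
    p11["eta:baseline"] = -50.0
    p11["omega_k:baseline"] = -50.0
    p11["omega_k:version"] = 0.0
    ll7 = run_model(m7, p7, ds)["pointwise_loglik"]
    ll11 = run_model(m11, p11, ds)["pointwise_loglik"]
    np.testing.assert_allclose(ll11, ll7, atol=1e-10)


@pytest.mark.parametrize("mid", ["m1", "m2", "m7", "m8", "m9", "m10",
                                 "m11", "m12", "m13"])
def test_choice_probabilities_strictly_inside_unit_interval(mid):
    spec = vl.get_model_spec(mid)
    sched = vl.make_schedule("aversive", "volatile_first", seed=13)
    rng = np.random.default_rng(sum(map(ord, mid)))
    for _ in range(3):
        params = {n: float(v) for n, v in
                  zip(spec.component_names(),
                      0.5 * rng.standard_normal(spec.n_components))}
        ds = vl.simulate_choices(spec, params, sched,
                                 seed=int(rng.integers(1 << 30)))
        out = run_model(spec, params, ds)
        probs = out["choice_prob"]
        assert np.all(probs > 0.0) and np.all(probs < 1.0)


def test_compiled_kernel_matches_reference_for_every_family():
    rng = np.random.default_rng(17)
    for mid in ["m1", "m2", "m7", "m8", "m9", "m10", "m11", "m13"]:
        spec = vl.get_model_spec(mid)
        pop = vl.default_population(spec)
        cohort = vl.CohortSpec(n_subjects=3, population=pop,
                               seed=int(rng.integers(1 << 30)),
                               missing_rate=0.05)
        truth = vl.simulate_cohort(cohort)
        model = vl.build_model(spec, truth.datasets, truth.scores)
        theta = truth.parameters[model.component_names()].to_numpy()
        llmat = model.loglik_matrix(theta)
        for s, subj in enumerate(model.subjects):
            runs = sorted((d for d in truth.datasets if d.subject == subj),
                          key=lambda d: d.task_version)
            pos = 0
            for ds in runs:
                ref = run_model(spec, truth.parameters.loc[subj].to_dict(), ds)
                np.testing.assert_allclose(
                    llmat[s, pos:pos + ds.n_trials],
                    ref["pointwise_loglik"], atol=1e-10,
                    err_msg=f"{mid} subject {subj}",
                )
                pos += ds.n_trials
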