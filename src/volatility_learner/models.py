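"""The thirteen-model reinforcement-learning family and its parameter algebra.

Every model is built from the same ingredients:

* a probability estimate updated by a Rescorla-Wagner rule (one estimate of
  "shape 1 is the good option", or two per-shape estimates, or Beta-Bernoulli
  pseudo-counts);
* a value rule combining the probability estimate with the trial's outcome
  magnitudes, either multiplicatively (expected value, model #1) or as an
  additive mixture weighted by ``lambda`` with a subjective magnitude
  exponent ``r``;
* a softmax choice rule with inverse temperature ``omega``, optionally a
  perseveration (choice-kernel) term with its own inverse temperature
  ``omega_k``, and optionally a lapse rate ``epsilon``.

Each natural-scale parameter is assembled per trial from *components* on the
unconstrained scale: a baseline plus effect-coded (+1/-1) contributions of
block type (volatile vs stable), task version (reward vs aversive/loss) and
the relative value (good vs bad) of the previous trial's outcome, plus their
interactions.  A link function then maps the sum to the parameter's range,
e.g. for the learning rate

    alpha = logistic(a_base + a_ver * chi_ver + a_blk * chi_blk + ...)

Outcome coding: ``O_t = 1`` iff choosing shape 1 on trial ``t`` yields (or
would have yielded) the *good* outcome -- reward received in the gain
version, shock/loss avoided in the aversive/loss versions.  Because exactly
one shape delivers the event each trial, ``O`` is determined by the schedule
alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import EVENT_IS_GOOD, TrialSchedule

# ---------------------------------------------------------------------------
# Links

LINKS = {
    "logistic01": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "log_positive": lambda x: np.exp(x),
    "scaled_logistic_0.1_10": lambda x: 0.1 + 9.9 / (1.0 + np.exp(-x)),
    "scaled_logistic_0_10": lambda x: 10.0 / (1.0 + np.exp(-x)),
}

#: integer codes used by the numba kernels
LINK_CODES = {name: i for i, name in enumerate(LINKS)}


def apply_link(link: str, x):
    return LINKS[link](x)


# ---------------------------------------------------------------------------
# Condition coding and model specifications

FACTORS = ("block", "version", "valence")

# component lists; a component is the tuple of factors whose effect codes
# are multiplied together (the empty tuple is the baseline)
_C1 = [()]
_C2V = [(), ("version",)]
_C4 = [(), ("version",), ("block",), ("block", "version")]
_C7 = _C4 + [("valence",), ("block", "valence"), ("version", "valence")]
_C8 = _C7 + [("block", "version", "valence")]


def component_name(param: str, comp: tuple[str, ...]) -> str:
    return f"{param}:{'*'.join(comp) if comp else 'baseline'}"


@dataclass(frozen=True)
class ConditionCoding:
    """Effect codes for one trial: +1/-1 (valence may be 0 on run starts)."""

    chi_block: int = 0      # +1 volatile, -1 stable
    chi_version: int = 0    # +1 reward gain, -1 aversive / reward loss
    chi_valence: int = 0    # +1 previous outcome good, -1 bad, 0 undefined

    def chi(self, comp: tuple[str, ...]) -> float:
        out = 1.0
        for f in comp:
            out *= getattr(self, f"chi_{f}")
        return out


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model family.

    ``family`` selects the state/value machinery: ``additive`` (single
    probability estimate, additive value rule; models #2-#8, #11),
    ``multiplicative`` (#1), ``two_estimate`` (#9, #12) and
    ``beta_bernoulli`` (#10, #13).  ``parameter_table`` maps each parameter
    to its component list and link.
    """

    model_id: str
    family: str
    parameter_table: dict[str, tuple[tuple[tuple[str, ...], ...], str]]

    @property
    def has_kernel(self) -> bool:
        return "eta" in self.parameter_table

    @property
    def has_lapse(self) -> bool:
        return "epsilon" in self.parameter_table

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.parameter_table)

    def components(self) -> list[tuple[str, tuple[str, ...]]]:
        """Flat ordered list of (parameter, component) pairs."""
        return [
            (p, c)
            for p, (comps, _link) in self.parameter_table.items()
            for c in comps
        ]

    def component_names(self) -> list[str]:
        return [component_name(p, c) for p, c in self.components()]

    @property
    def n_components(self) -> int:
        return len(self.components())

    def zero_parameters(self) -> dict[str, float]:
        return {name: 0.0 for name in self.component_names()}


def _spec(model_id, family, **params):
    table = {p: (tuple(comps), link) for p, (comps, link) in params.items()}
    return ModelSpec(model_id, family, table)


def _build_catalog() -> dict[str, ModelSpec]:
    lg, ln = "logistic01", "log_positive"
    sc = "scaled_logistic_0.1_10"
    sc10 = "scaled_logistic_0_10"
    cat = {}
    cat["m1"] = _spec("m1", "multiplicative",
                      alpha=(_C4, lg), gamma=(_C4, sc), omega=(_C4, ln))
    cat["m2"] = _spec("m2", "additive",
                      alpha=(_C4, lg), **{"lambda": (_C4, lg)}, omega=(_C4, ln))
    cat["m3"] = _spec("m3", "additive",
                      alpha=(_C7, lg), **{"lambda": (_C4, lg)}, omega=(_C4, ln))
    cat["m4"] = _spec("m4", "additive",
                      alpha=(_C4, lg), **{"lambda": (_C7, lg)}, omega=(_C7, ln))
    cat["m5"] = _spec("m5", "additive",
                      alpha=(_C7, lg), **{"lambda": (_C7, lg)}, omega=(_C7, ln))
    cat["m6"] = _spec("m6", "additive",
                      alpha=(_C8, lg), **{"lambda": (_C7, lg)}, omega=(_C7, ln))
    cat["m7"] = _spec("m7", "additive",
                      alpha=(_C7, lg), **{"lambda": (_C7, lg)}, omega=(_C7, ln),
                      r=(_C2V, sc))
    cat["m8"] = _spec("m8", "additive",
                      alpha=(_C7, lg), **{"lambda": (_C7, lg)}, omega=(_C7, ln),
                      r=(_C2V, sc), epsilon=(_C2V, lg))
    cat["m9"] = _spec("m9", "two_estimate",
                      alpha=(_C7, lg), **{"lambda": (_C7, lg)}, omega=(_C7, ln),
                      r=(_C2V, sc), delta=(_C2V, lg))
    cat["m10"] = _spec("m10", "beta_bernoulli",
                       alpha=(_C7, sc10), **{"lambda": (_C7, lg)},
                       omega=(_C7, ln), r=(_C2V, sc), delta=(_C2V, lg))
    cat["m11"] = _spec("m11", "additive",
                       alpha=(_C7, lg), **{"lambda": (_C7, lg)},
                       omega=(_C7, ln), r=(_C2V, sc),
                       eta=(_C1, lg), omega_k=(_C2V, ln))
    cat["m12"] = _spec("m12", "two_estimate",
                       alpha=(_C7, lg), **{"lambda": (_C7, lg)},
                       omega=(_C7, ln), r=(_C2V, sc), delta=(_C2V, lg),
                       eta=(_C1, lg), omega_k=(_C2V, ln))
    cat["m13"] = _spec("m13", "beta_bernoulli",
                       alpha=(_C7, sc10), **{"lambda": (_C7, lg)},
                       omega=(_C7, ln), r=(_C2V, sc), delta=(_C2V, lg),
                       eta=(_C1, lg), omega_k=(_C2V, ln))
    return cat


_CATALOG = _build_catalog()


def list_models() -> list[str]:
    return list(_CATALOG)


def get_model_spec(model_id: str, three_way: bool = False) -> ModelSpec:
    """Return a model specification.

    ``three_way=True`` adds the block x version x valence interaction to the
    learning rate only (the variant used to probe the three-way effect).
    """
    if model_id not in _CATALOG:
        raise ValueError(f"unknown model {model_id!r}; known: {list(_CATALOG)}")
    spec = _CATALOG[model_id]
    if not three_way:
        return spec
    table = dict(spec.parameter_table)
    comps, link = table["alpha"]
    extra = ("block", "version", "valence")
    if extra not in comps:
        table["alpha"] = (comps + (extra,), link)
    return ModelSpec(spec.model_id + "+3w", spec.family, table)


# ---------------------------------------------------------------------------
# Datasets

@dataclass
class ChoiceDataset:
    """One subject x one task run of choices aligned to a schedule.

    ``choice`` is 1 or 2, with 0 marking a missed response.  ``outcome``
    is the coded outcome ``O`` (1 iff shape 1 was/would have been the good
    choice).  ``received_magnitude`` is the magnitude of the outcome event
    actually experienced (0 when the event did not occur for the chooser or
    the response was missed).
    """

    subject: str
    schedule: TrialSchedule
    choice: np.ndarray
    outcome: np.ndarray
    received_magnitude: np.ndarray = field(default=None)

    def __post_init__(self):
        self.choice = np.asarray(self.choice, dtype=np.int64)
        self.outcome = np.asarray(self.outcome, dtype=np.int64)
        n = self.schedule.n_trials
        if len(self.choice) != n or len(self.outcome) != n:
            raise ValueError("choice/outcome length does not match schedule")
        if self.received_magnitude is None:
            self.received_magnitude = np.zeros(n)
        expected = coded_outcome(self.schedule)
        if not np.array_equal(self.outcome, expected):
            raise ValueError(
                "outcome coding disagrees with the schedule's event shapes "
                "and task-version valence map"
            )

    @property
    def task_version(self) -> str:
        return self.schedule.task_version

    @property
    def n_trials(self) -> int:
        return self.schedule.n_trials

    def good_outcome(self) -> np.ndarray:
        """Per trial: +1 received outcome good, -1 bad, 0 missed response."""
        good = np.where((self.choice == 1) == (self.outcome == 1), 1, -1)
        return np.where(self.choice == 0, 0, good)

    def to_frame(self) -> pd.DataFrame:
        t = self.schedule.trials
        return pd.DataFrame(
            {
                "subject": self.subject,
                "task_version": self.task_version,
                "trial": t["trial"],
                "block_type": t["block_type"],
                "M1": t["M1"],
                "M2": t["M2"],
                "choice": self.choice,
                "outcome_O": self.outcome,
                "received_magnitude": self.received_magnitude,
            }
        )


def coded_outcome(schedule: TrialSchedule) -> np.ndarray:
    """The coded outcome ``O`` implied by a schedule.

    ``O = 1`` iff shape 1 is the good option this trial: in the gain version
    that is when shape 1 delivers the event (reward); in the aversive and
    loss versions it is when shape 2 delivers the event.
    """
    event1 = schedule.event_shape == 1
    if EVENT_IS_GOOD[schedule.task_version]:
        return event1.astype(np.int64)
    return (~event1).astype(np.int64)


def trial_codings(dataset: ChoiceDataset) -> list[ConditionCoding]:
    """Per-trial effect codes for one dataset.

    The valence code on trial ``t`` reflects the outcome received on trial
    ``t - 1`` and is 0 on the first trial and after a missed response.
    """
    chi_version = 1 if dataset.task_version == "gain" else -1
    chi_block = np.where(dataset.schedule.block_type == "volatile", 1, -1)
    good = dataset.good_outcome()
    chi_valence = np.concatenate([[0], good[:-1]])
    return [
        ConditionCoding(int(b), chi_version, int(v))
        for b, v in zip(chi_block, chi_valence)
    ]


# ---------------------------------------------------------------------------
# Primitive operations (the per-trial arithmetic of the model family)

def resolve_parameter(spec: ModelSpec, params: dict[str, float],
                      coding: ConditionCoding, name: str) -> float:
    """Natural-scale value of a parameter under one trial's condition codes."""
    if name not in spec.parameter_table:
        raise KeyError(f"model {spec.model_id} has no parameter {name!r}")
    comps, link = spec.parameter_table[name]
    s = sum(params[component_name(name, c)] * coding.chi(c) for c in comps)
    return float(apply_link(link, s))


def update_probability(p: float, outcome: int, alpha: float) -> float:
    """Rescorla-Wagner update of a probability estimate."""
    return p + alpha * (outcome - p)


def risk_adjust(p: float, gamma: float) -> float:
    """Risk-adjusted probability used by the multiplicative model (#1)."""
    return min(max((p - 0.5) * gamma + 0.5, 0.0), 1.0)


def value_multiplicative(p_adj: float, m1: float, m2: float) -> float:
    """Difference in expected value (model #1)."""
    return p_adj * m1 - (1.0 - p_adj) * m2


def signed_power(x: float, r: float) -> float:
    """``sign(x) * |x| ** r`` -- the subjective magnitude transform."""
    return math.copysign(abs(x) ** r, x) if x != 0.0 else 0.0


def value_additive(p_diff: float, m1: float, m2: float,
                   lam: float, r: float = 1.0) -> float:
    """Additive mixture of probability difference and magnitude difference."""
    return lam * p_diff + (1.0 - lam) * signed_power(m1 - m2, r)


def update_choice_kernel(k: float, chose_shape1: int, eta: float) -> float:
    """Exponential moving average of past choices (perseveration kernel)."""
    return k + eta * (chose_shape1 - k)


def choice_probability(v: float, k: float = 0.5, omega: float = 1.0,
                       omega_k: float = 0.0, epsilon: float = 0.0) -> float:
    """Softmax probability of choosing shape 1, with optional kernel/lapse."""
    z = omega * v + omega_k * (2.0 * k - 1.0)
    if z >= 0.0:
        base = 1.0 / (1.0 + math.exp(-z))
    else:
        ez = math.exp(z)
        base = ez / (1.0 + ez)
    return (1.0 - epsilon) * base + epsilon / 2.0


def decay_probability(p: float, delta: float) -> float:
    """Decay a probability estimate toward 0.5 (models #9/#12)."""
    return (1.0 - delta) * p + delta * 0.5


def beta_bernoulli_step(counts: tuple[float, float, float, float],
                        chosen: int, good: bool,
                        alpha: float, delta: float):
    """One Beta-Bernoulli count update (models #10/#13).

    All four pseudo-counts decay by the factor ``delta``; the single count
    matching (chosen shape, outcome valence) additionally gains ``alpha``.
    Returns the new counts and the implied probability estimates
    ``p = (a+1)/(a+b+2)`` and ``q = (c+1)/(c+d+2)``.
    """
    a, b, c, d = (delta * x for x in counts)
    if chosen == 1:
        if good:
            a += alpha
        else:
            b += alpha
    elif chosen == 2:
        if good:
            c += alpha
        else:
            d += alpha
    else:
        raise ValueError("chosen must be 1 or 2")
    p = (a + 1.0) / (a + b + 2.0)
    q = (c + 1.0) / (c + d + 2.0)
    return (a, b, c, d), p, q


# ---------------------------------------------------------------------------
# Reference sequential evaluation

def run_model(spec: ModelSpec, params: dict[str, float],
              dataset: ChoiceDataset) -> dict:
    """Evaluate one model on one dataset, trial by trial.

    Returns per-trial choice probabilities (for shape 1), the pointwise
    log-likelihood of the observed choices (0 for missed responses) and
    their sum.  State is updated with the outcome of trial ``t - 1`` before
    the choice at trial ``t`` is evaluated; a missed response contributes no
    likelihood and triggers no state update (no outcome was observed).

    This is the readable reference implementation; the hierarchical sampler
    uses a numerically identical compiled kernel (see ``_kernels``).
    """
    unknown = set(params) - set(spec.component_names())
    missing = set(spec.component_names()) - set(params)
    if unknown or missing:
        raise ValueError(
            f"parameter set does not match {spec.model_id}: "
            f"unknown={sorted(unknown)}, missing={sorted(missing)}"
        )

    codings = trial_codings(dataset)
    m1, m2 = dataset.schedule.magnitudes
    m1 = m1 / 100.0
    m2 = m2 / 100.0
    choice = dataset.choice
    outcome = dataset.outcome
    good = dataset.good_outcome()
    n = dataset.n_trials

    p = q = k = 0.5
    counts = (0.0, 0.0, 0.0, 0.0)

    def par(name, coding):
        return resolve_parameter(spec, params, coding, name)

    probs = np.empty(n)
    logp = np.zeros(n)
    for t in range(n):
        cod = codings[t]
        prev_observed = t > 0 and choice[t - 1] != 0
        if prev_observed:
            if spec.family in ("additive", "multiplicative"):
                p = update_probability(p, outcome[t - 1], par("alpha", cod))
            elif spec.family == "two_estimate":
                alpha = par("alpha", cod)
                delta = par("delta", cod)
                prev_good = good[t - 1] == 1
                if choice[t - 1] == 1:
                    p = update_probability(p, 1 if prev_good else 0, alpha)
                else:
                    q = update_probability(q, 1 if prev_good else 0, alpha)
                p = decay_probability(p, delta)
                q = decay_probability(q, delta)
            elif spec.family == "beta_bernoulli":
                counts, p, q = beta_bernoulli_step(
                    counts, int(choice[t - 1]), good[t - 1] == 1,
                    par("alpha", cod), par("delta", cod),
                )
            if spec.has_kernel:
                k = update_choice_kernel(
                    k, 1 if choice[t - 1] == 1 else 0, par("eta", cod)
                )

        omega = par("omega", cod)
        if spec.family == "multiplicative":
            v = value_multiplicative(
                risk_adjust(p, par("gamma", cod)), m1[t], m2[t]
            )
        else:
            lam = par("lambda", cod)
            r = par("r", cod) if "r" in spec.parameter_table else 1.0
            p_diff = (p - q) if spec.family in ("two_estimate",
                                                "beta_bernoulli") else (2.0 * p - 1.0)
            v = lam * p_diff + (1.0 - lam) * signed_power(m1[t] - m2[t], r)

        omega_k = par("omega_k", cod) if spec.has_kernel else 0.0
        eps = par("epsilon", cod) if spec.has_lapse else 0.0
        probs[t] = choice_probability(v, k, omega, omega_k, eps)

        if choice[t] == 1:
            logp[t] = math.log(probs[t])
        elif choice[t] == 2:
            logp[t] = math.log1p(-probs[t])

    return {
        "choice_prob": probs,
        "pointwise_loglik": logp,
        "loglik": float(logp.sum()),
    }
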