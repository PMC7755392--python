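"""Synthetic cohorts: choice data from the population model and ordinal
questionnaire items from a planted bifactor structure.

The choice generator draws each subject's unconstrained parameter components
from the population linear model

    component ~ Normal(mu + bg*Xg + bd*Xd + ba*Xa, sigma^2)

with i.i.d. standard-normal factor scores (orthogonal by construction, the
property Anderson-Rubin scoring enforces on real data), then plays the
generative model forward on the task schedules.  Default population values
anchor the printed cross-group posterior means of the winning model (e.g.
volatile-stable learning-rate component 0.16, good-bad 0.50,
reward-aversive -0.21; general-factor weights -0.18 / -0.21 / -0.19 on the
volatility, valence and volatility-by-valence learning-rate components),
with population SD 0.5 on the unconstrained scale.

The item generator produces ordinal responses by thresholding latent
``loadings @ factors + noise`` variables, mimicking a battery in which every
item loads on a general internalizing factor and one of two specific
(depression / anxiety) factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as _m
from .models import ChoiceDataset, ModelSpec, component_name, get_model_spec
from .task import BLOCK_ORDERS, TrialSchedule, make_schedule

FACTOR_NAMES = ("general", "depression", "anxiety")


# ---------------------------------------------------------------------------
# Population model

@dataclass
class PopulationModel:
    """Population-level linear model for each parameter component."""

    spec: ModelSpec
    mu: dict[str, float]
    beta_g: dict[str, float]
    beta_d: dict[str, float]
    beta_a: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self):
        names = self.spec.component_names()
        for d in (self.mu, self.beta_g, self.beta_d, self.beta_a, self.sigma):
            unknown = set(d) - set(names)
            if unknown:
                raise ValueError(f"unknown components: {sorted(unknown)}")
        bad = [n for n, s in self.sigma.items() if s <= 0]
        if bad:
            raise ValueError(f"non-positive sigma for {bad}")

    def component_names(self) -> list[str]:
        return self.spec.component_names()

    def linear_predictor(self, scores: pd.DataFrame) -> pd.DataFrame:
        """(subjects x components) mean of each component."""
        names = self.component_names()
        out = np.zeros((len(scores), len(names)))
        for j, n in enumerate(names):
            out[:, j] = (
                self.mu.get(n, 0.0)
                + self.beta_g.get(n, 0.0) * scores["general"].to_numpy()
                + self.beta_d.get(n, 0.0) * scores["depression"].to_numpy()
                + self.beta_a.get(n, 0.0) * scores["anxiety"].to_numpy()
            )
        return pd.DataFrame(out, index=scores.index, columns=names)

    def sigma_vector(self) -> np.ndarray:
        return np.array(
            [self.sigma.get(n, 0.5) for n in self.component_names()]
        )


# per-parameter baseline anchors on the unconstrained scale; chosen so the
# natural-scale values are in the realistic behavioral range (learning rate
# ~0.27, mixture weight ~0.7 toward probability, inverse temperature ~4.5,
# magnitude exponent ~1, small perseveration)
_BASELINE_MU = {
    "alpha": -1.0,
    "gamma": -2.3,        # gamma ~ 1 (no risk distortion)
    "lambda": 0.9,
    "omega": 1.5,
    "omega_k": -0.5,
    "eta": -1.0,
    "r": -2.3,            # r ~ 1 (linear subjective magnitude)
    "delta": -2.0,
    "epsilon": -3.0,
}
# update-magnitude parameter of the Beta-Bernoulli family lives on (0, 10)
_BASELINE_MU_BB_ALPHA = -2.2  # ~1.0

# printed cross-group posterior means for learning-rate components and the
# mixture-weight version effect
_ANCHOR_MU = {
    ("alpha", ("version",)): -0.21,
    ("alpha", ("block",)): 0.16,
    ("alpha", ("valence",)): 0.50,
    ("alpha", ("block", "version")): 0.09,
    ("alpha", ("block", "valence")): 0.04,
    ("lambda", ("version",)): 0.26,
}
# credible general-factor effects on learning rate
_ANCHOR_BETA_G = {
    ("alpha", ("block",)): -0.18,
    ("alpha", ("valence",)): -0.21,
    ("alpha", ("block", "valence")): -0.19,
}


def default_population(spec: ModelSpec | str = "m11",
                       sigma: float = 0.5) -> PopulationModel:
    """Population model anchored at the printed cross-group estimates."""
    if isinstance(spec, str):
        spec = get_model_spec(spec)
    mu, bg = {}, {}
    for p, comp in spec.components():
        name = component_name(p, comp)
        if comp == ():
            if p == "alpha" and spec.family == "beta_bernoulli":
                mu[name] = _BASELINE_MU_BB_ALPHA
            else:
                mu[name] = _BASELINE_MU[p]
        else:
            mu[name] = _ANCHOR_MU.get((p, comp), 0.0)
        if (p, comp) in _ANCHOR_BETA_G:
            bg[name] = _ANCHOR_BETA_G[(p, comp)]
    names = spec.component_names()
    return PopulationModel(
        spec, mu, bg, {}, {}, {n: sigma for n in names}
    )


def draw_subject_parameters(population: PopulationModel, scores: pd.DataFrame,
                            seed: int) -> pd.DataFrame:
    """Draw each subject's components from the population linear model."""
    rng = np.random.default_rng(seed)
    mean = population.linear_predictor(scores)
    sig = population.sigma_vector()
    draws = mean + rng.standard_normal(mean.shape) * sig
    return draws


# ---------------------------------------------------------------------------
# Choice simulation

def simulate_choices(spec: ModelSpec, params: dict[str, float],
                     schedule: TrialSchedule, seed: int,
                     missing_rate: float = 0.0,
                     subject: str = "sim") -> ChoiceDataset:
    """Play the generative model forward on one schedule.

    At each trial the model's choice probability is computed exactly as in
    :func:`~volatility_learner.models.run_model`, a choice is drawn from it,
    and the outcome realized by the schedule's event shape determines the
    valence coding for the next trial.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    chi_version = 1 if schedule.task_version == "gain" else -1
    chi_block = np.where(schedule.block_type == "volatile", 1, -1)
    event_shape = schedule.event_shape
    m1_raw, m2_raw = schedule.magnitudes
    m1 = m1_raw / 100.0
    m2 = m2_raw / 100.0
    outcome = _m.coded_outcome(schedule)
    event_is_good = _m.EVENT_IS_GOOD[schedule.task_version]

    p = q = k = 0.5
    counts = (0.0, 0.0, 0.0, 0.0)
    prev_choice = 0
    prev_valence = 0

    choice = np.zeros(n, dtype=np.int64)
    received = np.zeros(n, dtype=float)
    probs = np.empty(n)

    for t in range(n):
        cod = _m.ConditionCoding(int(chi_block[t]), chi_version, prev_valence)

        def par(name):
            return _m.resolve_parameter(spec, params, cod, name)

        if prev_choice != 0:
            prev_good = prev_valence == 1
            if spec.family in ("additive", "multiplicative"):
                p = _m.update_probability(p, outcome[t - 1], par("alpha"))
            elif spec.family == "two_estimate":
                a, d = par("alpha"), par("delta")
                if prev_choice == 1:
                    p = _m.update_probability(p, 1 if prev_good else 0, a)
                else:
                    q = _m.update_probability(q, 1 if prev_good else 0, a)
                p = _m.decay_probability(p, d)
                q = _m.decay_probability(q, d)
            else:
                counts, p, q = _m.beta_bernoulli_step(
                    counts, prev_choice, prev_good, par("alpha"), par("delta")
                )
            if spec.has_kernel:
                k = _m.update_choice_kernel(
                    k, 1 if prev_choice == 1 else 0, par("eta")
                )

        if spec.family == "multiplicative":
            v = _m.value_multiplicative(
                _m.risk_adjust(p, par("gamma")), m1[t], m2[t]
            )
        else:
            lam = par("lambda")
            r = par("r") if "r" in spec.parameter_table else 1.0
            p_diff = (p - q) if spec.family in ("two_estimate",
                                                "beta_bernoulli") else (2.0 * p - 1.0)
            v = lam * p_diff + (1.0 - lam) * _m.signed_power(m1[t] - m2[t], r)

        probs[t] = _m.choice_probability(
            v, k,
            par("omega"),
            par("omega_k") if spec.has_kernel else 0.0,
            par("epsilon") if spec.has_lapse else 0.0,
        )

        missed = missing_rate > 0.0 and rng.random() < missing_rate
        c = 0 if missed else (1 if rng.random() < probs[t] else 2)
        choice[t] = c
        if c != 0:
            event_received = c == event_shape[t]
            received[t] = (m1_raw[t] if c == 1 else m2_raw[t]) if event_received else 0.0
            good = event_received == event_is_good
            prev_valence = 1 if good else -1
        else:
            prev_valence = 0
        prev_choice = c

    ds = ChoiceDataset(subject, schedule, choice, outcome, received)
    ds.choice_prob = probs  # generative probabilities, kept for diagnostics
    return ds


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class CohortSpec:
    """Design of a synthetic study."""

    n_subjects: int = 20
    task_versions: tuple[str, ...] = ("gain", "aversive")
    population: PopulationModel = None
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.population is None:
            self.population = default_population()


@dataclass
class GroundTruth:
    """Everything a synthetic study generated, regenerable from its spec."""

    cohort: CohortSpec
    scores: pd.DataFrame                 # subjects x factor scores
    parameters: pd.DataFrame             # subjects x components (truth)
    datasets: list[ChoiceDataset] = field(repr=False)

    @property
    def subjects(self) -> list[str]:
        return list(self.scores.index)


def _block_order_assignment(n_subjects: int, n_versions: int) -> list[tuple[str, ...]]:
    # counterbalance the block-order combination across versions; with two
    # versions this cycles through the four combinations so each is assigned
    # to n/4 subjects (+-1)
    combos = []
    n_combo = len(BLOCK_ORDERS) ** n_versions
    for i in range(n_combo):
        combo = []
        x = i
        for _ in range(n_versions):
            combo.append(BLOCK_ORDERS[x % len(BLOCK_ORDERS)])
            x //= len(BLOCK_ORDERS)
        combos.append(tuple(combo))
    return [combos[s % n_combo] for s in range(n_subjects)]


def simulate_cohort(cohort: CohortSpec) -> GroundTruth:
    """Simulate a full synthetic study.

    Factor scores are i.i.d. standard normal; subject parameters follow the
    population model; block orders are counterbalanced across subjects; the
    magnitude/event schedule for a given (version, block order) is shared by
    all subjects with that block order, mirroring the yoked magnitude
    sequences of the real task.
    """
    pop = cohort.population
    spec = pop.spec
    root = np.random.SeedSequence(cohort.seed)
    s_scores, s_params, s_choices = root.spawn(3)

    n = cohort.n_subjects
    subjects = [f"s{i:03d}" for i in range(n)]
    rng = np.random.default_rng(s_scores)
    scores = pd.DataFrame(
        rng.standard_normal((n, 3)), index=subjects, columns=list(FACTOR_NAMES)
    )
    params = draw_subject_parameters(pop, scores, s_params)

    schedules = {
        (v, order): make_schedule(v, order, cohort.seed)
        for v in cohort.task_versions
        for order in BLOCK_ORDERS
    }
    orders = _block_order_assignment(n, len(cohort.task_versions))
    choice_seeds = np.random.default_rng(s_choices).integers(
        0, 2**31 - 1, size=(n, len(cohort.task_versions))
    )

    datasets = []
    for s, subj in enumerate(subjects):
        pdict = params.loc[subj].to_dict()
        for j, version in enumerate(cohort.task_versions):
            ds = simulate_choices(
                spec, pdict, schedules[(version, orders[s][j])],
                int(choice_seeds[s, j]), cohort.missing_rate, subject=subj,
            )
            datasets.append(ds)
    return GroundTruth(cohort, scores, params, datasets)


# ---------------------------------------------------------------------------
# Ordinal questionnaire items from a planted bifactor structure

def make_bifactor_loadings(n_items: int = 128, general: float = 0.6,
                           specific: float = 0.4, seed: int = 0) -> np.ndarray:
    """Planted loading matrix: every item on the general factor plus one of
    two specific factors (first half depression-like, second half
    anxiety-like).

    Loadings are drawn with substantial heterogeneity around the target
    values, as in real symptom batteries; items with (near-)uniform loadings
    would make the general column nearly collinear with the sum of the
    specific-block indicators and collapse the common space to rank two.
    """
    rng = np.random.default_rng(seed)
    L = np.zeros((n_items, 3))
    # wide spread on the general loadings (items range from weak to strong
    # markers of the shared dimension); specific loadings stay bounded away
    # from zero so every item carries usable specific-factor information
    L[:, 0] = general + 0.3 * rng.uniform(-1, 1, n_items)
    half = n_items // 2
    L[:half, 1] = specific + rng.uniform(-0.15, 0.2, half)
    L[half:, 2] = specific + rng.uniform(-0.15, 0.2, n_items - half)
    # keep communalities comfortably below 1
    comm = (L**2).sum(axis=1)
    over = comm > 0.9
    L[over] *= np.sqrt(0.9 / comm[over])[:, None]
    return L


def default_thresholds(n_items: int, seed: int = 0,
                       category_counts: tuple[int, ...] = (2, 5, 6, 5, 6),
                       ) -> list[np.ndarray]:
    """Ordinal cutpoints per item, with a random skew shift as in real
    symptom inventories.

    The default category mixture mirrors the modelled battery: roughly one
    binary (yes/no personality) item for every four polytomous (5- or
    6-option) mood/anxiety items."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_items):
        n_cat = category_counts[i % len(category_counts)]
        base = np.linspace(0.15, 0.85, n_cat - 1)
        cuts = _norm_ppf(base) + 0.5 * rng.standard_normal()
        out.append(np.sort(cuts))
    return out


def _norm_ppf(q):
    from scipy.stats import norm

    return norm.ppf(q)


def simulate_item_responses(loadings: np.ndarray,
                            thresholds: list[np.ndarray],
                            n_subjects: int, seed: int):
    """Generate ordinal item responses from a planted bifactor structure.

    Latent factors are i.i.d. standard normal; each item's latent response is
    ``loadings @ factors`` plus Normal noise with variance ``1 - communality``
    so the latent responses are standardized; the observed code is the
    number of thresholds below the latent response.  Returns the observed
    (subjects x items) DataFrame and the latent factor values.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError("loadings must be (n_items, 3)")
    communality = (L**2).sum(axis=1)
    if np.any(communality > 1.0):
        raise ValueError("item communality exceeds 1")
    if len(thresholds) != L.shape[0]:
        raise ValueError("one threshold vector per item required")

    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_subjects, 3))
    noise = rng.standard_normal((n_subjects, L.shape[0]))
    latent = factors @ L.T + noise * np.sqrt(1.0 - communality)

    items = np.column_stack(
        [np.searchsorted(np.asarray(thresholds[j]), latent[:, j])
         for j in range(L.shape[0])]
    )
    subjects = [f"s{i:03d}" for i in range(n_subjects)]
    obs = pd.DataFrame(
        items, index=subjects,
        columns=[f"item{j:03d}" for j in range(L.shape[0])],
    )
    lat = pd.DataFrame(factors, index=subjects,
                       columns=["general", "specific1", "specific2"])
    return obs, lat
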