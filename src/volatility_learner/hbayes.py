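"""Hierarchical Bayesian estimation of the model family.

Every subject-level parameter component ``theta[s, c]`` (unconstrained
scale) receives an independent population-level prior

    theta[s, c] ~ Normal(mu_c + bg_c * Xg_s + bd_c * Xd_s + ba_c * Xa_s,
                         sigma_c^2)

where ``(Xg, Xd, Xa)`` are the subject's scores on the general,
depression-specific and anxiety-specific internalizing factors.  Hyperpriors
are Normal(0, 10) on the intercepts and weights and half-Cauchy(2.5) on the
population SDs.

Sampling is blocked MCMC tailored to this posterior's structure:

* subject components -- adaptive Metropolis-within-Gibbs, one component at a
  time, vectorized across subjects (subjects are conditionally independent
  given the population level);
* population intercepts/weights -- exact conjugate Gibbs draws (Bayesian
  linear regression with a known-variance Normal likelihood);
* population SDs -- adaptive Metropolis on ``log sigma``.

Proposal scales adapt only during the tuning phase, so the post-tune chain
is a valid time-homogeneous Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr

from . import models as _m
from ._kernels import FAMILY_CODES
from ._kernels import loglik_matrix as _loglik_matrix
from .models import ChoiceDataset, ModelSpec, component_name

HYPERPRIOR_SD = 10.0        # Normal(0, 10) on mu and betas
SIGMA_CAUCHY_SCALE = 2.5    # half-Cauchy(2.5) on sigma
COVARIATES = ("general", "depression", "anxiety")
RHAT_THRESHOLD = 1.1


# ---------------------------------------------------------------------------
# Model assembly

@dataclass
class HierarchicalModel:
    """A cohort likelihood plus its population-level structure.

    Trials of each subject's task runs are concatenated along one axis with
    per-run state resets; subjects with fewer trials are padded with missed
    responses, which contribute nothing to the likelihood.
    """

    spec: ModelSpec
    subjects: list[str]
    components: list[tuple[str, tuple[str, ...]]]
    scores: pd.DataFrame          # z-scored, indexed by subject
    _data: dict = field(repr=False)
    _designs: dict = field(repr=False)   # param -> (cols, D (S,T,Kp), link)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_subject_parameters(self) -> int:
        """Total subject-level parameter count (components x subjects)."""
        return self.n_components * self.n_subjects

    def component_names(self) -> list[str]:
        return [component_name(p, c) for p, c in self.components]

    @property
    def covariate_matrix(self) -> np.ndarray:
        """(S, 4) design [1, Xg, Xd, Xa] for the population linear model."""
        X = np.ones((self.n_subjects, 4))
        X[:, 1:] = self.scores.loc[self.subjects, list(COVARIATES)].to_numpy()
        return X

    @property
    def valid_mask(self) -> np.ndarray:
        """(S, T) mask of observed choices (real, non-missed trials)."""
        return self._data["choice"] > 0

    def natural_parameters(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Per-trial natural-scale parameter arrays for components theta."""
        nat = {}
        for p, (cols, D, link) in self._designs.items():
            nat[p] = _m.apply_link(link, np.einsum("stj,sj->st", D, theta[:, cols]))
        return nat

    def _kernel_args(self, nat: dict[str, np.ndarray]):
        d = self._data
        ones = d["_ones"]
        zeros = d["_zeros"]
        return (
            FAMILY_CODES[self.spec.family],
            nat["alpha"],
            nat.get("lambda", nat.get("gamma")),
            nat["omega"],
            nat.get("omega_k", zeros),
            nat.get("eta", zeros),
            nat.get("r", ones),
            nat.get("epsilon"),
            nat.get("delta", zeros),
            d["outcome"], d["choice"], d["good"], d["m1n"], d["m2n"],
            d["new_run"], d["_sign_dm"], d["_abs_dm"], d["_buf"],
        )

    def loglik_matrix(self, theta: np.ndarray,
                      nat: dict[str, np.ndarray] | None = None) -> np.ndarray:
        """(S, T) pointwise choice log-likelihood (0 at missed/padded)."""
        if nat is None:
            nat = self.natural_parameters(theta)
        return _loglik_matrix(*self._kernel_args(nat))

    def loglik(self, theta: np.ndarray,
               nat: dict[str, np.ndarray] | None = None) -> np.ndarray:
        """(S,) total log-likelihood per subject."""
        return self.loglik_matrix(theta, nat).sum(axis=1)


def _group_datasets(datasets) -> dict[str, list[ChoiceDataset]]:
    if isinstance(datasets, dict):
        grouped = {k: list(v) for k, v in datasets.items()}
    else:
        grouped = {}
        for ds in datasets:
            grouped.setdefault(ds.subject, []).append(ds)
    for runs in grouped.values():
        runs.sort(key=lambda ds: ds.task_version)
    return grouped


def build_model(spec: ModelSpec, datasets, scores) -> HierarchicalModel:
    """Assemble the hierarchical model for a cohort.

    ``datasets`` is a flat list of :class:`ChoiceDataset` (or a mapping
    subject -> runs); ``scores`` is a DataFrame indexed by subject with
    columns ``general``, ``depression``, ``anxiety``.  Factor scores are
    z-scored before entering the population linear model.  Components whose
    effect code never varies in the data (e.g. the version contrast when
    only one task version is present) are dropped with a warning.
    """
    grouped = _group_datasets(datasets)
    if not grouped:
        raise ValueError("no datasets supplied")
    subjects = sorted(grouped)

    scores = pd.DataFrame(scores).copy()
    missing = [s for s in subjects if s not in scores.index]
    if missing:
        raise ValueError(f"subjects missing factor scores: {missing}")
    scores = scores.loc[subjects, list(COVARIATES)].astype(float)
    sd = scores.std(ddof=0).replace(0.0, 1.0)
    scores = (scores - scores.mean()) / sd

    # stack trials: (S, T_max) arrays, padded with missed responses
    T = max(sum(ds.n_trials for ds in runs) for runs in grouped.values())
    S = len(subjects)
    outcome = np.zeros((S, T), dtype=np.int64)
    choice = np.zeros((S, T), dtype=np.int64)
    good = np.zeros((S, T), dtype=np.int64)
    m1n = np.full((S, T), 0.5)
    m2n = np.full((S, T), 0.5)
    new_run = np.zeros((S, T), dtype=np.bool_)
    chi = {f: np.zeros((S, T)) for f in _m.FACTORS}

    for s, subj in enumerate(subjects):
        pos = 0
        for ds in grouped[subj]:
            n = ds.n_trials
            sl = slice(pos, pos + n)
            outcome[s, sl] = ds.outcome
            choice[s, sl] = ds.choice
            good[s, sl] = ds.good_outcome()
            m1, m2 = ds.schedule.magnitudes
            m1n[s, sl] = m1 / 100.0
            m2n[s, sl] = m2 / 100.0
            new_run[s, pos] = True
            cods = _m.trial_codings(ds)
            chi["block"][s, sl] = [c.chi_block for c in cods]
            chi["version"][s, sl] = [c.chi_version for c in cods]
            chi["valence"][s, sl] = [c.chi_valence for c in cods]
            pos += n
        new_run[s, pos:] = False

    real = choice > 0  # padded trials never constrain identifiability

    def chi_product(comp: tuple[str, ...]) -> np.ndarray:
        out = np.ones((S, T))
        for f in comp:
            out = out * chi[f]
        return out

    components: list[tuple[str, tuple[str, ...]]] = []
    designs: dict[str, tuple[np.ndarray, np.ndarray, str]] = {}
    col = 0
    for p, (comps, link) in spec.parameter_table.items():
        kept, cols_p, prods = [], [], []
        for comp in comps:
            prod = chi_product(comp)
            flat = prod[real]
            constant = comp and np.ptp(flat) == 0.0
            collinear = any(
                np.ptp(flat - q[real]) == 0.0 or np.ptp(flat + q[real]) == 0.0
                for q in prods
            )
            if constant or collinear:
                warnings.warn(
                    f"dropping component {component_name(p, comp)}: its "
                    "effect code does not vary in the supplied data or is "
                    "confounded with another component",
                    stacklevel=2,
                )
                continue
            kept.append(comp)
            cols_p.append(col)
            prods.append(prod)
            components.append((p, comp))
            col += 1
        designs[p] = (
            np.array(cols_p, dtype=np.int64),
            np.stack(prods, axis=2),
            link,
        )

    dm = m1n - m2n
    with np.errstate(divide="ignore"):
        log_abs_dm = np.where(dm == 0.0, -745.0, np.log(np.abs(dm)))
    data = {
        "outcome": outcome, "choice": choice, "good": good,
        "m1n": m1n, "m2n": m2n, "new_run": new_run,
        "_zeros": np.zeros((S, T)), "_ones": np.ones((S, T)),
        "_sign_dm": np.sign(dm), "_abs_dm": log_abs_dm,
        "_buf": (np.empty((S, T)), np.empty((S, T))),
    }
    return HierarchicalModel(spec, subjects, components, scores, data, designs)


# ---------------------------------------------------------------------------
# Sampling

def _halfcauchy_logpdf(sigma: float, scale: float = SIGMA_CAUCHY_SCALE) -> float:
    return -np.log1p((sigma / scale) ** 2)


def _warm_start(model: HierarchicalModel, rounds: int = 3) -> np.ndarray:
    """Coordinate-ascent initialization of the subject components.

    A coarse per-component line search (vectorized across subjects) on the
    penalized likelihood puts chains in the typical set, avoiding stuck
    chains during adaptation.  Deterministic.
    """
    S, K = model.n_subjects, model.n_components
    theta = np.zeros((S, K))
    offsets = np.array([-1.5, -1.0, -0.6, -0.3, -0.1, 0.0,
                        0.1, 0.3, 0.6, 1.0, 1.5])
    for _ in range(rounds):
        for k in range(K):
            best = model.loglik(theta) - 0.125 * theta[:, k] ** 2
            best_val = theta[:, k].copy()
            for off in offsets:
                if off == 0.0:
                    continue
                cand = theta.copy()
                cand[:, k] = theta[:, k] + off
                obj = model.loglik(cand) - 0.125 * cand[:, k] ** 2
                better = obj > best
                best = np.where(better, obj, best)
                best_val = np.where(better, cand[:, k], best_val)
            theta[:, k] = best_val
        offsets = offsets / 2.0
    return theta


def _run_chain(model: HierarchicalModel, tune: int, draws: int,
               rng: np.random.Generator,
               theta_init: np.ndarray | None = None) -> dict[str, np.ndarray]:
    S, K = model.n_subjects, model.n_components
    X = model.covariate_matrix                    # (S, 4)
    XtX = X.T @ X
    comp_param = [p for p, _ in model.components]
    # column index of each global component within its parameter's design
    within = {}
    for p, (cols, _D, _l) in model._designs.items():
        for j, c in enumerate(cols):
            within[c] = j

    if theta_init is None:
        theta = 0.1 * rng.standard_normal((S, K))
    else:
        theta = theta_init + 0.1 * rng.standard_normal((S, K))
    # initialize the population level at its conditional fit to the starting
    # subject components; removes the transient wander of the coefficients
    # during short adaptation phases
    gamma, *_ = np.linalg.lstsq(X, theta, rcond=None)
    gamma = gamma.T                               # (K, 4): mu, bg, bd, ba
    resid = theta - X @ gamma.T
    sigma = np.clip(resid.std(axis=0), 0.2, 2.0)
    scales = np.full((S, K), 0.4)
    sigma_scales = np.full(K, 0.4)
    trans_scales = np.full((K, 4), 0.2)
    nc_scales = np.full(K, 0.3)

    # adaptive joint per-subject proposal (covariance learned in tuning)
    joint_from = max(tune // 3, 1)
    joint_scales = np.full(S, 2.38 / np.sqrt(K))
    joint_chol = np.broadcast_to(np.eye(K), (S, K, K)).copy()
    buf_n = 0
    buf_mean = np.zeros((S, K))
    buf_m2 = np.zeros((S, K, K))

    nat = model.natural_parameters(theta)
    ll = model.loglik(theta, nat)

    out_theta = np.empty((draws, S, K))
    out_gamma = np.empty((draws, K, 4))
    out_sigma = np.empty((draws, K))

    prior_prec = 1.0 / HYPERPRIOR_SD ** 2
    eye4 = np.eye(4)

    for it in range(tune + draws):
        tuning = it < tune
        for k in range(K):
            p = comp_param[k]
            cols, D, link = model._designs[p]
            j = within[k]

            prop = theta[:, k] + scales[:, k] * rng.standard_normal(S)
            theta_p = theta[:, cols].copy()
            theta_p[:, j] = prop
            nat_p_new = _m.apply_link(link, np.einsum("stj,sj->st", D, theta_p))
            nat_new = dict(nat)
            nat_new[p] = nat_p_new
            ll_new = model.loglik(None, nat_new)

            m = X @ gamma[k]
            dprior = ((theta[:, k] - m) ** 2 - (prop - m) ** 2) / (2.0 * sigma[k] ** 2)
            accept = np.log(rng.random(S)) < (ll_new - ll + dprior)

            theta[accept, k] = prop[accept]
            nat[p] = np.where(accept[:, None], nat_p_new, nat[p])
            ll = np.where(accept, ll_new, ll)
            if tuning:
                scales[:, k] *= np.where(accept, 1.12, 0.95)
                np.clip(scales[:, k], 1e-3, 10.0, out=scales[:, k])

            # joint shift of theta[:, k] along one population-design
            # direction together with the matching coefficient (intercept or
            # one covariate weight): residuals theta - X gamma are unchanged,
            # so only the likelihood and that coefficient's hyperprior enter.
            # This lets the population mean *and* the covariate weights mix
            # at their marginal scale instead of through the slow
            # subject-level random walk.  Directions cycle across sweeps.
            d_idx = (it + k) % 4
            xdir = X[:, d_idx]
            shift = trans_scales[k, d_idx] * rng.standard_normal()
            prop = theta[:, k] + shift * xdir
            theta_p = theta[:, cols].copy()
            theta_p[:, j] = prop
            nat_p_new = _m.apply_link(link,
                                      np.einsum("stj,sj->st", D, theta_p))
            nat_new = dict(nat)
            nat_new[p] = nat_p_new
            ll_new = model.loglik(None, nat_new)
            g_new = gamma[k, d_idx] + shift
            dhyper = (gamma[k, d_idx] ** 2 - g_new ** 2) * (0.5 * prior_prec)
            if np.log(rng.random()) < ll_new.sum() - ll.sum() + dhyper:
                theta[:, k] = prop
                gamma[k, d_idx] = g_new
                nat[p] = nat_p_new
                ll = ll_new
                if tuning:
                    trans_scales[k, d_idx] *= 1.12
            elif tuning:
                trans_scales[k, d_idx] *= 0.95
            trans_scales[k, d_idx] = min(max(trans_scales[k, d_idx], 1e-3), 5.0)

            # conjugate update of (mu, beta_g, beta_d, beta_a)
            V = np.linalg.inv(XtX / sigma[k] ** 2 + prior_prec * eye4)
            mean = V @ (X.T @ theta[:, k]) / sigma[k] ** 2
            gamma[k] = rng.multivariate_normal(mean, V, method="cholesky")

            # Metropolis on log sigma with half-Cauchy prior
            resid2 = float(((theta[:, k] - X @ gamma[k]) ** 2).sum())

            def sigma_logpost(s_val: float) -> float:
                return (
                    -S * np.log(s_val)
                    - resid2 / (2.0 * s_val ** 2)
                    + _halfcauchy_logpdf(s_val)
                    + np.log(s_val)  # Jacobian of the log transform
                )

            log_s = np.log(sigma[k])
            log_s_new = log_s + sigma_scales[k] * rng.standard_normal()
            if np.log(rng.random()) < sigma_logpost(np.exp(log_s_new)) - sigma_logpost(sigma[k]):
                sigma[k] = np.exp(log_s_new)
                if tuning:
                    sigma_scales[k] *= 1.10
            elif tuning:
                sigma_scales[k] *= 0.95
            sigma_scales[k] = min(max(sigma_scales[k], 1e-3), 5.0)

            # interleaved non-centered move: rescale sigma_k and the
            # residuals jointly, holding standardized residuals fixed --
            # this lets the chain traverse the hierarchical funnel instead
            # of collapsing sigma toward zero
            m = X @ gamma[k]
            log_s = np.log(sigma[k])
            log_s_new = log_s + nc_scales[k] * rng.standard_normal()
            c = np.exp(log_s_new - log_s)
            prop = m + c * (theta[:, k] - m)
            theta_p = theta[:, cols].copy()
            theta_p[:, j] = prop
            nat_p_new = _m.apply_link(link, np.einsum("stj,sj->st", D, theta_p))
            nat_new = dict(nat)
            nat_new[p] = nat_p_new
            ll_new = model.loglik(None, nat_new)
            logr = (
                ll_new.sum() - ll.sum()
                + _halfcauchy_logpdf(np.exp(log_s_new))
                - _halfcauchy_logpdf(sigma[k])
                + (log_s_new - log_s)      # Jacobian of the log transform
            )
            if np.log(rng.random()) < logr:
                sigma[k] = np.exp(log_s_new)
                theta[:, k] = prop
                nat[p] = nat_p_new
                ll = ll_new
                if tuning:
                    nc_scales[k] *= 1.10
            elif tuning:
                nc_scales[k] *= 0.95
            nc_scales[k] = min(max(nc_scales[k], 1e-3), 5.0)

        # joint per-subject move with the adapted proposal covariance
        if it >= joint_from:
            buf_n += 1
            d1 = theta - buf_mean
            buf_mean += d1 / buf_n
            buf_m2 += np.einsum("si,sj->sij", d1, theta - buf_mean)
            if tuning and buf_n >= 2 * K and it % 50 == 0:
                cov = buf_m2 / (buf_n - 1)
                cov += 1e-6 * np.eye(K)
                try:
                    joint_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
            z = rng.standard_normal((S, K))
            prop = theta + joint_scales[:, None] * np.einsum(
                "sij,sj->si", joint_chol, z)
            ll_new = model.loglik(prop)
            m_all = X @ gamma.T                    # (S, K) prior means
            dprior = (
                ((theta - m_all) ** 2 - (prop - m_all) ** 2)
                / (2.0 * sigma[None, :] ** 2)
            ).sum(axis=1)
            accept = np.log(rng.random(S)) < (ll_new - ll + dprior)
            if accept.any():
                theta[accept] = prop[accept]
                ll = np.where(accept, ll_new, ll)
                nat = model.natural_parameters(theta)
            if tuning:
                joint_scales *= np.where(accept, 1.1, 0.97)
                np.clip(joint_scales, 1e-3, 5.0, out=joint_scales)

        if not tuning:
            d = it - tune
            out_theta[d] = theta
            out_gamma[d] = gamma
            out_sigma[d] = sigma

    return {"theta": out_theta, "gamma": out_gamma, "sigma": out_sigma}


@dataclass
class FitResult:
    """Posterior draws, diagnostics and pointwise log-likelihood access."""

    model: HierarchicalModel
    posterior: dict[str, np.ndarray]
    # posterior arrays: mu/beta_g/beta_d/beta_a/sigma (chains, draws, K),
    # theta (chains, draws, S, K)
    config: dict

    @property
    def component_names(self) -> list[str]:
        return self.model.component_names()

    @property
    def n_chains(self) -> int:
        return self.posterior["mu"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.posterior["mu"].shape[1]

    def to_inference_data(self) -> az.InferenceData:
        names = self.component_names
        coords = {
            "component": names,
            "subject": self.model.subjects,
        }
        data = {
            k: (("chain", "draw", "component"), self.posterior[k])
            for k in ("mu", "beta_g", "beta_d", "beta_a", "sigma")
        }
        data["theta"] = (("chain", "draw", "subject", "component"),
                         self.posterior["theta"])
        return az.InferenceData(posterior=xr.Dataset(data, coords=coords))

    def rhat(self, population_only: bool = True) -> pd.DataFrame:
        idata = self.to_inference_data()
        var_names = ["mu", "beta_g", "beta_d", "beta_a", "sigma"]
        if not population_only:
            var_names.append("theta")
        r = az.rhat(idata, var_names=var_names)
        rows = []
        for v in var_names:
            arr = r[v]
            if v == "theta":
                for s in arr.subject.values:
                    for c in arr.component.values:
                        rows.append((f"theta[{s},{c}]",
                                     float(arr.sel(subject=s, component=c))))
            else:
                for c in arr.component.values:
                    rows.append((f"{v}[{c}]", float(arr.sel(component=c))))
        return pd.DataFrame(rows, columns=["parameter", "rhat"])

    def posterior_mean(self, var: str) -> np.ndarray:
        return self.posterior[var].mean(axis=(0, 1))

    def posterior_mean_theta(self) -> pd.DataFrame:
        """(subjects x components) posterior-mean subject parameters."""
        return pd.DataFrame(
            self.posterior_mean("theta"),
            index=self.model.subjects,
            columns=self.component_names,
        )

    def summary(self, var: str = "mu", mass: float = 0.95) -> pd.DataFrame:
        arr = self.posterior[var].reshape(-1, self.posterior[var].shape[-1])
        rows = []
        for i, name in enumerate(self.component_names):
            lo, hi = hdi(arr[:, i], mass)
            rows.append(
                {
                    "component": name,
                    "mean": arr[:, i].mean(),
                    "sd": arr[:, i].std(ddof=1),
                    f"hdi_{mass:.0%}_lower": lo,
                    f"hdi_{mass:.0%}_upper": hi,
                    "credible": credible((lo, hi)),
                }
            )
        return pd.DataFrame(rows)

    def pointwise_loglik(self, max_draws: int = 500,
                         seed: int | None = None) -> np.ndarray:
        """(n_points, n_draws) log-likelihood at observed choices.

        Draws are thinned evenly across chains.  Points are the observed
        (non-missed, non-padded) trials, subject-major.
        """
        theta = self.posterior["theta"].reshape(-1, *self.posterior["theta"].shape[2:])
        total = theta.shape[0]
        if total > max_draws:
            idx = np.linspace(0, total - 1, max_draws).astype(int)
            theta = theta[idx]
        mask = self.model.valid_mask
        out = np.empty((int(mask.sum()), theta.shape[0]))
        for d in range(theta.shape[0]):
            out[:, d] = self.model.loglik_matrix(theta[d])[mask]
        return out


def fit(model: HierarchicalModel, chains: int = 4, tune: int = 200,
        draws: int = 2000, seed: int | None = None) -> FitResult:
    """Sample the full posterior.

    Runs ``chains`` independent adaptive MCMC chains (see module docstring)
    with ``tune`` adaptation sweeps discarded and ``draws`` kept per chain.
    Warns if any population-level R-hat exceeds 1.1.
    """
    if model.n_subjects == 0:
        raise ValueError("cohort is empty")
    seqs = np.random.SeedSequence(seed).spawn(chains)
    theta_init = _warm_start(model)
    results = [
        _run_chain(model, tune, draws, np.random.default_rng(s), theta_init)
        for s in seqs
    ]
    posterior = {
        "theta": np.stack([r["theta"] for r in results]),
        "sigma": np.stack([r["sigma"] for r in results]),
    }
    gam = np.stack([r["gamma"] for r in results])  # (C, D, K, 4)
    for i, name in enumerate(("mu", "beta_g", "beta_d", "beta_a")):
        posterior[name] = gam[..., i]
    result = FitResult(
        model, posterior,
        {"chains": chains, "tune": tune, "draws": draws, "seed": seed},
    )
    if chains > 1:
        r = result.rhat()
        bad = r[r["rhat"] > RHAT_THRESHOLD]
        if len(bad):
            warnings.warn(
                f"{len(bad)} population-level parameters have R-hat > "
                f"{RHAT_THRESHOLD}: {bad['parameter'].tolist()[:10]}",
                stacklevel=2,
            )
    return result


# ---------------------------------------------------------------------------
# Posterior intervals

def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n == 0:
        raise ValueError("empty draw vector")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def credible(interval: tuple[float, float]) -> bool:
    """True iff the interval excludes zero (boundary zero is not credible)."""
    lo, hi = interval
    return lo > 0.0 or hi < 0.0
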