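"""Exploratory bifactor analysis of ordinal symptom items.

Pipeline: collapse sparsely endorsed response categories, estimate the
polychoric correlation matrix (two-step estimator), decide the dimensionality
by parallel analysis, extract an oblique factor solution (principal-axis
factoring + quartimin rotation by gradient projection), fit a single higher-
order factor to the lower-order factor correlations, and orthogonalize by
Schmid-Leiman so every item loads on one *general* factor and at most one
*specific* factor.  Factor scores use the Anderson-Rubin weighted-least-
squares solution, which keeps the score columns exactly uncorrelated with
unit variance on the estimation sample.

With exactly two lower-order factors the higher-order model is
under-identified; the standard equality constraint is imposed (both
lower-order factors load sqrt(phi) on the general factor, phi their
correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

# ---------------------------------------------------------------------------
# Category collapsing


def collapse_sparse_categories(items: pd.DataFrame,
                               threshold: float = 0.02) -> pd.DataFrame:
    """Merge response categories endorsed by fewer than ``threshold`` of
    subjects into their inward neighbor, repeating until every remaining
    category of every item reaches the threshold.  Category codes are
    re-indexed to be contiguous from 0.  Items left with a single category
    are dropped with a warning.
    """
    if not 0.0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    n = len(items)
    out = {}
    dropped = []
    for col in items.columns:
        x = items[col].to_numpy().copy()
        # contiguous re-code
        cats = np.unique(x)
        x = np.searchsorted(cats, x)
        while True:
            k = x.max() + 1
            if k <= 1:
                break
            freq = np.bincount(x, minlength=k) / n
            sparse = np.flatnonzero(freq < threshold)
            if len(sparse) == 0:
                break
            c = sparse[np.argmin(freq[sparse])]
            if c == 0:
                x[x == 0] = 1
            elif c == k - 1:
                x[x == k - 1] = k - 2
            else:  # interior: merge into the better-endorsed neighbor
                target = c - 1 if freq[c - 1] >= freq[c + 1] else c + 1
                x[x == c] = target
            cats = np.unique(x)
            x = np.searchsorted(cats, x)
        if x.max() == 0:
            dropped.append(col)
        else:
            out[col] = x
    if dropped:
        warnings.warn(
            f"dropping single-category items: {dropped}", stacklevel=2
        )
    return pd.DataFrame(out, index=items.index)


# ---------------------------------------------------------------------------
# Polychoric correlations

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)


def _bvn_cdf_grid(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate standard normal CDF on the grid h x k.

    Uses Phi2(h, k, rho) = Phi(h) Phi(k) + int_0^rho phi2(h, k, r) dr with
    fixed Gauss-Legendre nodes, accurate to ~1e-10 for |rho| <= 0.999.
    """
    H, K = np.meshgrid(h, k, indexing="ij")
    base = norm.cdf(H) * norm.cdf(K)
    if rho == 0.0:
        return base
    r = 0.5 * rho * (_GL_NODES + 1.0)
    w = 0.5 * rho * _GL_WEIGHTS
    Hr = H[..., None]
    Kr = K[..., None]
    om = 1.0 - r**2
    dens = np.exp(-(Hr**2 - 2.0 * r * Hr * Kr + Kr**2) / (2.0 * om)) / (
        2.0 * np.pi * np.sqrt(om)
    )
    return base + (dens * w).sum(axis=-1)


def _cell_probabilities(tau1: np.ndarray, tau2: np.ndarray,
                        rho: float) -> np.ndarray:
    """Probability of each (category1, category2) cell under the bivariate
    normal with thresholds tau1/tau2 (finite interior cutpoints)."""
    big = 1e10
    a = np.concatenate([[-big], tau1, [big]])
    b = np.concatenate([[-big], tau2, [big]])
    F = _bvn_cdf_grid(a, b, rho)
    return np.maximum(F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1], 1e-12)


def _item_thresholds(x: np.ndarray) -> np.ndarray:
    k = x.max() + 1
    cum = np.cumsum(np.bincount(x, minlength=k))[:-1] / len(x)
    return norm.ppf(cum)


def polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation of two ordinal variables."""
    tau1 = _item_thresholds(x)
    tau2 = _item_thresholds(y)
    table = np.zeros((x.max() + 1, y.max() + 1))
    np.add.at(table, (x, y), 1.0)

    def nll(rho):
        return -(table * np.log(_cell_probabilities(tau1, tau2, rho))).sum()

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def nearest_psd_correlation(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive semi-definite correlation matrix."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= eps:
        return R
    vals = np.clip(vals, eps, None)
    S = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def polychoric_correlation(items: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-step polychoric correlation matrix.

    Thresholds come from the marginal category frequencies via the inverse
    standard normal; each pairwise correlation maximizes the bivariate
    normal likelihood.  A non-positive-definite result is smoothed to the
    nearest PSD correlation matrix with a warning.
    """
    cols = list(items.columns)
    X = items.to_numpy().astype(np.int64)
    p = len(cols)
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            R[i, j] = R[j, i] = polychoric_pair(X[:, i], X[:, j])
    if np.linalg.eigvalsh(R).min() < 0:
        warnings.warn(
            "polychoric matrix not positive semi-definite; smoothing",
            stacklevel=2,
        )
        R = nearest_psd_correlation(R)
    return pd.DataFrame(R, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# Parallel analysis


def parallel_analysis(R: pd.DataFrame | np.ndarray, n_subjects: int,
                      n_sims: int = 50, seed: int = 0):
    """Factor retention by comparison with eigenvalues of random data.

    Simulates ``n_sims`` standard-normal (n_subjects x n_items) matrices,
    averages their correlation eigenvalue sequences, and retains the leading
    observed eigenvalues that exceed the simulated mean of the same rank.
    Returns (n_retained, eigenvalue table).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    obs = np.linalg.eigvalsh(R)[::-1]
    rng = np.random.default_rng(seed)
    sim = np.empty((n_sims, p))
    for s in range(n_sims):
        X = rng.standard_normal((n_subjects, p))
        sim[s] = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))[::-1]
    sim_mean = sim.mean(axis=0)
    above = obs > sim_mean
    n_retained = int(np.argmin(above)) if not above.all() else p
    table = pd.DataFrame(
        {"rank": np.arange(1, p + 1), "observed": obs, "random_mean": sim_mean}
    )
    return n_retained, table


# ---------------------------------------------------------------------------
# Factor extraction, rotation, Schmid-Leiman


def principal_axis(R: np.ndarray, n_factors: int, max_iter: int = 200,
                   tol: float = 1e-7) -> np.ndarray:
    """Principal-axis factoring with iterated communalities."""
    R = np.asarray(R, dtype=float)
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))  # squared multiple corr
    except np.linalg.LinAlgError:
        h2 = np.full(R.shape[0], 0.5)
    h2 = np.clip(h2, 0.0, 0.98)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:n_factors]
        L = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
        new_h2 = np.clip((L**2).sum(axis=1), 0.0, 0.995)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    # a factor whose eigenvalue is negligible carries no common variance
    L[:, np.clip(vals[idx], 0.0, None) < 0.02] = 0.0
    # orient each factor so its loading sum is positive
    signs = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    return L * signs


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    L2 = L**2
    N = np.ones((L.shape[1], L.shape[1])) - np.eye(L.shape[1])
    f = float((L2 * (L2 @ N)).sum()) / 4.0
    G = L * (L2 @ N)
    return f, G


def oblimin_rotate(A: np.ndarray, max_iter: int = 500,
                   tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Oblique quartimin rotation by gradient projection.

    Returns the rotated pattern matrix and the factor correlation matrix.
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    T = np.eye(m)
    L = A @ np.linalg.inv(T).T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ np.linalg.inv(T)).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag((T * G).sum(axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            Xn = X / np.sqrt((X**2).sum(axis=0))
            Lt = A @ np.linalg.inv(Xn).T
            ft, Gqt = _quartimin(Lt)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Xn
        L = Lt
        f = ft
        G = -(L.T @ Gqt @ np.linalg.inv(T)).T
    Phi = T.T @ T
    # orient factors positively
    signs = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


@dataclass
class FactorSolution:
    """Orthogonalized general + specific loadings of an item battery."""

    loadings: pd.DataFrame          # items x [general, specific1, ...]
    communalities: pd.Series
    item_assignment: pd.Series      # specific factor per item ('' if none)
    factor_correlation: np.ndarray  # lower-order factor correlations
    higher_order_loadings: np.ndarray

    @property
    def items(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def uniquenesses(self) -> pd.Series:
        return 1.0 - self.communalities


@dataclass
class FactorScores:
    """Per-subject orthogonal factor scores."""

    scores: pd.DataFrame            # subjects x factors

    def __getitem__(self, key):
        return self.scores[key]

    @property
    def frame(self) -> pd.DataFrame:
        return self.scores


def schmid_leiman(R: pd.DataFrame | np.ndarray, n_specific: int = 2,
                  assignment_threshold: float = 0.2) -> FactorSolution:
    """Bifactor solution by Schmid-Leiman orthogonalization.

    Extracts ``n_specific`` oblique lower-order factors, fits one higher-
    order factor to their correlations, and orthogonalizes: the general
    loading of an item is its lower-order loading times the higher-order
    loading; the specific loading is the lower-order loading times
    ``sqrt(1 - higher_order^2)``.  With two lower-order factors, equal
    higher-order loadings ``sqrt(phi)`` are imposed (under-identification
    constraint).
    """
    if n_specific < 2:
        raise ValueError("need at least two lower-order factors")
    if isinstance(R, pd.DataFrame):
        item_names = list(R.index)
        Rm = R.to_numpy()
    else:
        Rm = np.asarray(R, dtype=float)
        item_names = [f"item{j:03d}" for j in range(Rm.shape[0])]

    A = principal_axis(Rm, n_specific)
    P, Phi = oblimin_rotate(A)

    if n_specific == 2:
        phi = float(np.clip(Phi[0, 1], 0.0, 0.995))
        g = np.full(2, np.sqrt(phi))
    else:
        g = principal_axis(Phi, 1)[:, 0]
        g = np.clip(np.abs(g), 0.0, 0.9995)

    general = P @ g
    specific = P * np.sqrt(1.0 - g**2)

    h2 = np.clip(np.einsum("ij,jk,ik->i", P, Phi, P), 0.0, 1.0)
    heywood = np.flatnonzero(h2 > 0.998)
    if len(heywood):
        warnings.warn(
            f"near-Heywood communalities for items {heywood.tolist()}",
            stacklevel=2,
        )

    cols = ["general"] + [f"specific{j+1}" for j in range(n_specific)]
    loadings = pd.DataFrame(
        np.column_stack([general, specific]), index=item_names, columns=cols
    )
    assign = []
    for i in range(len(item_names)):
        s = np.abs(specific[i])
        j = int(np.argmax(s))
        assign.append(cols[1 + j] if s[j] > assignment_threshold else "")
    return FactorSolution(
        loadings,
        pd.Series(h2, index=item_names, name="communality"),
        pd.Series(assign, index=item_names, name="specific_factor"),
        Phi,
        g,
    )


# ---------------------------------------------------------------------------
# Factor scores


def _standardize(items: pd.DataFrame, stats: pd.DataFrame | None = None):
    if stats is None:
        mean = items.mean()
        sd = items.std(ddof=0).replace(0.0, 1.0)
    else:
        mean = stats["mean"]
        sd = stats["sd"].replace(0.0, 1.0)
    return (items - mean) / sd


def scoring_loadings(solution: FactorSolution) -> pd.DataFrame:
    """Bifactor pattern used for scoring: general loading plus the assigned
    specific loading only.

    The raw Schmid-Leiman loadings from two lower-order factors span a
    rank-2 column space (the general column is a linear combination of the
    specifics), which makes three-factor scoring singular.  Zeroing
    unassigned specific loadings -- the same purification the confirmatory
    item-assignment rule applies -- restores identifiability.
    """
    L = solution.loadings.copy()
    for col in L.columns[1:]:
        mask = solution.item_assignment != col
        L.loc[mask, col] = 0.0
    return L


def refine_pattern(R: pd.DataFrame | np.ndarray, solution: FactorSolution,
                   sweeps: int = 40) -> FactorSolution:
    """Re-estimate loading magnitudes under the assigned bifactor pattern.

    The Schmid-Leiman transform constrains every item's general:specific
    loading ratio to be constant within a lower-order factor, which blurs
    per-item differences when the battery is heterogeneous.  Holding the
    item assignment fixed, this step re-fits each item's free loadings
    (general + assigned specific) to the off-diagonal correlations by
    alternating least squares -- the exploratory counterpart of
    re-estimating loadings after item assignment.
    """
    Rm = R.to_numpy() if isinstance(R, pd.DataFrame) else np.asarray(R)
    P = scoring_loadings(solution).to_numpy().copy()
    mask = P != 0.0
    n = P.shape[0]
    for _ in range(sweeps):
        for i in range(n):
            idx = np.flatnonzero(mask[i])
            others = np.delete(np.arange(n), i)
            A = P[others][:, idx]
            P[i, idx] = np.linalg.lstsq(A, Rm[i, others], rcond=None)[0]
    h2 = np.clip((P**2).sum(axis=1), 0.0, 0.96)
    loadings = pd.DataFrame(P, index=solution.items,
                            columns=solution.loadings.columns)
    return FactorSolution(
        loadings,
        pd.Series(h2, index=solution.items, name="communality"),
        solution.item_assignment.copy(),
        solution.factor_correlation,
        solution.higher_order_loadings,
    )


def _ar_weights(L: np.ndarray, psi: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Anderson-Rubin scoring weights W such that cov(Z W) = I when
    cov(Z) = R: W = Psi^-1 L (L' Psi^-1 R Psi^-1 L)^(-1/2)."""
    A = L / psi[:, None]
    M = A.T @ R @ A
    vals, vecs = np.linalg.eigh(M)
    if vals.min() <= 1e-10:
        raise np.linalg.LinAlgError(
            "scoring matrix is singular; factors are not identified from "
            "these items"
        )
    M_inv_sqrt = (vecs / np.sqrt(vals)) @ vecs.T
    return A @ M_inv_sqrt


def anderson_rubin_scores(items: pd.DataFrame, R: pd.DataFrame | np.ndarray,
                          solution: FactorSolution) -> FactorScores:
    """Anderson-Rubin factor scores from ordinal/standardized responses.

    The responses are standardized and weighted by the solution's loadings
    and uniquenesses; the whitening step uses the sample correlation of the
    standardized responses, which makes the score columns exactly
    orthonormal on the estimation sample (the defining Anderson-Rubin
    property).  ``R`` (the analysis correlation matrix) is used as a
    fallback when the sample is too small to estimate its own correlations.
    """
    Z = _standardize(items[solution.items])
    Zm = Z.to_numpy()
    if len(items) > len(solution.items):
        R_score = np.corrcoef(Zm, rowvar=False)
    else:
        R_score = np.asarray(R, dtype=float)
    W = _ar_weights(
        scoring_loadings(solution).to_numpy(),
        np.clip(solution.uniquenesses.to_numpy(), 1e-3, None),
        R_score,
    )
    F = Zm @ W
    return FactorScores(
        pd.DataFrame(F, index=items.index, columns=solution.loadings.columns)
    )


def score_with_item_subset(solution: FactorSolution,
                           items_subset: pd.DataFrame,
                           normalization_stats: pd.DataFrame | None = None
                           ) -> FactorScores:
    """Score subjects from a subset of the solution's items.

    ``normalization_stats`` (columns ``mean``/``sd`` indexed by item) should
    come from the pooled reference sample so scores are comparable across
    datasets; when omitted the subset sample's own statistics are used.
    """
    subset = [c for c in solution.items if c in items_subset.columns]
    if not subset:
        raise ValueError("no overlap between subset items and the solution")
    missing = set(items_subset.columns) - set(solution.items)
    if missing:
        raise ValueError(f"items absent from the solution: {sorted(missing)}")
    Z = _standardize(items_subset[subset],
                     None if normalization_stats is None
                     else normalization_stats.loc[subset])
    Zm = Z.to_numpy()
    idx = [solution.items.index(c) for c in subset]
    L = scoring_loadings(solution).to_numpy()[idx]
    psi = np.clip(solution.uniquenesses.to_numpy()[idx], 1e-3, None)
    R_sub = np.corrcoef(Zm, rowvar=False) if len(items_subset) > len(subset) \
        else np.eye(len(subset))
    W = _ar_weights(L, psi, R_sub)
    return FactorScores(
        pd.DataFrame(Zm @ W, index=items_subset.index,
                     columns=solution.loadings.columns)
    )


# ---------------------------------------------------------------------------
# Congruence


def factor_congruence(L1: pd.DataFrame | np.ndarray,
                      L2: pd.DataFrame | np.ndarray) -> pd.Series:
    """Per-factor cosine similarity between two loading matrices.

    Factors of ``L2`` are greedily matched to those of ``L1`` by absolute
    cosine, and signs aligned before reporting, so a reflected but otherwise
    identical solution scores 1.
    """
    A = np.asarray(L1, dtype=float)
    B = np.asarray(L2, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("loading matrices cover different item sets")
    names = (list(L1.columns) if isinstance(L1, pd.DataFrame)
             else [f"factor{j}" for j in range(A.shape[1])])
    An = A / np.maximum(np.linalg.norm(A, axis=0), 1e-12)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0), 1e-12)
    C = An.T @ Bn
    out = {}
    free = list(range(B.shape[1]))
    order = np.argsort(-np.max(np.abs(C[:, free]), axis=1))
    for i in order:
        j = free[int(np.argmax(np.abs(C[i, free])))]
        out[names[i]] = float(abs(C[i, j]))
        free.remove(j)
        if not free:
            break
    return pd.Series(out).reindex(names)
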