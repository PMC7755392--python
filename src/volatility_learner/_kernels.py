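"""Compiled per-trial recursions for the model family.

The hierarchical sampler evaluates the choice log-likelihood of a whole
cohort thousands of times.  Only the agent-state recursion (probability
estimate, choice kernel, pseudo-counts) is inherently sequential and runs
in a numba loop of cheap arithmetic; the value rule, softmax and log
probabilities are elementwise and evaluated with vectorized numpy in
:meth:`volatility_learner.hbayes.HierarchicalModel.loglik_matrix`.

Condition-dependent natural parameters are resolved *outside* the kernel
(they are affine in the unconstrained components, so they reduce to
design-matrix products).  The arithmetic mirrors
:func:`volatility_learner.models.run_model` operation-for-operation, and a
test asserts agreement to 1e-10.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import expit

FAMILY_CODES = {
    "additive": 0,
    "multiplicative": 1,
    "two_estimate": 2,
    "beta_bernoulli": 3,
}


@njit(cache=True)
def state_kernel(family, alpha, eta, delta, outcome, choice, good, new_run,
                 p_out, k_out):
    """Run the sequential agent-state recursion for a stacked cohort.

    Writes, per (subject, trial), the probability term entering the value
    rule -- ``2p - 1`` for the single-estimate families, ``p`` itself for
    the multiplicative family (code 1) and ``p - q`` for the two-estimate
    and Beta-Bernoulli families -- into ``p_out``, and the choice kernel
    into ``k_out``.  State resets at ``new_run``; a missed response on the
    previous trial freezes all state (no outcome was observed).
    """
    n_sub, n_trials = outcome.shape
    for s in range(n_sub):
        p = 0.5
        q = 0.5
        k = 0.5
        ca = 0.0
        cb = 0.0
        cc = 0.0
        cd = 0.0
        for t in range(n_trials):
            if new_run[s, t]:
                p = 0.5
                q = 0.5
                k = 0.5
                ca = 0.0
                cb = 0.0
                cc = 0.0
                cd = 0.0
            prev_observed = (not new_run[s, t]) and choice[s, t - 1] != 0
            if prev_observed:
                if family == 0 or family == 1:
                    p = p + alpha[s, t] * (outcome[s, t - 1] - p)
                elif family == 2:
                    o = 1.0 if good[s, t - 1] == 1 else 0.0
                    if choice[s, t - 1] == 1:
                        p = p + alpha[s, t] * (o - p)
                    else:
                        q = q + alpha[s, t] * (o - q)
                    d = delta[s, t]
                    p = (1.0 - d) * p + d * 0.5
                    q = (1.0 - d) * q + d * 0.5
                else:
                    d = delta[s, t]
                    ca *= d
                    cb *= d
                    cc *= d
                    cd *= d
                    if choice[s, t - 1] == 1:
                        if good[s, t - 1] == 1:
                            ca += alpha[s, t]
                        else:
                            cb += alpha[s, t]
                    else:
                        if good[s, t - 1] == 1:
                            cc += alpha[s, t]
                        else:
                            cd += alpha[s, t]
                    p = (ca + 1.0) / (ca + cb + 2.0)
                    q = (cc + 1.0) / (cc + cd + 2.0)
                k = k + eta[s, t] * ((1.0 if choice[s, t - 1] == 1 else 0.0) - k)

            if family == 0:
                p_out[s, t] = 2.0 * p - 1.0
            elif family == 1:
                p_out[s, t] = p
            else:
                p_out[s, t] = p - q
            k_out[s, t] = k


def loglik_matrix(family, alpha, w2, omega, omega_k, eta, rpow, eps, delta,
                  outcome, choice, good, m1n, m2n, new_run,
                  sign_dm, log_abs_dm, buf):
    """Pointwise choice log-likelihood for a stacked cohort.

    All parameter arrays are natural-scale per-trial values of shape
    (n_subjects, n_trials); ``w2`` is ``lambda`` for the additive families
    and ``gamma`` for the multiplicative one.  ``sign_dm``/``log_abs_dm``
    are the sign and log magnitude of the normalized magnitude difference
    (data).  ``buf`` supplies two preallocated (n_subjects, n_trials)
    scratch arrays.  Missed responses contribute 0.
    """
    p_term, k_term = buf
    state_kernel(family, alpha, eta, delta, outcome, choice, good, new_run,
                 p_term, k_term)
    if family == 1:
        padj = np.clip((p_term - 0.5) * w2 + 0.5, 0.0, 1.0)
        v = padj * m1n - (1.0 - padj) * m2n
    else:
        # sign_dm * |dm|^r with the power as exp(r * log|dm|); log|dm| is
        # precomputed data (log_abs_dm), -745 standing in for log 0
        v = w2 * p_term + (1.0 - w2) * sign_dm * np.exp(rpow * log_abs_dm)
    z = omega * v + omega_k * (2.0 * k_term - 1.0)
    if eps is None:
        zz = np.where(choice == 1, -z, z)
        with np.errstate(over="ignore"):
            logp = np.where(choice == 0, 0.0, -np.log1p(np.exp(zz)))
    else:
        pc = expit(z)
        pc = (1.0 - eps) * pc + 0.5 * eps
        with np.errstate(divide="ignore"):
            logp = np.where(
                choice == 1, np.log(pc),
                np.where(choice == 2, np.log1p(-pc), 0.0),
            )
    return logp
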