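"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: marginal likelihoods are
recomputed by tensor-product Gauss-Jacobi quadrature (exact for the
polynomial integrands at hand), posterior means by dense-grid integration or
exhaustive enumeration, and Clopper-Pearson bounds by bisecting the binomial
tail equations directly.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import betaln, comb, roots_jacobi
from scipy.stats import binom, gamma as gamma_dist


def jacobi_rule(n_nodes: int, a: float, b: float):
    """Nodes/weights integrating f against the Beta(a, b) density on (0,1).

    Exact for polynomial f up to degree 2*n_nodes - 1, including a, b < 1
    (the endpoint singularity is absorbed into the weight function).
    """
    x, w = roots_jacobi(n_nodes, b - 1.0, a - 1.0)
    p = (1.0 + x) / 2.0
    const = math.exp(-betaln(a, b)) * 0.5 ** (a + b - 1.0)
    return p, w * const


def likelihood_terms(J, R, E, p, pi1, pi2):
    """Observed-data likelihood of one examiner (linear scale)."""
    return (comb(J, R) * comb(R, E)
            * (p * pi2) ** E * ((1.0 - p) * pi1) ** (R - E)
            * (p * (1.0 - pi2) + (1.0 - p) * (1.0 - pi1)) ** (J - R))


def marginal_nonignorable_quadrature(stats, hyper, n_nodes=40):
    """log marginal likelihood via 3-D Gauss-Jacobi quadrature.

    ``stats`` is an iterable of (J, R, E) triples; ``hyper`` anything with
    ab_p/ab_pi1/ab_pi2 accessors.  Exact for J <= n_nodes (integrand is a
    polynomial of per-variable degree <= J).
    """
    a_p, b_p = hyper.ab_p()
    a1, b1 = hyper.ab_pi1()
    a2, b2 = hyper.ab_pi2()
    p, wp = jacobi_rule(n_nodes, a_p, b_p)
    q1, w1 = jacobi_rule(n_nodes, a1, b1)
    q2, w2 = jacobi_rule(n_nodes, a2, b2)
    P = p[:, None, None]
    Q1 = q1[None, :, None]
    Q2 = q2[None, None, :]
    W = wp[:, None, None] * w1[None, :, None] * w2[None, None, :]
    total = 0.0
    for J, R, E in stats:
        total += math.log(float(np.sum(W * likelihood_terms(
            J, R, E, P, Q1, Q2))))
    return total


def marginal_ignorable_quadrature(stats, hyper, n_nodes=40):
    """log marginal under the ignorable model via 2-D quadrature."""
    a_p, b_p = hyper.ab_p()
    a_pi, b_pi = hyper.ab_pi1()
    p, wp = jacobi_rule(n_nodes, a_p, b_p)
    q, wq = jacobi_rule(n_nodes, a_pi, b_pi)
    total = 0.0
    for J, R, E in stats:
        lik_r = comb(J, R) * q ** R * (1.0 - q) ** (J - R)
        lik_e = comb(R, E) * p ** E * (1.0 - p) ** (R - E)
        total += (math.log(float(np.dot(wq, lik_r)))
                  + math.log(float(np.dot(wp, lik_e))))
    return total


def loglik_by_completion(J, R, E, p, pi1, pi2):
    """Sum the complete-data probability over all 2^(J-R) missing patterns."""
    base = (comb(J, R) * comb(R, E)
            * (p * pi2) ** E * ((1.0 - p) * pi1) ** (R - E))
    total = 0.0
    m = J - R
    for mask in range(2 ** m):
        term = 1.0
        for j in range(m):
            if (mask >> j) & 1:
                term *= p * (1.0 - pi2)        # suppressed error
            else:
                term *= (1.0 - p) * (1.0 - pi1)  # suppressed correct answer
        total += term
    return math.log(base * total) if m else math.log(base)


def posterior_mean_p_grid(E, R, priors, n_mu=400, n_tau=400, tau_max=80.0):
    """E[p_1 | data] for the conjugate hierarchy with sampled (mu, tau).

    Marginalizes the hyperparameters on a dense grid: given (mu, tau) the
    examiner-level posteriors are conjugate Betas, so
    E[p_1 | data] = E_{mu,tau|data}[(mu tau + E_1) / (tau + R_1)].
    Used as an oracle for both the naive and ignorable p-blocks.
    """
    E = np.asarray(E, dtype=float)
    R = np.asarray(R, dtype=float)
    mu = np.linspace(1e-4, 1 - 1e-4, n_mu)
    tau = np.linspace(1e-4, tau_max, n_tau)
    MU, TAU = np.meshgrid(mu, tau, indexing="ij")
    A, B = MU * TAU, (1 - MU) * TAU
    logw = ((priors.mu_a - 1) * np.log(MU) + (priors.mu_b - 1) * np.log1p(-MU)
            + gamma_dist.logpdf(TAU, priors.tau_shape,
                                scale=1.0 / priors.tau_rate))
    for e, r in zip(E, R):
        logw += betaln(A + e, B + r - e) - betaln(A, B)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    cond_mean = (A + E[0]) / (TAU + R[0])
    return float(np.sum(w * cond_mean))


def posterior_mean_p_nonignorable(J, R, E, hyper, n_nodes=40):
    """E[p | E, R] for one examiner under fixed hyperparameters.

    With hyperparameters fixed, examiners are a posteriori independent; the
    mean is a ratio of two Gauss-Jacobi integrals.
    """
    a_p, b_p = hyper.ab_p()
    a1, b1 = hyper.ab_pi1()
    a2, b2 = hyper.ab_pi2()
    p, wp = jacobi_rule(n_nodes, a_p, b_p)
    q1, w1 = jacobi_rule(n_nodes, a1, b1)
    q2, w2 = jacobi_rule(n_nodes, a2, b2)
    P = p[:, None, None]
    W = (wp[:, None, None] * w1[None, :, None] * w2[None, None, :])
    lik = likelihood_terms(J, R, E, P, q1[None, :, None], q2[None, None, :])
    return float(np.sum(W * P * lik) / np.sum(W * lik))


def clopper_pearson_bisect(x, n, level=0.95, tol=1e-12):
    """CP bounds by direct bisection of the binomial tail equations."""
    alpha = 1.0 - level

    def solve(fun, lo, hi):
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if fun(mid) > 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    lower = 0.0 if x == 0 else solve(
        lambda p: binom.sf(x - 1, n, p) - alpha / 2, 0.0, x / n)
    upper = 1.0 if x == n else solve(
        lambda p: -(binom.cdf(x, n, p) - alpha / 2), x / n, 1.0)
    return lower, upper
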