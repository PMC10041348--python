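"""Conjugate / data-augmentation Gibbs samplers and convergence diagnostics.

All three models admit exact conjugate updates for the examiner-level
probabilities.  The non-ignorable sampler augments with the latent number of
missing errors ``z_i`` per examiner, after which every conditional is a
standard Beta or Binomial draw.  When hyperparameters are sampled (naive and
ignorable models) they move in a joint random-walk Metropolis step on the
(logit mu, log tau) scale whose proposal scale adapts during burn-in only,
so detailed balance holds for every retained draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import betaln

from .likelihood import HyperParams, PriorSpec
from .panel import StudyPanel

__all__ = [
    "ChainConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "fit_naive",
    "fit_ignorable",
    "fit_nonignorable_eb",
    "fit_nonignorable_fullbayes",
    "batch_means_mcse",
    "gelman_rubin_multivariate",
    "assess_convergence",
]

MCSE_THRESHOLD = 0.01
PSRF_THRESHOLD = {"naive": 1.1, "ignorable": 1.1, "nonignorable": 1.2}


@dataclass(frozen=True)
class ChainConfig:
    n_chains: int = 2
    n_iter: int = 15_000
    n_burn: int = 5_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("need n_chains >= 1 and thin >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    def chain_rngs(self) -> list[np.random.Generator]:
        # distinct per-chain substreams derived from one master seed
        return [np.random.default_rng(np.random.SeedSequence(entropy=self.seed,
                                                             spawn_key=(c,)))
                for c in range(self.n_chains)]


@dataclass
class PosteriorDraws:
    """Retained MCMC draws; probability arrays have shape (chains, kept, I)."""

    model: str
    examiner_ids: list
    p: np.ndarray
    pi: Optional[np.ndarray] = None       # ignorable response block
    pi1: Optional[np.ndarray] = None      # non-ignorable: response | correct
    pi2: Optional[np.ndarray] = None      # non-ignorable: response | error
    hyper: dict = field(default_factory=dict)  # sampled hyperparameter chains
    fixed_hyper: Optional[HyperParams] = None
    config: Optional[ChainConfig] = None
    policy: Optional[str] = None
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.p.shape[0] * self.p.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws for one block flattened over chains: shape (draws, I)."""
        arr = getattr(self, name)
        if arr is None:
            raise KeyError(f"model {self.model!r} has no block {name!r}")
        return arr.reshape(-1, arr.shape[-1])

    def monitored(self) -> np.ndarray:
        """All probability parameters, shape (chains, kept, d)."""
        blocks = [self.p] + [b for b in (self.pi, self.pi1, self.pi2)
                             if b is not None]
        return np.concatenate(blocks, axis=2)

    def monitored_names(self) -> list[str]:
        out = [f"p[{e}]" for e in self.examiner_ids]
        for tag, b in (("pi", self.pi), ("pi1", self.pi1), ("pi2", self.pi2)):
            if b is not None:
                out += [f"{tag}[{e}]" for e in self.examiner_ids]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iter, parameter, value) table of all draws."""
        names = self.monitored_names()
        mon = self.monitored()
        frames = []
        for c in range(mon.shape[0]):
            df = pd.DataFrame(mon[c], columns=names)
            df.insert(0, "iter", np.arange(mon.shape[1]))
            df.insert(0, "chain", c)
            frames.append(df.melt(id_vars=["chain", "iter"],
                                  var_name="parameter", value_name="value"))
        long = pd.concat(frames, ignore_index=True)
        for hname, harr in self.hyper.items():
            for c in range(harr.shape[0]):
                frames = pd.DataFrame({
                    "chain": c, "iter": np.arange(harr.shape[1]),
                    "parameter": hname, "value": harr[c]})
                long = pd.concat([long, frames], ignore_index=True)
        return long


# ---------------------------------------------------------------------------
# Metropolis block for a (mu, tau) hyperparameter pair
# ---------------------------------------------------------------------------

class _HyperBlock:
    """Joint random-walk update of one (mu, tau) pair on (logit, log) scale.

    Targets  prod_i Beta(x_i; mu tau, (1-mu) tau) * prior(mu) * prior(tau),
    including the transform Jacobian mu(1-mu)tau.  The proposal scale adapts
    toward a 0.2-0.45 acceptance rate during burn-in and is frozen after.
    """

    def __init__(self, priors: PriorSpec, mu0: float, tau0: float):
        self.priors = priors
        self.mu, self.tau = mu0, tau0
        self.scale = 0.25
        self.n_prop = 0
        self.n_acc = 0
        self._win_prop = 0
        self._win_acc = 0

    def _logpost(self, mu: float, tau: float,
                 n: int, slog: float, slog1m: float) -> float:
        lp = self.priors.log_mu_prior(mu) + self.priors.log_tau_prior(tau)
        if not math.isfinite(lp):
            return -math.inf
        a, b = mu * tau, (1.0 - mu) * tau
        lp += (a - 1.0) * slog + (b - 1.0) * slog1m - n * betaln(a, b)
        # Jacobian of (logit mu, log tau)
        lp += math.log(mu) + math.log1p(-mu) + math.log(tau)
        return lp

    def step(self, x: np.ndarray, rng: np.random.Generator,
             adapt: bool) -> None:
        n = x.shape[0]
        slog = float(np.log(x).sum())
        slog1m = float(np.log1p(-x).sum())
        cur = self._logpost(self.mu, self.tau, n, slog, slog1m)
        lm = math.log(self.mu / (1.0 - self.mu)) + self.scale * rng.normal()
        lt = math.log(self.tau) + self.scale * rng.normal()
        mu_new = 1.0 / (1.0 + math.exp(-lm))
        tau_new = math.exp(lt)
        prop = self._logpost(mu_new, tau_new, n, slog, slog1m)
        self.n_prop += 1
        self._win_prop += 1
        if math.log(rng.uniform()) < prop - cur:
            self.mu, self.tau = mu_new, tau_new
            self.n_acc += 1
            self._win_acc += 1
        if adapt and self._win_prop >= 50:
            rate = self._win_acc / self._win_prop
            self.scale *= math.exp(1.2 * (rate - 0.3))
            self.scale = min(max(self.scale, 1e-3), 5.0)
            self._win_prop = self._win_acc = 0

    @property
    def accept_rate(self) -> float:
        return self.n_acc / self.n_prop if self.n_prop else math.nan


def _beta_draw(rng, a, b):
    x = rng.beta(a, b)
    return np.clip(x, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def fit_naive(
    panel: StudyPanel,
    priors: PriorSpec = PriorSpec(),
    config: ChainConfig = ChainConfig(),
    hyper: Optional[HyperParams] = None,
) -> PosteriorDraws:
    """Complete-data model on observed items of responding examiners only.

    ``p_i`` is conjugate Beta given (E_i^obs, R_i); (mu_p, tau_p) move by
    Metropolis unless ``hyper`` pins them (then only the conjugate step runs).
    """
    sub = panel.responders()
    if sub.I == 0:
        raise ValueError("no examiner with R > 0")
    E, R = sub.E_obs.astype(float), sub.R.astype(float)
    I = sub.I
    kept = config.n_kept
    p_out = np.empty((config.n_chains, kept, I))
    h_out = {"mu_p": np.empty((config.n_chains, kept)),
             "tau_p": np.empty((config.n_chains, kept))}
    acc = {}
    for c, rng in enumerate(config.chain_rngs()):
        if hyper is None:
            block = _HyperBlock(priors, mu0=0.5, tau0=2.0)
        p = np.full(I, 0.1)
        k = 0
        for it in range(config.n_iter):
            if hyper is None:
                a, b = block.mu * block.tau, (1.0 - block.mu) * block.tau
            else:
                a, b = hyper.ab_p()
            p = _beta_draw(rng, a + E, b + R - E)
            if hyper is None:
                block.step(p, rng, adapt=it < config.n_burn)
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                p_out[c, k] = p
                h_out["mu_p"][c, k] = block.mu if hyper is None else hyper.mu_p
                h_out["tau_p"][c, k] = block.tau if hyper is None else hyper.tau_p
                k += 1
        if hyper is None:
            acc[f"chain{c}:mu_tau_p"] = block.accept_rate
    return PosteriorDraws("naive", list(sub.examiner_ids), p_out,
                          hyper=h_out if hyper is None else {},
                          fixed_hyper=hyper, config=config,
                          policy=sub.policy.value, accept_rates=acc)


def fit_ignorable(
    panel: StudyPanel,
    priors: PriorSpec = PriorSpec(),
    config: ChainConfig = ChainConfig(),
    hyper: Optional[HyperParams] = None,
) -> PosteriorDraws:
    """Ignorable-missingness model over the full panel (all I examiners).

    Under ignorability the missing error indicators carry no information
    about ``p_i``, so its conjugate update uses observed errors only; the
    response probabilities ``pi_i`` get their own conjugate block.
    """
    if panel.I == 0:
        raise ValueError("empty panel")
    E, R, J = (x.astype(float) for x in (panel.E_obs, panel.R, panel.J))
    I = panel.I
    kept = config.n_kept
    p_out = np.empty((config.n_chains, kept, I))
    pi_out = np.empty((config.n_chains, kept, I))
    h_out = {k: np.empty((config.n_chains, kept))
             for k in ("mu_p", "tau_p", "mu_pi", "tau_pi")}
    acc = {}
    for c, rng in enumerate(config.chain_rngs()):
        if hyper is None:
            bp = _HyperBlock(priors, 0.5, 2.0)
            bpi = _HyperBlock(priors, 0.5, 2.0)
        k = 0
        for it in range(config.n_iter):
            if hyper is None:
                a_p, b_p = bp.mu * bp.tau, (1.0 - bp.mu) * bp.tau
                a_r, b_r = bpi.mu * bpi.tau, (1.0 - bpi.mu) * bpi.tau
            else:
                a_p, b_p = hyper.ab_p()
                a_r, b_r = hyper.ab_pi1()
            p = _beta_draw(rng, a_p + E, b_p + R - E)
            pi = _beta_draw(rng, a_r + R, b_r + J - R)
            if hyper is None:
                adapt = it < config.n_burn
                bp.step(p, rng, adapt)
                bpi.step(pi, rng, adapt)
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                p_out[c, k] = p
                pi_out[c, k] = pi
                if hyper is None:
                    h_out["mu_p"][c, k], h_out["tau_p"][c, k] = bp.mu, bp.tau
                    h_out["mu_pi"][c, k], h_out["tau_pi"][c, k] = bpi.mu, bpi.tau
                else:
                    h_out["mu_p"][c, k], h_out["tau_p"][c, k] = hyper.mu_p, hyper.tau_p
                    h_out["mu_pi"][c, k], h_out["tau_pi"][c, k] = hyper.mu_pi, hyper.tau_pi
                k += 1
        if hyper is None:
            acc[f"chain{c}:mu_tau_p"] = bp.accept_rate
            acc[f"chain{c}:mu_tau_pi"] = bpi.accept_rate
    return PosteriorDraws("ignorable", list(panel.examiner_ids), p_out,
                          pi=pi_out, hyper=h_out if hyper is None else {},
                          fixed_hyper=hyper, config=config,
                          policy=panel.policy.value, accept_rates=acc)


def fit_nonignorable_eb(
    panel: StudyPanel,
    hyper: HyperParams,
    config: ChainConfig = ChainConfig(n_iter=40_000, n_burn=10_000),
) -> PosteriorDraws:
    """Selection-model sampler with hyperparameters fixed (empirical Bayes).

    Gibbs cycle per examiner: latent missing-error count
    ``z_i ~ Binomial(J_i - R_i, q_i)`` with
    ``q_i = p_i(1-pi2_i) / [p_i(1-pi2_i) + (1-p_i)(1-pi1_i)]``,
    then conjugate Beta draws for ``p_i``, ``pi1_i`` and ``pi2_i``.
    """
    if panel.I == 0:
        raise ValueError("empty panel")
    hyper = HyperParams(**hyper.to_dict())  # validates
    E, R, J = panel.E_obs, panel.R, panel.J
    M = (J - R).astype(np.int64)
    Ef, Rf, Jf, Mf = (x.astype(float) for x in (E, R, J, M))
    a_p, b_p = hyper.ab_p()
    a1, b1 = hyper.ab_pi1()
    a2, b2 = hyper.ab_pi2()
    I = panel.I
    kept = config.n_kept
    p_out = np.empty((config.n_chains, kept, I))
    pi1_out = np.empty((config.n_chains, kept, I))
    pi2_out = np.empty((config.n_chains, kept, I))
    for c, rng in enumerate(config.chain_rngs()):
        p = _beta_draw(rng, np.full(I, a_p), np.full(I, b_p))
        pi1 = _beta_draw(rng, np.full(I, a1), np.full(I, b1))
        pi2 = _beta_draw(rng, np.full(I, a2), np.full(I, b2))
        k = 0
        for it in range(config.n_iter):
            num = p * (1.0 - pi2)
            den = num + (1.0 - p) * (1.0 - pi1)
            q = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            z = rng.binomial(M, q)
            p = _beta_draw(rng, a_p + Ef + z, b_p + Jf - Ef - z)
            pi1 = _beta_draw(rng, a1 + Rf - Ef, b1 + Mf - z)
            pi2 = _beta_draw(rng, a2 + Ef, b2 + z)
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                p_out[c, k] = p
                pi1_out[c, k] = pi1
                pi2_out[c, k] = pi2
                k += 1
    return PosteriorDraws("nonignorable", list(panel.examiner_ids), p_out,
                          pi1=pi1_out, pi2=pi2_out, fixed_hyper=hyper,
                          config=config, policy=panel.policy.value)


def fit_nonignorable_fullbayes(
    panel: StudyPanel,
    priors: dict,
    config: ChainConfig = ChainConfig(n_iter=40_000, n_burn=10_000),
    experimental: bool = False,
) -> PosteriorDraws:
    """Fully Bayesian selection model: samples all six hyperparameters.

    Experimental.  With default diffuse priors the hyperparameters are only
    weakly identified at realistic non-response rates, so this entry point
    demands both an explicit opt-in and user-supplied informative
    :class:`PriorSpec` objects under keys ``"p"``, ``"pi1"``, ``"pi2"``.
    """
    if not experimental:
        raise ValueError("opt in with experimental=True and informative priors")
    for key in ("p", "pi1", "pi2"):
        if key not in priors or not isinstance(priors[key], PriorSpec):
            raise ValueError(f"priors[{key!r}] must be a PriorSpec")
    E, R, J = panel.E_obs, panel.R, panel.J
    M = (J - R).astype(np.int64)
    Ef, Rf, Jf, Mf = (x.astype(float) for x in (E, R, J, M))
    I = panel.I
    kept = config.n_kept
    p_out = np.empty((config.n_chains, kept, I))
    pi1_out = np.empty((config.n_chains, kept, I))
    pi2_out = np.empty((config.n_chains, kept, I))
    h_out = {k: np.empty((config.n_chains, kept))
             for k in ("mu_p", "tau_p", "mu_pi1", "tau_pi1", "mu_pi2", "tau_pi2")}
    for c, rng in enumerate(config.chain_rngs()):
        blocks = {k: _HyperBlock(priors[k], 0.5, 2.0) for k in ("p", "pi1", "pi2")}
        p = np.full(I, 0.1)
        pi1 = np.full(I, 0.5)
        pi2 = np.full(I, 0.5)
        k = 0
        for it in range(config.n_iter):
            num = p * (1.0 - pi2)
            den = num + (1.0 - p) * (1.0 - pi1)
            q = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            z = rng.binomial(M, q)
            bp, b1, b2 = blocks["p"], blocks["pi1"], blocks["pi2"]
            p = _beta_draw(rng, bp.mu * bp.tau + Ef + z,
                           (1 - bp.mu) * bp.tau + Jf - Ef - z)
            pi1 = _beta_draw(rng, b1.mu * b1.tau + Rf - Ef,
                             (1 - b1.mu) * b1.tau + Mf - z)
            pi2 = _beta_draw(rng, b2.mu * b2.tau + Ef, (1 - b2.mu) * b2.tau + z)
            adapt = it < config.n_burn
            bp.step(p, rng, adapt)
            b1.step(pi1, rng, adapt)
            b2.step(pi2, rng, adapt)
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                p_out[c, k], pi1_out[c, k], pi2_out[c, k] = p, pi1, pi2
                for tag, blk in (("p", bp), ("pi1", b1), ("pi2", b2)):
                    h_out[f"mu_{tag}"][c, k] = blk.mu
                    h_out[f"tau_{tag}"][c, k] = blk.tau
                k += 1
    return PosteriorDraws("nonignorable", list(panel.examiner_ids), p_out,
                          pi1=pi1_out, pi2=pi2_out, hyper=h_out,
                          config=config, policy=panel.policy.value)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def batch_means_mcse(x: np.ndarray) -> float:
    """Nonoverlapping batch-means Monte Carlo standard error of the mean.

    Batch size b = floor(sqrt(n)); the MCSE is the standard deviation of the
    a = floor(n/b) batch means divided by sqrt(a).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError("chain too short for batch means (need n >= 4)")
    b = int(math.floor(math.sqrt(n)))
    a = n // b
    bm = x[: a * b].reshape(a, b).mean(axis=1)
    v = bm.var(ddof=1)
    return float(math.sqrt(v / a))


def gelman_rubin_multivariate(chains: np.ndarray | PosteriorDraws):
    """Brooks-Gelman multivariate potential scale reduction factor.

    Accepts draws shaped (m_chains, n, d) or a :class:`PosteriorDraws`
    (monitoring all probability parameters).  Returns ``(mpsrf, fallback)``
    where ``fallback`` is True when the pooled within-chain covariance was
    singular and the maximum univariate PSRF was returned instead.
    """
    if isinstance(chains, PosteriorDraws):
        chains = chains.monitored()
    x = np.asarray(chains, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    m, n, d = x.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    chain_means = x.mean(axis=1)                      # (m, d)
    grand = chain_means.mean(axis=0)
    Bn = np.einsum("md,me->de",
                   chain_means - grand, chain_means - grand) / (m - 1)
    W = np.zeros((d, d))
    for c in range(m):
        dev = x[c] - chain_means[c]
        W += dev.T @ dev / (n - 1)
    W /= m
    try:
        lam = float(np.max(np.real(
            np.linalg.eigvals(np.linalg.solve(W, Bn)))))
        if not math.isfinite(lam) or lam < -1e-8:
            raise np.linalg.LinAlgError
        mpsrf = (n - 1) / n + (m + 1) / m * lam
        return float(mpsrf), False
    except np.linalg.LinAlgError:
        wdiag = np.diag(W)
        ok = wdiag > 0
        psrf = np.ones(d)
        psrf[ok] = (n - 1) / n + (m + 1) / m * np.diag(Bn)[ok] / wdiag[ok]
        return float(np.sqrt(np.max(psrf))), True


@dataclass
class ConvergenceReport:
    mcse: dict
    max_mcse: float
    mpsrf: float
    mpsrf_fallback: bool
    mcse_threshold: float
    psrf_threshold: float

    @property
    def passed(self) -> bool:
        return (self.max_mcse < self.mcse_threshold
                and self.mpsrf < self.psrf_threshold)

    def to_dict(self) -> dict:
        return {
            "max_mcse": self.max_mcse,
            "mpsrf": self.mpsrf,
            "mpsrf_fallback": self.mpsrf_fallback,
            "mcse_threshold": self.mcse_threshold,
            "psrf_threshold": self.psrf_threshold,
            "passed": self.passed,
        }


def assess_convergence(draws: PosteriorDraws,
                       psrf_threshold: float | None = None,
                       mcse_threshold: float = MCSE_THRESHOLD,
                       per_parameter: bool = False) -> ConvergenceReport:
    """Batch-means MCSE per probability parameter plus the multivariate PSRF.

    The MCSE for each parameter is the worst (largest) value across chains.
    """
    if psrf_threshold is None:
        psrf_threshold = PSRF_THRESHOLD.get(draws.model, 1.1)
    mon = draws.monitored()                            # (m, n, d)
    m, n, d = mon.shape
    b = int(math.floor(math.sqrt(n)))
    a = n // b
    bm = mon[:, : a * b, :].reshape(m, a, b, d).mean(axis=2)
    mcse_all = np.sqrt(bm.var(axis=1, ddof=1) / a).max(axis=0)  # (d,)
    names = draws.monitored_names()
    mcse = dict(zip(names, mcse_all)) if per_parameter else {}
    if m >= 2:
        mpsrf, fb = gelman_rubin_multivariate(mon)
    else:
        mpsrf, fb = math.nan, True
    return ConvergenceReport(
        mcse=mcse, max_mcse=float(mcse_all.max()), mpsrf=mpsrf,
        mpsrf_fallback=fb, mcse_threshold=mcse_threshold,
        psrf_threshold=psrf_threshold)
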