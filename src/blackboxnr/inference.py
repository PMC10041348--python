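"""Posterior-predictive error proportions and classical baselines.

The study-level quantity of interest is PE: the proportion of errors
expected in a new study with the same assignment/response pattern.  For the
naive model the "study" is the observed items only (denominator R_tot over
the responding examiners); for the missingness-aware models it is all
assigned items (denominator J), with unanswered items contributing their own
predicted errors.  Each retained posterior draw yields one PE draw by
simulating the per-examiner binomial counts the model implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .mcmc import PosteriorDraws
from .panel import StudyPanel

__all__ = [
    "PEPredictive",
    "CPResult",
    "pe_predictive",
    "examiner_posterior_interval",
    "clopper_pearson",
    "pe_table",
]


@dataclass
class PEPredictive:
    """Draws and summaries of the predicted study error proportion."""

    draws: np.ndarray
    model: str
    policy: Optional[str]
    denominator: int
    level: float = 0.95

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if np.any(self.draws < 0) or np.any(self.draws > 1):
            raise ValueError("PE draws must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def interval(self) -> tuple:
        alpha = 1.0 - self.level
        lo, hi = np.quantile(self.draws, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)

    def summary_row(self) -> dict:
        lo, hi = self.interval
        return {
            "model": self.model,
            "inconclusives": self.policy,
            "pe_mean_pct": 100.0 * self.mean,
            "pe_low_pct": 100.0 * lo,
            "pe_high_pct": 100.0 * hi,
            "denominator": self.denominator,
        }


def pe_predictive(draws: PosteriorDraws, panel: StudyPanel,
                  seed: int | None = 0) -> PEPredictive:
    """Simulate the posterior-predictive PE, one PE draw per posterior draw.

    naive:          E_i^obs ~ Bin(R_i, p_i),            PE = sum E / R_tot
    ignorable:      E_i^obs ~ Bin(R_i, p_i pi_i),
                    E_i^mis ~ Bin(J_i - R_i, p_i (1-pi_i)),  PE = total / J
    non-ignorable:  same with pi2_i in both roles.
    """
    rng = np.random.default_rng(seed)
    p = draws.flat("p")                       # (ndraw, I)
    if draws.model == "naive":
        sub = panel.responders()
        if list(sub.examiner_ids) != list(draws.examiner_ids):
            raise ValueError("draws do not match the panel's responders")
        R = sub.R[None, :]
        e_obs = rng.binomial(np.broadcast_to(R, p.shape), p)
        pe = e_obs.sum(axis=1) / sub.R_total
        return PEPredictive(pe, "naive", draws.policy, sub.R_total)
    if list(panel.examiner_ids) != list(draws.examiner_ids):
        raise ValueError("draws do not match the panel")
    R, J = panel.R[None, :], panel.J[None, :]
    if draws.model == "ignorable":
        resp = draws.flat("pi")
    elif draws.model == "nonignorable":
        resp = draws.flat("pi2")
    else:
        raise ValueError(f"unknown model tag {draws.model!r}")
    e_obs = rng.binomial(np.broadcast_to(R, p.shape), p * resp)
    e_mis = rng.binomial(np.broadcast_to(J - R, p.shape), p * (1.0 - resp))
    pe = (e_obs + e_mis).sum(axis=1) / panel.J_total
    return PEPredictive(pe, draws.model, draws.policy, panel.J_total)


def examiner_posterior_interval(draws: PosteriorDraws, examiner_id,
                                level: float = 0.95) -> tuple:
    """Equal-tailed credible interval for one examiner's error probability."""
    try:
        i = list(draws.examiner_ids).index(examiner_id)
    except ValueError:
        raise KeyError(f"examiner {examiner_id!r} not in draws") from None
    x = draws.flat("p")[:, i]
    alpha = 1.0 - level
    lo, hi = np.quantile(x, [alpha / 2, 1 - alpha / 2])
    return float(x.mean()), float(lo), float(hi)


@dataclass(frozen=True)
class CPResult:
    x: int
    n: int
    level: float
    point: float
    lower: float
    upper: float

    def to_dict(self) -> dict:
        return {"x": self.x, "n": self.n, "level": self.level,
                "point": self.point, "lower": self.lower, "upper": self.upper}


def clopper_pearson(x: int, n: int, level: float = 0.95) -> CPResult:
    """Exact binomial confidence interval via Beta-quantile tail inversion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= x <= n):
        raise ValueError("need 0 <= x <= n")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return CPResult(x=int(x), n=int(n), level=level,
                    point=x / n, lower=lower, upper=upper)


def pe_table(results: list[PEPredictive]) -> pd.DataFrame:
    """Summary table: model, policy, E(PE|Y,R) %, 2.5%, 97.5%."""
    return pd.DataFrame([r.summary_row() for r in results])
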