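"""Synthetic black-box studies from the hierarchical generative processes.

Generates complete studies — latent error indicators, response indicators,
and the emitted decision records — under MCAR, ignorable or non-ignorable
response mechanisms, with optional relabelling of observed decisions as
inconclusive / no-value to emulate the 'don't know' layer real studies have.
Every stage of the modelling pipeline is testable against the retained
latent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .likelihood import HyperParams
from .panel import Decision, GroundTruth

__all__ = ["GeneratorConfig", "SyntheticStudy", "generate_study",
           "palmar_print_fixture", "PALMAR_TRUTH"]

#: Hyperparameter regime emulating a large palmar-print proficiency study's
#: different-source stratum: low mean error probability, widely dispersed
#: response propensities, and strong selection (errors rarely answered).
PALMAR_TRUTH = HyperParams(mu_p=0.2, tau_p=7.1,
                           mu_pi1=0.6, tau_pi1=0.4,
                           mu_pi2=0.01, tau_pi2=3.5)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and truth parameters for one synthetic stratum.

    ``mechanism`` controls the response model: ``mcar`` fixes a single common
    response probability ``mu_pi1`` for everyone regardless of the error
    indicator; ``ignorable`` draws one examiner-level response probability
    (pi1 = pi2); ``nonignorable`` draws the two response blocks separately.
    ``error_inconclusive_odds`` multiplies the odds that an *error* item is
    relabelled inconclusive (1 = independent of the latent error).
    """

    I: int
    J_items: int | np.ndarray
    hyper: HyperParams
    mechanism: str = "nonignorable"
    inconclusive_rate: float = 0.0
    no_value_rate: float = 0.0
    error_inconclusive_odds: float = 1.0
    ground_truth: GroundTruth = GroundTruth.DIFFERENT_SOURCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("mcar", "ignorable", "nonignorable"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for name in ("inconclusive_rate", "no_value_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.error_inconclusive_odds <= 0:
            raise ValueError("error_inconclusive_odds must be positive")
        J = np.atleast_1d(np.asarray(self.J_items, dtype=np.int64))
        if self.I < 1 or int(J.max(initial=0)) < 1:
            raise ValueError("need I >= 1 and at least one assigned item")

    def j_vector(self) -> np.ndarray:
        J = np.asarray(self.J_items, dtype=np.int64)
        if J.ndim == 0:
            return np.full(self.I, int(J))
        if J.shape != (self.I,):
            raise ValueError("per-examiner J_items must have length I")
        return J.copy()


@dataclass
class SyntheticStudy:
    """Emitted records plus the latent truth that produced them."""

    records: pd.DataFrame
    assignments: pd.DataFrame
    examiner_truth: pd.DataFrame   # per-examiner p, pi1, pi2
    item_truth: pd.DataFrame       # per (examiner, item): y, r, decision
    config: GeneratorConfig = field(repr=False, default=None)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        self.assignments.to_csv(outdir / "assignments.csv", index=False)
        self.examiner_truth.to_csv(outdir / "truth_examiners.csv", index=False)
        self.item_truth.to_csv(outdir / "truth_items.csv", index=False)


def _examiner_rng(seed: int, i: int) -> np.random.Generator:
    # independent substream per examiner: growing I never perturbs earlier ones
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(i,)))


def _correct_decision(gt: GroundTruth) -> str:
    return (Decision.EXCLUSION.value if gt is GroundTruth.DIFFERENT_SOURCE
            else Decision.IDENTIFICATION.value)


def _error_decision(gt: GroundTruth) -> str:
    return (Decision.IDENTIFICATION.value if gt is GroundTruth.DIFFERENT_SOURCE
            else Decision.EXCLUSION.value)


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Draw one complete synthetic study.

    Per examiner i: p_i ~ Beta(mu_p tau_p, .); response probabilities per
    ``mechanism``; y_ij ~ Bern(p_i); r_ij ~ Bern(pi1_i) on correct items and
    Bern(pi2_i) on error items.  A record is emitted for every r_ij = 1,
    with the decision optionally relabelled inconclusive / no-value.
    """
    J = config.j_vector()
    gt = GroundTruth(config.ground_truth)
    h = config.hyper
    a_p, b_p = h.ab_p()
    a1, b1 = h.ab_pi1()
    a2, b2 = h.ab_pi2()

    ex_rows, item_rows, rec_rows = [], [], []
    for i in range(config.I):
        rng = _examiner_rng(config.seed, i)
        eid = f"E{i:04d}"
        p = float(rng.beta(a_p, b_p))
        if config.mechanism == "mcar":
            pi1 = pi2 = h.mu_pi1
        elif config.mechanism == "ignorable":
            pi1 = pi2 = float(rng.beta(a1, b1))
        else:
            pi1 = float(rng.beta(a1, b1))
            pi2 = float(rng.beta(a2, b2))
        y = rng.random(J[i]) < p
        r = np.where(y, rng.random(J[i]) < pi2, rng.random(J[i]) < pi1)
        u_inc = rng.random(J[i])
        u_nv = rng.random(J[i])

        rho = config.inconclusive_rate
        if rho > 0 and config.error_inconclusive_odds != 1.0:
            odds = config.error_inconclusive_odds * rho / (1.0 - rho)
            rho_err = odds / (1.0 + odds)
        else:
            rho_err = rho
        p_inc = np.where(y, rho_err, rho)

        ex_rows.append((eid, p, pi1, pi2))
        for j in range(J[i]):
            iid = f"I{i:04d}_{j:03d}"
            decision = None
            if r[j]:
                if u_inc[j] < p_inc[j]:
                    decision = Decision.INCONCLUSIVE.value
                elif u_nv[j] < config.no_value_rate:
                    decision = Decision.NO_VALUE.value
                else:
                    decision = (_error_decision(gt) if y[j]
                                else _correct_decision(gt))
                rec_rows.append((eid, iid, gt.value, decision))
            item_rows.append((eid, iid, int(y[j]), int(r[j]), decision or ""))

    records = pd.DataFrame(
        rec_rows, columns=["examiner_id", "item_id", "ground_truth", "decision"])
    assignments = pd.DataFrame(
        {"examiner_id": [row[0] for row in ex_rows], "n_assigned": J})
    examiner_truth = pd.DataFrame(
        ex_rows, columns=["examiner_id", "p", "pi1", "pi2"])
    item_truth = pd.DataFrame(
        item_rows, columns=["examiner_id", "item_id", "y", "r", "decision"])
    return SyntheticStudy(records, assignments, examiner_truth, item_truth,
                          config)


def palmar_print_fixture(seed: int = 0,
                         inconclusive_rate: float = 0.30,
                         no_value_rate: float = 0.05) -> SyntheticStudy:
    """Synthetic stand-in for a palmar-print study's different-source stratum.

    226 examiners x 22 different-source items, non-ignorable truth at the
    hyperparameter regime of :data:`PALMAR_TRUTH`, with roughly 30% of the
    returned decisions relabelled inconclusive and 5% no-value.  Synthetic:
    emulates only the missingness regime, not the real item structure.
    """
    cfg = GeneratorConfig(I=226, J_items=22, hyper=PALMAR_TRUTH,
                          mechanism="nonignorable",
                          inconclusive_rate=inconclusive_rate,
                          no_value_rate=no_value_rate, seed=seed)
    return generate_study(cfg)
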