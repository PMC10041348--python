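"""Decision records, inconclusive-handling policies, and study panels.

A black-box study assigns each examiner a set of comparison items with known
ground truth (same source / different source).  Examiners return one of four
decisions per item — identification, exclusion, inconclusive, no value — or
no decision at all.  The models downstream consume only per-examiner
sufficient statistics: items assigned ``J_i``, definitive responses ``R_i``
and observed errors ``E_i^obs``.  This module builds those statistics from
long-format records under the two inconclusive-handling policies used in
practice (count inconclusives as observed-correct, or count them as missing);
'no value' outcomes and unanswered items are missing under both policies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "Decision",
    "InconclusivePolicy",
    "DecisionRecord",
    "StudyPanel",
    "build_panel",
    "nonresponse_rate",
    "empirical_error_rate",
    "read_records",
    "read_assignments",
    "report_pct",
]


class GroundTruth(str, enum.Enum):
    SAME_SOURCE = "same_source"
    DIFFERENT_SOURCE = "different_source"


class Decision(str, enum.Enum):
    IDENTIFICATION = "identification"
    EXCLUSION = "exclusion"
    INCONCLUSIVE = "inconclusive"
    NO_VALUE = "no_value"


class InconclusivePolicy(str, enum.Enum):
    """How inconclusive decisions enter the error-rate panel.

    ``AS_CORRECT_OBSERVED`` counts an inconclusive as an observed, correct
    answer (the prevalent black-box-study convention); ``AS_MISSING`` counts
    it as a non-response.  'No value' is missing under both.
    """

    AS_CORRECT_OBSERVED = "as_correct_observed"
    AS_MISSING = "as_missing"


@dataclass(frozen=True)
class DecisionRecord:
    """One examiner-item outcome, before any policy is applied."""

    examiner_id: str
    item_id: str
    ground_truth: GroundTruth
    decision: Decision


@dataclass
class StudyPanel:
    """Per-examiner sufficient statistics for one ground-truth stratum.

    Arrays are aligned with ``examiner_ids``.  ``y_obs`` holds each
    examiner's ordered observed error indicators (errors first is *not*
    assumed; order follows item_id sort) and is retained for descriptive
    output only — the likelihoods depend solely on (J_i, R_i, E_i^obs).
    """

    examiner_ids: list
    J: np.ndarray
    R: np.ndarray
    E_obs: np.ndarray
    policy: InconclusivePolicy
    stratum: GroundTruth
    y_obs: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.int64)
        self.R = np.asarray(self.R, dtype=np.int64)
        self.E_obs = np.asarray(self.E_obs, dtype=np.int64)
        n = len(self.examiner_ids)
        if not (self.J.shape == self.R.shape == self.E_obs.shape == (n,)):
            raise ValueError("panel arrays must align with examiner_ids")
        if np.any(self.E_obs < 0) or np.any(self.E_obs > self.R):
            raise ValueError("need 0 <= E_obs <= R for every examiner")
        if np.any(self.R > self.J):
            raise ValueError("need R <= J for every examiner")

    # -- totals ------------------------------------------------------------
    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return len(self.examiner_ids)

    @property
    def I_star(self) -> int:
        """Number of examiners with at least one definitive response."""
        return int(np.sum(self.R > 0))

    @property
    def J_total(self) -> int:
        return int(self.J.sum())

    @property
    def R_total(self) -> int:
        return int(self.R.sum())

    @property
    def E_total_obs(self) -> int:
        return int(self.E_obs.sum())

    def index_of(self, examiner_id) -> int:
        try:
            return self.examiner_ids.index(examiner_id)
        except ValueError:
            raise KeyError(f"unknown examiner {examiner_id!r}") from None

    def responders(self) -> "StudyPanel":
        """Sub-panel restricted to the I* examiners with R_i > 0."""
        keep = self.R > 0
        ids = [e for e, k in zip(self.examiner_ids, keep) if k]
        ys = [y for y, k in zip(self.y_obs, keep) if k] if self.y_obs else []
        return StudyPanel(ids, self.J[keep], self.R[keep], self.E_obs[keep],
                          self.policy, self.stratum, ys)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "examiner_id": self.examiner_ids,
            "J": self.J,
            "R": self.R,
            "E_obs": self.E_obs,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _error_indicator(decision: Decision, stratum: GroundTruth) -> int:
    """1 iff the definitive decision contradicts the ground truth."""
    if stratum is GroundTruth.DIFFERENT_SOURCE:
        return int(decision is Decision.IDENTIFICATION)
    return int(decision is Decision.EXCLUSION)


def _coerce_records(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [(r.examiner_id, r.item_id,
              GroundTruth(r.ground_truth).value, Decision(r.decision).value)
             for r in records],
            columns=["examiner_id", "item_id", "ground_truth", "decision"],
        )
    required = {"examiner_id", "item_id", "ground_truth", "decision"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    bad = set(df["decision"].unique()) - {d.value for d in Decision}
    if bad:
        raise ValueError(f"unknown decision labels: {sorted(bad)}")
    bad = set(df["ground_truth"].unique()) - {g.value for g in GroundTruth}
    if bad:
        raise ValueError(f"unknown ground-truth labels: {sorted(bad)}")
    return df


def build_panel(
    records,
    assignments: Mapping,
    policy: InconclusivePolicy = InconclusivePolicy.AS_CORRECT_OBSERVED,
    stratum: GroundTruth = GroundTruth.DIFFERENT_SOURCE,
    include_unit_nonrespondents: bool = False,
) -> StudyPanel:
    """Build per-examiner sufficient statistics for one stratum.

    Parameters
    ----------
    records
        Iterable of :class:`DecisionRecord` or a DataFrame with columns
        ``examiner_id,item_id,ground_truth,decision``.  Records outside
        ``stratum`` are ignored.
    assignments
        Mapping (or two-column DataFrame ``examiner_id,n_assigned``) from
        examiner to the number of stratum items assigned.
    policy
        Inconclusive handling; 'no value' is missing under both modes.
    include_unit_nonrespondents
        If False (default), examiners listed in ``assignments`` but with no
        record at all in this stratum are dropped — matching the common
        restriction of analyses to participants who returned something.
        If True they enter with R_i = 0.
    """
    policy = InconclusivePolicy(policy)
    stratum = GroundTruth(stratum)
    df = _coerce_records(records)
    df = df[df["ground_truth"] == stratum.value]

    if isinstance(assignments, pd.DataFrame):
        amap = dict(zip(assignments["examiner_id"], assignments["n_assigned"]))
    else:
        amap = dict(assignments)

    unknown = set(df["examiner_id"].unique()) - set(amap)
    if unknown:
        raise ValueError(f"records for unassigned examiners: {sorted(map(str, unknown))}")
    if df.duplicated(["examiner_id", "item_id"]).any():
        raise ValueError("duplicate (examiner_id, item_id) record")

    observed = {
        InconclusivePolicy.AS_CORRECT_OBSERVED:
            {Decision.IDENTIFICATION.value, Decision.EXCLUSION.value,
             Decision.INCONCLUSIVE.value},
        InconclusivePolicy.AS_MISSING:
            {Decision.IDENTIFICATION.value, Decision.EXCLUSION.value},
    }[policy]

    with_record = set(df["examiner_id"].unique())
    # sorted for permutation invariance over input order
    ids = sorted(amap, key=str)
    if not include_unit_nonrespondents:
        ids = [e for e in ids if e in with_record]

    grouped = {e: g.sort_values("item_id") for e, g in df.groupby("examiner_id")}
    J, R, E, ys = [], [], [], []
    for e in ids:
        Ji = int(amap[e])
        g = grouped.get(e)
        if g is None:
            J.append(Ji); R.append(0); E.append(0); ys.append(np.zeros(0, dtype=np.int64))
            continue
        if len(g) > Ji:
            raise ValueError(f"examiner {e!r}: {len(g)} records exceed {Ji} assigned")
        obs = g[g["decision"].isin(observed)]
        y = np.array(
            [_error_indicator(Decision(d), stratum) if d in
             (Decision.IDENTIFICATION.value, Decision.EXCLUSION.value) else 0
             for d in obs["decision"]],
            dtype=np.int64,
        )
        J.append(Ji); R.append(len(obs)); E.append(int(y.sum())); ys.append(y)
    return StudyPanel(ids, np.array(J), np.array(R), np.array(E), policy, stratum, ys)


def nonresponse_rate(panel: StudyPanel) -> float:
    """Pooled non-response rate 1 - R_tot/J (unit/item distinction dropped)."""
    if panel.J_total == 0:
        raise ValueError("no assigned items: non-response rate undefined")
    return 1.0 - panel.R_total / panel.J_total


def empirical_error_rate(panel: StudyPanel, examiner_id) -> float:
    """Observed error fraction E_obs/R for one examiner; needs R > 0."""
    i = panel.index_of(examiner_id)
    if panel.R[i] == 0:
        raise ValueError(f"examiner {examiner_id!r} has no definitive responses")
    return panel.E_obs[i] / panel.R[i]


def report_pct(x: float) -> float:
    """Fraction -> percent, one decimal, round-half-even (reporting style)."""
    return round(100.0 * float(x), 1)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), dtype=str)
    return _coerce_records(df)


def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    if list(df.columns[:2]) != ["examiner_id", "n_assigned"]:
        raise ValueError("assignment CSV must have header examiner_id,n_assigned")
    df["examiner_id"] = df["examiner_id"].astype(str)
    df["n_assigned"] = df["n_assigned"].astype(int)
    if (df["n_assigned"] < 0).any():
        raise ValueError("n_assigned must be >= 0")
    return df
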