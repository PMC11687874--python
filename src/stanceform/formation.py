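"""Initial→final stance transitions and the stance-formation cohorts.

The transition matrix counts users by their stance in the first and last
period of the window.  The cohort analysis then narrows to initially
neutral users: those who changed stance exactly once — to pro or to anti —
and kept the new stance to the end (neutral-to-pro / neutral-to-anti), and
those who stayed neutral in every period (remaining-neutral).  Everyone
else, including the initially non-neutral, is "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from stanceform._stances import ANTI, NEUTRAL, PRO, STANCES
from stanceform.timeline import StanceTimeline

NEUTRAL_TO_PRO = "neutral_to_pro"
NEUTRAL_TO_ANTI = "neutral_to_anti"
REMAINING_NEUTRAL = "remaining_neutral"
OTHER = "other"
COHORTS = (NEUTRAL_TO_PRO, NEUTRAL_TO_ANTI, REMAINING_NEUTRAL, OTHER)


@dataclass(frozen=True)
class TransitionMatrix:
    """3×3 initial→final user counts with derived margins."""

    counts: pd.DataFrame  # index: initial stance, columns: final stance

    @classmethod
    def from_counts(cls, counts) -> "TransitionMatrix":
        frame = pd.DataFrame(
            np.asarray(counts, dtype=np.int64), index=list(STANCES), columns=list(STANCES)
        )
        return cls(frame)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.row_totals
        out.loc["Total"] = out.sum(axis=0)
        return out


def transition_matrix(timelines: Mapping[str, StanceTimeline]) -> TransitionMatrix:
    """Count users by (stance at period 0, stance at the last period)."""
    counts = np.zeros((3, 3), dtype=np.int64)
    idx = {s: i for i, s in enumerate(STANCES)}
    for tl in timelines.values():
        counts[idx[tl.initial], idx[tl.final]] += 1
    return TransitionMatrix.from_counts(counts)


def percent_round(pct: float) -> float:
    """Percentages rounded presentation-style: whole percent at >= 10%,
    one decimal below 10% (half-up)."""
    pct = float(pct)
    if not np.isfinite(pct):
        return float("nan")
    quantum = Decimal("1") if pct >= 10 else Decimal("0.1")
    return float(Decimal(repr(pct)).quantize(quantum, rounding=ROUND_HALF_UP))


def retention_and_shift_stats(matrix: TransitionMatrix) -> pd.DataFrame:
    """Per initial stance: retention and per-destination shift percentages.

    Columns ``to_pro / to_neutral / to_anti / retention`` are rounded via
    :func:`percent_round`; ``*_raw`` columns keep full precision.  Rows with a
    zero total are flagged undefined (NaN percentages).
    """
    rows = []
    for initial in STANCES:
        total = int(matrix.row_totals[initial])
        row: dict[str, object] = {"initial": initial, "total": total}
        for final in STANCES:
            raw = 100.0 * matrix.counts.loc[initial, final] / total if total else float("nan")
            row[f"to_{final}_raw"] = raw
            row[f"to_{final}"] = percent_round(raw)
        row["retention_raw"] = row[f"to_{initial}_raw"]
        row["retention"] = row[f"to_{initial}"]
        row["undefined"] = total == 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("initial")


@dataclass(frozen=True)
class CohortAssignment:
    user_id: str
    cohort: str
    change_period: int | None = None
    change_month: int | None = None


def _assign_one(user_id: str, stances: tuple[str, ...]) -> CohortAssignment:
    if stances[0] != NEUTRAL:
        return CohortAssignment(user_id, OTHER)
    changes = [t for t in range(1, len(stances)) if stances[t] != stances[t - 1]]
    if not changes:
        return CohortAssignment(user_id, REMAINING_NEUTRAL)
    if len(changes) == 1:
        t = changes[0]
        final = stances[t]
        if final == PRO:
            return CohortAssignment(user_id, NEUTRAL_TO_PRO, t, t // 3)
        if final == ANTI:
            return CohortAssignment(user_id, NEUTRAL_TO_ANTI, t, t // 3)
    return CohortAssignment(user_id, OTHER)


def assign_cohorts(timelines: Mapping[str, StanceTimeline]) -> dict[str, CohortAssignment]:
    """Classify each filled timeline into the four cohorts.

    Exactly-one-change is judged on the filled per-period trajectory, with
    the earliest admissible change at period 1; ``change_month`` is the
    0-based month offset containing the change period.
    """
    return {u: _assign_one(u, tl.stances) for u, tl in timelines.items()}


def cohort_counts(assignments: Mapping[str, CohortAssignment]) -> dict[str, int]:
    out = {c: 0 for c in COHORTS}
    for a in assignments.values():
        out[a.cohort] += 1
    return out


def cohorts_to_frame(assignments: Mapping[str, CohortAssignment]) -> pd.DataFrame:
    rows = [
        {
            "user_id": a.user_id,
            "cohort": a.cohort,
            "change_period": a.change_period,
            "change_month": a.change_month,
        }
        for a in (assignments[u] for u in sorted(assignments))
    ]
    return pd.DataFrame(rows, columns=["user_id", "cohort", "change_period", "change_month"])


def write_transition_matrix(matrix: TransitionMatrix, path) -> None:
    matrix.with_margins().to_csv(path)


def write_cohorts(assignments: Mapping[str, CohortAssignment], path) -> None:
    cohorts_to_frame(assignments).to_csv(path, index=False)
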