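"""Per-subject conditional stay probabilities.

The dependent variable of the strategy analysis: for each consecutive
trial pair (t-1, t) with valid stage-1 choices on both trials and a valid
outcome on trial t-1, the pair contributes to the cell (reward at t-1,
transition at t-1) and scores a "stay" when the stage-1 choice repeats.
Cells with fewer pairs than ``min_cell_count`` are flagged; flagged
subjects are excluded listwise from the ANOVA by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .task import SessionData

__all__ = ["StayTable", "compute_stay_table", "stay_tables_to_frame", "stay_tables_to_long"]

#: Cell order used everywhere: (reward in {1, 0}) x (transition common/rare).
CELLS = [(1, "common"), (1, "rare"), (0, "common"), (0, "rare")]

# CSV column stems: first letter transition (c/r), second reward (c = rewarded,
# u = unrewarded).
_CELL_COLUMNS = {(1, "common"): "cc", (1, "rare"): "rc", (0, "common"): "cu", (0, "rare"): "ru"}


@dataclass
class StayTable:
    """2x2 (reward x transition) stay proportions and pair counts."""

    subject_id: str
    group: str
    stay: dict[tuple[int, str], float]
    counts: dict[tuple[int, str], int]
    min_cell_count: int = 4
    flagged: set = field(default_factory=set)

    @property
    def has_flagged_cells(self) -> bool:
        return bool(self.flagged)

    def to_row(self) -> dict:
        row: dict = {"subject_id": self.subject_id, "group": self.group}
        for cell, stem in _CELL_COLUMNS.items():
            row[f"stay_{stem}"] = self.stay[cell]
            row[f"n_{stem}"] = self.counts[cell]
        row["flagged"] = self.has_flagged_cells
        return row


def compute_stay_table(session: SessionData, min_cell_count: int = 4) -> StayTable:
    """Tabulate stay behaviour conditional on the previous trial's reward
    and transition type.

    Pairs are dropped when trial t-1 has a missed stage-1 or stage-2
    response (the conditioning variables are undefined) or trial t has a
    missed stage-1 response (the stay outcome is undefined).  Pairs
    spanning block boundaries count; blocks are presentation breaks only.
    """
    if len(session.trials) < 2:
        raise ValueError("need at least 2 trials to compute stay probabilities")
    stays = {cell: 0 for cell in CELLS}
    counts = {cell: 0 for cell in CELLS}
    for prev, cur in zip(session.trials, session.trials[1:]):
        if prev.choice1 is None or prev.reward is None or cur.choice1 is None:
            continue
        cell = (prev.reward, prev.transition)
        counts[cell] += 1
        if cur.choice1 == prev.choice1:
            stays[cell] += 1
    stay = {
        cell: (stays[cell] / counts[cell]) if counts[cell] > 0 else math.nan
        for cell in CELLS
    }
    flagged = {cell for cell in CELLS if counts[cell] < min_cell_count}
    return StayTable(
        subject_id=session.subject_id,
        group=session.group,
        stay=stay,
        counts=counts,
        min_cell_count=min_cell_count,
        flagged=flagged,
    )


def stay_tables_to_frame(tables: list[StayTable]) -> pd.DataFrame:
    """Wide format, one row per subject (the stay-table CSV layout)."""
    return pd.DataFrame([t.to_row() for t in tables])


def stay_tables_to_long(tables: list[StayTable]) -> pd.DataFrame:
    """Long format for ANOVA: subject, group, reward, transition, stay."""
    rows = []
    for t in tables:
        for (reward, transition), p in t.stay.items():
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "group": t.group,
                    "reward": "rewarded" if reward == 1 else "unrewarded",
                    "transition": transition,
                    "stay": p,
                }
            )
    return pd.DataFrame(rows)
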