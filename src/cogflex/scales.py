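"""Questionnaire scoring and participant screening.

Instruments:

* SNAP-IV (parent-rated ADHD symptoms): 26 items on 0-3, scored as the
  item mean (the reported group means, 1.658 vs 0.527 on a 0-3 metric, are
  only consistent with item-mean scoring); subscales inattention (9),
  hyperactivity/impulsivity (9), oppositional (8).  Controls scoring 1.8
  or above are screened out ("below 1.8" retained).
* CFS (self-rated cognitive flexibility): 12 items on 1-6, summed (12-72).
* PSSES (perceived social self-efficacy): 25 items on 1-5, summed (25-125).
* SDQ emotional-symptoms and conduct-problems subscales (parent-rated):
  5 items each on 0-2, summed (0-10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaleSpec",
    "SNAP_IV",
    "CFS",
    "PSSES",
    "SDQ_EMOTIONAL",
    "SDQ_CONDUCT",
    "SCALES",
    "score_scale",
    "screen_participants",
]


@dataclass(frozen=True)
class ScaleSpec:
    name: str
    n_items: int
    item_min: int
    item_max: int
    scoring: str  # "mean" | "sum"
    subscales: dict[str, tuple[int, int]] = field(default_factory=dict)  # name -> item slice [start, stop)

    def __post_init__(self) -> None:
        if self.scoring not in ("mean", "sum"):
            raise ValueError("scoring must be 'mean' or 'sum'")
        if self.item_min >= self.item_max:
            raise ValueError("item_min must be < item_max")

    @property
    def score_range(self) -> tuple[float, float]:
        lo, hi = self.n_items * self.item_min, self.n_items * self.item_max
        if self.scoring == "mean":
            return lo / self.n_items, hi / self.n_items
        return float(lo), float(hi)


SNAP_IV = ScaleSpec(
    "SNAP-IV", 26, 0, 3, "mean",
    subscales={"inattention": (0, 9), "hyperactivity_impulsivity": (9, 18), "oppositional": (18, 26)},
)
CFS = ScaleSpec("CFS", 12, 1, 6, "sum")
PSSES = ScaleSpec("PSSES", 25, 1, 5, "sum")
SDQ_EMOTIONAL = ScaleSpec("SDQ-emotional", 5, 0, 2, "sum")
SDQ_CONDUCT = ScaleSpec("SDQ-conduct", 5, 0, 2, "sum")

SCALES = {s.name: s for s in (SNAP_IV, CFS, PSSES, SDQ_EMOTIONAL, SDQ_CONDUCT)}


def score_scale(
    item_responses: Sequence[float], spec: ScaleSpec, subscales: bool = False
) -> float | tuple[float, dict[str, float]]:
    """Score a complete item-response vector under a scale spec.

    Returns the total score, or ``(total, subscale_scores)`` when
    ``subscales=True``.  Incomplete or out-of-range responses raise.
    """
    x = np.asarray(item_responses, dtype=float)
    if x.shape != (spec.n_items,):
        raise ValueError(f"{spec.name} expects {spec.n_items} items, got {x.shape}")
    if np.isnan(x).any():
        raise ValueError(f"{spec.name}: missing item responses")
    if ((x < spec.item_min) | (x > spec.item_max)).any():
        raise ValueError(
            f"{spec.name}: responses outside [{spec.item_min}, {spec.item_max}]"
        )
    total = float(x.mean() if spec.scoring == "mean" else x.sum())
    if not subscales:
        return total
    subs = {
        name: float(x[a:b].mean() if spec.scoring == "mean" else x[a:b].sum())
        for name, (a, b) in spec.subscales.items()
    }
    return total, subs


def screen_participants(
    records: pd.DataFrame,
    snap_threshold: float = 1.8,
    age_bounds: tuple[float, float] = (6.0, 15.0),
    control_label: str = "control",
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the inclusion rules: controls must score strictly below the
    SNAP-IV threshold (1.8); everyone must be 6-15 years old.

    Returns the retained records and an exclusion log (one entry per
    excluded participant, with the reason)."""
    if records.empty:
        return records.copy(), []
    keep = []
    log: list[dict] = []
    for _, row in records.iterrows():
        reason = None
        if not (age_bounds[0] <= row["age"] <= age_bounds[1]):
            reason = f"age {row['age']} outside [{age_bounds[0]:g}, {age_bounds[1]:g}]"
        elif row["group"] == control_label and row["snap_score"] >= snap_threshold:
            reason = f"control SNAP-IV score {row['snap_score']:.3f} >= {snap_threshold}"
        if reason is None:
            keep.append(row)
        else:
            log.append({"id": row["id"], "group": row["group"], "reason": reason})
    kept = pd.DataFrame(keep, columns=records.columns).reset_index(drop=True)
    return kept, log
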