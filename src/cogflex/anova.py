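"""Mixed and within-subject ANOVAs on stay probabilities, and the
strategy classification they support.

The design is 2 (group, between) x 2 (reward, within) x 2 (transition
aka context, within).  With two-level within factors the mixed ANOVA is
computed exactly by the per-subject contrast decomposition: each within
effect reduces to one contrast score per subject, tested against that
contrast's own subject-level error stratum; the between effect is the
one-way ANOVA of the subject means.  Group effects use unweighted
(Type III) marginal means, so unequal group sizes are handled; sphericity
is trivially satisfied with two-level factors.

Strategy signatures: a significant reward main effect marks model-free
(habitual, outcome-driven) responding; a significant reward x transition
interaction marks model-based (transition-aware) responding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stay import StayTable

__all__ = ["EffectResult", "AnovaResult", "mixed_anova", "simple_effects", "classify_strategy"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect: F ratio, degrees of freedom, p-value, partial eta
    squared (SS_effect / (SS_effect + SS_error) in the effect's own error
    stratum), and the sums of squares themselves."""

    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


class AnovaResult:
    """Ordered collection of :class:`EffectResult` with a text summary."""

    def __init__(self, effects: list[EffectResult], design: str):
        self.effects = {e.name: e for e in effects}
        self.design = design

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def __contains__(self, name: str) -> bool:
        return name in self.effects

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.name,
                    "F": e.F,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "ss_effect": e.ss_effect,
                    "ss_error": e.ss_error,
                }
                for e in self.effects.values()
            ]
        )

    def summary(self) -> str:
        lines = [f"ANOVA ({self.design})", "-" * 64]
        lines.append(f"{'effect':<28}{'F':>8}{'df':>9}{'p':>9}{'eta_p^2':>9}")
        for e in self.effects.values():
            lines.append(
                f"{e.name:<28}{e.F:>8.3f}{f'({e.df_num},{e.df_den})':>9}"
                f"{e.p:>9.4f}{e.partial_eta_sq:>9.3f}"
            )
        return "\n".join(lines)


# -- contrast machinery ---------------------------------------------------


def _subject_scores(table: StayTable) -> dict[str, float]:
    s = table.stay
    rc, rr = s[(1, "common")], s[(1, "rare")]
    uc, ur = s[(0, "common")], s[(0, "rare")]
    return {
        "mean": (rc + rr + uc + ur) / 4.0,
        "reward": (rc + rr - uc - ur) / 2.0,
        "transition": (rc + uc - rr - ur) / 2.0,
        "reward:transition": (rc - rr) - (uc - ur),
    }


def _one_sample_effect(name: str, y: np.ndarray, df_den: int | None = None) -> EffectResult:
    n = y.size
    mean = float(y.mean())
    ss_err = float(((y - mean) ** 2).sum())
    dfe = n - 1 if df_den is None else df_den
    ss_eff = n * mean**2
    mse = ss_err / dfe if dfe > 0 else np.nan
    F = ss_eff / mse if mse > 0 else np.inf if ss_eff > 0 else 0.0
    p = float(stats.f.sf(F, 1, dfe)) if np.isfinite(F) else 0.0
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return EffectResult(name, float(F), 1, dfe, p, float(eta), ss_eff, ss_err)


def _two_group_effects(
    names: tuple[str, str], y1: np.ndarray, y2: np.ndarray
) -> tuple[EffectResult, EffectResult]:
    """Type III tests of the unweighted mean (``names[0]``) and the group
    difference (``names[1]``) of a per-subject score."""
    n1, n2 = y1.size, y2.size
    m1, m2 = float(y1.mean()), float(y2.mean())
    ss_err = float(((y1 - m1) ** 2).sum() + ((y2 - m2) ** 2).sum())
    dfe = n1 + n2 - 2
    mse = ss_err / dfe

    def effect(name: str, estimate: float, var_factor: float) -> EffectResult:
        ss_eff = estimate**2 / var_factor
        F = ss_eff / mse if mse > 0 else np.inf if ss_eff > 0 else 0.0
        p = float(stats.f.sf(F, 1, dfe)) if np.isfinite(F) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return EffectResult(name, float(F), 1, dfe, p, float(eta), float(ss_eff), ss_err)

    grand = effect(names[0], (m1 + m2) / 2.0, (1.0 / n1 + 1.0 / n2) / 4.0)
    diff = effect(names[1], m1 - m2, 1.0 / n1 + 1.0 / n2)
    return grand, diff


def _screen_tables(tables: list[StayTable], on_flagged: str) -> list[StayTable]:
    flagged = [t for t in tables if t.has_flagged_cells]
    if flagged:
        if on_flagged == "error":
            ids = [t.subject_id for t in flagged]
            raise ValueError(f"subjects with sparse stay cells present: {ids}")
        if on_flagged == "exclude":
            for t in flagged:
                logger.warning(
                    "excluding subject %s: sparse cells %s", t.subject_id, sorted(t.flagged)
                )
            tables = [t for t in tables if not t.has_flagged_cells]
        elif on_flagged != "include":
            raise ValueError("on_flagged must be 'exclude', 'error' or 'include'")
    return tables


def mixed_anova(tables: list[StayTable], on_flagged: str = "exclude") -> AnovaResult:
    """Three-way mixed ANOVA: group (between) x reward x transition
    (within), Type III sums of squares, on per-subject stay tables."""
    tables = _screen_tables(tables, on_flagged)
    groups = sorted({t.group for t in tables})
    if len(groups) != 2:
        raise ValueError(f"mixed ANOVA needs exactly 2 groups, got {groups}")
    by_group = {g: [t for t in tables if t.group == g] for g in groups}
    for g, ts in by_group.items():
        if len(ts) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 usable subjects")

    scores = {
        g: pd.DataFrame([_subject_scores(t) for t in ts]) for g, ts in by_group.items()
    }
    g1, g2 = groups
    effects: list[EffectResult] = []
    # Between-subject factor on the subject means.
    _, grp = _two_group_effects(
        ("(grand mean)", "group"), scores[g1]["mean"].to_numpy(), scores[g2]["mean"].to_numpy()
    )
    effects.append(grp)
    for contrast in ("reward", "transition", "reward:transition"):
        main, inter = _two_group_effects(
            (contrast, f"{contrast}:group"),
            scores[g1][contrast].to_numpy(),
            scores[g2][contrast].to_numpy(),
        )
        effects.extend([main, inter])
    return AnovaResult(effects, design=f"mixed 2x2x2, groups={groups}")


def simple_effects(tables: list[StayTable], on_flagged: str = "exclude") -> AnovaResult:
    """2x2 within-subject ANOVA (reward, transition) for a single group."""
    tables = _screen_tables(tables, on_flagged)
    groups = {t.group for t in tables}
    if len(groups) != 1:
        raise ValueError(f"simple-effects analysis expects a single group, got {sorted(groups)}")
    if len(tables) < 2:
        raise ValueError("need at least 2 subjects")
    scores = pd.DataFrame([_subject_scores(t) for t in tables])
    effects = [
        _one_sample_effect(c, scores[c].to_numpy())
        for c in ("reward", "transition", "reward:transition")
    ]
    return AnovaResult(effects, design=f"within 2x2, group={groups.pop()}")


def classify_strategy(result: AnovaResult, alpha: float = 0.05) -> str:
    """Label the strategy signature carried by an ANOVA result.

    model-free  : significant reward main effect only
    model-based : significant reward x transition interaction only
    hybrid      : both significant
    neither     : neither significant
    """
    if "reward" not in result or "reward:transition" not in result:
        raise ValueError("result must contain 'reward' and 'reward:transition' effects")
    mf = result["reward"].p < alpha
    mb = result["reward:transition"].p < alpha
    if mf and mb:
        return "hybrid"
    if mf:
        return "model-free"
    if mb:
        return "model-based"
    return "neither"
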