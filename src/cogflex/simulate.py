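"""Synthetic cohorts: questionnaire tables from a linear path model and
behavioral sessions from agent populations of known strategy.

The questionnaire generator draws, per participant, a latent conduct
covariate C and ADHD-symptom latent X (correlated rho), then a cognitive-
flexibility latent M = a*X + g_m*C + e_M and two outcome latents
(social self-efficacy and emotional symptoms) Y = c'*X + b*M + g_y*C + e_Y.
The clinical group receives a mean offset on X which propagates through
the structural paths.  Latents are mapped affinely onto the instruments'
score ranges (clipped when necessary, counts logged) and split into
item-level responses deterministically (as even as possible, remainder on
the first items) so that re-scoring the items reproduces each score
exactly.

Because every score map is affine with positive slope, the standardized
regression paths implied by the latent model carry over to the scores;
:meth:`PathModelSpec.implied_standardized_effects` returns them in closed
form for parameter-recovery and coverage checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .agents import AgentParams, HybridAgent, WSLSAgent
from .task import EnvConfig, SessionData, run_session
from .scales import CFS, PSSES, SDQ_CONDUCT, SDQ_EMOTIONAL, SNAP_IV, ScaleSpec

__all__ = [
    "PathModelSpec",
    "GroupSpec",
    "CohortSpec",
    "generate_questionnaire_cohort",
    "generate_behavioral_cohort",
    "default_cohort_spec",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathModelSpec:
    """True path-model parameters of the questionnaire generator.

    Defaults qualitatively mimic the clinical-group pattern: ADHD symptoms
    depress cognitive flexibility (a < 0), flexibility supports social
    self-efficacy (b > 0) and dampens emotional symptoms, with conduct
    problems loading on both mediator and outcomes.
    """

    n_clinical: int = 20
    n_control: int = 23
    a: float = -0.6
    b: float = 0.5
    c_prime: float = -0.3
    b_emotional: float = -0.5
    c_prime_emotional: float = 0.3
    cov_loading_m: float = 0.3
    cov_loading_y: float = 0.3
    x_cov_corr: float = 0.3
    residual_sd_m: float = 0.7
    residual_sd_y: float = 0.7
    x_offset_clinical: float = 3.2
    m_offset_clinical: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.residual_sd_m <= 0 or self.residual_sd_y <= 0:
            raise ValueError("residual SDs must be > 0")
        if not -1.0 < self.x_cov_corr < 1.0:
            raise ValueError("x_cov_corr must lie in (-1, 1)")
        if self.n_clinical < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")

    # -- implied moments (within group; offsets shift means only) ------
    def _moments(self, outcome: str) -> dict[str, float]:
        a, rho = self.a, self.x_cov_corr
        gm, gy = self.cov_loading_m, self.cov_loading_y
        sm, sy = self.residual_sd_m, self.residual_sd_y
        if outcome == "sse":
            b, c = self.b, self.c_prime
        elif outcome == "emotional":
            b, c = self.b_emotional, self.c_prime_emotional
        else:
            raise ValueError("outcome must be 'sse' or 'emotional'")
        var_m = a**2 + gm**2 + 2 * a * gm * rho + sm**2
        cov_xm = a + gm * rho
        cov_cm = a * rho + gm
        var_y = (
            c**2 + b**2 * var_m + gy**2 + sy**2
            + 2 * c * b * cov_xm + 2 * c * gy * rho + 2 * b * gy * cov_cm
        )
        return {"b": b, "c": c, "var_m": var_m, "var_y": var_y}

    def implied_standardized_effects(self, outcome: str = "sse") -> dict[str, float]:
        """Closed-form standardized a/b/c'/total/indirect paths implied by
        the generating parameters (var(X) = var(C) = 1 within group)."""
        mm = self._moments(outcome)
        sd_m, sd_y = math.sqrt(mm["var_m"]), math.sqrt(mm["var_y"])
        a_std = self.a / sd_m
        b_std = mm["b"] * sd_m / sd_y
        c_std = mm["c"] / sd_y
        return {
            "a": a_std,
            "b": b_std,
            "c_prime": c_std,
            "indirect": a_std * b_std,
            "total": c_std + a_std * b_std,
        }


# Affine score maps: score = intercept + slope * standardized latent.
_SCORE_MAPS: dict[str, tuple[ScaleSpec, float, float]] = {
    "snap_score": (SNAP_IV, 0.70, 0.30),
    "cfs_score": (CFS, 51.9, 10.0),
    "psses_score": (PSSES, 91.8, 14.0),
    "sdq_emotional": (SDQ_EMOTIONAL, 0.7, 0.8),
    "sdq_conduct": (SDQ_CONDUCT, 1.8, 1.2),
}

_ITEM_PREFIX = {
    "snap_score": "snap_q",
    "cfs_score": "cfs_q",
    "psses_score": "psses_q",
    "sdq_emotional": "sdq_emo_q",
    "sdq_conduct": "sdq_con_q",
}


def _distribute_items(total: int, spec: ScaleSpec) -> list[int]:
    """Split an integer item total across items as evenly as possible,
    remainder on the first items; exact re-aggregation is guaranteed."""
    n, lo, hi = spec.n_items, spec.item_min, spec.item_max
    total = int(min(max(total, n * lo), n * hi))
    q, r = divmod(total - n * lo, n)
    return [lo + q + 1] * r + [lo + q] * (n - r)


def _score_and_items(latent_z: np.ndarray, column: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Map standardized latents onto a scale; returns (scores, items, n_clipped)."""
    spec, intercept, slope = _SCORE_MAPS[column]
    raw = intercept + slope * latent_z
    lo, hi = spec.score_range
    clipped = int(((raw < lo) | (raw > hi)).sum())
    raw = np.clip(raw, lo, hi)
    items = np.empty((raw.size, spec.n_items), dtype=int)
    scores = np.empty(raw.size)
    for i, v in enumerate(raw):
        total = round(v * spec.n_items) if spec.scoring == "mean" else round(v)
        items[i] = _distribute_items(total, spec)
        scores[i] = items[i].mean() if spec.scoring == "mean" else items[i].sum()
    return scores, items, clipped


def generate_questionnaire_cohort(spec: PathModelSpec) -> pd.DataFrame:
    """Draw a two-group participant table from the path model.

    Emits scores, exactly consistent item-level responses, demographics
    and the underlying standardized latents (columns ``*_latent``).
    Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    clip_total = 0
    for group, n, x_off, m_off in (
        ("clinical", spec.n_clinical, spec.x_offset_clinical, spec.m_offset_clinical),
        ("control", spec.n_control, 0.0, 0.0),
    ):
        if n == 0:
            continue
        rho = spec.x_cov_corr
        C = rng.standard_normal(n)
        # The clinical X offset propagates through the structural paths.
        X = x_off + rho * C + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        M = spec.a * X + spec.cov_loading_m * C + spec.residual_sd_m * rng.standard_normal(n)
        Y_sse = (
            spec.c_prime * X + spec.b * M
            + spec.cov_loading_y * C + spec.residual_sd_y * rng.standard_normal(n)
        )
        Y_emo = (
            spec.c_prime_emotional * X + spec.b_emotional * M
            + spec.cov_loading_y * C + spec.residual_sd_y * rng.standard_normal(n)
        )
        mm_sse = spec._moments("sse")
        mm_emo = spec._moments("emotional")
        z = {
            "snap_score": X,
            "cfs_score": M / math.sqrt(mm_sse["var_m"]) + m_off,
            "psses_score": Y_sse / math.sqrt(mm_sse["var_y"]),
            "sdq_emotional": Y_emo / math.sqrt(mm_emo["var_y"]),
            "sdq_conduct": C,
        }
        data: dict[str, np.ndarray] = {
            "group": np.repeat(group, n),
            "sex": rng.choice(
                ["M", "F"], size=n, p=[0.75, 0.25] if group == "clinical" else [0.3, 0.7]
            ),
            "age": rng.integers(7, 14, size=n),
        }
        for col, latent in z.items():
            scores, items, clipped = _score_and_items(latent, col)
            clip_total += clipped
            data[col] = scores
            for j in range(items.shape[1]):
                data[f"{_ITEM_PREFIX[col]}{j + 1}"] = items[:, j]
            data[f"{col}_latent"] = latent
        frames.append(pd.DataFrame(data))
    if clip_total:
        logger.warning("clipped %d scores to their scale ranges", clip_total)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not out.empty:
        out.insert(0, "id", [f"P{i + 1:03d}" for i in range(len(out))])
    return out


# -- behavioral cohorts ---------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic group: label, size and the agents' parameters."""

    label: str
    n_subjects: int
    params: AgentParams
    agent: str = "hybrid"  # "hybrid" | "wsls"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.agent not in ("hybrid", "wsls"):
            raise ValueError("agent must be 'hybrid' or 'wsls'")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    env: EnvConfig = EnvConfig()
    seed: Optional[int] = None


def default_cohort_spec(seed: Optional[int] = None) -> CohortSpec:
    """Two groups of 21 subjects (the Study-2 sample sizes).  Controls are
    hybrid learners (w = 0.5, beta = 5); the synthetic clinical group is a
    noisy, lapse-prone stand-in (beta = 0.5, lapse 0.1), not a claim about
    the mechanism of the observed null pattern."""
    return CohortSpec(
        groups=(
            GroupSpec("control", 21, AgentParams(w=0.5, alpha=0.7, lam=0.6, beta=5.0)),
            GroupSpec(
                "clinical", 21, AgentParams(w=0.5, alpha=0.7, lam=0.6, beta=0.5, lapse_prob=0.1)
            ),
        ),
        seed=seed,
    )


def _make_agent(group: GroupSpec, seed: int):
    params = replace(group.params, seed=seed)
    if group.agent == "wsls":
        return WSLSAgent(params)
    return HybridAgent(params)


def generate_behavioral_cohort(spec: CohortSpec) -> list[SessionData]:
    """One seeded session per synthetic subject, group labels attached."""
    rng = np.random.default_rng(spec.seed)
    sessions: list[SessionData] = []
    counter = 0
    for group in spec.groups:
        for _ in range(group.n_subjects):
            counter += 1
            env_seed, agent_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
            config = replace(spec.env, seed=env_seed)
            agent = _make_agent(group, agent_seed)
            sessions.append(
                run_session(
                    agent, config, subject_id=f"S{counter:03d}", group=group.label
                )
            )
    return sessions
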