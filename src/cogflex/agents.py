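"""Synthetic decision-making agents for the two-step task.

The generative model is the canonical hybrid of model-based (MB) and
model-free (MF) control used throughout the two-step literature: a
temporal-difference (TD) critic with learning rate alpha and eligibility
lambda maintains MF values; an MB planner evaluates stage-1 options
prospectively through the known 70/30 transition matrix; the two are mixed
with weight w (1 = pure MB, 0 = pure MF) and passed through a softmax with
inverse temperature beta, plus a perseveration bonus kappa for repeating
the previous stage-1 choice.  A win-stay/lose-shift (WSLS) heuristic agent
— stay after reward, switch after no reward, transitions ignored — is
provided as the outcome-driven strategy young children are reported to use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .task import COMMON_DESTINATION, TrialRecord

__all__ = ["AgentParams", "HybridAgent", "WSLSAgent", "softmax_choice_prob"]


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth strategy parameters for a synthetic subject.

    w
        MB/MF mixing weight in [0, 1]; 1 is pure model-based.
    alpha
        TD learning rate in [0, 1].
    lam
        Eligibility-trace parameter in [0, 1]: how much of the stage-2
        prediction error propagates to the stage-1 value.
    beta
        Softmax inverse temperature, >= 0 (0 = uniform random choice).
    kappa
        Perseveration bonus added to repeating the previous stage-1 choice.
    lapse_prob
        Per-stage probability of a missed response, in [0, 1).
    """

    w: float = 0.5
    alpha: float = 0.7
    lam: float = 0.6
    beta: float = 5.0
    kappa: float = 0.0
    lapse_prob: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("w", "alpha", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.lapse_prob < 1.0:
            raise ValueError("lapse_prob must be in [0, 1)")


def softmax_choice_prob(value0: float, value1: float, beta: float) -> float:
    """P(option 0) under a two-option softmax with inverse temperature beta."""
    return 1.0 / (1.0 + math.exp(-beta * (value0 - value1)))


class HybridAgent:
    """Hybrid MB/MF temporal-difference agent.

    Stage-2 values are shared by the MF critic and the MB planner; the
    transition matrix is fixed at the true 70/30 structure (the task
    instructions teach it), not learned.  Values are initialised at 0.
    """

    def __init__(self, params: AgentParams, transition_prob: float = 0.70):
        self.params = params
        self.transition_prob = transition_prob
        self.rng = np.random.default_rng(params.seed)
        self.reset()

    def reset(self) -> None:
        self.q2 = [[0.0, 0.0], [0.0, 0.0]]  # [stage2_state][option]
        self.q1_mf = [0.0, 0.0]
        self.last_choice1: Optional[int] = None

    # -- valuation ----------------------------------------------------
    def q_mb(self, action: int) -> float:
        p = self.transition_prob
        common = COMMON_DESTINATION[action]
        return p * max(self.q2[common]) + (1.0 - p) * max(self.q2[1 - common])

    def net_stage1_values(self) -> tuple[float, float]:
        w, kappa = self.params.w, self.params.kappa
        vals = []
        for a in (0, 1):
            v = w * self.q_mb(a) + (1.0 - w) * self.q1_mf[a]
            if self.last_choice1 is not None and a == self.last_choice1:
                v += kappa
            vals.append(v)
        return vals[0], vals[1]

    # -- choice -------------------------------------------------------
    def _lapse(self) -> bool:
        return self.params.lapse_prob > 0 and self.rng.random() < self.params.lapse_prob

    def choose_stage1(self) -> Optional[int]:
        if self._lapse():
            return None
        v0, v1 = self.net_stage1_values()
        p0 = softmax_choice_prob(v0, v1, self.params.beta)
        return 0 if self.rng.random() < p0 else 1

    def choose_stage2(self, stage2_state: int) -> Optional[int]:
        if self._lapse():
            return None
        q = self.q2[stage2_state]
        p0 = softmax_choice_prob(q[0], q[1], self.params.beta)
        return 0 if self.rng.random() < p0 else 1

    # -- learning -----------------------------------------------------
    def observe(self, trial: TrialRecord) -> None:
        """TD update from one trial; missed trials leave values unchanged."""
        if trial.choice1 is None:
            return
        self.last_choice1 = trial.choice1
        if trial.choice2 is None or trial.reward is None:
            return
        a, s, c, r = trial.choice1, trial.stage2_state, trial.choice2, trial.reward
        alpha, lam = self.params.alpha, self.params.lam
        delta1 = self.q2[s][c] - self.q1_mf[a]
        self.q1_mf[a] += alpha * delta1
        delta2 = r - self.q2[s][c]
        self.q2[s][c] += alpha * delta2
        self.q1_mf[a] += alpha * lam * delta2


class WSLSAgent:
    """Win-stay/lose-shift heuristic: repeat the previous stage-1 choice
    iff its outcome was rewarded, switch otherwise, blind to transition
    type.  With no completed history the choice is uniform; stage-2 choices
    are uniform."""

    def __init__(self, params: Optional[AgentParams] = None, seed: Optional[int] = None):
        self.params = params if params is not None else AgentParams(lapse_prob=0.0, seed=seed)
        self.rng = np.random.default_rng(self.params.seed)
        self.reset()

    def reset(self) -> None:
        self.last_choice1: Optional[int] = None
        self.last_reward: Optional[int] = None

    def _lapse(self) -> bool:
        return self.params.lapse_prob > 0 and self.rng.random() < self.params.lapse_prob

    def choose_stage1(self) -> Optional[int]:
        if self._lapse():
            return None
        if self.last_reward is None:
            return int(self.rng.integers(0, 2))
        if self.last_reward == 1:
            return self.last_choice1
        return 1 - self.last_choice1

    def choose_stage2(self, stage2_state: int) -> Optional[int]:
        if self._lapse():
            return None
        return int(self.rng.integers(0, 2))

    def observe(self, trial: TrialRecord) -> None:
        if trial.choice1 is not None and trial.reward is not None:
            self.last_choice1 = trial.choice1
            self.last_reward = trial.reward
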