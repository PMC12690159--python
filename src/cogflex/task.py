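"""Two-stage Markov decision ("two-step") task environment.

The task has a first stage with two options (the "blue car" and "green
car"), each of which leads more often to one of two second-stage states
(the "duck farm" and "chicken farm"): its *common* destination is reached
with probability 0.70 and the other, *rare*, destination with probability
0.30.  In the second stage the subject picks one of two options and is
rewarded with a probability that drifts slowly and independently per
(state, option) cell, reflected inside [0.250, 0.750].  A session is 200
trials organised in blocks of 50; blocks are bookkeeping only, the reward
walk is never reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EnvConfig",
    "EnvState",
    "TrialRecord",
    "SessionData",
    "MissedChoiceError",
    "initial_state",
    "step_transition",
    "drift_reward_probs",
    "sample_reward",
    "run_session",
]

#: Stage-1 option labels, indexed 0/1.
OPTION_LABELS = ("blue", "green")
#: Stage-2 state labels, indexed 0/1.
STATE_LABELS = ("duck", "chicken")
#: Stage-2 option labels within a state.
STAGE2_OPTION_LABELS = ("white", "spotted")

# Fixed transition map: stage-1 option i goes commonly to stage-2 state i
# (blue -> duck, green -> chicken), i.e. common destination == choice index.
COMMON_DESTINATION = (0, 1)


class MissedChoiceError(ValueError):
    """Raised when a stage transition or reward draw is requested for a
    missed (None) choice: no transition occurs on an aborted trial."""


@dataclass(frozen=True)
class EnvConfig:
    """Parameters of the two-step environment.

    Defaults are the task as administered: 70/30 transitions, reward
    probabilities drifting within [0.250, 0.750] by a Gaussian random walk
    (sd 0.025 per trial, reflecting boundaries), 200 trials in blocks of 50.
    """

    common_transition_prob: float = 0.70
    reward_prob_bounds: tuple[float, float] = (0.250, 0.750)
    drift_sd: float = 0.025
    n_trials: int = 200
    trials_per_block: int = 50
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = self.reward_prob_bounds
        if not 0.5 < self.common_transition_prob < 1.0:
            raise ValueError(
                "common_transition_prob must lie in (0.5, 1), got "
                f"{self.common_transition_prob}"
            )
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"reward_prob_bounds must satisfy 0 < lo < hi < 1, got {self.reward_prob_bounds}")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        if self.trials_per_block <= 0:
            raise ValueError("trials_per_block must be positive")
        if self.n_trials % self.trials_per_block != 0:
            raise ValueError(
                f"n_trials ({self.n_trials}) must be divisible by trials_per_block ({self.trials_per_block})"
            )


@dataclass
class EnvState:
    """Mutable environment state: the four reward probabilities (one per
    stage-2 state x option cell), the trial counter and the RNG."""

    reward_probs: np.ndarray  # shape (2, 2): [stage2_state, option]
    trial_index: int
    rng: np.random.Generator

    def copy_probs(self) -> np.ndarray:
        return self.reward_probs.copy()


@dataclass(frozen=True)
class TrialRecord:
    """One two-stage trial.  Missed choices are None; the downstream
    fields of a missed choice are None as well (no transition occurs after
    a missed stage-1 response; no reward after a missed stage-2 response).
    """

    trial_index: int
    choice1: Optional[int]
    transition: Optional[str]  # "common" | "rare"
    stage2_state: Optional[int]
    choice2: Optional[int]
    reward: Optional[int]  # 1 rewarded, 0 unrewarded
    reward_probs_snapshot: tuple[float, float, float, float] = (np.nan,) * 4

    def __post_init__(self) -> None:
        if self.choice1 is None:
            if not (self.transition is None and self.stage2_state is None
                    and self.choice2 is None and self.reward is None):
                raise ValueError("missed stage-1 choice must void the rest of the trial")
        else:
            if self.transition is not None and self.stage2_state is not None:
                expected = "common" if self.stage2_state == COMMON_DESTINATION[self.choice1] else "rare"
                if self.transition != expected:
                    raise ValueError(
                        f"transition label {self.transition!r} inconsistent with "
                        f"choice {self.choice1} -> state {self.stage2_state}"
                    )
            if self.choice2 is None and self.reward is not None:
                raise ValueError("missed stage-2 choice cannot carry a reward")


@dataclass
class SessionData:
    """A subject's full task session."""

    subject_id: str
    group: str
    trials: list[TrialRecord]
    config: EnvConfig

    def __post_init__(self) -> None:
        if len(self.trials) != self.config.n_trials:
            raise ValueError(
                f"session has {len(self.trials)} trials but config.n_trials={self.config.n_trials}"
            )
        for i, t in enumerate(self.trials, start=1):
            if t.trial_index != i:
                raise ValueError("trial indices must increase strictly from 1")

    def __len__(self) -> int:
        return len(self.trials)


def initial_state(config: EnvConfig, rng: Optional[np.random.Generator] = None) -> EnvState:
    """Initial environment state.

    Initial reward probabilities are drawn uniformly inside the bounds
    (the task literature states only the bounds, not starting values).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.reward_prob_bounds
    probs = rng.uniform(lo, hi, size=(2, 2))
    return EnvState(reward_probs=probs, trial_index=0, rng=rng)


def step_transition(choice1: Optional[int], state: EnvState, config: EnvConfig) -> tuple[int, str]:
    """Resolve the stage-1 -> stage-2 transition for a (non-missed) choice.

    Returns ``(stage2_state, label)`` where the label is ``"common"`` iff
    the destination is the choice's frequent one (probability
    ``common_transition_prob``).
    """
    if choice1 is None:
        raise MissedChoiceError("no transition occurs after a missed stage-1 response")
    if choice1 not in (0, 1):
        raise ValueError(f"invalid stage-1 choice {choice1!r}")
    common_dest = COMMON_DESTINATION[choice1]
    if state.rng.random() < config.common_transition_prob:
        return common_dest, "common"
    return 1 - common_dest, "rare"


def _reflect(p: float, lo: float, hi: float) -> float:
    # Reflecting boundaries; the loop handles increments larger than the band.
    while p < lo or p > hi:
        if p > hi:
            p = 2.0 * hi - p
        elif p < lo:
            p = 2.0 * lo - p
    return p


def drift_reward_probs(state: EnvState, config: EnvConfig) -> EnvState:
    """Apply one Gaussian random-walk step (sd ``drift_sd``) independently
    to each of the four reward probabilities, reflecting at the bounds.
    Mutates and returns ``state``."""
    lo, hi = config.reward_prob_bounds
    if config.drift_sd > 0:
        steps = state.rng.normal(0.0, config.drift_sd, size=(2, 2))
        probs = state.reward_probs + steps
        for idx in np.ndindex(2, 2):
            probs[idx] = _reflect(float(probs[idx]), lo, hi)
        state.reward_probs = probs
    return state


def sample_reward(stage2_state: int, choice2: Optional[int], state: EnvState) -> Optional[int]:
    """Bernoulli reward draw at the current probability of the chosen
    (stage-2 state, option) cell; a missed choice yields None."""
    if choice2 is None:
        return None
    if choice2 not in (0, 1) or stage2_state not in (0, 1):
        raise ValueError("invalid stage-2 state/option")
    p = float(state.reward_probs[stage2_state, choice2])
    return int(state.rng.random() < p)


def run_session(
    agent,
    config: EnvConfig = EnvConfig(),
    subject_id: str = "S1",
    group: str = "control",
) -> SessionData:
    """Run one agent through a full session.

    Per trial: the agent chooses at stage 1 (possibly a lapse/miss, which
    aborts the trial), the transition resolves, the agent chooses at stage
    2 (a miss there records the transition but no reward), the outcome is
    sampled, the agent observes the trial, and finally the reward
    probabilities take one drift step — so each record's snapshot is the
    probability in force when its outcome was sampled.  Fully reproducible
    from ``config.seed`` plus the agent's own seed.
    """
    state = initial_state(config)
    trials: list[TrialRecord] = []
    for t in range(1, config.n_trials + 1):
        snapshot = tuple(float(x) for x in state.reward_probs.ravel())
        choice1 = agent.choose_stage1()
        if choice1 is None:
            trial = TrialRecord(t, None, None, None, None, None, snapshot)
        else:
            stage2, label = step_transition(choice1, state, config)
            choice2 = agent.choose_stage2(stage2)
            reward = sample_reward(stage2, choice2, state)
            trial = TrialRecord(t, choice1, label, stage2, choice2, reward, snapshot)
        agent.observe(trial)
        trials.append(trial)
        drift_reward_probs(state, config)
        state.trial_index = t
    return SessionData(subject_id=subject_id, group=group, trials=trials, config=config)
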