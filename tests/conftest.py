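import numpy as np
import pytest

from cogflex.stay import CELLS, StayTable
from cogflex.task import EnvConfig, SessionData, TrialRecord


def make_stay_table(
    subject_id: str,
    group: str,
    cc: float,
    rc: float,
    cu: float,
    ru: float,
    count: int = 50,
) -> StayTable:
    """Stay table from the four cell proportions (common/rare x rewarded/
    unrewarded), all cell counts equal."""
    stay = {(1, "common"): cc, (1, "rare"): rc, (0, "common"): cu, (0, "rare"): ru}
    counts = {cell: count for cell in CELLS}
    return StayTable(subject_id=subject_id, group=group, stay=stay, counts=counts)


@pytest.fixture
def seven_trial_session() -> SessionData:
    """Hand-enumerated session exercising all stay cells plus missed data.

    Pairs (t-1 -> t): (reward=1, common) stay x2; (reward=0, rare) shift;
    (reward=1, rare) shift; (reward=0, common) stay; the trial-6 pair is
    dropped (outcome missing at t-1).
    """
    trials = [
        TrialRecord(1, 0, "common", 0, 0, 1),
        TrialRecord(2, 0, "rare", 1, 1, 0),
        TrialRecord(3, 1, "common", 1, 0, 1),
        TrialRecord(4, 1, "rare", 0, 1, 1),
        TrialRecord(5, 0, "common", 0, 0, 0),
        TrialRecord(6, 0, "rare", 1, None, None),
        TrialRecord(7, 1, "common", 1, 1, 0),
    ]
    config = EnvConfig(n_trials=7, trials_per_block=7)
    return SessionData(subject_id="hand", group="control", trials=trials, config=config)


class AlwaysStayAgent:
    """Picks option 0 at both stages, every trial."""

    def choose_stage1(self):
        return 0

    def choose_stage2(self, stage2_state):
        return 0

    def observe(self, trial):
        pass


class AlternatingAgent:
    """Alternates the stage-1 option every trial."""

    def __init__(self):
        self.next = 0

    def choose_stage1(self):
        c = self.next
        self.next = 1 - self.next
        return c

    def choose_stage2(self, stage2_state):
        return 0

    def observe(self, trial):
        pass
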