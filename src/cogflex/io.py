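"""CSV interchange for sessions, stay tables and participant cohorts.

Session CSV layout (one row per trial, UTF-8, header required):
subject_id, group, trial, choice1, transition, stage2_state, choice2,
reward, missed1, missed2 — with the task's labels (blue/green,
common/rare, duck/chicken, white/spotted) and empty fields for the parts
of a trial voided by a missed response.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .task import (
    EnvConfig,
    OPTION_LABELS,
    STAGE2_OPTION_LABELS,
    STATE_LABELS,
    SessionData,
    TrialRecord,
)

__all__ = [
    "session_to_frame",
    "frame_to_session",
    "write_session_csv",
    "read_session_csv",
    "write_sessions",
    "read_sessions",
]

_SESSION_COLUMNS = [
    "subject_id", "group", "trial", "choice1", "transition",
    "stage2_state", "choice2", "reward", "missed1", "missed2",
]


def session_to_frame(session: SessionData) -> pd.DataFrame:
    rows = []
    for t in session.trials:
        rows.append(
            {
                "subject_id": session.subject_id,
                "group": session.group,
                "trial": t.trial_index,
                "choice1": OPTION_LABELS[t.choice1] if t.choice1 is not None else "",
                "transition": t.transition or "",
                "stage2_state": STATE_LABELS[t.stage2_state] if t.stage2_state is not None else "",
                "choice2": STAGE2_OPTION_LABELS[t.choice2] if t.choice2 is not None else "",
                "reward": "" if t.reward is None else t.reward,
                "missed1": int(t.choice1 is None),
                "missed2": int(t.choice1 is not None and t.choice2 is None),
            }
        )
    return pd.DataFrame(rows, columns=_SESSION_COLUMNS)


def _parse_label(value, labels: tuple[str, ...], column: str, row: int) -> Optional[int]:
    if value == "" or pd.isna(value):
        return None
    try:
        return labels.index(value)
    except ValueError:
        raise ValueError(f"row {row}: unknown {column} label {value!r}") from None


def frame_to_session(frame: pd.DataFrame, config: Optional[EnvConfig] = None) -> SessionData:
    """Rebuild a session from its CSV frame.

    The environment config is not stored in the CSV; pass one to attach,
    otherwise a default config with matching trial count is used.
    """
    missing = [c for c in _SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"session table missing columns: {missing}")
    subject_ids = frame["subject_id"].unique()
    if len(subject_ids) != 1:
        raise ValueError("one session per frame; found multiple subject_ids")
    trials = []
    for i, row in frame.sort_values("trial").iterrows():
        reward = row["reward"]
        trials.append(
            TrialRecord(
                trial_index=int(row["trial"]),
                choice1=_parse_label(row["choice1"], OPTION_LABELS, "choice1", i),
                transition=row["transition"] if row["transition"] not in ("", None) and pd.notna(row["transition"]) else None,
                stage2_state=_parse_label(row["stage2_state"], STATE_LABELS, "stage2_state", i),
                choice2=_parse_label(row["choice2"], STAGE2_OPTION_LABELS, "choice2", i),
                reward=None if reward in ("", None) or pd.isna(reward) else int(reward),
            )
        )
    if config is None:
        n = len(trials)
        block = n if n > 0 else 1
        config = EnvConfig(n_trials=n, trials_per_block=block) if n else EnvConfig(n_trials=0)
    return SessionData(
        subject_id=str(subject_ids[0]),
        group=str(frame["group"].iloc[0]),
        trials=trials,
        config=config,
    )


def write_session_csv(session: SessionData, path) -> None:
    session_to_frame(session).to_csv(path, index=False, encoding="utf-8")


def read_session_csv(path, config: Optional[EnvConfig] = None) -> SessionData:
    frame = pd.read_csv(path, keep_default_na=False, na_values=[])
    frame["reward"] = frame["reward"].replace("", None)
    return frame_to_session(frame, config=config)


def write_sessions(sessions: list[SessionData], directory) -> list[Path]:
    """One CSV per subject; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in sessions:
        p = directory / f"session_{s.subject_id}.csv"
        write_session_csv(s, p)
        paths.append(p)
    return paths


def read_sessions(directory, config: Optional[EnvConfig] = None) -> list[SessionData]:
    directory = Path(directory)
    return [
        read_session_csv(p, config=config) for p in sorted(directory.glob("session_*.csv"))
    ]
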