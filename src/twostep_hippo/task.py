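"""Two-step decision task: structure, outcome sampling and event timelines.

The task has a first step in which the subject chooses between two options
(``S1_PLUS``/``S1_MINUS``) and a second step in which one of two states
(``S2_PLUS``/``S2_MINUS``) is presented and pecked for a probabilistic
reward.  Choices map to second-step states through a fixed transition
matrix (rows: first-step options, columns: second-step states) and each
second-step state carries a fixed reward probability.  The default
contingencies are 80/20 in both structures, so ``S1_PLUS`` commonly leads
to the high-reward state ``S2_PLUS``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "S1_PLUS",
    "S1_MINUS",
    "S2_PLUS",
    "S2_MINUS",
    "TaskConfig",
    "TrialRecord",
    "sample_transition",
    "sample_reward",
    "build_timeline",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
]

# Integer codes for options/states; index 0 is the "+" (high value) one.
S1_PLUS, S1_MINUS = 0, 1
S2_PLUS, S2_MINUS = 0, 1

CHOICE_LABELS = ("S1_PLUS", "S1_MINUS")
STATE_LABELS = ("S2_PLUS", "S2_MINUS")

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the two-step task.

    ``transition_probs[c, s]`` is the probability that choosing option
    ``c`` leads to second-step state ``s``; each row must sum to one.
    ``reward_probs[s]`` is the reward probability when state ``s`` is
    pecked.  Timing fields lay out the per-trial event sequence.
    """

    transition_probs: tuple[tuple[float, float], tuple[float, float]] = (
        (0.8, 0.2),
        (0.2, 0.8),
    )
    reward_probs: tuple[float, float] = (0.8, 0.2)
    iti_s: float = 5.0
    response_window_s: float = 2.0
    reward_duration_s: float = 3.0
    trials_per_session: int = 50
    n_sessions: int = 60
    # reaction-time jitter window for synthetic timelines (seconds)
    rt_range_s: tuple[float, float] = (0.5, 2.0)
    # second-step peck latency window; kept inside the 1 s post-transition
    # analysis window so pre-peck features fall inside it
    rt2_range_s: tuple[float, float] = (0.5, 0.9)
    s2_onset_delay_s: float = 0.05

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_probs, dtype=float)
        R = np.asarray(self.reward_probs, dtype=float)
        if T.shape != (2, 2):
            raise ValueError("transition_probs must be 2x2")
        if np.any(T < 0) or np.any(T > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(T.sum(axis=1), 1.0, atol=_PROB_TOL):
            raise ValueError("each transition row must sum to 1")
        if R.shape != (2,) or np.any(R < 0) or np.any(R > 1):
            raise ValueError("reward_probs must be two probabilities in [0, 1]")
        if self.iti_s <= 0 or self.response_window_s <= 0:
            raise ValueError("iti_s and response_window_s must be positive")
        if not (0 < self.rt_range_s[0] <= self.rt_range_s[1]):
            raise ValueError("rt_range_s must be a positive, ordered interval")

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.asarray(self.transition_probs, dtype=float)

    @property
    def reward_vector(self) -> np.ndarray:
        return np.asarray(self.reward_probs, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.trials_per_session * self.n_sessions


@dataclass
class TrialRecord:
    """One behavioral trial with outcomes and event timestamps (seconds)."""

    session_idx: int
    trial_idx: int
    choice: int
    second_state: int
    rewarded: bool
    t_s1_onset: float
    t_step1_peck: float
    t_s2_onset: float
    t_step2_peck: float
    reaction_time_s: float
    valid: bool = True
    marker_side: int = 0  # left/right position of the S1+ marker; unused downstream
    artifact: bool = False  # gross-motion flag, honored by QC

    def __post_init__(self) -> None:
        times = (self.t_s1_onset, self.t_step1_peck, self.t_s2_onset, self.t_step2_peck)
        if not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing within a trial")
        if self.reaction_time_s < 0:
            raise ValueError("reaction time must be nonnegative")

    @property
    def common_transition(self) -> bool:
        """True when the sampled state is the 80%-probable one for the choice."""
        return self.choice == self.second_state


def _check_row(row: np.ndarray) -> None:
    if abs(float(row.sum()) - 1.0) > _PROB_TOL or np.any(row < 0):
        raise ValueError(f"malformed probability row {row!r}: must be nonnegative and sum to 1")


def sample_transition(choice: int, cfg: TaskConfig, rng: np.random.Generator) -> int:
    """Sample the second-step state reached from a first-step choice."""
    if choice not in (S1_PLUS, S1_MINUS):
        raise ValueError(f"invalid choice {choice}")
    row = cfg.transition_matrix[choice]
    _check_row(row)
    return S2_PLUS if rng.random() < row[S2_PLUS] else S2_MINUS


def sample_reward(second_state: int, cfg: TaskConfig, rng: np.random.Generator) -> bool:
    """Sample whether pecking ``second_state`` is rewarded."""
    if second_state not in (S2_PLUS, S2_MINUS):
        raise ValueError(f"invalid second-step state {second_state}")
    p = float(cfg.reward_vector[second_state])
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"reward probability {p} outside [0, 1]")
    return bool(rng.random() < p)


def build_timeline(
    outcomes: Sequence[tuple[int, int, bool]],
    cfg: TaskConfig,
    rng: np.random.Generator,
    slow_flags: Sequence[bool] | None = None,
) -> list[TrialRecord]:
    """Lay out (choice, second_state, rewarded) outcomes on a global clock.

    Each trial occupies: ITI -> S1 onset -> step-1 peck after a uniform
    reaction time -> S2 onset -> step-2 peck -> reward window.  Trials marked
    in ``slow_flags`` get a reaction time beyond the response window and are
    flagged invalid.
    """
    if len(outcomes) == 0:
        raise ValueError("trial count must be positive")
    if slow_flags is not None and len(slow_flags) != len(outcomes):
        raise ValueError("slow_flags length must match outcomes")

    per_session = cfg.trials_per_session
    lo, hi = cfg.rt_range_s
    lo2, hi2 = cfg.rt2_range_s
    trials: list[TrialRecord] = []
    t = 0.0
    for i, (choice, state, rewarded) in enumerate(outcomes):
        slow = bool(slow_flags[i]) if slow_flags is not None else False
        rt = cfg.response_window_s + 0.5 if slow else float(rng.uniform(lo, hi))
        rt2 = float(rng.uniform(lo2, hi2))
        t_s1 = t + cfg.iti_s
        t_p1 = t_s1 + rt
        t_s2 = t_p1 + cfg.s2_onset_delay_s
        t_p2 = t_s2 + rt2
        valid = rt <= cfg.response_window_s and rt2 <= cfg.response_window_s
        trials.append(
            TrialRecord(
                session_idx=i // per_session,
                trial_idx=i % per_session,
                choice=choice,
                second_state=state,
                rewarded=bool(rewarded),
                t_s1_onset=t_s1,
                t_step1_peck=t_p1,
                t_s2_onset=t_s2,
                t_step2_peck=t_p2,
                reaction_time_s=rt,
                valid=valid,
                marker_side=int(rng.integers(2)),
            )
        )
        t = t_p2 + cfg.reward_duration_s
    return trials


_CSV_COLUMNS = [f.name for f in dataclasses.fields(TrialRecord)]
_TIME_COLUMNS = ("t_s1_onset", "t_step1_peck", "t_s2_onset", "t_step2_peck", "reaction_time_s")


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate trials, one row per TrialRecord."""
    return pd.DataFrame([dataclasses.asdict(tr) for tr in trials], columns=_CSV_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    out: list[TrialRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            TrialRecord(
                session_idx=int(d["session_idx"]),
                trial_idx=int(d["trial_idx"]),
                choice=int(d["choice"]),
                second_state=int(d["second_state"]),
                rewarded=bool(d["rewarded"]),
                t_s1_onset=float(d["t_s1_onset"]),
                t_step1_peck=float(d["t_step1_peck"]),
                t_s2_onset=float(d["t_s2_onset"]),
                t_step2_peck=float(d["t_step2_peck"]),
                reaction_time_s=float(d["reaction_time_s"]),
                valid=bool(d["valid"]),
                marker_side=int(d.get("marker_side", 0)),
                artifact=bool(d.get("artifact", False)),
            )
        )
    return out


def write_trials_csv(trials: Sequence[TrialRecord], path) -> None:
    """Write trials as CSV; times are recorded with 6 decimal places."""
    df = trials_to_frame(trials)
    df[list(_TIME_COLUMNS)] = df[list(_TIME_COLUMNS)].round(6)
    df.to_csv(path, index=False, float_format="%.6f")


def read_trials_csv(path) -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path))
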