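"""Successor-representation agent for the two-step task.

The agent maintains a transition matrix ``T`` of discounted expected
state occupancies and a reward vector ``R`` of discounted expected
immediate rewards.  With a single step between the first-step options and
the second-step states, option values are the inner product of the
option's ``T`` row with ``R`` and state values equal ``R`` itself:

    Q_S1[c] = sum_s T[c, s] * R[s]
    Q_S2[s] = R[s]

Choices follow a softmax over the option values with inverse temperature
``beta``.  ``T`` and ``R`` are tracked trial-by-trial with an
exponentially-weighted delta rule whose target is scaled by the
discount/forgetting parameter ``gamma``, so that at ``gamma = 1`` the
running estimates converge to the true contingencies and at ``gamma = 0``
all structure is forgotten.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import S1_MINUS, S1_PLUS, TaskConfig, TrialRecord, build_timeline, sample_reward, sample_transition

__all__ = [
    "SRState",
    "AgentParams",
    "initial_state",
    "compute_values",
    "softmax_choice_prob",
    "update",
    "simulate_agent",
    "AgentHistory",
]


@dataclass
class SRState:
    """Running SR estimates: transition matrix T, reward vector R, values Q."""

    T: np.ndarray
    R: np.ndarray
    Q_S1: np.ndarray | None = None
    Q_S2: np.ndarray | None = None

    def copy(self) -> "SRState":
        return SRState(
            T=self.T.copy(),
            R=self.R.copy(),
            Q_S1=None if self.Q_S1 is None else self.Q_S1.copy(),
            Q_S2=None if self.Q_S2 is None else self.Q_S2.copy(),
        )


@dataclass(frozen=True)
class AgentParams:
    """SR agent parameters.

    gamma: discount/forgetting parameter in [0, 1].
    beta: softmax inverse temperature, >= 0.
    alpha_T, alpha_R: learning rates of the running T/R estimators in (0, 1].
    """

    gamma: float
    beta: float
    alpha_T: float = 0.1
    alpha_R: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        for a in (self.alpha_T, self.alpha_R):
            if not 0.0 < a <= 1.0:
                raise ValueError("learning rates must lie in (0, 1]")


def initial_state(gamma: float) -> SRState:
    """Uninformative initial SR state, scaled by gamma for consistency."""
    return SRState(T=np.full((2, 2), 0.5 * gamma), R=np.full(2, 0.5 * gamma))


def compute_values(state: SRState) -> SRState:
    """Populate option values Q_S1 = T @ R and state values Q_S2 = R."""
    state.Q_S1 = state.T @ state.R
    state.Q_S2 = state.R.copy()
    return state


def softmax_choice_prob(q_s1: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice probabilities over option values (max-shifted)."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    z = beta * np.asarray(q_s1, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def update(
    state: SRState,
    params: AgentParams,
    choice: int,
    observed_s2: int,
    reward: bool,
) -> SRState:
    """Delta-rule update of T and R after one trial.

    The chosen option's T row moves toward ``gamma`` at the observed state
    and toward 0 at the other; the visited state's R entry moves toward
    ``gamma * I(reward)``.  Unchosen options and unvisited states are left
    untouched.
    """
    g, aT, aR = params.gamma, params.alpha_T, params.alpha_R
    other = 1 - observed_s2
    state.T[choice, observed_s2] += aT * (g - state.T[choice, observed_s2])
    state.T[choice, other] *= 1.0 - aT
    state.R[observed_s2] += aR * (g * (1.0 if reward else 0.0) - state.R[observed_s2])
    return state


@dataclass
class AgentHistory:
    """Per-trial internal quantities of a simulated agent."""

    q_s1: np.ndarray  # trials x 2, option values before the choice
    q_s2: np.ndarray  # trials x 2, state values before the choice
    p_choice: np.ndarray  # trials x 2, softmax probabilities
    gamma: np.ndarray  # trials, scheduled gamma
    beta: np.ndarray  # trials, scheduled beta


def _expand_schedule(params_schedule, n_trials: int) -> list[AgentParams]:
    if isinstance(params_schedule, AgentParams):
        return [params_schedule] * n_trials
    schedule = list(params_schedule)
    if len(schedule) != n_trials:
        raise ValueError(
            f"parameter schedule covers {len(schedule)} trials but {n_trials} are required"
        )
    return schedule


def simulate_agent(
    params_schedule,
    cfg: TaskConfig,
    rng: np.random.Generator,
    init: SRState | None = None,
    slow_flags=None,
) -> tuple[list[TrialRecord], AgentHistory]:
    """Run the agent through the task in closed loop.

    ``params_schedule`` is either a single :class:`AgentParams` (static) or a
    per-trial sequence of length ``cfg.n_trials``.  Returns the event
    timeline and the per-trial value/probability history.
    """
    n = cfg.n_trials
    schedule = _expand_schedule(params_schedule, n)
    state = init.copy() if init is not None else initial_state(schedule[0].gamma)

    outcomes: list[tuple[int, int, bool]] = []
    q_s1 = np.empty((n, 2))
    q_s2 = np.empty((n, 2))
    p_choice = np.empty((n, 2))
    gammas = np.empty(n)
    betas = np.empty(n)
    for i, params in enumerate(schedule):
        compute_values(state)
        p = softmax_choice_prob(state.Q_S1, params.beta)
        q_s1[i] = state.Q_S1
        q_s2[i] = state.Q_S2
        p_choice[i] = p
        gammas[i] = params.gamma
        betas[i] = params.beta
        choice = S1_PLUS if rng.random() < p[S1_PLUS] else S1_MINUS
        s2 = sample_transition(choice, cfg, rng)
        rewarded = sample_reward(s2, cfg, rng)
        update(state, params, choice, s2, rewarded)
        outcomes.append((choice, s2, rewarded))

    trials = build_timeline(outcomes, cfg, rng, slow_flags=slow_flags)
    history = AgentHistory(q_s1=q_s1, q_s2=q_s2, p_choice=p_choice, gamma=gammas, beta=betas)
    return trials, history


def session_choice_rates(trials) -> np.ndarray:
    """Per-session fraction of S1+ choices, in session order."""
    import pandas as pd

    df = pd.DataFrame(
        {"session": [t.session_idx for t in trials], "plus": [t.choice == S1_PLUS for t in trials]}
    )
    return df.groupby("session")["plus"].mean().to_numpy()
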