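"""MAP fitting of the SR agent's (gamma, beta) to observed choice sequences.

The likelihood replays the agent deterministically through the observed
trial sequence: values are recomputed before each trial from the running
T/R estimates, the softmax probability of the observed choice is
accumulated, and T/R are updated with the observed transition and reward.
Weakly informative priors — Gamma(shape=1.2, scale=5.0) on beta and
Beta(1.1, 1.1) on gamma — turn the likelihood into a posterior, maximised
with bounded quasi-Newton starts jittered across restarts.

The dynamic variant partitions the sequence into contiguous windows and
fits each window independently; the agent state entering a window is
produced by replaying all earlier trials under the candidate gamma, which
avoids discontinuities at window edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .agent import AgentParams, compute_values, initial_state, simulate_agent, softmax_choice_prob, update
from .task import TaskConfig

__all__ = [
    "FitConfig",
    "WindowFit",
    "FitResult",
    "choice_negloglik",
    "fit_map",
    "fit_dynamic",
    "compare_dynamic_static",
]

GAMMA_BOUNDS = (1e-6, 1.0 - 1e-6)
BETA_BOUNDS = (1e-6, 50.0)


@dataclass(frozen=True)
class FitConfig:
    """Settings for MAP fitting."""

    n_windows: int = 1
    prior_beta_shape: float = 1.2
    prior_beta_scale: float = 5.0
    prior_gamma_a: float = 1.1
    prior_gamma_b: float = 1.1
    n_restarts: int = 5
    seed: int = 0
    alpha_T: float = 0.1
    alpha_R: float = 0.1
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        for p in (
            self.prior_beta_shape,
            self.prior_beta_scale,
            self.prior_gamma_a,
            self.prior_gamma_b,
        ):
            if p <= 0:
                raise ValueError("prior parameters must be positive")


@dataclass
class WindowFit:
    """MAP estimate for one trial window."""

    start: int
    stop: int  # half-open [start, stop)
    gamma_hat: float
    beta_hat: float
    log_posterior: float
    converged: bool


@dataclass
class FitResult:
    """Per-window MAP fits; a single window is the static model."""

    windows: list[WindowFit]

    @property
    def gamma_hat(self) -> np.ndarray:
        return np.array([w.gamma_hat for w in self.windows])

    @property
    def beta_hat(self) -> np.ndarray:
        return np.array([w.beta_hat for w in self.windows])

    @property
    def is_static(self) -> bool:
        return len(self.windows) == 1

    def to_dict(self) -> dict:
        return {
            "windows": [
                {
                    "start": w.start,
                    "stop": w.stop,
                    "gamma_hat": w.gamma_hat,
                    "beta_hat": w.beta_hat,
                    "log_posterior": w.log_posterior,
                    "converged": w.converged,
                }
                for w in self.windows
            ]
        }


def _extract(trials) -> tuple[list[int], list[int], list[float]]:
    choices = [t.choice for t in trials]
    states = [t.second_state for t in trials]
    rewards = [1.0 if t.rewarded else 0.0 for t in trials]
    return choices, states, rewards


def _replay_nll(
    choices,
    states,
    rewards,
    gamma: float,
    beta: float,
    alpha_T: float,
    alpha_R: float,
    start: int = 0,
    stop: int | None = None,
) -> float:
    """Negative log-likelihood of choices in [start, stop).

    Trials before ``start`` are replayed (updates only) to warm-start the
    agent state.  Plain-float inner loop: this is the hot path of fitting.
    """
    stop = len(choices) if stop is None else stop
    g = float(gamma)
    b = float(beta)
    aT = float(alpha_T)
    aR = float(alpha_R)
    t00 = t01 = t10 = t11 = 0.5 * g
    r0 = r1 = 0.5 * g
    nll = 0.0
    log = math.log
    exp = math.exp
    for i in range(stop):
        if i >= start:
            q0 = t00 * r0 + t01 * r1
            q1 = t10 * r0 + t11 * r1
            # log P(observed choice) via a stable log-sum-exp on 2 options
            d = b * (q1 - q0) if choices[i] == 0 else b * (q0 - q1)
            # P(chosen) = 1 / (1 + exp(d))
            if d > 35.0:
                nll += d
            else:
                nll += log(1.0 + exp(d))
        c = choices[i]
        s = states[i]
        target = g * rewards[i]
        if c == 0:
            if s == 0:
                t00 += aT * (g - t00)
                t01 *= 1.0 - aT
            else:
                t01 += aT * (g - t01)
                t00 *= 1.0 - aT
        else:
            if s == 0:
                t10 += aT * (g - t10)
                t11 *= 1.0 - aT
            else:
                t11 += aT * (g - t11)
                t10 *= 1.0 - aT
        if s == 0:
            r0 += aR * (target - r0)
        else:
            r1 += aR * (target - r1)
    return nll


def choice_negloglik(
    trials,
    gamma: float,
    beta: float,
    alpha_T: float = 0.1,
    alpha_R: float = 0.1,
) -> float:
    """Negative log-likelihood of a full trial sequence under (gamma, beta)."""
    if len(trials) == 0:
        raise ValueError("trial sequence is empty")
    if not (0.0 <= gamma <= 1.0) or beta < 0:
        raise ValueError("parameters out of bounds")
    choices, states, rewards = _extract(trials)
    return _replay_nll(choices, states, rewards, gamma, beta, alpha_T, alpha_R)


def _neg_log_posterior(
    params: np.ndarray,
    choices,
    states,
    rewards,
    cfg: FitConfig,
    start: int,
    stop: int,
) -> float:
    gamma, beta = float(params[0]), float(params[1])
    nll = _replay_nll(choices, states, rewards, gamma, beta, cfg.alpha_T, cfg.alpha_R, start, stop)
    lp = stats.gamma.logpdf(beta, a=cfg.prior_beta_shape, scale=cfg.prior_beta_scale)
    lp += stats.beta.logpdf(gamma, cfg.prior_gamma_a, cfg.prior_gamma_b)
    if not np.isfinite(lp):
        return 1e12
    return nll - lp


def _fit_window(choices, states, rewards, cfg: FitConfig, start: int, stop: int, rng) -> WindowFit:
    if stop <= start:
        raise ValueError("empty trial window")
    if stop - start < 20:
        import warnings

        warnings.warn(f"window [{start}, {stop}) has fewer than 20 trials", stacklevel=2)
    best = None
    converged = False
    starts = [(0.5, 3.0)]
    for _ in range(max(0, cfg.n_restarts - 1)):
        starts.append(
            (
                float(rng.uniform(0.05, 0.95)),
                float(stats.gamma.rvs(cfg.prior_beta_shape, scale=cfg.prior_beta_scale, random_state=rng)),
            )
        )
    for x0 in starts:
        res = optimize.minimize(
            _neg_log_posterior,
            x0=np.clip(x0, [GAMMA_BOUNDS[0], BETA_BOUNDS[0]], [GAMMA_BOUNDS[1], BETA_BOUNDS[1]]),
            args=(choices, states, rewards, cfg, start, stop),
            method="L-BFGS-B",
            bounds=[GAMMA_BOUNDS, BETA_BOUNDS],
            options={"ftol": cfg.tol, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    return WindowFit(
        start=start,
        stop=stop,
        gamma_hat=float(best.x[0]),
        beta_hat=float(best.x[1]),
        log_posterior=-float(best.fun),
        converged=converged,
    )


def fit_map(trials, cfg: FitConfig | None = None) -> FitResult:
    """Static MAP fit of (gamma, beta) over the whole trial sequence."""
    cfg = cfg or FitConfig()
    if len(trials) == 0:
        raise ValueError("trial sequence is empty")
    choices, states, rewards = _extract(trials)
    rng = np.random.default_rng(cfg.seed)
    return FitResult([_fit_window(choices, states, rewards, cfg, 0, len(trials), rng)])


def fit_dynamic(trials, cfg: FitConfig) -> FitResult:
    """Windowed MAP fit: independent (gamma, beta) per contiguous window."""
    if len(trials) == 0:
        raise ValueError("trial sequence is empty")
    n = len(trials)
    if cfg.n_windows > n:
        raise ValueError("more windows than trials")
    if cfg.n_windows == 1:
        return fit_map(trials, cfg)
    choices, states, rewards = _extract(trials)
    edges = np.linspace(0, n, cfg.n_windows + 1).round().astype(int)
    rng = np.random.default_rng(cfg.seed)
    windows = [
        _fit_window(choices, states, rewards, cfg, int(a), int(b), rng)
        for a, b in zip(edges[:-1], edges[1:])
    ]
    return FitResult(windows)


def _schedule_from_fit(fit: FitResult, n_trials: int, cfg: FitConfig) -> list[AgentParams]:
    schedule: list[AgentParams] = []
    for w in fit.windows:
        schedule.extend(
            [AgentParams(w.gamma_hat, w.beta_hat, cfg.alpha_T, cfg.alpha_R)] * (w.stop - w.start)
        )
    if len(schedule) != n_trials:
        raise ValueError("fit windows do not cover the trial sequence")
    return schedule


def replay_values(trials, fit: FitResult, cfg: FitConfig | None = None) -> "AgentHistory":
    """Replay observed trials under fitted parameters; return value history.

    The agent state evolves continuously across windows under each
    window's fitted gamma, mirroring the warm-start convention used when
    fitting.  Q values are recorded before each trial's update.
    """
    from .agent import AgentHistory

    cfg = cfg or FitConfig()
    n = len(trials)
    schedule = _schedule_from_fit(fit, n, cfg) if not fit.is_static else [
        AgentParams(fit.windows[0].gamma_hat, fit.windows[0].beta_hat, cfg.alpha_T, cfg.alpha_R)
    ] * n
    state = initial_state(schedule[0].gamma)
    q_s1 = np.empty((n, 2))
    q_s2 = np.empty((n, 2))
    p_choice = np.empty((n, 2))
    for i, (tr, params) in enumerate(zip(trials, schedule)):
        compute_values(state)
        q_s1[i] = state.Q_S1
        q_s2[i] = state.Q_S2
        p_choice[i] = softmax_choice_prob(state.Q_S1, params.beta)
        update(state, params, tr.choice, tr.second_state, tr.rewarded)
    return AgentHistory(
        q_s1=q_s1,
        q_s2=q_s2,
        p_choice=p_choice,
        gamma=np.array([p.gamma for p in schedule]),
        beta=np.array([p.beta for p in schedule]),
    )


def compare_dynamic_static(
    task_cfg: TaskConfig,
    fit_dyn: FitResult,
    fit_stat: FitResult,
    n_rounds: int = 50,
    rng: np.random.Generator | None = None,
    fit_cfg: FitConfig | None = None,
) -> dict:
    """Simulate fitted agents and return session-wise S1+ choice-rate curves.

    Each fitted parameterization is run ``n_rounds`` times through the task;
    the returned dict holds per-round curves plus mean and SD per session,
    for overlay against an empirical learning curve.
    """
    from .agent import session_choice_rates

    rng = rng if rng is not None else np.random.default_rng(0)
    fit_cfg = fit_cfg or FitConfig()
    n_trials = task_cfg.n_trials
    out: dict = {}
    for name, fit in (("dynamic", fit_dyn), ("static", fit_stat)):
        if fit.is_static:
            schedule: list[AgentParams] | AgentParams = AgentParams(
                fit.windows[0].gamma_hat, fit.windows[0].beta_hat, fit_cfg.alpha_T, fit_cfg.alpha_R
            )
        else:
            schedule = _schedule_from_fit(fit, n_trials, fit_cfg)
        curves = np.empty((n_rounds, task_cfg.n_sessions))
        for r in range(n_rounds):
            trials, _ = simulate_agent(schedule, task_cfg, rng)
            curves[r] = session_choice_rates(trials)
        out[name] = {"curves": curves, "mean": curves.mean(axis=0), "sd": curves.std(axis=0)}
    return out
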