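import warnings

import numpy as np
import pytest

from twostep_hippo import agent, preprocess, spectral, synth, task

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cfg():
    return task.TaskConfig()


@pytest.fixture(scope="session")
def small_cfg():
    return task.TaskConfig(trials_per_session=10, n_sessions=3)


@pytest.fixture(scope="session")
def static_trials():
    """1,000 trials from a converged-ish static agent (shared, read-only)."""
    cfg = task.TaskConfig(trials_per_session=50, n_sessions=20)
    trials, history = agent.simulate_agent(
        agent.AgentParams(gamma=0.9, beta=5.0), cfg, np.random.default_rng(42)
    )
    return cfg, trials, history


@pytest.fixture(scope="session")
def lfp_chain():
    """Small synthetic chain: trials -> recording -> clean TF power.

    8 channels and 30 trials keep the wavelet transform cheap; the planted
    effect sizes are the package defaults.
    """
    cfg = task.TaskConfig(trials_per_session=10, n_sessions=3)
    n = cfg.n_trials
    sched = [
        agent.AgentParams(g, b)
        for g, b in zip(np.linspace(0.3, 0.98, n), np.linspace(0.5, 8.0, n))
    ]
    trials, history = agent.simulate_agent(sched, cfg, np.random.default_rng(7))
    gen_cfg = synth.LFPGenConfig(n_channels=8, learned_boundary=n // 2)
    rec, gt = synth.generate_recording(trials, history, gen_cfg, rng=np.random.default_rng(8))
    clean = preprocess.preprocess_recording(rec)
    kept, _ = preprocess.qc_filter(trials)
    epochs = preprocess.epoch(clean, kept)
    tf = spectral.morlet_power(epochs)
    tf = spectral.mask_peck_artifacts(tf)
    tfn = spectral.baseline_normalize(tf, spectral.slice_window(tf, (-2.5, -2.0)))
    return {
        "cfg": cfg,
        "gen_cfg": gen_cfg,
        "trials": trials,
        "history": history,
        "rec": rec,
        "gt": gt,
        "clean": clean,
        "epochs": epochs,
        "tf": tfn,
    }
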