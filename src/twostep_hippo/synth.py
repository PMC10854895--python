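"""Synthetic 16-channel LFP with known ground-truth structure.

The generator lays realistic nuisance structure (1/f background, 50 Hz
line interference with per-channel phase, a broadband common-mode
component, biphasic peck artifacts) under planted task effects:

* high-band oscillatory bursts (20 and 45 Hz carriers, 1 s Hann envelope)
  in the pre-peck windows of both steps, with amplitude linear in the
  model-based value of the current option/state (``a0 + a1 * Q``);
* a 6 Hz component with a trial-specific random spatial amplitude pattern
  across channels, repeated identically in the step-1 and step-2 windows
  on common-transition trials after learning and drawn independently
  otherwise — the substrate of the low-band similarity effect.

Every planted quantity is returned in :class:`GroundTruth`, so each
downstream analysis stage can be tested against what was injected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .agent import AgentHistory, session_choice_rates
from .task import TrialRecord

__all__ = [
    "LFPRecording",
    "GroundTruth",
    "LFPGenConfig",
    "generate_recording",
    "write_recording",
    "read_recording",
    "pink_noise",
]


@dataclass
class LFPRecording:
    """Continuous multichannel recording with event markers."""

    signal: np.ndarray  # channels x samples, microvolts (float32)
    fs: float
    channel_ids: list[str]
    events: list[tuple[float, str]]  # (time_s, label), sorted by time

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal))
        if self.events != sorted(self.events, key=lambda e: e[0]):
            raise ValueError("events must be sorted by time")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GroundTruth:
    """Planted per-trial effect parameters, reproducible from the seed."""

    amp_s1: np.ndarray  # high-band burst amplitude in the step-1 pre-peck window
    amp_s2: np.ndarray  # high-band burst amplitude in the step-2 pre-peck window
    q_choice: np.ndarray  # Q of the chosen option per trial
    q_state: np.ndarray  # Q of the visited state per trial
    shared_low_band: np.ndarray  # bool per trial: S1/S2 share the 6 Hz pattern
    artifact_times: np.ndarray  # all peck times carrying a transient
    learned_boundary: int  # first trial index counted as "after learning"
    line_amp: float
    common_mode_amp: float
    seed: int | None


@dataclass(frozen=True)
class LFPGenConfig:
    """Generator amplitudes (microvolts) and effect layout."""

    fs: float = 2000.0
    n_channels: int = 16
    background_amp: float = 20.0
    common_mode_amp: float = 25.0
    line_amp: float = 15.0
    line_freq: float = 50.0
    burst_carriers: tuple[float, float] = (20.0, 45.0)
    # each pre-peck window carries a train of short bursts at random times:
    # window-mean power tracks the value coupling while the burst timing is
    # incoherent across trials (no systematic within-window envelope)
    burst_window_s: float = 1.0
    n_bursts: int = 5
    burst_len_range: tuple[float, float] = (0.1, 0.25)
    a0: float = 4.0
    a1: float = 18.0
    low_freq: float = 6.0
    low_amp: float = 20.0
    # 6 Hz envelope spans, relative to the step-1 peck
    low_s1_span: tuple[float, float] = (-0.7, -0.1)
    low_s2_span: tuple[float, float] = (0.2, 0.8)
    artifact_amp: float = 200.0
    artifact_dur_s: float = 0.02
    # spatial heterogeneity of burst gains across channels (lognormal sigma);
    # nonzero so planted effects survive common-average re-referencing
    burst_gain_sigma: float = 0.6
    pattern_sigma: float = 0.8
    tail_s: float = 4.0
    # None: boundary = first trial of the first session with >90% S1+ choices
    learned_boundary: int | None = None
    shared_low_band_enabled: bool = True

    def channel_labels(self) -> list[str]:
        # 4x4 grid labels row-major: r0c0 ... r3c3
        side = int(np.sqrt(self.n_channels))
        if side * side == self.n_channels:
            return [f"ch{r}{c}" for r in range(side) for c in range(side)]
        return [f"ch{i:02d}" for i in range(self.n_channels)]


def pink_noise(n_samples: int, rng: np.random.Generator, n_channels: int = 1) -> np.ndarray:
    """1/f-power noise, unit standard deviation per channel."""
    from scipy import fft as sfft

    nfft = sfft.next_fast_len(n_samples)  # keep the FFT size 5-smooth
    white = rng.standard_normal((n_channels, nfft))
    spec = sfft.rfft(white, axis=1)
    f = sfft.rfftfreq(nfft)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = sfft.irfft(spec * scale, n=nfft, axis=1)[:, :n_samples]
    x /= x.std(axis=1, keepdims=True)
    return x


def _hann(n: int) -> np.ndarray:
    return np.hanning(n)


def _add_windowed(
    signal: np.ndarray, fs: float, t0: float, t1: float, wave_fn, gains: np.ndarray
) -> None:
    """Add gains[:, None] * wave_fn(t) * hann over [t0, t1) in place."""
    i0 = max(0, int(round(t0 * fs)))
    i1 = min(signal.shape[1], int(round(t1 * fs)))
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    wave = wave_fn(t) * _hann(i1 - i0)
    signal[:, i0:i1] += gains[:, None] * wave[None, :]


def _default_learned_boundary(trials: Sequence[TrialRecord]) -> int:
    rates = session_choice_rates(trials)
    per_session = max(t.trial_idx for t in trials) + 1
    above = np.nonzero(rates > 0.9)[0]
    if len(above) == 0:
        return len(trials)  # never learned: no shared-pattern trials
    return int(above[0]) * per_session


def generate_recording(
    trials: Sequence[TrialRecord],
    values: AgentHistory,
    gen_cfg: LFPGenConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[LFPRecording, GroundTruth]:
    """Synthesize a continuous recording for a simulated behavioral run."""
    cfg = gen_cfg or LFPGenConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    n_trials = len(trials)
    if n_trials == 0:
        raise ValueError("no trials")
    if values.q_s1.shape[0] != n_trials:
        raise ValueError(
            f"values cover {values.q_s1.shape[0]} trials but {n_trials} trials were given"
        )

    fs = cfg.fs
    total_s = trials[-1].t_step2_peck + cfg.tail_s
    n = int(round(total_s * fs))
    nch = cfg.n_channels

    # nuisance structure
    signal = cfg.background_amp * pink_noise(n, rng, nch)
    signal += cfg.common_mode_amp * pink_noise(n, rng, 1)
    tvec = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, nch)
    signal += cfg.line_amp * np.sin(2 * np.pi * cfg.line_freq * tvec[None, :] + phases[:, None])

    boundary = (
        cfg.learned_boundary
        if cfg.learned_boundary is not None
        else _default_learned_boundary(trials)
    )

    q_choice = values.q_s1[np.arange(n_trials), [t.choice for t in trials]]
    q_state = values.q_s2[np.arange(n_trials), [t.second_state for t in trials]]
    amp_s1 = cfg.a0 + cfg.a1 * q_choice
    amp_s2 = cfg.a0 + cfg.a1 * q_state
    shared = np.zeros(n_trials, dtype=bool)
    artifact_times = []

    c1, c2 = cfg.burst_carriers
    norm = 1.0 / np.sqrt(2.0)

    def burst_wave(t):
        return norm * (np.sin(2 * np.pi * c1 * t) + np.sin(2 * np.pi * c2 * t))

    def burst_gains() -> np.ndarray:
        # heterogeneous across channels so the burst is not a pure common
        # mode (which CAR removes); redrawn per window occurrence so no
        # stable spatial pattern links the S1 and S2 windows in the high band
        g = np.exp(rng.normal(0.0, cfg.burst_gain_sigma, nch))
        return g * (nch / g.sum())

    art_gains_base = rng.uniform(0.5, 1.5, nch)

    def add_burst_train(peck: float, amp: float) -> None:
        for _ in range(cfg.n_bursts):
            length = float(rng.uniform(*cfg.burst_len_range))
            onset = peck - cfg.burst_window_s + float(
                rng.uniform(0.0, cfg.burst_window_s - length)
            )
            _add_windowed(
                signal, fs, onset, onset + length, burst_wave,
                amp * float(rng.uniform(0.8, 1.2)) * burst_gains(),
            )

    for i, tr in enumerate(trials):
        # (i) value-coupled high-band burst trains before each peck
        add_burst_train(tr.t_step1_peck, amp_s1[i])
        add_burst_train(tr.t_step2_peck, amp_s2[i])

        # (ii) 6 Hz component with spatial pattern, shared on learned common trials
        pat1 = np.exp(rng.normal(0.0, cfg.pattern_sigma, nch))
        pat1 *= nch / pat1.sum()
        is_shared = bool(
            cfg.shared_low_band_enabled and tr.common_transition and i >= boundary
        )
        if is_shared:
            pat2 = pat1
        else:
            pat2 = np.exp(rng.normal(0.0, cfg.pattern_sigma, nch))
            pat2 *= nch / pat2.sum()
        shared[i] = is_shared
        phase = rng.uniform(0, 2 * np.pi)

        def low_wave(t, ph=phase):
            return np.sin(2 * np.pi * cfg.low_freq * t + ph)

        p1 = tr.t_step1_peck
        _add_windowed(
            signal, fs, p1 + cfg.low_s1_span[0], p1 + cfg.low_s1_span[1], low_wave, cfg.low_amp * pat1
        )
        _add_windowed(
            signal, fs, p1 + cfg.low_s2_span[0], p1 + cfg.low_s2_span[1], low_wave, cfg.low_amp * pat2
        )

        # (iii) biphasic peck transients (one 50 Hz cycle, 20 ms)
        for tp in (tr.t_step1_peck, tr.t_step2_peck):
            artifact_times.append(tp)
            _add_windowed(
                signal,
                fs,
                tp - cfg.artifact_dur_s / 2,
                tp + cfg.artifact_dur_s / 2,
                lambda t: np.sin(2 * np.pi * (1.0 / cfg.artifact_dur_s) * (t - t[0])),
                cfg.artifact_amp * art_gains_base,
            )

    events: list[tuple[float, str]] = []
    for tr in trials:
        events.append((tr.t_s1_onset, "s1_onset"))
        events.append((tr.t_step1_peck, "step1_peck"))
        events.append((tr.t_s2_onset, "s2_onset"))
        events.append((tr.t_step2_peck, "step2_peck"))
    events.sort(key=lambda e: e[0])

    rec = LFPRecording(
        signal=signal.astype(np.float32),
        fs=fs,
        channel_ids=cfg.channel_labels(),
        events=events,
    )
    gt = GroundTruth(
        amp_s1=amp_s1,
        amp_s2=amp_s2,
        q_choice=q_choice,
        q_state=q_state,
        shared_low_band=shared,
        artifact_times=np.array(artifact_times),
        learned_boundary=boundary,
        line_amp=cfg.line_amp,
        common_mode_amp=cfg.common_mode_amp,
        seed=seed,
    )
    return rec, gt


def write_recording(rec: LFPRecording, path) -> None:
    """Write a recording to HDF5 (/signal, /fs, /channel_ids, /events)."""
    opts = {"track_times": False}  # keep files byte-identical across runs
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal, **opts)
        f.create_dataset("fs", data=float(rec.fs), **opts)
        f.create_dataset(
            "channel_ids", data=np.array(rec.channel_ids, dtype=h5py.string_dtype()), **opts
        )
        grp = f.create_group("events")
        grp.create_dataset("time", data=np.array([e[0] for e in rec.events], dtype=float), **opts)
        grp.create_dataset(
            "label", data=np.array([e[1] for e in rec.events], dtype=h5py.string_dtype()), **opts
        )


def read_recording(path) -> LFPRecording:
    """Read a recording written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        for key in ("signal", "fs", "channel_ids", "events"):
            if key not in f:
                raise ValueError(f"malformed recording file: missing /{key}")
        signal = f["signal"][()]
        fs = float(f["fs"][()])
        channel_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_ids"][()]]
        times = f["events/time"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["events/label"][()]]
    events = list(zip(times.tolist(), labels))
    return LFPRecording(signal=signal, fs=fs, channel_ids=channel_ids, events=events)
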