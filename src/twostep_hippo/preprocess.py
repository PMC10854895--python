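"""LFP preprocessing: downsample, re-reference, de-line, QC and epoch.

The cascade mirrors standard multichannel electrophysiology cleaning:

1. median downsampling from the acquisition rate to 1 kHz (each output
   sample is the median of its non-overlapping input block — robust to
   the brief, large peck transients);
2. adaptive common average reference (CAR): the cross-channel average is
   built with per-channel weights that track each channel's correlation
   with the plain common average over a sliding window, then subtracted
   from every channel;
3. adaptive 50 Hz notch via LMS noise cancellation against a sine/cosine
   reference pair (block-updated weights), which removes the line tone
   while leaving neighboring frequencies intact.

Trials with reaction times under 0.5 s or flagged motion artifacts are
excluded, and the survivors are epoched relative to the step-1 peck:
baseline [-2.5, -2.0] s, choice [-1, 0] s, S2 [0, 1] s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synth import LFPRecording
from .task import TrialRecord

__all__ = [
    "EpochSet",
    "median_downsample",
    "adaptive_car",
    "lms_notch_50hz",
    "qc_filter",
    "epoch",
    "WINDOWS",
]

# analysis windows in seconds relative to the step-1 peck; half-open [t0, t1)
WINDOWS: dict[str, tuple[float, float]] = {
    "baseline": (-2.5, -2.0),
    "choice": (-1.0, 0.0),
    "s2": (0.0, 1.0),
    # one concatenated span for time-frequency work; analysis windows are
    # sliced from its transform to avoid wavelet edge effects at seams
    "full": (-2.5, 1.0),
}

RT_EXCLUSION_S = 0.5  # strict: rt < 0.5 s is excluded, rt == 0.5 s retained


@dataclass
class EpochSet:
    """Event-aligned epochs for one analysis window set.

    ``data[name]`` is trials x channels x samples at ``fs``; all epochs of a
    window have equal length.  ``trials`` holds the retained TrialRecords in
    row order; ``excluded`` maps trial keys to exclusion reasons.
    """

    data: dict[str, np.ndarray]
    fs: float
    windows: dict[str, tuple[float, float]]
    trials: list[TrialRecord]
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def median_downsample(rec: LFPRecording, target_fs: float = 1000.0) -> LFPRecording:
    """Reduce the sampling rate by block medians; events are unchanged."""
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(f"fs {rec.fs} is not an integer multiple of target {target_fs}")
    r = int(round(ratio))
    if r == 1:
        return LFPRecording(rec.signal.copy(), target_fs, list(rec.channel_ids), list(rec.events))
    n_keep = (rec.n_samples // r) * r
    blocks = rec.signal[:, :n_keep].reshape(rec.n_channels, -1, r)
    out = np.median(blocks, axis=2).astype(rec.signal.dtype)
    return LFPRecording(out, target_fs, list(rec.channel_ids), list(rec.events))


def _sliding_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average along the last axis (edges: shrinking window)."""
    cs = np.cumsum(np.pad(x, [(0, 0)] * (x.ndim - 1) + [(1, 0)], mode="constant"), axis=-1)
    n = x.shape[-1]
    idx = np.arange(n)
    lo = np.clip(idx - w // 2, 0, n)
    hi = np.clip(idx + w // 2 + 1, 0, n)
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def adaptive_car(rec: LFPRecording, window_s: float = 1.0, adaptive: bool = True) -> LFPRecording:
    """Subtract a correlation-weighted common average reference.

    Per-channel weights are the sliding-window correlation of each channel
    with the plain common average, clipped at zero and renormalized to mean
    one; the weighted cross-channel average is then subtracted from every
    channel.  With ``adaptive=False`` this reduces to the plain CAR.
    """
    x = rec.signal.astype(np.float64)
    nch = rec.n_channels
    if nch < 2:
        warnings.warn("adaptive CAR requires >= 2 channels; returning input unchanged")
        return LFPRecording(rec.signal.copy(), rec.fs, list(rec.channel_ids), list(rec.events))
    ca = x.mean(axis=0, keepdims=True)
    if not adaptive:
        out = x - ca
        return LFPRecording(
            out.astype(rec.signal.dtype), rec.fs, list(rec.channel_ids), list(rec.events)
        )
    w = max(3, int(round(window_s * rec.fs)))
    mx = _sliding_mean(x, w)
    mc = _sliding_mean(ca, w)
    cov = _sliding_mean(x * ca, w) - mx * mc
    vx = _sliding_mean(x * x, w) - mx * mx
    vc = _sliding_mean(ca * ca, w) - mc * mc
    denom = np.sqrt(np.clip(vx, 0, None) * np.clip(vc, 0, None))
    corr = np.where(denom > 1e-12, cov / np.where(denom > 1e-12, denom, 1.0), 0.0)
    weights = np.clip(corr, 0.0, None)
    wsum = weights.mean(axis=0, keepdims=True)
    weights = np.where(wsum > 1e-12, weights / np.where(wsum > 1e-12, wsum, 1.0), 1.0)
    ref = (weights * x).mean(axis=0, keepdims=True)
    out = x - ref
    return LFPRecording(
        out.astype(rec.signal.dtype), rec.fs, list(rec.channel_ids), list(rec.events)
    )


def lms_notch_50hz(
    rec: LFPRecording,
    mu: float = 0.1,
    freq: float = 50.0,
    block_s: float = 0.05,
) -> LFPRecording:
    """Adaptive 50 Hz cancellation with a sine/cosine reference pair.

    Classic two-weight LMS noise canceller; the weight update is applied
    per short block (block LMS) so the filter stays adaptive to slow
    amplitude/phase drift of the interference while running vectorised.
    The reference pair has unit power, so stability requires
    ``0 < mu < 2``.
    """
    if rec.fs <= 2 * freq:
        raise ValueError("sampling rate must exceed twice the line frequency")
    if not 0.0 < mu < 2.0:
        raise ValueError("mu outside the stable range (0, 2) for a unit-power reference")
    n = rec.n_samples
    t = np.arange(n) / rec.fs
    ref_s = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t)
    ref_c = np.sqrt(2.0) * np.cos(2 * np.pi * freq * t)
    block = max(1, int(round(block_s * rec.fs)))
    x = rec.signal.astype(np.float64)
    out = np.empty_like(x)
    nch = rec.n_channels
    ws = np.zeros(nch)
    wc = np.zeros(nch)
    for i0 in range(0, n, block):
        i1 = min(n, i0 + block)
        rs = ref_s[i0:i1]
        rc = ref_c[i0:i1]
        est = ws[:, None] * rs[None, :] + wc[:, None] * rc[None, :]
        err = x[:, i0:i1] - est
        out[:, i0:i1] = err
        L = i1 - i0
        ws += (mu / L) * err @ rs
        wc += (mu / L) * err @ rc
    return LFPRecording(
        out.astype(rec.signal.dtype), rec.fs, list(rec.channel_ids), list(rec.events)
    )


def qc_filter(
    trials: Sequence[TrialRecord],
) -> tuple[list[TrialRecord], list[tuple[int, str]]]:
    """Drop trials with fast reactions (< 0.5 s) or motion-artifact flags.

    Returns retained trials and an exclusion log of (global trial index,
    reason).
    """
    kept: list[TrialRecord] = []
    log: list[tuple[int, str]] = []
    for i, tr in enumerate(trials):
        if tr.reaction_time_s < RT_EXCLUSION_S:
            log.append((i, f"reaction_time {tr.reaction_time_s:.3f}s < {RT_EXCLUSION_S}s"))
        elif tr.artifact:
            log.append((i, "motion artifact flag"))
        elif not tr.valid:
            log.append((i, "invalid trial (missed response window)"))
        else:
            kept.append(tr)
    return kept, log


def flag_motion_artifacts(
    rec: LFPRecording,
    trials: Sequence[TrialRecord],
    factor: float = 5.0,
    window: tuple[float, float] = (-1.0, 1.0),
) -> list[TrialRecord]:
    """Flag gross-motion trials by broadband epoch RMS.

    A trial is flagged when the RMS of its peck-aligned window exceeds
    ``factor`` times the session median RMS.  Returns new TrialRecords with
    the ``artifact`` flag set; trials already flagged stay flagged.
    """
    import dataclasses

    rms = np.full(len(trials), np.nan)
    for i, tr in enumerate(trials):
        i0 = int(round((tr.t_step1_peck + window[0]) * rec.fs))
        i1 = int(round((tr.t_step1_peck + window[1]) * rec.fs))
        if 0 <= i0 < i1 <= rec.n_samples:
            rms[i] = np.sqrt(np.mean(rec.signal[:, i0:i1].astype(np.float64) ** 2))
    sessions = np.array([tr.session_idx for tr in trials])
    out: list[TrialRecord] = []
    for i, tr in enumerate(trials):
        med = np.nanmedian(rms[sessions == tr.session_idx])
        flagged = bool(np.isfinite(rms[i]) and np.isfinite(med) and rms[i] > factor * med)
        out.append(dataclasses.replace(tr, artifact=tr.artifact or flagged))
    return out


def epoch(
    rec: LFPRecording,
    trials: Sequence[TrialRecord],
    windows: dict[str, tuple[float, float]] | None = None,
) -> EpochSet:
    """Extract event-aligned epochs (aligned on the step-1 peck).

    Sample windows are half-open ``[start, end)``.  Trials whose windows
    fall outside the recording are excluded with a logged reason.
    """
    windows = dict(windows or WINDOWS)
    fs = rec.fs
    lengths = {
        name: int(round((t1 - t0) * fs)) for name, (t0, t1) in windows.items()
    }
    kept: list[TrialRecord] = []
    excluded: list[tuple[int, str]] = []
    rows: dict[str, list[np.ndarray]] = {name: [] for name in windows}
    for i, tr in enumerate(trials):
        align = tr.t_step1_peck
        cuts = {}
        ok = True
        for name, (t0, t1) in windows.items():
            i0 = int(round((align + t0) * fs))
            i1 = i0 + lengths[name]
            if i0 < 0 or i1 > rec.n_samples:
                excluded.append((i, f"window '{name}' out of recording bounds"))
                ok = False
                break
            cuts[name] = rec.signal[:, i0:i1]
        if ok:
            kept.append(tr)
            for name, cut in cuts.items():
                rows[name].append(cut)
    data = {
        name: (np.stack(lst) if lst else np.empty((0, rec.n_channels, lengths[name])))
        for name, lst in rows.items()
    }
    return EpochSet(data=data, fs=fs, windows=windows, trials=kept, excluded=excluded)


def preprocess_recording(
    rec: LFPRecording,
    target_fs: float = 1000.0,
    car: bool = True,
    notch: bool = True,
    mu: float = 0.1,
) -> LFPRecording:
    """Full cascade: median downsample -> adaptive CAR -> LMS notch."""
    out = median_downsample(rec, target_fs)
    if car:
        out = adaptive_car(out)
    if notch:
        out = lms_notch_50hz(out, mu=mu)
    return out
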