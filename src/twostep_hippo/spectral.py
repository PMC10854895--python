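"""Morlet time-frequency power, baseline normalization and band averaging.

Power is estimated with Morlet wavelets on 50 logarithmically spaced
frequencies between 1 and 100 Hz, on a single concatenated epoch spanning
[-2.5, +1] s around the step-1 peck (reflection-padded against wavelet
edge effects); analysis windows are sliced from that epoch afterwards.
Samples within +/-50 ms of a peck can be masked to missing and are then
excluded from every downstream average.  Normalization divides each
trial's power, per frequency, by that trial's mean baseline power pooled
over electrodes and the [-2.5, -2.0] s baseline samples, which removes
per-trial global drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .preprocess import EpochSet
from .task import TrialRecord

__all__ = [
    "BANDS",
    "LOW_GROUP",
    "HIGH_GROUP",
    "default_freqs",
    "EpochedTF",
    "BandPower",
    "morlet_power",
    "mask_peck_artifacts",
    "baseline_normalize",
    "slice_window",
    "band_average",
    "power_dynamics",
    "moving_average",
]

# canonical band table (Hz); each band is [lo, hi), the top band includes 100 Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 60.0),
    "high_gamma": (60.0, 100.0),
}
LOW_GROUP: tuple[str, ...] = ("delta", "theta", "alpha")  # 1-12 Hz
HIGH_GROUP: tuple[str, ...] = ("beta", "low_gamma", "high_gamma")  # 12-100 Hz
BAND_GROUPS: dict[str, tuple[str, ...]] = {
    "low": LOW_GROUP,
    "high": HIGH_GROUP,
    "all": tuple(BANDS),
}


def default_freqs(n: int = 50, fmin: float = 1.0, fmax: float = 100.0) -> np.ndarray:
    """Logarithmically spaced analysis frequencies."""
    return np.logspace(np.log10(fmin), np.log10(fmax), n)


def band_freq_mask(freqs: np.ndarray, band: str) -> np.ndarray:
    lo, hi = BANDS[band]
    top = max(b[1] for b in BANDS.values())
    if hi >= top:
        return (freqs >= lo) & (freqs <= hi + 1e-9)
    return (freqs >= lo) & (freqs < hi)


@dataclass
class EpochedTF:
    """Time-frequency power tensor: trials x electrodes x frequencies x time."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # seconds relative to the step-1 peck
    trials: list[TrialRecord]
    normalized: bool = False
    edge_padded: bool = False

    @property
    def fs_tf(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.times)))


@dataclass
class BandPower:
    """Mean normalized power per trial x electrode x band."""

    values: np.ndarray  # trials x electrodes x bands (NaN where fully masked)
    bands: tuple[str, ...]
    trials: list[TrialRecord]
    window: tuple[float, float]

    def group(self, name: str) -> np.ndarray:
        """trials x electrodes mean over a band group ('low'/'high'/'all')."""
        idx = [self.bands.index(b) for b in BAND_GROUPS[name]]
        return np.nanmean(self.values[:, :, idx], axis=2)

    def group_features(self, name: str) -> np.ndarray:
        """trials x (electrodes * group bands) feature matrix for decoding."""
        idx = [self.bands.index(b) for b in BAND_GROUPS[name]]
        sub = self.values[:, :, idx]
        return sub.reshape(sub.shape[0], -1)


def _reflect_pad(x: np.ndarray, pad: int) -> np.ndarray:
    """Reflection-pad the last axis, repeating as needed when pad >= length."""
    while pad > 0:
        step = min(pad, x.shape[-1] - 1)
        x = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(step, step)], mode="reflect")
        pad -= step
    return x


def morlet_power(
    epochs: EpochSet,
    n_cycles: float = 7.0,
    window: str = "full",
    freqs: np.ndarray | None = None,
    decim: int = 10,
    pad_s: float = 2.0,
) -> EpochedTF:
    """Morlet wavelet power of an epoch window, reflection-padded at edges.

    ``decim`` subsamples the power time axis (10 -> 100 Hz resolution at a
    1 kHz input), which is ample for 100 ms feature epochs downstream.
    """
    from mne.time_frequency import tfr_array_morlet

    if window not in epochs.data:
        raise ValueError(f"EpochSet has no '{window}' window")
    x = epochs.data[window].astype(np.float64)
    if x.shape[0] == 0:
        raise ValueError("no epochs to transform")
    freqs = default_freqs() if freqs is None else np.asarray(freqs, float)
    fs = epochs.fs
    n_time = x.shape[2]
    # longest wavelet: Gaussian envelope truncated at 5 SD each side
    sigma_t = n_cycles / (2.0 * np.pi * freqs.min())
    support = int(np.ceil(10.0 * sigma_t * fs)) + 1
    pad = max(int(round(pad_s * fs)), (support - n_time) // 2 + 1)
    pad = int(np.ceil(pad / decim)) * decim  # keep decimated axes aligned
    padded = n_time < support  # epochs shorter than the longest wavelet are flagged
    n_out = n_time // decim
    off = pad // decim
    chunks = []
    batch = max(1, int(2e8 // (x.shape[1] * len(freqs) * (n_time + 2 * pad))))
    for i0 in range(0, x.shape[0], batch):
        xp = _reflect_pad(x[i0 : i0 + batch], pad)
        p = tfr_array_morlet(
            xp,
            sfreq=fs,
            freqs=freqs,
            n_cycles=n_cycles,
            output="power",
            decim=decim,
            zero_mean=True,
            verbose="error",
        )
        chunks.append(p[:, :, :, off : off + n_out].astype(np.float32))
    power = np.concatenate(chunks, axis=0)
    t0, _ = epochs.windows[window]
    times = t0 + np.arange(n_out) * (decim / fs)
    return EpochedTF(
        power=power,
        freqs=freqs,
        times=times,
        trials=list(epochs.trials),
        normalized=False,
        edge_padded=bool(padded),
    )


def mask_peck_artifacts(tf: EpochedTF, half_width_s: float = 0.05) -> EpochedTF:
    """Mask samples within +/-``half_width_s`` of any peck to missing (NaN).

    Peck times are taken from each trial's own records, expressed relative
    to the step-1 peck (which is 0 by alignment).
    """
    power = tf.power.copy()
    for i, tr in enumerate(tf.trials):
        pecks = (0.0, tr.t_step2_peck - tr.t_step1_peck)
        for tp in pecks:
            sel = np.abs(tf.times - tp) <= half_width_s
            if sel.any():
                power[i, :, :, sel] = np.nan
    return replace(tf, power=power)


def slice_window(tf: EpochedTF, span: tuple[float, float]) -> EpochedTF:
    """Slice a half-open time span [t0, t1) out of the TF tensor."""
    t0, t1 = span
    sel = (tf.times >= t0) & (tf.times < t1)
    if not sel.any():
        raise ValueError(f"window {span} outside the TF time axis")
    return replace(tf, power=tf.power[:, :, :, sel], times=tf.times[sel])


def baseline_normalize(tf: EpochedTF, baseline_tf: EpochedTF) -> EpochedTF:
    """Divide power by the per-trial, per-frequency mean baseline power.

    The divisor pools electrodes and baseline time samples within each
    trial, so a constant scaling of the whole recording cancels exactly.
    """
    if tf.power.shape[1:3] != baseline_tf.power.shape[1:3]:
        raise ValueError("trial/electrode/frequency axes must match the baseline")
    base = np.nanmean(baseline_tf.power, axis=(1, 3))  # trials x freqs
    if np.any(~np.isfinite(base)) or np.any(base <= 0):
        raise ValueError("baseline power must be positive and finite")
    out = tf.power / base[:, None, :, None]
    return replace(tf, power=out.astype(np.float32), normalized=True)


def band_average(
    tf: EpochedTF,
    window: tuple[float, float],
    bands: Sequence[str] = tuple(BANDS),
) -> BandPower:
    """Mean power over a time window and within each frequency band.

    Masked (NaN) samples are excluded from the means; a fully masked
    window yields a missing value.
    """
    if not tf.normalized:
        raise ValueError("band_average expects baseline-normalized power")
    sub = slice_window(tf, window)
    n_tr, n_ch = sub.power.shape[:2]
    out = np.full((n_tr, n_ch, len(bands)), np.nan)
    import warnings as _w

    for k, band in enumerate(bands):
        fsel = band_freq_mask(sub.freqs, band)
        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)  # all-NaN slices -> NaN
            out[:, :, k] = np.nanmean(sub.power[:, :, fsel, :], axis=(2, 3))
    return BandPower(values=out, bands=tuple(bands), trials=list(tf.trials), window=window)


def band_average_prepeck(
    tf: EpochedTF,
    peck_times_rel: np.ndarray,
    width_s: float = 0.5,
    bands: Sequence[str] = tuple(BANDS),
) -> BandPower:
    """Mean band power in a per-trial window [peck - width, peck).

    ``peck_times_rel`` gives each trial's peck time on the TF time axis
    (seconds relative to the step-1 peck), so step-2 windows can track the
    per-trial step-2 peck latency.
    """
    if not tf.normalized:
        raise ValueError("band_average_prepeck expects baseline-normalized power")
    n_tr, n_ch = tf.power.shape[:2]
    out = np.full((n_tr, n_ch, len(bands)), np.nan)
    import warnings as _w

    fsel = [band_freq_mask(tf.freqs, b) for b in bands]
    for i in range(n_tr):
        t1 = float(peck_times_rel[i])
        sel = (tf.times >= t1 - width_s) & (tf.times < t1)
        if not sel.any():
            continue
        cut = tf.power[i][:, :, sel]
        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)
            for k, fs_k in enumerate(fsel):
                out[i, :, k] = np.nanmean(cut[:, fs_k, :], axis=(1, 2))
    return BandPower(values=out, bands=tuple(bands), trials=list(tf.trials), window=(-width_s, 0.0))


def moving_average(x: np.ndarray, w: int = 5) -> np.ndarray:
    """Centered moving average; edges use a shrinking window. NaN-aware."""
    x = np.asarray(x, float)
    n = len(x)
    out = np.empty(n)
    half = w // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = x[lo:hi]
        out[i] = np.nan if np.all(np.isnan(seg)) else np.nanmean(seg)
    return out


def power_dynamics(
    band_power: BandPower,
    band_group: str = "high",
    trial_mask: np.ndarray | None = None,
    n_sessions: int | None = None,
    smooth: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Session-wise mean band power for a trial subset, 5-point smoothed.

    Returns ``(raw, smoothed)`` arrays of length ``n_sessions``; sessions
    with no qualifying trials are NaN and are bridged by the smoother.
    """
    vals = np.nanmean(band_power.group(band_group), axis=1)  # trials
    sessions = np.array([t.session_idx for t in band_power.trials])
    if trial_mask is None:
        trial_mask = np.ones(len(vals), dtype=bool)
    n_sessions = int(sessions.max()) + 1 if n_sessions is None else n_sessions
    raw = np.full(n_sessions, np.nan)
    for s in range(n_sessions):
        sel = trial_mask & (sessions == s) & np.isfinite(vals)
        if sel.any():
            raw[s] = vals[sel].mean()
    return raw, moving_average(raw, smooth)
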