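"""Representational similarity between the step-1 and step-2 windows.

For every trial, the time-frequency transform is binned into 100 ms
epochs spaced every 20 ms (80% overlap).  Within each trial, power is
z-scored per electrode and frequency across all of that trial's epochs,
then averaged into the six canonical bands, giving one feature vector of
K = electrodes x bands entries per epoch.  Cosine similarity between
every step-1 epoch i and step-2 epoch j yields a per-trial similarity
map rho(i, j); maps are averaged by condition (common/uncommon
transition, early/late learning stage) and contrasted with a
cluster-based permutation test (4-connected supra-threshold clusters
scored by mass, family-wise corrected against the permutation
distribution of the maximum cluster mass).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .spectral import BAND_GROUPS, BANDS, EpochedTF, band_freq_mask
from .task import S1_PLUS, TrialRecord

__all__ = [
    "S1_WINDOW",
    "S2_WINDOW",
    "TrialFeatures",
    "SimilarityMaps",
    "Cluster",
    "ContrastResult",
    "build_epochs",
    "cosine_map",
    "similarity_maps",
    "condition_average",
    "select_stage_trials",
    "cluster_contrast",
    "band_restricted_similarity",
    "troi_mean",
]

S1_WINDOW: tuple[float, float] = (-1.0, 0.0)
S2_WINDOW: tuple[float, float] = (0.0, 1.0)
_SD_GUARD = 1e-12


@dataclass
class TrialFeatures:
    """Per-epoch feature vectors for each analysis window.

    ``features[name]`` has shape (trials, epochs, K) with K = electrodes x
    selected bands; NaN rows mark epochs lost to artifact masking.
    """

    features: dict[str, np.ndarray]
    centers: dict[str, np.ndarray]
    bands: tuple[str, ...]
    trials: list[TrialRecord]


@dataclass
class SimilarityMaps:
    """Per-trial cosine-similarity maps over S1-epoch x S2-epoch pairs."""

    rho: np.ndarray  # trials x n_s1_epochs x n_s2_epochs, in [-1, 1] or NaN
    s1_centers: np.ndarray
    s2_centers: np.ndarray
    trials: list[TrialRecord]


@dataclass
class Cluster:
    mask: np.ndarray  # boolean cell membership
    mass: float
    p_corr: float
    sign: int = 1  # +1: group A > B inside the cluster, -1: A < B


@dataclass
class ContrastResult:
    mean_diff: np.ndarray
    t_map: np.ndarray
    clusters: list[Cluster]
    sig_mask: np.ndarray  # cells in clusters with p_corr < 0.05
    cell_threshold: float
    n_perm: int


def _epoch_starts(t0: float, t1: float, epoch_len: float, step: float) -> np.ndarray:
    n = int(np.floor((t1 - t0 - epoch_len) / step + 1e-9)) + 1
    if n < 1:
        raise ValueError(f"window ({t0}, {t1}) shorter than one epoch of {epoch_len}s")
    return t0 + step * np.arange(n)


def build_epochs(
    tf: EpochedTF,
    windows: dict[str, tuple[float, float]] | None = None,
    epoch_len: float = 0.1,
    step: float = 0.02,
    bands: Sequence[str] = tuple(BANDS),
) -> TrialFeatures:
    """Bin the TF transform into overlapping epochs and build feature vectors.

    z-scoring uses the mean and SD of all epochs of the trial (pooled over
    every requested window) separately per electrode and frequency; an SD
    below 1e-12 yields z = 0.  Band averaging happens after z-scoring.
    """
    windows = windows or {"s1": S1_WINDOW, "s2": S2_WINDOW}
    n_tr, n_ch, n_fr, _ = tf.power.shape
    starts = {name: _epoch_starts(t0, t1, epoch_len, step) for name, (t0, t1) in windows.items()}
    centers = {name: s + epoch_len / 2 for name, s in starts.items()}

    # per-epoch mean power: (trials, channels, freqs, epochs) per window
    import warnings as _w

    raw: dict[str, np.ndarray] = {}
    for name, st in starts.items():
        cols = []
        for s0 in st:
            sel = (tf.times >= s0 - 1e-9) & (tf.times < s0 + epoch_len - 1e-9)
            with _w.catch_warnings():
                _w.simplefilter("ignore", category=RuntimeWarning)
                cols.append(np.nanmean(tf.power[:, :, :, sel], axis=3))
        raw[name] = np.stack(cols, axis=3)

    pooled = np.concatenate(list(raw.values()), axis=3)  # trials x ch x freqs x all_epochs
    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(pooled, axis=3, keepdims=True)
        sd = np.nanstd(pooled, axis=3, keepdims=True)

    band_sel = [band_freq_mask(tf.freqs, b) for b in bands]
    features: dict[str, np.ndarray] = {}
    for name, arr in raw.items():
        z = np.where(sd > _SD_GUARD, (arr - mean) / np.where(sd > _SD_GUARD, sd, 1.0), 0.0)
        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)  # fully-masked epochs
            bz = np.stack(
                [np.nanmean(z[:, :, fsel, :], axis=2) for fsel in band_sel], axis=2
            )  # trials x ch x bands x epochs
        n_ep = bz.shape[3]
        feats = bz.transpose(0, 3, 1, 2).reshape(n_tr, n_ep, n_ch * len(bands))
        features[name] = feats
    return TrialFeatures(
        features=features, centers=centers, bands=tuple(bands), trials=list(tf.trials)
    )


def cosine_map(s1_epochs: np.ndarray, s2_epochs: np.ndarray) -> np.ndarray:
    """Cosine similarity for every pair of S1/S2 epoch feature vectors.

    Inputs are (n_i, K) and (n_j, K); vectors with zero norm or missing
    entries produce NaN cells.
    """
    a = np.asarray(s1_epochs, float)
    b = np.asarray(s2_epochs, float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions must match")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (a @ b.T) / np.outer(na, nb)
    rho[~np.isfinite(rho)] = np.nan
    bad_a = ~np.isfinite(a).all(axis=1) | (na < 1e-300)
    bad_b = ~np.isfinite(b).all(axis=1) | (nb < 1e-300)
    rho[bad_a, :] = np.nan
    rho[:, bad_b] = np.nan
    return rho


def similarity_maps(feats: TrialFeatures, s1: str = "s1", s2: str = "s2") -> SimilarityMaps:
    """Per-trial cosine maps between two feature windows."""
    f1, f2 = feats.features[s1], feats.features[s2]
    n_tr = f1.shape[0]
    rho = np.stack([cosine_map(f1[i], f2[i]) for i in range(n_tr)])
    return SimilarityMaps(
        rho=rho, s1_centers=feats.centers[s1], s2_centers=feats.centers[s2], trials=feats.trials
    )


def condition_average(maps: SimilarityMaps, mask: np.ndarray, name: str = "condition") -> np.ndarray:
    """Cell-wise, missing-aware mean map over the selected trials."""
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError(f"no trials in condition '{name}'")
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(maps.rho[mask], axis=0)


def select_stage_trials(
    all_trials: Sequence[TrialRecord],
    stage: str,
    n_trials: int = 100,
    early_threshold: float = 0.65,
    late_threshold: float = 0.90,
    eligible: Sequence[bool] | None = None,
) -> np.ndarray:
    """Indices of early/late learning-stage trials.

    Early: the first ``n_trials`` valid trials from sessions whose S1+
    choice rate is below ``early_threshold``; late: the last ``n_trials``
    valid trials from sessions above ``late_threshold``.  Session rates
    are computed over all trials of the session.  ``eligible`` can restrict
    the candidate pool (e.g. to trials retained by QC/epoching).
    """
    if stage not in ("early", "late"):
        raise ValueError("stage must be 'early' or 'late'")
    sessions = np.array([t.session_idx for t in all_trials])
    plus = np.array([t.choice == S1_PLUS for t in all_trials], dtype=float)
    valid = np.array([t.valid for t in all_trials], dtype=bool)
    if eligible is not None:
        valid &= np.asarray(eligible, bool)
    rates = {s: plus[sessions == s].mean() for s in np.unique(sessions)}
    if stage == "early":
        sess_ok = {s for s, r in rates.items() if r < early_threshold}
    else:
        sess_ok = {s for s, r in rates.items() if r > late_threshold}
    pool = np.nonzero(valid & np.isin(sessions, sorted(sess_ok)))[0]
    if len(pool) < n_trials:
        raise ValueError(
            f"stage '{stage}' requires {n_trials} qualifying trials, only {len(pool)} available"
        )
    return pool[:n_trials] if stage == "early" else pool[-n_trials:]


def _t_map(x: np.ndarray, na: int) -> np.ndarray:
    """Two-sample pooled-variance t statistic per cell; NaN-aware."""
    import warnings as _w

    a, b = x[:na], x[na:]
    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        ma, mb = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        va, vb = np.nanvar(a, axis=0, ddof=1), np.nanvar(b, axis=0, ddof=1)
        ca = np.sum(np.isfinite(a), axis=0)
        cb = np.sum(np.isfinite(b), axis=0)
        df = ca + cb - 2
        sp2 = ((ca - 1) * va + (cb - 1) * vb) / np.where(df > 0, df, 1)
        se = np.sqrt(sp2 * (1.0 / np.where(ca > 0, ca, 1) + 1.0 / np.where(cb > 0, cb, 1)))
        t = (ma - mb) / np.where(se > 0, se, np.nan)
    t[(ca < 2) | (cb < 2)] = np.nan
    return t


_CONN4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _signed_clusters(t: np.ndarray, thresh: float) -> list[tuple[np.ndarray, float, int]]:
    """Positive and negative supra-threshold clusters as (mask, mass, sign)."""
    out: list[tuple[np.ndarray, float, int]] = []
    tt = np.nan_to_num(t)
    for sign in (1, -1):
        supra = (sign * tt) > thresh
        if not supra.any():
            continue
        labels, n = ndimage.label(supra, structure=_CONN4)
        for k in range(1, n + 1):
            mask = labels == k
            out.append((mask, float(np.abs(tt[mask]).sum()), sign))
    return out


def _max_cluster_mass(t: np.ndarray, thresh: float) -> float:
    clusters = _signed_clusters(t, thresh)
    return max((mass for _, mass, _ in clusters), default=0.0)


def cluster_contrast(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 1000,
    cell_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    exclude_mask: np.ndarray | None = None,
    ids_a: Sequence | None = None,
    ids_b: Sequence | None = None,
) -> ContrastResult:
    """Cluster-based permutation contrast of two sets of similarity maps.

    Cell-wise two-sample t statistics are thresholded two-sided at
    ``cell_alpha``; 4-connected supra-threshold clusters are scored by the
    sum of |t| and corrected against the permutation distribution of the
    maximum cluster mass under random reassignment of maps to groups.
    """
    import warnings as _w

    if ids_a is not None and ids_b is not None and set(ids_a) & set(ids_b):
        raise ValueError("groups share trial ids")
    if n_perm < 100:
        _w.warn("n_perm < 100 gives a coarse corrected-p resolution", stacklevel=2)
    rng = rng if rng is not None else np.random.default_rng(0)
    a = np.asarray(maps_a, float)
    b = np.asarray(maps_b, float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("map shapes differ between groups")
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least two maps per group")
    x = np.concatenate([a, b], axis=0)
    if exclude_mask is not None:
        x = x.copy()
        x[:, np.asarray(exclude_mask, bool)] = np.nan
    na = len(a)
    n_all = len(x)
    df = n_all - 2
    thresh = stats.t.ppf(1 - cell_alpha / 2, df)

    t_obs = _t_map(x, na)
    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        mean_diff = np.nanmean(x[:na], axis=0) - np.nanmean(x[na:], axis=0)

    obs_clusters = _signed_clusters(t_obs, thresh)

    null_max = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n_all)
        null_max[p] = _max_cluster_mass(_t_map(x[perm], na), thresh)

    clusters = []
    for mask, mass, sign in obs_clusters:
        p_corr = float((1 + np.sum(null_max >= mass)) / (n_perm + 1))
        clusters.append(Cluster(mask=mask, mass=mass, p_corr=p_corr, sign=sign))
    clusters.sort(key=lambda c: c.mass, reverse=True)
    sig = np.zeros(t_obs.shape, dtype=bool)
    for c in clusters:
        if c.p_corr < 0.05:
            sig |= c.mask
    return ContrastResult(
        mean_diff=mean_diff,
        t_map=t_obs,
        clusters=clusters,
        sig_mask=sig,
        cell_threshold=float(thresh),
        n_perm=n_perm,
    )


def band_restricted_similarity(
    tf: EpochedTF,
    band_group: str = "all",
    windows: dict[str, tuple[float, float]] | None = None,
    epoch_len: float = 0.1,
    step: float = 0.02,
) -> SimilarityMaps:
    """Similarity maps computed from a band subset ('low', 'high' or 'all')."""
    bands = BAND_GROUPS[band_group]
    if len(bands) == 0:
        raise ValueError("empty band selection")
    feats = build_epochs(tf, windows=windows, epoch_len=epoch_len, step=step, bands=bands)
    return similarity_maps(feats)


def troi_mean(maps: SimilarityMaps, cluster_mask: np.ndarray) -> np.ndarray:
    """Per-trial mean similarity over the cells of a cluster (tROI)."""
    import warnings as _w

    mask = np.asarray(cluster_mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty tROI")
    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(maps.rho[:, mask], axis=1)
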