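"""Similarity maps: feature epochs, cosine maps, stages, cluster contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep_hippo import similarity, task
from twostep_hippo.similarity import (
    band_restricted_similarity,
    build_epochs,
    cluster_contrast,
    condition_average,
    cosine_map,
    select_stage_trials,
    similarity_maps,
    troi_mean,
)
from twostep_hippo.spectral import EpochedTF, default_freqs


def _random_tf(rng, n_trials=3, n_ch=4):
    times = np.arange(-1.0, 1.0, 0.01)
    power = rng.gamma(2.0, 1.0, size=(n_trials, n_ch, 50, len(times))).astype(np.float32)
    return EpochedTF(power=power, freqs=default_freqs(), times=times,
                     trials=[None] * n_trials, normalized=True)


class TestBuildEpochs:
    def test_epoch_count_and_centers(self, rng):
        """A 1 s window at 100 ms / 20 ms tiling gives 46 epochs with
        centers from 0.05 to 0.95 s (floor((1.0-0.1)/0.02)+1)."""
        tf = _random_tf(rng)
        feats = build_epochs(tf, windows={"w": (0.0, 1.0)})
        assert feats.features["w"].shape[1] == 46
        np.testing.assert_allclose(feats.centers["w"], 0.05 + 0.02 * np.arange(46))

    def test_zscores_have_zero_mean_unit_sd(self, rng):
        tf = _random_tf(rng, n_ch=2)
        feats = build_epochs(
            tf, windows={"w": (-1.0, 1.0)}, bands=("delta", "theta", "alpha",
                                                   "beta", "low_gamma", "high_gamma")
        )
        # reconstruct per-frequency z-scores indirectly: band means of z have
        # near-zero mean across epochs
        f = feats.features["w"]
        assert np.abs(np.nanmean(f, axis=1)).max() < 0.2

    def test_constant_power_yields_zero_z(self):
        times = np.arange(-1.0, 1.0, 0.01)
        power = np.ones((2, 3, 50, len(times)), dtype=np.float32)
        tf = EpochedTF(power=power, freqs=default_freqs(), times=times,
                       trials=[None, None], normalized=True)
        feats = build_epochs(tf, windows={"w": (0.0, 1.0)})
        np.testing.assert_allclose(feats.features["w"], 0.0, atol=1e-12)

    def test_window_shorter_than_epoch_rejected(self, rng):
        with pytest.raises(ValueError):
            build_epochs(_random_tf(rng), windows={"w": (0.0, 0.05)})


class TestCosineMap:
    def test_identical_orthogonal_antialigned(self):
        v = np.array([[1.0, 2.0, 3.0]])
        u = np.array([[1.0, 2.0, 3.0], [3.0, 0.0, -1.0], [-1.0, -2.0, -3.0]])
        rho = cosine_map(v, u)
        np.testing.assert_allclose(rho[0], [1.0, 0.0, -1.0], atol=1e-12)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_positive_rescaling_invariance(self, scale):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 6))
        b = rng.normal(size=(5, 6))
        np.testing.assert_allclose(cosine_map(a * scale, b), cosine_map(a, b), atol=1e-9)

    def test_zero_norm_vector_gives_missing(self):
        a = np.zeros((1, 3))
        b = np.ones((2, 3))
        assert np.all(np.isnan(cosine_map(a, b)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_map(np.ones((2, 3)), np.ones((2, 4)))


class TestConditionAverage:
    def _maps(self, rho):
        return similarity.SimilarityMaps(
            rho=np.asarray(rho, float), s1_centers=np.arange(2.0),
            s2_centers=np.arange(2.0), trials=[None] * len(rho),
        )

    def test_single_map_is_itself(self):
        m = self._maps([np.full((2, 2), 0.3)])
        np.testing.assert_allclose(condition_average(m, [True]), 0.3)

    def test_two_constant_maps_average(self):
        m = self._maps([np.full((2, 2), 0.2), np.full((2, 2), 0.6)])
        np.testing.assert_allclose(condition_average(m, [True, True]), 0.4)

    def test_empty_condition_rejected_by_name(self):
        m = self._maps([np.zeros((2, 2))])
        with pytest.raises(ValueError, match="late-common"):
            condition_average(m, [False], name="late-common")


class TestStageSelection:
    def _trials(self, rates, per_session=20):
        trials = []
        t = 0.0
        for s, rate in enumerate(rates):
            n_plus = int(round(rate * per_session))
            for i in range(per_session):
                choice = task.S1_PLUS if i < n_plus else task.S1_MINUS
                t += 10.0
                trials.append(task.TrialRecord(
                    session_idx=s, trial_idx=i, choice=choice, second_state=choice,
                    rewarded=True, t_s1_onset=t, t_step1_peck=t + 1, t_s2_onset=t + 1.05,
                    t_step2_peck=t + 1.8, reaction_time_s=1.0,
                ))
        return trials

    def test_stages_populated_and_disjoint(self):
        trials = self._trials([0.5, 0.55, 0.6, 0.95, 0.95, 1.0])
        early = select_stage_trials(trials, "early", 40)
        late = select_stage_trials(trials, "late", 40)
        assert len(early) == len(late) == 40
        assert set(early).isdisjoint(late)
        sessions = np.array([trials[i].session_idx for i in early])
        assert sessions.max() <= 2

    def test_intermediate_rates_give_empty_stages(self):
        trials = self._trials([0.75] * 4)
        with pytest.raises(ValueError, match="only 0 available"):
            select_stage_trials(trials, "early", 10)
        with pytest.raises(ValueError):
            select_stage_trials(trials, "late", 10)

    def test_achievable_count_reported(self):
        trials = self._trials([0.5, 0.95])
        with pytest.raises(ValueError, match="only 20 available"):
            select_stage_trials(trials, "early", 21)


class TestClusterContrast:
    def test_null_calibration_false_positive_rate(self):
        """Groups drawn from one null distribution: the family-wise error of
        the corrected cluster p stays near the nominal 5% (<= 7% over 200
        repetitions)."""
        rng = np.random.default_rng(99)
        n_rep, fp = 200, 0
        for _ in range(n_rep):
            a = rng.normal(size=(20, 20, 20))
            b = rng.normal(size=(20, 20, 20))
            res = cluster_contrast(a, b, n_perm=250, rng=rng)
            if any(c.p_corr < 0.05 for c in res.clusters):
                fp += 1
        assert fp / n_rep <= 0.07

    def test_planted_block_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(25, 30, 30))
        b = rng.normal(size=(25, 30, 30))
        b[:, 8:16, 10:20] += 1.5
        res = cluster_contrast(a, b, n_perm=500, rng=rng)
        top = res.clusters[0]
        assert top.p_corr < 0.05 and top.sign == -1  # B > A in the block
        ii, jj = np.nonzero(top.mask)
        assert 8 <= np.median(ii) <= 16 and 10 <= np.median(jj) <= 20
        assert res.sig_mask.any()

    def test_deterministic_under_seed(self, rng):
        a = rng.normal(size=(12, 10, 10))
        b = rng.normal(size=(12, 10, 10)) + 0.4
        r1 = cluster_contrast(a, b, n_perm=200, rng=np.random.default_rng(3))
        r2 = cluster_contrast(a, b, n_perm=200, rng=np.random.default_rng(3))
        assert [c.p_corr for c in r1.clusters] == [c.p_corr for c in r2.clusters]
        np.testing.assert_array_equal(r1.sig_mask, r2.sig_mask)

    def test_overlapping_ids_rejected(self, rng):
        a = rng.normal(size=(5, 4, 4))
        with pytest.raises(ValueError, match="share"):
            cluster_contrast(a, a, n_perm=100, rng=rng, ids_a=[1, 2, 3, 4, 5],
                             ids_b=[5, 6, 7, 8, 9])

    def test_low_perm_warns(self, rng):
        a = rng.normal(size=(5, 4, 4))
        b = rng.normal(size=(5, 4, 4))
        with pytest.warns(UserWarning):
            cluster_contrast(a, b, n_perm=50, rng=rng)


class TestBandRestricted:
    def test_all_bands_equals_full_computation(self, lfp_chain):
        tf = lfp_chain["tf"]
        full = band_restricted_similarity(tf, "all")
        feats = build_epochs(tf)
        again = similarity_maps(feats)
        np.testing.assert_allclose(full.rho, again.rho, atol=1e-6)

    def test_empty_band_selection_rejected(self, lfp_chain):
        with pytest.raises(KeyError):
            band_restricted_similarity(lfp_chain["tf"], "nonexistent")

    def test_shared_pattern_raises_low_band_similarity(self, lfp_chain):
        """Trials with the planted shared 6 Hz pattern show higher low-band
        similarity in the envelope block than trials without it."""
        tf = lfp_chain["tf"]
        gt = lfp_chain["gt"]
        maps = band_restricted_similarity(tf, "low")
        s1c, s2c = maps.s1_centers, maps.s2_centers
        mask = np.zeros((len(s1c), len(s2c)), dtype=bool)
        mask[np.ix_((s1c > -0.7) & (s1c < -0.1), (s2c > 0.2) & (s2c < 0.8))] = True
        vals = troi_mean(maps, mask)
        shared = gt.shared_low_band
        assert np.nanmean(vals[shared]) > np.nanmean(vals[~shared]) + 0.02

    def test_no_high_band_shared_pattern(self, lfp_chain):
        tf = lfp_chain["tf"]
        gt = lfp_chain["gt"]
        maps = band_restricted_similarity(tf, "high")
        s1c, s2c = maps.s1_centers, maps.s2_centers
        mask = np.zeros((len(s1c), len(s2c)), dtype=bool)
        mask[np.ix_((s1c > -0.7) & (s1c < -0.1), (s2c > 0.2) & (s2c < 0.8))] = True
        vals = troi_mean(maps, mask)
        shared = gt.shared_low_band
        diff = np.nanmean(vals[shared]) - np.nanmean(vals[~shared])
        assert abs(diff) < 0.05


def test_map_dimensions_golden(rng):
    """Map shape and epoch centers are fully determined by (window,
    epoch_len, step)."""
    tf = _random_tf(rng, n_trials=1)
    feats = build_epochs(tf, windows={"s1": (-1.0, 0.0), "s2": (0.0, 1.0)},
                         epoch_len=0.1, step=0.02)
    maps = similarity_maps(feats)
    assert maps.rho.shape == (1, 46, 46)
    np.testing.assert_allclose(maps.s1_centers[:3], [-0.95, -0.93, -0.91])
    np.testing.assert_allclose(maps.s2_centers[-1], 0.95)
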