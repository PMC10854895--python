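"""End-to-end pipeline: behavior -> synthetic LFP -> preprocessing ->
model fitting -> spectra -> similarity -> value linking.

A run is reproducible bit-for-bit from (config, seed): the root seed
spawns one independent stream per stage.  Every stage writes its
artifacts into the run directory and registers them in a manifest of
SHA-256 hashes; the final summary records whether the four planted
signatures were detected:

1. high-band (12-100 Hz) normalized power increases with learning for
   the commonly rewarded option/state;
2. high-band power regresses significantly on model-based value;
3. the step-1 choice decodes better from high-band than low-band power
   (margin >= 0.1);
4. a low-frequency (1-12 Hz) similarity cluster appears for common
   transitions late in learning, with no high-band counterpart.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import agent, fitting, preprocess, similarity, spectral, synth, task, valuelink
from .task import S1_PLUS, S2_PLUS, TaskConfig

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("twostep_hippo")


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    task: dict = field(default_factory=dict)  # TaskConfig overrides
    gen: dict = field(default_factory=dict)  # LFPGenConfig overrides
    # linear per-trial ramps of the generating agent's parameters
    gamma_start: float = 0.2
    gamma_end: float = 0.98
    beta_start: float = 0.3
    beta_end: float = 8.0
    ramp_fraction: float = 0.5  # ramp over this fraction of trials, then hold
    n_windows: int = 12
    n_restarts: int = 3
    compare_rounds: int = 0  # dynamic-vs-static simulation rounds (0: skip)
    stage_trials: int = 100
    n_perm: int = 1000
    prepeck_width_s: float = 0.5
    decim: int = 10

    def task_config(self) -> TaskConfig:
        d = dict(self.task)
        for key in ("transition_probs", "rt_range_s", "rt2_range_s"):
            if key in d:
                d[key] = tuple(tuple(r) if isinstance(r, (list, tuple)) else r for r in d[key]) if key == "transition_probs" else tuple(d[key])
        if "reward_probs" in d:
            d["reward_probs"] = tuple(d["reward_probs"])
        return TaskConfig(**d)

    def gen_config(self) -> synth.LFPGenConfig:
        d = dict(self.gen)
        for key in ("burst_carriers", "low_s1_span", "low_s2_span"):
            if key in d:
                d[key] = tuple(d[key])
        return synth.LFPGenConfig(**d)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["behavior", "synth", "fit", "rsa", "link", "compare"]
    seqs = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


def agent_schedule(cfg: RunConfig, n_trials: int) -> list[agent.AgentParams]:
    n_ramp = max(2, int(round(cfg.ramp_fraction * n_trials)))
    ramp = np.clip(np.arange(n_trials) / (n_ramp - 1), 0.0, 1.0)
    g = cfg.gamma_start + (cfg.gamma_end - cfg.gamma_start) * ramp
    b = cfg.beta_start + (cfg.beta_end - cfg.beta_start) * ramp
    return [agent.AgentParams(float(gi), float(bi)) for gi, bi in zip(g, b)]


def run_behavior(cfg: RunConfig, outdir: Path, rng) -> tuple[list, agent.AgentHistory]:
    tc = cfg.task_config()
    schedule = agent_schedule(cfg, tc.n_trials)
    trials, history = agent.simulate_agent(schedule, tc, rng)
    task.write_trials_csv(trials, outdir / "trials.csv")
    np.savez(
        outdir / "values.npz",
        q_s1=history.q_s1,
        q_s2=history.q_s2,
        p_choice=history.p_choice,
        gamma=history.gamma,
        beta=history.beta,
    )
    log.info("behavior: %d trials over %d sessions", len(trials), tc.n_sessions)
    return trials, history


def run_synth(cfg: RunConfig, outdir: Path, trials, history, rng) -> tuple[synth.LFPRecording, synth.GroundTruth]:
    rec, gt = synth.generate_recording(trials, history, cfg.gen_config(), rng=rng)
    synth.write_recording(rec, outdir / "recording.h5")
    np.savez(
        outdir / "ground_truth.npz",
        amp_s1=gt.amp_s1,
        amp_s2=gt.amp_s2,
        q_choice=gt.q_choice,
        q_state=gt.q_state,
        shared_low_band=gt.shared_low_band,
        artifact_times=gt.artifact_times,
        learned_boundary=gt.learned_boundary,
    )
    log.info("synth: %d channels x %d samples at %g Hz", rec.n_channels, rec.n_samples, rec.fs)
    return rec, gt


def run_preprocess(cfg: RunConfig, outdir: Path, rec, trials) -> preprocess.EpochSet:
    clean = preprocess.preprocess_recording(rec)
    kept, qc_log = preprocess.qc_filter(trials)
    epochs = preprocess.epoch(clean, kept)
    with open(outdir / "exclusions.csv", "w") as f:
        f.write("trial_id,reason\n")
        for tid, reason in qc_log + epochs.excluded:
            f.write(f"{tid},{reason}\n")
    log.info(
        "preprocess: kept %d/%d trials (%d QC, %d epoching exclusions)",
        epochs.n_trials,
        len(trials),
        len(qc_log),
        len(epochs.excluded),
    )
    return epochs


def run_fit(cfg: RunConfig, outdir: Path, trials, rng) -> tuple[fitting.FitResult, fitting.FitResult]:
    fcfg = fitting.FitConfig(
        n_windows=cfg.n_windows, n_restarts=cfg.n_restarts, seed=int(rng.integers(2**31))
    )
    fit_dyn = fitting.fit_dynamic(trials, fcfg)
    fit_stat = fitting.fit_map(trials, dataclasses.replace(fcfg, n_windows=1))
    payload = {"dynamic": fit_dyn.to_dict(), "static": fit_stat.to_dict()}
    if cfg.compare_rounds > 0:
        comparison = fitting.compare_dynamic_static(
            cfg.task_config(), fit_dyn, fit_stat, n_rounds=cfg.compare_rounds, rng=rng, fit_cfg=fcfg
        )
        payload["comparison"] = {
            name: {"mean": c["mean"].tolist(), "sd": c["sd"].tolist()}
            for name, c in comparison.items()
        }
    (outdir / "fits.json").write_text(json.dumps(payload, indent=2))
    log.info(
        "fit: dynamic gamma %.2f->%.2f, beta %.2f->%.2f",
        fit_dyn.gamma_hat[0],
        fit_dyn.gamma_hat[-1],
        fit_dyn.beta_hat[0],
        fit_dyn.beta_hat[-1],
    )
    return fit_dyn, fit_stat


def compute_tf(cfg: RunConfig, epochs: preprocess.EpochSet) -> spectral.EpochedTF:
    tf = spectral.morlet_power(epochs, decim=cfg.decim)
    tf = spectral.mask_peck_artifacts(tf)
    baseline = spectral.slice_window(tf, preprocess.WINDOWS["baseline"])
    return spectral.baseline_normalize(tf, baseline)


def run_spectral(cfg: RunConfig, outdir: Path, tf: spectral.EpochedTF) -> dict:
    trials = tf.trials
    bp_choice = spectral.band_average(tf, (-cfg.prepeck_width_s, 0.0))
    peck2 = np.array([t.t_step2_peck - t.t_step1_peck for t in trials])
    bp_s2 = spectral.band_average_prepeck(tf, peck2, cfg.prepeck_width_s)
    choice_arr = np.array([t.choice for t in trials])
    state_arr = np.array([t.second_state for t in trials])
    n_sessions = max(t.session_idx for t in trials) + 1
    curves = {}
    for name, bp, mask in (
        ("s1_plus", bp_choice, choice_arr == S1_PLUS),
        ("s1_minus", bp_choice, choice_arr != S1_PLUS),
        ("s2_plus", bp_s2, state_arr == S2_PLUS),
        ("s2_minus", bp_s2, state_arr != S2_PLUS),
    ):
        for group in ("high", "low"):
            raw, smooth = spectral.power_dynamics(bp, group, mask, n_sessions)
            curves[f"{name}_{group}"] = {"raw": raw, "smoothed": smooth}
    np.savez(
        outdir / "band_power.npz",
        choice=bp_choice.values,
        s2=bp_s2.values,
        bands=np.array(bp_choice.bands),
        **{f"curve_{k}_{fld}": v[fld] for k, v in curves.items() for fld in ("raw", "smoothed")},
    )
    return {"bp_choice": bp_choice, "bp_s2": bp_s2, "curves": curves}


def run_rsa(cfg: RunConfig, outdir: Path, tf: spectral.EpochedTF, rng) -> dict:
    trials = tf.trials
    idx_early = similarity.select_stage_trials(trials, "early", cfg.stage_trials)
    idx_late = similarity.select_stage_trials(trials, "late", cfg.stage_trials)
    choice = np.array([t.choice for t in trials])
    state = np.array([t.second_state for t in trials])
    common = (choice == S1_PLUS) & (state == S2_PLUS)
    uncommon = (choice == S1_PLUS) & (state != S2_PLUS)

    results: dict = {"stage_early": idx_early, "stage_late": idx_late}
    for group in ("low", "high"):
        maps = similarity.band_restricted_similarity(tf, group)
        late_common = np.intersect1d(idx_late, np.nonzero(common)[0])
        late_uncommon = np.intersect1d(idx_late, np.nonzero(uncommon)[0])
        early_common = np.intersect1d(idx_early, np.nonzero(common)[0])
        contrast_cu = similarity.cluster_contrast(
            maps.rho[late_common],
            maps.rho[late_uncommon],
            n_perm=cfg.n_perm,
            rng=rng,
            ids_a=late_common.tolist(),
            ids_b=late_uncommon.tolist(),
        )
        contrast_el = similarity.cluster_contrast(
            maps.rho[late_common],
            maps.rho[early_common],
            n_perm=cfg.n_perm,
            rng=rng,
            ids_a=late_common.tolist(),
            ids_b=early_common.tolist(),
        )
        results[group] = {
            "maps": maps,
            "common_vs_uncommon_late": contrast_cu,
            "late_vs_early_common": contrast_el,
        }
        np.savetxt(
            outdir / f"rsa_{group}_sigmask_common_vs_uncommon_late.csv",
            contrast_cu.sig_mask.astype(int),
            fmt="%d",
            delimiter=",",
        )
    log.info(
        "rsa: low-band common-vs-uncommon min p(corr)=%s",
        min((c.p_corr for c in results["low"]["common_vs_uncommon_late"].clusters), default=None),
    )
    return results


def run_link(
    cfg: RunConfig,
    outdir: Path,
    spectra: dict,
    fit_dyn: fitting.FitResult,
    trials,
    rng,
) -> dict:
    history = fitting.replay_values(trials, fit_dyn)
    sessions = np.array([t.session_idx for t in trials])
    choice = np.array([t.choice for t in trials])
    state = np.array([t.second_state for t in trials])
    n_sessions = int(sessions.max()) + 1

    def session_mean(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
        out = np.full(n_sessions, np.nan)
        for s in range(n_sessions):
            sel = mask & (sessions == s) & np.isfinite(values)
            if sel.any():
                out[s] = values[sel].mean()
        return out

    regressions = []
    condition_specs = [
        ("s1_plus", spectra["bp_choice"], choice == S1_PLUS, history.q_s1[:, 0]),
        ("s1_minus", spectra["bp_choice"], choice != S1_PLUS, history.q_s1[:, 1]),
        ("s2_plus", spectra["bp_s2"], state == S2_PLUS, history.q_s2[:, 0]),
        ("s2_minus", spectra["bp_s2"], state != S2_PLUS, history.q_s2[:, 1]),
    ]
    for name, bp, mask, q in condition_specs:
        for group in ("low", "high"):
            power = np.nanmean(bp.group(group), axis=1)
            y = session_mean(power, mask)
            x = session_mean(q, mask)
            res = valuelink.session_value_regression(y, x, condition=name, band_group=group)
            regressions.append(res)

    decode = {}
    bp_choice = spectra["bp_choice"]
    for group in ("low", "high"):
        decode[group] = valuelink.decode_choice(
            bp_choice.group_features(group), choice, band_group=group, rng=rng
        )

    with open(outdir / "regressions.csv", "w") as f:
        f.write("condition,band_group,r_squared,p_value,f_statistic,beta0,beta1,n_sessions\n")
        for r in regressions:
            f.write(
                f"{r.condition},{r.band_group},{r.r_squared:.6f},{r.p_value:.6g},"
                f"{r.f_statistic:.4f},{r.beta0:.6f},{r.beta1:.6f},{r.n_sessions}\n"
            )
    with open(outdir / "decoding.csv", "w") as f:
        f.write("band_group,accuracy_mean,accuracy_sd,n_rounds,n_trials\n")
        for group, d in decode.items():
            f.write(f"{group},{d.mean:.4f},{d.sd:.4f},{len(d.accuracies)},{d.n_trials}\n")
    return {"regressions": regressions, "decode": decode, "history": history}


def detect_signatures(spectra: dict, rsa: dict, link: dict, tf: spectral.EpochedTF) -> dict:
    trials = tf.trials
    choice = np.array([t.choice for t in trials])
    state = np.array([t.second_state for t in trials])
    idx_early, idx_late = rsa["stage_early"], rsa["stage_late"]

    def stage_power(bp, mask):
        vals = np.nanmean(bp.group("high"), axis=1)
        e = vals[np.intersect1d(idx_early, np.nonzero(mask)[0])]
        l = vals[np.intersect1d(idx_late, np.nonzero(mask)[0])]
        rep = valuelink.stat_tests(l[np.isfinite(l)], e[np.isfinite(e)])
        return bool(np.nanmean(l) > np.nanmean(e) and rep.p_value < 0.05), rep

    sig1_s1, rep1 = stage_power(spectra["bp_choice"], choice == S1_PLUS)
    sig1_s2, rep2 = stage_power(spectra["bp_s2"], state == S2_PLUS)

    reg = {(r.condition, r.band_group): r for r in link["regressions"]}
    sig2 = bool(
        reg[("s1_plus", "high")].p_value < 0.05
        and reg[("s1_plus", "high")].beta1 > 0
        and reg[("s2_plus", "high")].p_value < 0.05
        and reg[("s2_plus", "high")].beta1 > 0
    )

    margin = link["decode"]["high"].mean - link["decode"]["low"].mean
    sig3 = bool(margin >= 0.1)

    # an "increase" is a positive cluster (common > uncommon)
    low_p = min(
        (c.p_corr for c in rsa["low"]["common_vs_uncommon_late"].clusters if c.sign > 0),
        default=1.0,
    )
    high_p = min(
        (c.p_corr for c in rsa["high"]["common_vs_uncommon_late"].clusters if c.sign > 0),
        default=1.0,
    )
    sig4 = bool(low_p < 0.05 and high_p >= 0.05)

    return {
        "high_band_power_learning": {
            "detected": bool(sig1_s1 and sig1_s2),
            "p_s1_plus": rep1.p_value,
            "p_s2_plus": rep2.p_value,
        },
        "high_band_value_regression": {
            "detected": sig2,
            "p_s1_plus_high": reg[("s1_plus", "high")].p_value,
            "p_s2_plus_high": reg[("s2_plus", "high")].p_value,
            "r2_s2_plus_high": reg[("s2_plus", "high")].r_squared,
        },
        "high_over_low_decoding": {
            "detected": sig3,
            "high_accuracy": link["decode"]["high"].mean,
            "low_accuracy": link["decode"]["low"].mean,
            "margin": margin,
        },
        "low_band_similarity_cluster": {
            "detected": sig4,
            "low_min_p_corr": low_p,
            "high_min_p_corr": high_p,
        },
    }


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Execute every stage and write artifacts, manifest and summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(cfg.to_json())
    rngs = _stage_rngs(cfg.seed)

    stage = "behavior"
    try:
        trials, history = run_behavior(cfg, outdir, rngs["behavior"])
        stage = "synth"
        rec, gt = run_synth(cfg, outdir, trials, history, rngs["synth"])
        stage = "preprocess"
        epochs = run_preprocess(cfg, outdir, rec, trials)
        del rec
        stage = "fit"
        fit_dyn, fit_stat = run_fit(cfg, outdir, trials, rngs["fit"])
        stage = "spectral"
        tf = compute_tf(cfg, epochs)
        spectra = run_spectral(cfg, outdir, tf)
        stage = "rsa"
        rsa = run_rsa(cfg, outdir, tf, rngs["rsa"])
        stage = "link"
        link = run_link(cfg, outdir, spectra, fit_dyn, epochs.trials, rngs["link"])
        stage = "summary"
        signatures = detect_signatures(spectra, rsa, link, tf)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        log.error("pipeline aborted in stage '%s': %s", stage, exc)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    summary = {
        "seed": cfg.seed,
        "n_trials": len(trials),
        "n_retained": len(epochs.trials),
        "signatures": signatures,
        "all_detected": all(s["detected"] for s in signatures.values()),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))

    manifest = {
        "config_seed": cfg.seed,
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
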