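"""End-to-end pipeline orchestration with reproducible configuration.

``run_pipeline`` drives the full chain on a synthetic cohort:

    synth -> behavior -> preprocess -> localize -> dynamics -> coupling
          -> mkl -> stats

writing every stage's outputs under a run directory together with a
provenance manifest (config hash, per-stage seeds, package version).  All
stage outputs are deterministic functions of (config, seed): running the
same config twice produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import assign_presses, score_run
from .coupling import run_coupling
from .dynamics import (POST_WINDOW_MS, PRE_WINDOW_MS, time_to_peak,
                       window_mean)
from .io import (write_channel_table, write_envelope, write_events,
                 write_ground_truth, write_json, write_recording,
                 write_responses, write_run_score, write_trial_table)
from .localize import (cluster_permutation_test, epoch, screen_network,
                       select_trials)
from .mkl import band_contributions, build_kernels, fit_mkl, trial_features
from .preprocess import BAND_TABLE, preprocess_run, smooth_envelope
from .stats import run_recipe
from .synth import (ChannelEffect, NoiseSpec, PairCoupling,
                    make_stimulus_sequence, simulate_behavior,
                    simulate_recording)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]

#: network-specific evoked-response defaults: (sign, peak latency ms)
NETWORK_PROFILES = {"DAN": (+1, 500.0), "SN": (+1, 700.0), "DMN": (-1, 1000.0)}


@dataclass
class PipelineConfig:
    """Complete, explicit configuration of a synthetic-cohort pipeline run."""

    n_subjects: int = 3
    task_runs_per_subject: int = 2
    rest_runs_per_subject: int = 1
    n_trials: int = 120
    mountain_rate: float = 0.1
    transition_ms: float = 800.0
    fs: float = 500.0
    line_freq: float = 60.0
    pre_task_s: float = 20.0
    electrodes_per_network: int = 2
    unlabeled_electrodes: int = 1
    effect_amplitude: float = 0.8
    effect_width_ms: float = 400.0
    coupling_r: float = -0.8
    coupling_lag_s: float = 0.4
    lapse_rate: float = 0.25
    omission_rate: float = 0.03
    rt_mean: float = 0.70
    rt_sd: float = 0.15
    n_perm: int = 500
    smooth_ms: float = 50.0
    recipes: tuple[str, ...] = ("ttp_network", "dprime_coupling", "task_rest")
    seeds: dict = field(default_factory=lambda: {
        "synth": 101, "behavior": 202, "baseline_subsample": 303,
        "localize": 404, "mkl": 505,
    })

    def validate(self) -> None:
        required = {"synth", "behavior", "baseline_subsample", "localize",
                    "mkl"}
        missing = required - set(self.seeds)
        if missing:
            raise ValueError(f"config lacks explicit seeds for {sorted(missing)}")
        if self.fs < 500:
            raise ValueError("fs must be >= 500 Hz")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(cfg: PipelineConfig, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def load_config(path: Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "recipes" in raw:
        raw["recipes"] = tuple(raw["recipes"])
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------


def _subject_layout(cfg: PipelineConfig, subject: str):
    effects, rows = [], []
    for net, (sign, ttp) in NETWORK_PROFILES.items():
        for k in range(cfg.electrodes_per_network):
            ch = f"{subject}-{net}{k}"
            effects.append(ChannelEffect(
                channel=ch, network=net, sign=sign,
                amplitude=cfg.effect_amplitude, ttp_ms=ttp,
                width_ms=cfg.effect_width_ms, err_pre_amp=0.3,
                err_post_gain=1.3))
            rows.append({"channel": ch, "subject": subject, "network": net})
    for k in range(cfg.unlabeled_electrodes):
        ch = f"{subject}-none{k}"
        effects.append(ChannelEffect(channel=ch, network="none"))
        rows.append({"channel": ch, "subject": subject, "network": "none"})
    pair = PairCoupling(f"{subject}-DAN0", f"{subject}-DMN0",
                        r_target=cfg.coupling_r, lag_s=cfg.coupling_lag_s)
    return effects, pd.DataFrame(rows), pair


def run_pipeline(cfg: PipelineConfig, out_dir: Path) -> Path:
    """Execute every stage and write outputs + manifest under ``out_dir``."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = cfg.seeds
    subjects = [f"s{str(i + 1).zfill(2)}" for i in range(cfg.n_subjects)]

    channel_tables = []
    ttp_rows, coupling_rows, dprime_rows, mkl_out = [], [], [], {}
    responsive_tables = []

    for si, subject in enumerate(subjects):
        effects, chan_table, pair = _subject_layout(cfg, subject)
        channel_tables.append(chan_table)
        sdir = out / subject
        write_channel_table(chan_table, sdir / "channels.tsv")

        run_envs, run_tables, run_seqs, run_scores = [], [], [], []
        for run in range(cfg.task_runs_per_subject):
            tag = f"task-{run + 1:02d}"
            base = seeds["synth"] + 97 * si + 7 * run
            seq = make_stimulus_sequence(cfg.n_trials, cfg.mountain_rate,
                                         cfg.transition_ms, seed=base,
                                         run_id=tag)
            presses, truth = simulate_behavior(
                seq, cfg.rt_mean, cfg.rt_sd, cfg.lapse_rate,
                cfg.omission_rate, seed=seeds["behavior"] + 97 * si + 7 * run)
            rec, truth = simulate_recording(
                seq, truth, effects, coupling=[pair], noise=NoiseSpec(
                    line_freq=cfg.line_freq), fs=cfg.fs,
                seed=base + 1, condition="task", run_id=tag,
                pre_task_s=cfg.pre_task_s)
            write_events(seq, sdir / tag / "events.tsv")
            write_responses(presses, sdir / tag / "responses.tsv")
            write_recording(rec, sdir / tag / "recording")
            write_ground_truth(truth, sdir / tag / "ground_truth.json")

            table = assign_presses(seq, presses)
            score = score_run(table)
            write_trial_table(table, sdir / tag / "trials.tsv")
            write_run_score(score, sdir / tag / "score.json")

            env, _ = preprocess_run(rec, line_freq=cfg.line_freq)
            env = smooth_envelope(env, cfg.smooth_ms)
            write_envelope(env, sdir / tag / "envelope")
            run_envs.append(env)
            run_tables.append(table)
            run_seqs.append(seq)
            run_scores.append(score)

        rest_envs = []
        for run in range(cfg.rest_runs_per_subject):
            tag = f"rest-{run + 1:02d}"
            rec, _ = simulate_recording(
                None, None, effects, coupling=[pair],
                noise=NoiseSpec(line_freq=cfg.line_freq), fs=cfg.fs,
                seed=seeds["synth"] + 97 * si + 1000 + run,
                duration=cfg.n_trials * cfg.transition_ms / 1000.0
                + cfg.pre_task_s, condition="rest", run_id=tag)
            write_recording(rec, sdir / tag / "recording")
            env, _ = preprocess_run(rec, line_freq=cfg.line_freq)
            env = smooth_envelope(env, cfg.smooth_ms)
            write_envelope(env, sdir / tag / "envelope")
            rest_envs.append(env)

        # ---- localization: pool epochs across task runs per channel -------
        results = []
        hfb_epochs: dict[str, dict[str, list]] = {}
        for ch_i, ch in enumerate(run_envs[0].channels):
            tgt_list, base_list = [], []
            for env, table, seq in zip(run_envs, run_tables, run_seqs):
                sel = select_trials(table, seed=seeds["baseline_subsample"]
                                    + 97 * si)
                hfb = env.band("hfb")[ch_i]
                t0 = -cfg.pre_task_s
                tgt = epoch(hfb, env.fs, seq.onsets[sel.targets], t0=t0,
                            valid=env.valid, channel=ch)
                bas = epoch(hfb, env.fs, seq.onsets[sel.baselines], t0=t0,
                            valid=env.valid, channel=ch)
                tgt_list.append(tgt)
                base_list.append(bas)
            tgt_all = tgt_list[0]
            tgt_all.data = np.vstack([e.data for e in tgt_list])
            bas_all = base_list[0]
            bas_all.data = np.vstack([e.data for e in base_list])
            hfb_epochs[ch] = {"targets": tgt_all, "baselines": bas_all}
            results.append(cluster_permutation_test(
                tgt_all, bas_all, n_perm=cfg.n_perm,
                seed=seeds["localize"] + 97 * si + ch_i))
        screened = screen_network(results, chan_table)
        screened.to_csv(sdir / "responsive.tsv", sep="\t", index=False,
                        float_format="%.6g")
        responsive_tables.append(screened)

        # ---- dynamics -----------------------------------------------------
        window_rows = []
        for _, row in screened[screened["retained"]].iterrows():
            ch = row["channel"]
            es = hfb_epochs[ch]["targets"]
            mean_resp = es.data.mean(axis=0)
            rec_ttp = time_to_peak(mean_resp, es.times_ms,
                                   sign=int(row["sign"]), channel=ch)
            ttp_rows.append({"subject": subject, "channel": ch,
                             "network": row["network"],
                             "ttp_ms": rec_ttp.ttp_ms})
            for name, win in (("pre", PRE_WINDOW_MS), ("post", POST_WINDOW_MS)):
                ws = window_mean(es, win)
                window_rows.append({"subject": subject, "channel": ch,
                                    "network": row["network"], "window": name,
                                    "mean": ws.mean})
        pd.DataFrame(window_rows).to_csv(sdir / "window_stats.tsv", sep="\t",
                                         index=False, float_format="%.6g")

        # ---- coupling (task runs and rest runs, DAN0-DMN0 pair) -----------
        pair_idx = (run_envs[0].channels.index(pair.ch_i),
                    run_envs[0].channels.index(pair.ch_j))
        for env, score, seq in zip(run_envs, run_scores, run_seqs):
            res = run_coupling(env.band("hfb")[pair_idx[0]],
                               env.band("hfb")[pair_idx[1]], env.fs,
                               ch_i=pair.ch_i, ch_j=pair.ch_j,
                               condition="task", run_id=env.run_id)
            coupling_rows.append(_coupling_row(subject, res))
            dprime_rows.append({"subject": subject, "run": env.run_id,
                                "d_prime": score.d_prime,
                                "mountain_rate": seq.mountain_rate,
                                "zero_lag_z": res.zero_lag_z,
                                "lag_min_z": res.lag_min_z})
        for env in rest_envs:
            res = run_coupling(env.band("hfb")[pair_idx[0]],
                               env.band("hfb")[pair_idx[1]], env.fs,
                               ch_i=pair.ch_i, ch_j=pair.ch_j,
                               condition="rest", run_id=env.run_id)
            coupling_rows.append(_coupling_row(subject, res))

        # ---- MKL ----------------------------------------------------------
        feats, labels = _mkl_features(cfg, run_envs, run_tables, run_seqs)
        if labels is not None:
            stack = build_kernels(feats, tuple(BAND_TABLE), labels,
                                  seed=seeds["mkl"] + 97 * si)
            n_min = min(np.sum(stack.labels == 0), np.sum(stack.labels == 1))
            n_folds = int(min(10, n_min))
            if n_folds >= 3:
                model = fit_mkl(stack, n_folds=n_folds,
                                seed=seeds["mkl"] + 97 * si)
                mkl_out[subject] = {
                    "balanced_accuracy": model.balanced_accuracy,
                    "class_accuracy": model.class_accuracy,
                    "band_contributions": band_contributions(model),
                    "chosen_C": model.fold_C.tolist(),
                }

    # ---- cohort-level tables and stats ------------------------------------
    ttp_table = pd.DataFrame(ttp_rows)
    ttp_table.to_csv(out / "ttp.tsv", sep="\t", index=False,
                     float_format="%.6g")
    coupling_table = pd.DataFrame(coupling_rows)
    coupling_table.to_csv(out / "coupling.tsv", sep="\t", index=False,
                          float_format="%.6g")
    dprime_table = pd.DataFrame(dprime_rows)
    dprime_table.to_csv(out / "dprime_runs.tsv", sep="\t", index=False,
                        float_format="%.6g")
    write_json(mkl_out, out / "mkl.json")

    stats_out = {}
    for name in cfg.recipes:
        try:
            res = _dispatch_recipe(name, ttp_table, dprime_table,
                                   coupling_table)
        except ValueError as err:
            stats_out[name] = {"error": str(err)}
            continue
        entry = {
            "params": {k: float(v) for k, v in res.params.items()},
            "tests": {t.term: {"F": t.f_stat, "df": [t.df_num, t.df_den],
                               "p": t.p} for t in res.tests.values()},
            "n_obs": res.n_obs,
        }
        if res.adj_r2:
            entry["adj_r2"] = res.adj_r2
        if res.extras:
            entry["extras"] = res.extras
        stats_out[name] = entry
    write_json(stats_out, out / "stats.json")

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seeds": seeds,
        "version": __version__,
        "subjects": subjects,
        "stages": ["synth", "behavior", "preprocess", "localize", "dynamics",
                   "coupling", "mkl", "stats"],
    }
    write_json(manifest, out / "manifest.json")
    return out


def _coupling_row(subject: str, res) -> dict:
    return {"subject": subject, "pair": f"{res.ch_i}|{res.ch_j}",
            "condition": res.condition, "run_id": res.run_id,
            "zero_lag_r": res.zero_lag_r, "zero_lag_z": res.zero_lag_z,
            "lag_min_r": res.lag_min_r, "lag_min_z": res.lag_min_z,
            "lag_at_min_s": res.lag_at_min_s}


def _mkl_features(cfg, run_envs, run_tables, run_seqs):
    """Per-electrode (band x trial) feature arrays over pooled task runs."""
    feats: dict[str, list] = {ch: [] for ch in run_envs[0].channels}
    labels = []
    for env, table, seq in zip(run_envs, run_tables, run_seqs):
        sel = select_trials(table, seed=0)
        trials = np.concatenate([sel.targets, sel.baselines_all])
        lab = np.concatenate([np.ones(len(sel.targets), dtype=int),
                              np.zeros(len(sel.baselines_all), dtype=int)])
        t0 = -cfg.pre_task_s
        # epochs near the record edges are dropped; the drop pattern is
        # shared across channels/bands (the edge mask is global)
        probe = epoch(env.data[0, 0], env.fs, seq.onsets[trials], t0=t0,
                      valid=env.valid)
        keep = np.setdiff1d(np.arange(len(trials)), probe.dropped_trials)
        trials, lab = trials[keep], lab[keep]
        for ch_i, ch in enumerate(env.channels):
            per_band = []
            for band in env.bands:
                es = epoch(env.data[ch_i, env.bands.index(band)], env.fs,
                           seq.onsets[trials], t0=t0, valid=env.valid)
                per_band.append(trial_features(es.data, es.times_ms))
            feats[ch].append(np.vstack(per_band))
        labels.append(lab)
    feats = {ch: np.concatenate(parts, axis=1) for ch, parts in feats.items()}
    labels = np.concatenate(labels)
    if len(np.unique(labels)) < 2:
        return {}, None
    return feats, labels


def _dispatch_recipe(name, ttp_table, dprime_table, coupling_table):
    if name == "ttp_network":
        return run_recipe(name, ttp_table)
    if name == "dprime_coupling":
        return run_recipe(name, dprime_table)
    if name == "task_rest":
        # average runs on the z scale within pair x condition
        agg = coupling_table.groupby(
            ["subject", "pair", "condition"], as_index=False)[
            ["zero_lag_z", "lag_min_z"]].mean()
        return run_recipe(name, agg)
    raise ValueError(f"pipeline does not wire recipe {name!r}")
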