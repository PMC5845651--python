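"""End-to-end pipeline orchestration with run provenance.

A pipeline run simulates a dataset (or loads one), applies trial selection,
and runs the analysis stages, writing every table as CSV plus a markdown
report and a manifest recording seeds, config hash, and per-stage output
digests.  All randomness derives from a single root seed through named
substreams, so adding a stage never perturbs the others and identical
manifests imply bit-identical deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import (
    MazeConfig,
    SelectionCriteria,
    NoTrialsError,
    select_trials,
    write_session_log,
    write_trajectories,
)
from .agents import AgentSpec, TrajectoryParams, simulate_dataset, write_ground_truth
from .psychometrics import fit_psychometric, lapse_rate
from .evidence_weighting import fit_spatial_logistic, weight_decay_ratio, minority_cue_profile
from .choice_models import fit_history_model, StrategyModelSpec, strategy_predict, estimate_side_lapses
from .model_selection import CVScheme, ConstantRateModel, crossval_evaluate, pairwise_run_p
from .kinematics import trajectory_angles_on_grid, choice_decoder, speed_summary, DEFAULT_Y_GRID

DEFAULT_CONFIG = {
    "seed": 0,
    "n_sessions": 8,
    "trials_per_session": 250,
    "agent": {"kind": "k_random_tower", "k": 1, "lapse_r": 0.1, "lapse_l": 0.1},
    "trajectories": True,
    "selection": {"min_trials_per_mouse": 500},
    "cv": {"n_runs": 5, "n_folds": 3},
    "stages": [
        "simulate",
        "select",
        "psychometrics",
        "evidence_weighting",
        "choice_models",
        "model_comparison",
        "kinematics",
    ],
}


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """Named substream: root seed + stage name -> independent generator."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    started: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict) -> None:
        digests = {}
        for name, path in outputs.items():
            p = Path(path)
            digests[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16] if p.exists() else None
        self.stages[stage] = {"outputs": digests, "finished": time.strftime("%Y-%m-%dT%H:%M:%S")}


def _agent_from_config(cfg: dict) -> AgentSpec:
    return AgentSpec(**cfg)


def run_pipeline(config: Optional[dict] = None, out_dir="pipeline_out") -> RunManifest:
    """Execute the configured stages; halts on failure with a partial manifest."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k] = {**cfg[k], **v}
            else:
                cfg[k] = v
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(
        config_hash=hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16],
        seed=seed,
        package_version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    report: list[str] = [f"# accumtowers pipeline report\n\nseed: {seed}\n"]
    stages = cfg["stages"]
    trials = None
    dataset = None
    try:
        if "simulate" in stages:
            traj_params = TrajectoryParams() if cfg.get("trajectories") else None
            dataset = simulate_dataset(
                _agent_from_config(cfg["agent"]),
                n_sessions=int(cfg["n_sessions"]),
                trials_per_session=int(cfg["trials_per_session"]),
                rng=stage_rng(seed, "simulate"),
                trajectory_params=traj_params,
            )
            log_path = out / "sessions.jsonl"
            write_session_log(dataset.trials, log_path)
            write_ground_truth(dataset, out / "ground_truth.json")
            outputs = {"sessions": log_path, "ground_truth": out / "ground_truth.json"}
            if dataset.trajectories is not None:
                write_trajectories(dataset.trajectories, out / "trajectories.csv")
                outputs["trajectories"] = out / "trajectories.csv"
            manifest.record("simulate", outputs)
            trials = dataset.trials
            report.append(f"## simulate\n\n{len(trials)} trials, "
                          f"{cfg['n_sessions']} sessions, agent {cfg['agent']['kind']}\n")

        if "select" in stages and trials is not None:
            kept, ledger = select_trials(trials, SelectionCriteria(**cfg.get("selection", {})))
            pd.DataFrame([asdict(ledger)]).to_csv(out / "selection_ledger.csv", index=False)
            manifest.record("select", {"ledger": out / "selection_ledger.csv"})
            report.append(f"## select\n\nkept {ledger.n_kept}/{ledger.n_input} trials\n")
            trials = kept

        if "psychometrics" in stages and trials:
            fit = fit_psychometric(trials)
            lapse, lapse_ci = lapse_rate(trials)
            pd.DataFrame(
                {
                    "delta": fit.bins.abscissa,
                    "p_right": fit.bins.p_right,
                    "n": fit.bins.n,
                    "ci_low": fit.bins.ci_low,
                    "ci_high": fit.bins.ci_high,
                }
            ).to_csv(out / "psychometric_bins.csv", index=False)
            summary = {
                "b": fit.b, "a": fit.a, "delta0": fit.delta0, "lam_sig": fit.lam_sig,
                "slope_percent_per_tower": fit.slope_percent_per_tower,
                "lapse_percent": lapse, "lapse_ci": list(lapse_ci),
                "overall_accuracy_percent": 100.0 * np.mean([t.correct for t in trials]),
            }
            (out / "psychometric_fit.json").write_text(json.dumps(summary, indent=1))
            manifest.record("psychometrics", {"bins": out / "psychometric_bins.csv",
                                              "fit": out / "psychometric_fit.json"})
            report.append(
                "## psychometrics\n\n"
                f"overall accuracy {summary['overall_accuracy_percent']:.1f}% | "
                f"slope {summary['slope_percent_per_tower']:.2f} %/tower | "
                f"lapse {lapse:.1f}%\n"
            )

        if "evidence_weighting" in stages and trials:
            rng = stage_rng(seed, "evidence_weighting")
            fit = fit_spatial_logistic(trials, n_boot=50, rng=rng)
            ratio, p = weight_decay_ratio(fit, trials, n_shuffle=50, rng=rng)
            prof = minority_cue_profile(trials)
            pd.DataFrame(
                {"bin": np.arange(1, 6), "beta": fit.beta, "beta_sd": fit.beta_sd}
            ).to_csv(out / "spatial_weights.csv", index=False)
            (out / "weight_decay.json").write_text(
                json.dumps({"decay_ratio": ratio, "shuffle_p": p}, indent=1)
            )
            manifest.record("evidence_weighting", {"weights": out / "spatial_weights.csv",
                                                   "decay": out / "weight_decay.json"})
            report.append(f"## evidence weighting\n\ndecay ratio {ratio:.2f} (shuffle p = {p:.3f})\n")

        if "choice_models" in stages and trials:
            hist_fit = fit_history_model(trials, evidence_form="spatial_bins")
            summary = {
                "beta0": hist_fit.params.beta0,
                "beta_delta": hist_fit.params.beta_delta.tolist(),
                "beta_e": hist_fit.params.beta_e,
                "beta0_r": hist_fit.params.beta0_r,
                "beta0_l": hist_fit.params.beta0_l,
                "beta_h": hist_fit.params.beta_h.tolist(),
                "loglik": hist_fit.loglik,
                "penalty": hist_fit.penalty,
            }
            (out / "history_model.json").write_text(json.dumps(summary, indent=1))
            manifest.record("choice_models", {"history_model": out / "history_model.json"})
            report.append(f"## choice models\n\nhistory model lnL {hist_fit.loglik:.1f}\n")

        if "model_comparison" in stages and trials:
            class _HistModel:
                def fit(self, train):
                    return fit_history_model(train, evidence_form="spatial_bins")

            class _EvidenceOnly:
                def fit(self, train):
                    return fit_history_model(train, evidence_form="none")

            scheme = CVScheme(seed=seed, **cfg.get("cv", {}))
            evals = crossval_evaluate(
                {"evidence+history": _HistModel(), "history_only": _EvidenceOnly(),
                 "constant": ConstantRateModel()},
                trials,
                scheme,
            )
            rows = [
                {"model": name, "median_mi_bits_per_trial": ev.median_mi}
                for name, ev in evals.items()
            ]
            p_eh = pairwise_run_p(evals["evidence+history"], evals["history_only"])
            pd.DataFrame(rows).to_csv(out / "model_comparison.csv", index=False)
            (out / "model_comparison.json").write_text(
                json.dumps({"p_evidence_vs_history_only": p_eh}, indent=1)
            )
            manifest.record("model_comparison", {"table": out / "model_comparison.csv"})
            report.append(
                "## model comparison\n\n"
                + "\n".join(f"- {r['model']}: {r['median_mi_bits_per_trial']:.4f} bits/trial"
                            for r in rows)
                + f"\n\nP(evidence model underperforms history-only) = {p_eh:.3f}\n"
            )

        if "kinematics" in stages:
            if dataset is not None and dataset.trajectories is not None:
                key_cols = ["mouse_id", "session_id", "trial_index"]
                angles = trajectory_angles_on_grid(dataset.trajectories)
                keys = {tuple(k) for k in angles[key_cols].to_numpy()}
                sel = [t for t in dataset.trials
                       if (t.mouse_id, t.session_id, t.trial_index) in keys]
                amap = {tuple(r[:3]): r[3:] for r in angles.to_numpy()}
                theta = np.array(
                    [amap[(t.mouse_id, t.session_id, t.trial_index)] for t in sel], dtype=float
                )
                dec = choice_decoder([t.choice for t in sel], theta)
                spd = speed_summary(dataset.trajectories)
                pd.DataFrame(
                    {"y_cm": dec.y_grid, "boundary": dec.boundary,
                     "accuracy_percent": dec.accuracy_percent}
                ).to_csv(out / "choice_decoding.csv", index=False)
                (out / "speed_summary.json").write_text(json.dumps(
                    {"mean_speed": spd.mean_speed,
                     "within_session_sd": spd.within_session_sd,
                     "across_session_sd": spd.across_session_sd}, indent=1))
                manifest.record("kinematics", {"decoding": out / "choice_decoding.csv",
                                               "speed": out / "speed_summary.json"})
                report.append(
                    f"## kinematics\n\nmean speed {spd.mean_speed:.1f} cm/s; "
                    f"decoding at y=200: {dec.accuracy_at(200.0):.1f}%\n"
                )
            else:
                report.append("## kinematics\n\nskipped: no trajectories in this run\n")
    except NoTrialsError as exc:
        report.append(f"\n**halted**: {exc}\n")
        _write_manifest(manifest, out, report)
        raise
    _write_manifest(manifest, out, report)
    return manifest


def _write_manifest(manifest: RunManifest, out: Path, report: list) -> None:
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=1))
    (out / "report.md").write_text("\n".join(report))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
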