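"""End-to-end pipelines: synthetic neural data -> clustering -> statistics,
and RNN train -> evaluate -> cluster -> connection graph -> lesion ->
similarity, with config, logging and reproducible report bundles."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import synth, trajclust, stats, rnn

logger = logging.getLogger("neurocue")


class ConfigValidationError(ValueError):
    pass


@dataclass
class NeuralStageConfig:
    seed: int | None = None
    n_per_cluster: dict = field(default_factory=lambda: {
        "visual": 40, "sustained": 40, "late_accumulation": 40,
        "reorienting": 40, "conscious_report": 40, "null": 100})
    n_trials: int = 200
    noise_sd: float = 1.0
    amplitude: float = 1.0
    interaction_amplitude: float = 0.5
    k_range: list = field(default_factory=lambda: list(range(2, 13)))
    n_restarts: int = 20
    alpha: float = 0.05


@dataclass
class RNNStageConfig:
    seed: int | None = None
    n_units: int = 50
    n_iterations: int = 20000
    batch: int = 50
    lr: float = 1e-2
    contrast: float = 0.10
    eval_batches: int = 20
    lesion_batches: int = 20
    similarity_samples: int = 100
    n_perm: int = 1000


@dataclass
class PipelineConfig:
    """Single config with per-stage sections; every stochastic stage must
    carry an explicit seed."""

    out_dir: str = "runs/neurocue"
    neural: NeuralStageConfig = field(default_factory=NeuralStageConfig)
    rnn: RNNStageConfig = field(default_factory=RNNStageConfig)

    def validate(self, stages: tuple[str, ...] = ("neural", "rnn")) -> None:
        for stage in stages:
            if getattr(self, stage).seed is None:
                raise ConfigValidationError(f"stage {stage!r} has no seed")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(out_dir=raw.get("out_dir", "runs/neurocue"),
                  neural=NeuralStageConfig(**raw.get("neural", {})),
                  rnn=RNNStageConfig(**raw.get("rnn", {})))
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        # hash the analysis-relevant sections only, not the output location
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(out_dir / "pipeline.log")
    logger.addHandler(fh)


def _write_manifest(out_dir: Path, cfg: PipelineConfig, summary: dict) -> None:
    manifest = {"config_hash": cfg.hash(), "config": cfg.to_dict(),
                "summary": summary}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def run_neural_pipeline(cfg: PipelineConfig) -> dict:
    """Synthetic contacts -> trajectory clustering -> time-resolved ANOVA.

    Writes the trial table, cluster solution, stats tables and a summary
    JSON (best k, conscious-report-significant clusters, effect windows)
    under ``cfg.out_dir``; returns the summary dict.
    """
    cfg.validate(stages=("neural",))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    nc = cfg.neural
    logger.info("neural pipeline: seed=%s hash=%s", nc.seed, cfg.hash())

    templates = synth.make_profile_templates(nc.amplitude, nc.interaction_amplitude)
    ds = synth.generate_contacts(templates, nc.n_per_cluster, nc.n_trials,
                                 nc.noise_sd, seed=nc.seed)
    ds.trials.to_csv(out / "trials.csv", index=False)

    trajs = trajclust.trajectories_from_contacts(ds)
    sel = trajclust.select_k(trajs, k_range=nc.k_range,
                             n_restarts=nc.n_restarts, seed=nc.seed)
    sol = sel.solutions[sel.best_k]
    (out / "cluster_solution.json").write_text(sol.to_json())

    vr = ds.validity_report_means()             # (n, 2 validity, 2 report, T)
    sig_clusters = {}
    stats_frames = []
    for c in range(sol.k):
        members = sol.members(c)
        if len(members) < 2:
            continue
        data = vr[members]                       # (m, 2, 2, T)
        res = stats.factorial_anova_timecourse(
            data, ds.times_ms, ("validity", "report"), alpha=nc.alpha)
        frame = res.to_frame()
        frame["cluster"] = c
        stats_frames.append(frame)
        mask = res.significant["report"]
        if mask.any():
            sig_clusters[c] = {
                "n_contacts": int(len(members)),
                "report_windows_ms": _mask_windows(mask, ds.times_ms),
            }
    import pandas as pd
    pd.concat(stats_frames, ignore_index=True).to_csv(
        out / "cluster_stats.csv", index=False)
    summary = {
        "stage": "neural", "seed": nc.seed, "config_hash": cfg.hash(),
        "best_k": sel.best_k,
        "silhouettes": {int(k): float(v) for k, v in sel.silhouettes.items()},
        "n_report_significant_clusters": len(sig_clusters),
        "report_significant_clusters": sig_clusters,
    }
    with open(out / "neural_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _write_manifest(out, cfg, summary)
    return summary


def _mask_windows(mask: np.ndarray, times: np.ndarray) -> list[list[float]]:
    windows, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = times[i]
        elif not m and start is not None:
            windows.append([float(start), float(times[i - 1])])
            start = None
    if start is not None:
        windows.append([float(start), float(times[-1])])
    return windows


def run_rnn_pipeline(cfg: PipelineConfig) -> dict:
    """Train the task model, evaluate psychometrics, cluster units, build
    the E/I connection graph, run lesions and the similarity test."""
    cfg.validate(stages=("rnn",))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    rc = cfg.rnn
    logger.info("rnn pipeline: seed=%s hash=%s", rc.seed, cfg.hash())

    params0 = rnn.init_network(rc.n_units, seed=rc.seed)
    result = rnn.train_network(params0, n_iterations=rc.n_iterations,
                               batch=rc.batch, lr=rc.lr, seed=rc.seed)
    trained = result.params
    np.savez(out / "checkpoint.npz", W_in=trained.W_in, W_rec=trained.W_rec,
             W_out=trained.W_out, b_rec=trained.b_rec, b_out=trained.b_out,
             sign_vector=trained.sign_vector, loss_curve=result.loss_curve)

    trials = rnn.evaluate_performance(trained, n_batches=rc.eval_batches,
                                      batch=rc.batch, seed=rc.seed)
    perf = rnn.performance_summary(trials)
    perf.to_csv(out / "psychometrics.csv", index=False)
    present = perf[perf.validity != "catch"]
    agg = present.groupby("contrast").detection_rate.mean()
    fit = rnn.fit_psychometric(agg.index.to_numpy(), agg.to_numpy())

    try:
        clusters = rnn.cluster_units(trained, contrast=rc.contrast, seed=rc.seed)
    except ValueError as first_err:
        logger.warning("unit clustering at contrast %.2f failed (%s); "
                       "retrying at the highest training contrast", rc.contrast,
                       first_err)
        try:
            clusters = rnn.cluster_units(trained, contrast=rnn.MAX_CONTRAST,
                                         seed=rc.seed)
        except ValueError as err:
            logger.warning("unit clustering skipped: %s", err)
            summary = {
                "stage": "rnn", "seed": rc.seed, "config_hash": cfg.hash(),
                "final_loss": float(result.loss_curve[-1, 1]),
                "psychometric_midpoint": fit.midpoint,
                "cluster_error": str(err),
            }
            with open(out / "rnn_summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            _write_manifest(out, cfg, summary)
            return summary
    (out / "unit_clusters.json").write_text(clusters.solution.to_json())

    groups = rnn.ei_groups(trained, clusters.solution, clusters.labels)
    graph = rnn.connection_graph(trained, groups) if groups else None
    if graph is not None:
        graph.edges.to_csv(out / "connection_graph.csv", index=False)

    named = {name: clusters.solution.members(c)
             for c, name in clusters.labels.items() if not name.startswith("other")}
    lesions = rnn.lesion_experiment(trained, named,
                                    n_batches=rc.lesion_batches,
                                    batch=rc.batch, seed=rc.seed)
    lesions.to_csv(out / "lesion_table.csv", index=False)

    untrained = rnn.init_network(rc.n_units, seed=rc.seed + 1)
    neural_cfg = PipelineConfig(out_dir=str(out), neural=cfg.neural, rnn=rc)
    templates = synth.make_profile_templates()
    neural_times = synth.DEFAULT_TIMES_MS
    neural_trajs = {}
    for c, name in clusters.labels.items():
        if name.startswith("other") or name not in templates:
            continue
        tpl = templates[name]
        seen = 0.5 * (tpl.mean(neural_times, "valid", "seen")
                      + tpl.mean(neural_times, "invalid", "seen"))
        unseen = tpl.mean(neural_times, "valid", "unseen")
        neural_trajs[name] = np.stack([seen, unseen])
    sim = rnn.similarity_test(
        trained, untrained,
        {name: clusters.solution.members(c)
         for c, name in clusters.labels.items() if name in neural_trajs},
        neural_trajs, neural_times, contrast=rc.contrast,
        n_samples=rc.similarity_samples, n_perm=rc.n_perm, seed=rc.seed)
    sim.to_csv(out / "similarity.csv", index=False)

    summary = {
        "stage": "rnn", "seed": rc.seed, "config_hash": cfg.hash(),
        "final_loss": float(result.loss_curve[-1, 1]),
        "psychometric_midpoint": fit.midpoint,
        "best_k": clusters.select.best_k,
        "silhouettes": {int(k): float(v)
                        for k, v in clusters.select.silhouettes.items()},
        "cluster_labels": {int(c): n for c, n in clusters.labels.items()},
        "lesion_intact_rows": int((lesions.lesion == "intact").sum()),
    }
    with open(out / "rnn_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _write_manifest(out, cfg, summary)
    return summary
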