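"""Stage orchestration: simulate -> pretrain -> extract -> cluster ->
annotate -> prognose -> report, with config-hash stamping so that every
artifact records the exact configuration and seed that produced it and
stale mixtures of stages are refused.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, clustering, io, prognosis, synthetic
from .augment import AugmentationPolicy
from .byol import TrainConfig, extract_features, load_checkpoint, save_checkpoint, train_byol

STAGES = ["simulate", "pretrain", "extract", "cluster", "annotate", "prognose", "report"]


class PipelineError(RuntimeError):
    pass


def default_config() -> dict:
    return {
        "cohort": {"n_patients": 120, "eyes_per_patient": 1, "visits_per_eye": 3},
        "image_size": [64, 64],
        "train": {"steps": 500, "batch_size": 64},
        "policy": {},
        "k": 6,
        "benchmark": {"n_seeds": 3, "n_folds": 10},
        "n_attribution_examples": 4,
    }


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    base = default_config()
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            base[key].update(val)
        else:
            base[key] = val
    return base


def _stamp(outdir: Path, stage: str, config: dict, seed: int):
    (outdir / f"{stage}.stamp.json").write_text(
        json.dumps({"stage": stage, "config_hash": config_hash(config),
                    "seed": seed, "config": config}, indent=2, default=str))


def _check_stamp(outdir: Path, stage: str, config: dict):
    path = outdir / f"{stage}.stamp.json"
    if not path.exists():
        raise PipelineError(f"missing upstream artifact: run stage '{stage}' first")
    stamp = json.loads(path.read_text())
    if stamp["config_hash"] != config_hash(config):
        old, new = stamp["config"], config
        diff = sorted({k for k in set(old) | set(new) if old.get(k) != new.get(k)})
        raise PipelineError(f"config hash mismatch with stage '{stage}'; "
                            f"differing keys: {diff}")


def run_pipeline(config: dict, outdir, seed: int = 0, stages=None) -> dict:
    """Run the requested stages in dependency order; returns artifact paths."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    h, w = config["image_size"]
    if "simulate" in stages:
        cc = synthetic.CohortConfig(image_size=(h, w), seed=seed, **config["cohort"])
        images, visits, truth = synthetic.generate_cohort(cc)
        np.save(outdir / "images.npy", images)
        io.write_manifest(visits, outdir / "manifest.csv")
        np.save(outdir / "masks.npy", truth.masks)
        truth.conversions.to_csv(outdir / "conversions.csv", index=False,
                                 float_format="%.6g")
        pd.DataFrame({"class_label": truth.class_labels}).to_csv(
            outdir / "class_labels.csv", index=False)
        with open(outdir / "truth.json", "w") as f:
            json.dump({"outcome_coeffs": truth.outcome_coeffs}, f, indent=2, default=str)
        _stamp(outdir, "simulate", config, seed)
        artifacts["manifest"] = outdir / "manifest.csv"

    if "pretrain" in stages:
        _check_stamp(outdir, "simulate", config)
        images = np.load(outdir / "images.npy")
        policy = AugmentationPolicy(out_size=(h, w), **config["policy"])
        tc = TrainConfig(seed=seed, **config["train"])
        state = train_byol(images, policy, tc)
        save_checkpoint(state, outdir / "checkpoint.h5")
        pd.DataFrame(state.log, columns=["step", "loss"]).to_csv(
            outdir / "trainlog.csv", index=False, float_format="%.6g")
        _stamp(outdir, "pretrain", config, seed)
        artifacts["checkpoint"] = outdir / "checkpoint.h5"

    if "extract" in stages:
        _check_stamp(outdir, "pretrain", config)
        state = load_checkpoint(outdir / "checkpoint.h5")
        images = np.load(outdir / "images.npy")
        feats = extract_features(state, images)
        io.save_features(feats, outdir / "features.h5")
        _stamp(outdir, "extract", config, seed)
        artifacts["features"] = outdir / "features.h5"

    if "cluster" in stages:
        _check_stamp(outdir, "extract", config)
        feats = io.load_features(outdir / "features.h5")
        visits = io.read_manifest(outdir / "manifest.csv")
        model = clustering.kmeans_fit(feats, k=config["k"], seed=seed)
        clustering.order_clusters_by_va(model, visits["letters"].to_numpy(float))
        model.save(outdir / "cluster_model.h5")
        ids = clustering.assign(feats, model)
        sim = clustering.similarity_matrix(feats, model)
        visits["cluster_id"] = ids
        for j in range(model.k):
            visits[f"sim_{j + 1}"] = sim[:, j]
        io.write_manifest(visits, outdir / "manifest_clustered.csv")
        _stamp(outdir, "cluster", config, seed)
        artifacts["cluster_model"] = outdir / "cluster_model.h5"

    if "annotate" in stages:
        _check_stamp(outdir, "cluster", config)
        visits = io.read_manifest(outdir / "manifest_clustered.csv")
        feats = io.load_features(outdir / "features.h5")
        model = clustering.ClusterModel.load(outdir / "cluster_model.h5")
        ids = visits["cluster_id"].to_numpy()
        mat, flagged = annotation.stage_cluster_matrix(ids, visits["grading_label"])
        mat.to_csv(outdir / "stage_cluster.csv", float_format="%.6g")
        table = annotation.cluster_summary_table(ids, visits["patient_id"])
        table.to_csv(outdir / "summary_table.csv", index=False, float_format="%.6g")
        probe = annotation.fit_linear_probe(model.transform(feats), ids,
                                            mean=model.mean, sd=model.sd)
        state = load_checkpoint(outdir / "checkpoint.h5")
        images = np.load(outdir / "images.npy")
        rng = np.random.default_rng(seed)
        panels = annotation.sample_review_panels(ids, visits["patient_id"], rng)
        lines = ["# Cluster review panels", ""]
        for c, panel in panels.items():
            lines.append(f"## Cluster {c} (seen {len(panel.seen)}, "
                         f"unseen {len(panel.unseen)})")
            lines.append(f"seen: {panel.seen}")
            lines.append(f"unseen: {panel.unseen}")
            lines.append("")
        (outdir / "panels.md").write_text("\n".join(lines))
        n_ex = int(config.get("n_attribution_examples", 4))
        for i in rng.choice(len(images), size=min(n_ex, len(images)), replace=False):
            att = annotation.gradcam_attribution(state, probe, images[i], int(ids[i]))
            io.save_image_png(att.map, outdir / f"attribution_{i}.png")
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(mat.to_numpy(dtype=float), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(mat.index)), [f"C{c}" for c in mat.index])
        ax.set_title("P(grading stage | cluster)")
        fig.tight_layout()
        fig.savefig(outdir / "stage_cluster.png", dpi=100)
        plt.close(fig)
        _stamp(outdir, "annotate", config, seed)
        artifacts["summary_table"] = outdir / "summary_table.csv"

    if "prognose" in stages:
        _check_stamp(outdir, "cluster", config)
        visits = io.read_manifest(outdir / "manifest_clustered.csv")
        feats = io.load_features(outdir / "features.h5")
        conversions = pd.read_csv(outdir / "conversions.csv")
        outcomes = prognosis.build_outcomes(visits, conversions)
        bench = prognosis.run_benchmark(feats, outcomes, k=config["k"],
                                        **config["benchmark"], seed0=seed)
        bench.grid.to_csv(outdir / "benchmark_grid.csv", index=False,
                          float_format="%.6g")
        bench.summary.to_csv(outdir / "benchmark_summary.csv", index=False,
                             float_format="%.6g")
        strat = prognosis.va_stratification(visits["cluster_id"].to_numpy(),
                                            visits["letters"].to_numpy(float))
        strat.to_csv(outdir / "va_stratification.csv", index=False,
                     float_format="%.6g")
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 3))
        err = np.nan_to_num((strat["mean"] - strat["ci_lo"]).to_numpy())
        ax.bar(strat["cluster"], strat["mean"], yerr=err, color="steelblue")
        ax.set_xlabel("ordered cluster")
        ax.set_ylabel("mean letters")
        fig.tight_layout()
        fig.savefig(outdir / "va_stratification.png", dpi=100)
        plt.close(fig)
        _stamp(outdir, "prognose", config, seed)
        artifacts["benchmark"] = outdir / "benchmark_summary.csv"

    if "report" in stages:
        _check_stamp(outdir, "annotate", config)
        _check_stamp(outdir, "prognose", config)
        summary = pd.read_csv(outdir / "benchmark_summary.csv")
        table = pd.read_csv(outdir / "summary_table.csv")
        lines = ["# Pipeline report", "",
                 f"config hash: {config_hash(config)}  seed: {seed}", "",
                 "## Cluster summary", table.to_markdown(index=False), "",
                 "## Benchmark (MAE mean +/- SD over folds x seeds)",
                 summary.to_markdown(index=False), ""]
        (outdir / "report.md").write_text("\n".join(lines))
        _stamp(outdir, "report", config, seed)
        artifacts["report"] = outdir / "report.md"

    return artifacts
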