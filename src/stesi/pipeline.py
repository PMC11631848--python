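"""Experiment orchestration: in-domain and cross-simulator evaluation runs.

An experiment builds a head model, simulates a dataset with one of the two
generators, trains the requested networks on the training split, solves the
validation split with every requested method, evaluates the five-metric
suite per sample, and renders per-method mean/std tables plus the
ANOVA/Tukey comparison.  The out-of-domain run reuses models trained on one
generator and evaluates them on a dataset from the other; the linear
baselines do not train and are therefore identical across the two reports.

Every artifact is stamped with the config hash and master seed; all
per-stage randomness is derived from the master seed keyed by stage name
and sample index, so adding methods never perturbs data generation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import Dataset, derive_seed, generate_dataset
from .head_model import build_spherical_head
from .inverse import InverseConfig, mne_solve, sloreta_solve
from .metrics import METRIC_FIELDS, ComparisonTable, compare_methods, evaluate_sample
from .networks import ArchitectureSpec, TrainConfig, build_model, predict, train
from .nmm import NMMConfig
from .sereega import SereegaConfig

__all__ = ["ExperimentConfig", "run_in_domain", "run_out_of_domain",
           "render_report", "solve_dataset", "train_networks"]

log = logging.getLogger(__name__)

# lower-is-better / higher-is-better direction per metric, for the reports
METRIC_DIRECTION = {"le_mm": "down", "auc_pct": "up", "nmse": "down",
                    "psnr_db": "up", "time_error_ms": "down"}


@dataclass
class ExperimentConfig:
    """Configuration of one experiment run (toy-scale defaults)."""

    n_electrodes: int = 32
    n_sources_full: int = 400
    n_regions: int = 50
    shell_radii: tuple = (79.0, 82.0, 87.0)
    conductivities: tuple = (0.3, 0.006, 0.3)
    generator: str = "sereega"              # "sereega" | "nmm"
    generator_options: dict = field(default_factory=dict)
    n_samples: int = 200
    split: float = 0.8
    methods: tuple = ("mne", "sloreta")
    arch_options: dict = field(default_factory=dict)
    train_options: dict = field(default_factory=dict)
    inverse_lambda: float | str = "auto"
    multi_source_le: str = "global"
    output_dir: str | None = None
    master_seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def generator_config(self):
        seed = derive_seed(self.master_seed, "simulate", self.generator)
        if self.generator == "sereega":
            return SereegaConfig(rng_seed=seed, **self.generator_options)
        if self.generator == "nmm":
            return NMMConfig(rng_seed=seed, **self.generator_options)
        raise ValueError(f"unknown generator {self.generator!r}")

    def architecture(self, kind: str) -> ArchitectureSpec:
        opts = dict(self.arch_options)
        return ArchitectureSpec(kind=kind, n_electrodes=self.n_electrodes,
                                n_sources=self.n_regions, **opts)


def _build_head(cfg: ExperimentConfig):
    return build_spherical_head(
        n_electrodes=cfg.n_electrodes, n_sources_full=cfg.n_sources_full,
        n_regions=cfg.n_regions, shell_radii=cfg.shell_radii,
        conductivities=cfg.conductivities,
        rng_seed=derive_seed(cfg.master_seed, "head"))


def train_networks(cfg: ExperimentConfig, head, dataset: Dataset) -> dict:
    """Train every learned method in cfg.methods; returns {kind: (model, hist)}."""
    out = {}
    for kind in cfg.methods:
        if kind in ("mne", "sloreta"):
            continue
        t0 = time.perf_counter()
        spec = cfg.architecture(kind)
        model = build_model(spec, rng_seed=derive_seed(cfg.master_seed, "init", kind))
        tc = TrainConfig(rng_seed=derive_seed(cfg.master_seed, "train", kind),
                         **cfg.train_options)
        model, hist = train(model, dataset, tc)
        log.info("trained %s: %d epochs, best val %.4f (%.1f s)", kind,
                 hist["epochs_run"], hist["best_val_loss"],
                 time.perf_counter() - t0)
        out[kind] = (model, hist)
    return out


def solve_dataset(cfg: ExperimentConfig, head, samples, models: dict) -> list:
    """Apply every method to each sample; returns MetricReport list."""
    inv_cfg_kwargs = {"lambda_": cfg.inverse_lambda}
    reports = []
    for i, sample in enumerate(samples):
        for kind in cfg.methods:
            if kind == "mne":
                sol = mne_solve(head.leadfield_regional, sample.Y,
                                InverseConfig(method="mne",
                                              snr_assumed_db=sample.snr_db,
                                              **inv_cfg_kwargs))
            elif kind == "sloreta":
                sol = sloreta_solve(head.leadfield_regional, sample.Y,
                                    InverseConfig(method="sloreta",
                                                  snr_assumed_db=sample.snr_db,
                                                  **inv_cfg_kwargs))
            else:
                sol = predict(models[kind][0], sample.Y, head.leadfield_regional)
            rep = evaluate_sample(sample, sol, head,
                                  multi_source=cfg.multi_source_le)
            rep.sample_id = i
            reports.append(rep)
    return reports


def render_report(reports, comparison: ComparisonTable | None,
                  out_dir: str | None = None, stamp: dict | None = None):
    """Per-method mean/std table (metrics as rows) + optional comparison.

    Returns (summary DataFrame, files written).  The best method per metric
    is marked in a machine-readable ``best_<metric>`` column of the JSON
    stamp, honouring each metric's direction.
    """
    df = pd.DataFrame([r.as_dict() for r in reports])
    if df.empty:
        raise ValueError("no reports to render")
    means = df.groupby("method")[list(METRIC_FIELDS)].mean().T
    stds = df.groupby("method")[list(METRIC_FIELDS)].std().T
    means.index.name = "metric"
    best = {}
    for metric in METRIC_FIELDS:
        row = means.loc[metric]
        best[f"best_{metric}"] = (row.idxmin() if METRIC_DIRECTION[metric] == "down"
                                  else row.idxmax())
    files = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mpath = out / "metric_means.csv"
        means.to_csv(mpath)
        stds.to_csv(out / "metric_stds.csv")
        meta = {"directions": METRIC_DIRECTION, **best, **(stamp or {})}
        if comparison is not None:
            comparison.anova.to_csv(out / "anova.csv")
            meta["tukey"] = {m: comparison.tukey[m].to_dict()
                             for m in comparison.tukey}
        (out / "report.json").write_text(json.dumps(meta, indent=2, default=str))
        files = [str(mpath)]
    return means, best, files


def _stamp(cfg: ExperimentConfig, extra=None) -> dict:
    base = {"config_hash": cfg.config_hash(), "master_seed": cfg.master_seed,
            "git_describe": _git_describe()}
    base.update(extra or {})
    return base


def _git_describe() -> str:
    import subprocess
    try:
        return subprocess.run(["git", "describe", "--always", "--dirty"],
                              capture_output=True, text=True, timeout=5,
                              check=False).stdout.strip() or "unknown"
    except Exception:
        return "unknown"


def run_in_domain(cfg: ExperimentConfig):
    """Train and evaluate all methods on one generator's data."""
    head = _build_head(cfg)
    dataset = generate_dataset(head, cfg.generator_config(), cfg.n_samples,
                               split=cfg.split, master_seed=cfg.master_seed)
    models = train_networks(cfg, head, dataset)
    reports = solve_dataset(cfg, head, dataset.validation, models)
    comparison = compare_methods(reports) if len(cfg.methods) > 1 else None
    means, best, _ = render_report(
        reports, comparison, cfg.output_dir,
        _stamp(cfg, {"experiment": "in_domain", "generator": cfg.generator}))
    return {"head": head, "dataset": dataset, "models": models,
            "reports": reports, "comparison": comparison, "means": means,
            "best": best}


def run_out_of_domain(cfg_train: ExperimentConfig, cfg_eval: ExperimentConfig):
    """Evaluate models trained under cfg_train on cfg_eval's generator."""
    for f in ("n_electrodes", "n_sources_full", "n_regions", "shell_radii",
              "conductivities", "master_seed"):
        if getattr(cfg_train, f) != getattr(cfg_eval, f):
            raise ValueError(f"head-model mismatch between configs: {f}")
    head = _build_head(cfg_train)
    ds_train = generate_dataset(head, cfg_train.generator_config(),
                                cfg_train.n_samples, split=cfg_train.split,
                                master_seed=cfg_train.master_seed)
    models = train_networks(cfg_train, head, ds_train)
    ds_eval = generate_dataset(head, cfg_eval.generator_config(),
                               cfg_eval.n_samples, split=cfg_eval.split,
                               master_seed=cfg_eval.master_seed)
    cfg_mixed = cfg_eval
    reports = solve_dataset(cfg_train, head, ds_eval.validation, models)
    for r in reports:
        r.degenerate_flags["eval_generator"] = cfg_mixed.generator
    comparison = compare_methods(reports) if len(cfg_train.methods) > 1 else None
    means, best, _ = render_report(
        reports, comparison, cfg_eval.output_dir,
        _stamp(cfg_train, {"experiment": "out_of_domain",
                           "train_generator": cfg_train.generator,
                           "eval_generator": cfg_eval.generator}))
    return {"head": head, "models": models, "reports": reports,
            "comparison": comparison, "means": means, "best": best,
            "eval_dataset": ds_eval}
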