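"""Reproducible experiment orchestration.

A manifest names a cohort of networks (seeds), the task set and intrinsic
values, the training budget and the analyses to run.  ``run_experiment``
trains (or reloads) each network, runs the requested analyses, and writes
a results bundle of checkpoints, trial logs and tidy tables keyed by
network id and seed.  Reruns with an identical manifest skip work that is
already on disk (content-hash match).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, neuro, ppo, taskenv
from .network import NetworkConfig, init_params, load_checkpoint, save_checkpoint
from .ppo import PPOConfig, evaluate, evaluate_criteria, run_trials, train
from .utils import derive_rng


@dataclass
class ExperimentManifest:
    name: str
    tasks: list
    seeds: list
    rho: dict = field(default_factory=lambda: dict(taskenv.DEFAULT_RHO))
    n_neurons: int = 256
    frac_exc: float = 0.8
    max_env_steps: int = 20_000_000
    analyses: list = field(default_factory=list)
    out_dir: str = "results"
    constrained_offers: bool = False
    eval_trials_per_task: int = 1000
    ppo_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be unique")
        unknown = set(self.tasks) - set(taskenv.TASK_NAMES)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentManifest":
        with open(path) as f:
            return cls(**yaml.safe_load(f))


def _network_dir(manifest: ExperimentManifest, seed: int) -> Path:
    return Path(manifest.out_dir) / manifest.name / f"net_{seed:04d}"


def train_or_load(manifest: ExperimentManifest, seed: int, verbose=False):
    """Train one cohort member, or reload it when the manifest hash matches."""
    d = _network_dir(manifest, seed)
    d.mkdir(parents=True, exist_ok=True)
    ckpt = d / "checkpoint.h5"
    meta = d / "meta.json"
    h = manifest.content_hash()
    if ckpt.exists() and meta.exists():
        info = json.loads(meta.read_text())
        if info.get("manifest_hash") == h:
            try:
                log = pd.read_csv(d / "training_log.csv")
            except (pd.errors.EmptyDataError, FileNotFoundError):
                log = pd.DataFrame()
            return load_checkpoint(ckpt), log, True
    specs_all = taskenv.make_tasks(manifest.rho)
    specs = [specs_all[t] for t in manifest.tasks]
    ncfg = NetworkConfig(n_neurons=manifest.n_neurons,
                         frac_exc=manifest.frac_exc)
    rng = derive_rng(seed, "train")
    params = init_params(ncfg, rng)
    cfg = PPOConfig(max_env_steps=manifest.max_env_steps,
                    **manifest.ppo_overrides)
    sampler = taskenv.constrained_offer_sampler if manifest.constrained_offers else None
    params, report = train(params, specs, cfg, rng, rho=manifest.rho,
                           offer_sampler=sampler, verbose=verbose)
    save_checkpoint(ckpt, params, extra={"seed": seed})
    report.to_csv(d / "training_log.csv", index=False)
    meta.write_text(json.dumps({
        "manifest_hash": h, "seed": seed,
        "criteria_met": bool(report.attrs.get("criteria_met", False)),
        "total_trials": int(report.attrs.get("total_trials", 0)),
    }))
    return params, report, False


def analyze_behavior(manifest, seed, params) -> dict:
    specs_all = taskenv.make_tasks(manifest.rho)
    fits = {}
    for t in manifest.tasks:
        rng = derive_rng(seed, "behavior", t)
        frame, _ = run_trials(params, specs_all[t], manifest.eval_trials_per_task,
                              rng, rho=manifest.rho)
        if frame["completed"].sum() < 50:
            continue
        fit = behavior.fit_behavior(frame, t)
        fits[t] = fit.params_vector() | {
            "log_likelihood": fit.log_likelihood, "n_trials": fit.n_trials,
            "separable": fit.separable,
        }
    return fits


def analyze_dimensionality(manifest, seed, params) -> dict:
    specs_all = taskenv.make_tasks(manifest.rho)
    out = {}
    for t in manifest.tasks:
        rng = derive_rng(seed, "rates", t)
        tensor = neuro.collect_rate_tensor(
            params, specs_all[t], min(manifest.eval_trials_per_task, 1000),
            rng, rho=manifest.rho)
        epoch = "offer2" if specs_all[t].sequential else "offer"
        act = neuro.offer_window_activity(tensor, epoch=epoch)
        exc = params.dale_sign > 0
        out[t] = {
            "pr_all": neuro.participation_ratio(act),
            "pr_exc": neuro.participation_ratio(act[:, exc]),
            "pr_inh": neuro.participation_ratio(act[:, ~exc]),
        }
    return out


ANALYSES = {
    "behavior": analyze_behavior,
    "dimensionality": analyze_dimensionality,
}


def run_experiment(manifest: ExperimentManifest, verbose=False) -> dict:
    """Train/load the cohort and run the requested analyses.

    Returns the results bundle as a dict; every table is also written under
    ``out_dir/name``.  Per-network failures are isolated and reported.
    """
    bundle = {"manifest": dataclasses.asdict(manifest),
              "hash": manifest.content_hash(), "networks": {}, "errors": {}}
    for seed in manifest.seeds:
        try:
            params, report, cached = train_or_load(manifest, seed, verbose=verbose)
            entry = {
                "cached": cached,
                "criteria_met": bool(report.attrs.get("criteria_met", report["criteria_met"].iloc[-1] if "criteria_met" in report else False)),
                "checkpoint": str(_network_dir(manifest, seed) / "checkpoint.h5"),
            }
            for name in manifest.analyses:
                entry[name] = ANALYSES[name](manifest, seed, params)
            bundle["networks"][seed] = entry
        except Exception as exc:  # isolate per-network failures
            bundle["errors"][seed] = repr(exc)
    out = Path(manifest.out_dir) / manifest.name
    out.mkdir(parents=True, exist_ok=True)
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2, default=str))
    return bundle
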