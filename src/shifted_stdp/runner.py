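"""Config-driven experiment runner with manifests and tabular outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import metrics
from .lif_core import run_simulation
from .presets import ExperimentConfig
from .spike_gen import generate_ensemble

__all__ = ["run_experiment", "RunManifest", "run_single"]

log = logging.getLogger("shifted_stdp.runner")


def _config_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_config_dict(v) for v in obj]
    return obj


def _config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    name: str
    seeds: list
    outputs: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def run_single(config: ExperimentConfig, seed: int, free_run: bool = False):
    """Execute one (non-scan) run; returns (record, metrics dict)."""
    config.validate()
    rule = None if config.rule_kind == "none" else config.rule
    ensemble = generate_ensemble(config.ensemble, config.duration, seed=seed)
    rec = run_simulation(
        ensemble, config.neuron, config.synapses, rule,
        duration=config.duration, dt=config.dt,
        snapshot_every=config.snapshot_every, seed=seed,
    )
    w_max = getattr(rule, "w_max", None) if config.rule_kind == "pair" else None
    if config.rule_kind == "jittered":
        w_max = config.rule.base.w_max
    elif config.rule_kind == "triplet":
        w_max = config.rule.pair.w_max
    bounds = (0.0, w_max)
    try:
        modality = metrics.summarize_weights(rec.final_weights, bounds=bounds).modality
    except ValueError:  # too few synapses to classify
        modality = "unclassifiable"
    out = {
        "seed": seed,
        "postsynaptic_rate_hz": rec.postsynaptic_rate,
        "mean_weight_mv": float(rec.final_weights.mean()),
        "std_weight_mv": float(rec.final_weights.std()),
        "modality": modality,
    }
    try:
        out["steady_state"] = metrics.steady_state_reached(
            rec.snapshot_times, rec.snapshots, rec.post_spikes,
            window=config.steady_state_window, tol=config.steady_state_tol,
        )
    except ValueError:
        out["steady_state"] = None
    try:
        out["isi_cv"] = metrics.isi_cv(rec.post_spikes)
    except ValueError:
        out["isi_cv"] = None
    if config.ensemble.n_correlated and config.ensemble.correlated_fraction < 1.0:
        comp = metrics.competition_outcome(rec.final_weights, ensemble.group_labels)
        out["mean_correlated_mv"] = comp.mean_correlated
        out["mean_uncorrelated_mv"] = comp.mean_uncorrelated
        out["winner"] = comp.winner
    if free_run:
        from .lif_core import free_run_stats

        mv, sv = free_run_stats(
            generate_ensemble(config.ensemble, min(config.duration, 100.0), seed=seed + 1),
            config.neuron, config.synapses, rec.final_weights,
            duration=min(config.duration, 100.0), dt=config.dt, seed=seed + 1,
        )
        out["mean_v_over_theta"] = mv
        out["std_v_over_theta"] = sv
    log.info("run %s seed=%d rate=%.2fHz w=%.3fmV %s",
             config.name, seed, out["postsynaptic_rate_hz"], out["mean_weight_mv"],
             out["modality"])
    return rec, out


def run_experiment(config: ExperimentConfig, out_dir, seed: int = 0,
                   free_run: bool = False) -> RunManifest:
    """Execute a config (single run or scan), persisting results and a manifest.

    Scans are resumable: grid points whose result file already exists under
    the manifest's hash are skipped.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    seeds = [seed + k for k in range(config.n_seeds)]
    outputs = []

    points = [(None, config)] if config.scan_param is None else [
        (v, config.with_scan_value(v)) for v in config.scan_grid
    ]
    rows = []
    for value, cfg in points:
        for s in seeds:
            tag = f"{config.name}_{chash}" + (
                f"_{config.scan_param.split('.')[-1]}={value:g}" if value is not None else ""
            ) + f"_seed{s}"
            res_path = out_dir / f"{tag}.json"
            if res_path.exists():
                with open(res_path) as fh:
                    row = json.load(fh)
                log.info("skipping completed point %s", tag)
            else:
                rec, row = run_single(cfg, s, free_run=free_run)
                if value is not None:
                    row[config.scan_param] = float(value)
                with open(res_path, "w") as fh:
                    json.dump(row, fh, indent=2)
                rec.snapshots_to_csv(out_dir / f"{tag}_snapshots.csv")
                outputs.append(str(out_dir / f"{tag}_snapshots.csv"))
            rows.append(row)
            outputs.append(str(res_path))

    import pandas as pd

    table = pd.DataFrame(rows)
    table_path = out_dir / f"{config.name}_{chash}_results.csv"
    table.to_csv(table_path, index=False)
    outputs.append(str(table_path))
    manifest = RunManifest(config_hash=chash, name=config.name, seeds=seeds, outputs=outputs)
    manifest.to_json(out_dir / f"{config.name}_{chash}_manifest.json")
    return manifest
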