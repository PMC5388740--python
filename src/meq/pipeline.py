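"""End-to-end pipeline: simulate -> detect -> analyze -> classify -> decode.

``run_pipeline`` drives every stage off a single seed and returns a
structured report; each report quantity names the stage and parameters
that produced it.  Stage failures abort with a stage-tagged error.
"""

from __future__ import annotations

import numpy as np

from .analysis import movement_onsets
from .classification import classify_population, summarize_population
from .decoder import NetworkSpec, assemble_dataset, train_network
from .synth import (KinematicsModel, TaskConfig, generate_session,
                    make_reference_population, simulate_rate_pool)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_CONFIG = {
    "n_cells": 8,
    "n_trials_per_condition": 4,
    "amplitudes": (10.0, 20.0),
    "seed": 0,
    "decode": True,
    "decoder_samples_per_stratum": 20,
    "decoder_trials_per_stratum": 6,
    "use_traces": False,      # trace-free fast path for large populations
}


def run_pipeline(config: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed, "config": {k: v for k, v in cfg.items()}}

    try:
        cells = cfg.get("cells") or make_reference_population(
            seed=seed, n_cells=int(cfg["n_cells"]))
        task = TaskConfig(n_trials_per_condition=int(cfg["n_trials_per_condition"]),
                          amplitudes=tuple(cfg["amplitudes"]), seed=seed)
        kin = cfg.get("kinematics") or KinematicsModel()
        trials = generate_session(task, kin, cells, seed=seed,
                                  include_traces=bool(cfg["use_traces"]))
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc
    report["n_trials"] = len(trials)
    report["n_cells"] = len(cells)

    try:
        onsets = movement_onsets(trials)
        intervals = [h - s for s, h in onsets.values()
                     if s is not None and h is not None]
        report["kinematics"] = {
            "stage": "movement detection (saccade 20 deg/s, hand 1% of peak)",
            "n_eye_hand_pairs": len(intervals),
            "eye_hand_interval_mean_ms": float(np.mean(intervals)) if intervals else None,
            "eye_hand_interval_sd_ms": float(np.std(intervals, ddof=1)) if len(intervals) > 1 else None,
        }
    except Exception as exc:
        raise PipelineError(f"kinematics: {exc}") from exc

    try:
        classifications = classify_population(
            trials, len(cells), onsets=onsets,
            cell_ids=[c.cell_id for c in cells], seed=seed)
        summary = summarize_population(classifications)
        report["classification"] = {
            "stage": "screen + four-column labels",
            "counts": summary["counts"],
            "true_labels": [c.true_labels() for c in cells],
        }
        report["_classifications"] = classifications
    except Exception as exc:
        raise PipelineError(f"classify: {exc}") from exc

    if cfg["decode"]:
        try:
            pool_task = TaskConfig(
                n_trials_per_condition=int(cfg["decoder_trials_per_stratum"]),
                amplitudes=(10.0,), seed=seed + 1)
            pool = simulate_rate_pool(cells, pool_task, kin, seed=seed + 1)
            ds = assemble_dataset(pool, "direction", pool_task.conditions,
                                  pool_task.directions,
                                  int(cfg["decoder_samples_per_stratum"]),
                                  seed=seed)
            spec = NetworkSpec(output_units=len(pool_task.directions),
                               restarts=int(cfg.get("decoder_restarts", 3)))
            net = train_network(ds, spec, seed=seed)
            report["decoder"] = {
                "stage": "55-50-8-style tanh network, direction task",
                "n_samples": len(ds),
                "direction_accuracy": net.test_accuracy,
                "chance": 1.0 / ds.n_classes,
            }
        except Exception as exc:
            raise PipelineError(f"decode: {exc}") from exc
    return report
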