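"""Session files, configuration and the packaged reference classification table.

A session is one JSONL file (one trial per line, self-describing schema,
versioned) plus a CSV manifest with one row per trial.  Everything is plain
text so sessions diff and version cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import CellArchetype, KinematicsModel, TaskConfig, TrialRecord

SCHEMA_VERSION = 1
_REQUIRED = ("schema_version", "trial_id", "condition", "target_direction",
             "target_amplitude", "event_times", "spike_times")


class SessionFormatError(ValueError):
    """A session file violates the schema; the message names the line."""


def _trial_to_dict(trial: TrialRecord) -> dict:
    def arr(a):
        return None if a is None else np.asarray(a).tolist()
    return {
        "schema_version": SCHEMA_VERSION,
        "trial_id": trial.trial_id,
        "condition": trial.condition,
        "target_direction": trial.target_direction,
        "target_amplitude": trial.target_amplitude,
        "event_times": trial.event_times,
        "eye_sample_rate": trial.eye_sample_rate,
        "hand_sample_rate": trial.hand_sample_rate,
        "eye_trace": arr(trial.eye_trace),
        "hand_trace": arr(trial.hand_trace),
        "spike_times": [np.asarray(s).tolist() for s in trial.spike_times],
        "ground_truth": _jsonable(trial.ground_truth),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _trial_from_dict(d: dict, line_no: int) -> TrialRecord:
    missing = [k for k in _REQUIRED if k not in d]
    if missing:
        raise SessionFormatError(
            f"line {line_no}: missing field(s) {missing}")
    if d["schema_version"] != SCHEMA_VERSION:
        raise SessionFormatError(
            f"line {line_no}: unsupported schema version {d['schema_version']}")
    return TrialRecord(
        trial_id=int(d["trial_id"]), condition=d["condition"],
        target_direction=float(d["target_direction"]),
        target_amplitude=float(d["target_amplitude"]),
        event_times=d["event_times"],
        eye_sample_rate=float(d.get("eye_sample_rate", 1000.0)),
        hand_sample_rate=float(d.get("hand_sample_rate", 666.0)),
        eye_trace=None if d.get("eye_trace") is None else np.asarray(d["eye_trace"]),
        hand_trace=None if d.get("hand_trace") is None else np.asarray(d["hand_trace"]),
        spike_times=[np.asarray(s, dtype=float) for s in d["spike_times"]],
        ground_truth=d.get("ground_truth", {}))


def write_session(trials, path, manifest_path=None) -> None:
    """Write trials as JSONL plus a CSV manifest next to it."""
    path = Path(path)
    with path.open("w") as fh:
        for trial in trials:
            fh.write(json.dumps(_trial_to_dict(trial)) + "\n")
    if manifest_path is None:
        manifest_path = path.with_suffix(".manifest.csv")
    pd.DataFrame([{"trial_id": t.trial_id, "condition": t.condition,
                   "direction": t.target_direction,
                   "amplitude": t.target_amplitude, "outcome": "success"}
                  for t in trials]).to_csv(manifest_path, index=False)


def read_session(path, manifest_path=None, validate_manifest: bool = True):
    """Read a session JSONL; raises SessionFormatError naming the bad line."""
    path = Path(path)
    trials = []
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SessionFormatError(f"line {i}: invalid JSON ({exc})") from exc
            trials.append(_trial_from_dict(d, i))
    if validate_manifest:
        if manifest_path is None:
            manifest_path = path.with_suffix(".manifest.csv")
        manifest_path = Path(manifest_path)
        if manifest_path.exists():
            mf = pd.read_csv(manifest_path)
            if len(mf) != len(trials):
                raise SessionFormatError(
                    f"manifest lists {len(mf)} trials, session has {len(trials)}")
    return trials


# ---------------------------------------------------------------------------
# reference classification table
# ---------------------------------------------------------------------------

def load_reference_table() -> pd.DataFrame:
    """The packaged 55-cell reference classification table.

    Columns: cell_id, on_direction, intensity, duration, onset.
    """
    from importlib.resources import files
    with (files("meq") / "data" / "reference_classification.csv").open() as fh:
        return pd.read_csv(fh)


def write_classification_table(classifications, path) -> None:
    rows = []
    for c in classifications:
        rows.append({"cell_id": c.cell_id, "is_meq": c.is_meq,
                     "on_direction": c.on_direction, "intensity": c.intensity,
                     "duration": c.duration, "onset": c.onset})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_classification_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path):
    """(TaskConfig, KinematicsModel, cells) from a YAML file.

    The ``cells`` section is either an explicit list of archetype parameter
    mappings or ``population: {kind: reference, seed: N, n_cells: M}``.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    task_kw = dict(cfg.get("task", {}))
    for key in ("fixation_ms", "instruction_ms", "delay_ms"):
        if key in task_kw:
            task_kw[key] = tuple(task_kw[key])
    task = TaskConfig(**task_kw)
    kin = KinematicsModel(**cfg.get("kinematics", {}))
    if "cells" in cfg:
        cells = []
        for c in cfg["cells"]:
            c = dict(c)
            if c.get("mixed_field_transition") is not None:
                c["mixed_field_transition"] = tuple(c["mixed_field_transition"])
            cells.append(CellArchetype(**c))
    else:
        pop = cfg.get("population", {"kind": "reference"})
        from .synth import make_reference_population
        cells = make_reference_population(seed=int(pop.get("seed", 0)),
                                       n_cells=int(pop.get("n_cells", 55)))
    return task, kin, cells
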