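"""File formats and run provenance.

Epoched tensors and decision values are stored as directory containers of
raw ``.npy`` arrays plus a JSON sidecar carrying the trial metadata,
channel names and provenance (config hash, seed, schema version); tables
(RTs, time courses, RDMs, searchlight maps) are TSV with a header row,
UTF-8 and ``.`` decimal. Raw ``.npy`` + canonical JSON keeps every artifact
byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet, RTTable, SceneDecisionValues

SCHEMA_VERSION = 1
PathLike = Union[str, Path]


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    return hashlib.sha256(_canonical_json(cfg).encode()).hexdigest()[:16]


def load_config(path: PathLike) -> dict:
    """Read a YAML (or JSON — a YAML subset) pipeline configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return cfg


def _write_json(path: Path, obj) -> None:
    path.write_text(_canonical_json(obj) + "\n", encoding="utf-8")


def _read_json(path: Path) -> dict:
    return json.loads(path.read_text(encoding="utf-8"))


def _check_schema(meta: dict, what: str) -> None:
    v = meta.get("schema_version")
    if v != SCHEMA_VERSION:
        raise ValueError(
            f"{what}: unknown schema version {v!r} (expected "
            f"{SCHEMA_VERSION}); re-export with the current package")


# -- EpochSet container --------------------------------------------------

def save_epochs(e: EpochSet, path: PathLike,
                provenance: Optional[dict] = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", e.data)
    np.save(path / "times.npy", e.times)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "channels": list(e.channel_names),
        "trials": {c: e.trials[c].tolist() for c in e.trials.columns},
        "n_trials": e.n_trials,
        "units": "arbitrary",
        "provenance": provenance or {},
    }
    _write_json(path / "meta.json", meta)
    return path


def load_epochs(path: PathLike) -> EpochSet:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no epoch container at {path}")
    meta = _read_json(meta_path)
    _check_schema(meta, f"epoch container {path}")
    data = np.load(path / "data.npy")
    times = np.load(path / "times.npy")
    trials = pd.DataFrame(meta["trials"])
    from .containers import TRIAL_COLUMNS
    order = [c for c in TRIAL_COLUMNS if c in trials.columns]
    order += [c for c in trials.columns if c not in order]
    trials = trials[order]
    if len(trials) != meta["n_trials"] or len(trials) != data.shape[0]:
        raise ValueError(
            f"epoch container {path}: metadata rows ({len(trials)}) do not "
            f"match tensor trials ({data.shape[0]})")
    return EpochSet(data, times, trials, meta["channels"])


# -- SceneDecisionValues container ----------------------------------------

def save_decision_values(d: SceneDecisionValues, path: PathLike,
                         provenance: Optional[dict] = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "values.npy", d.values)
    np.save(path / "times.npy", d.times)
    if d.abs_values is not None:
        np.save(path / "abs_values.npy", d.abs_values)
    _write_json(path / "meta.json", {
        "schema_version": SCHEMA_VERSION,
        "participants": list(d.participants),
        "scenes": list(d.scenes),
        "task": d.task,
        "n_repeats": d.n_repeats,
        "provenance": provenance or {},
    })
    return path


def load_decision_values(path: PathLike) -> SceneDecisionValues:
    path = Path(path)
    meta = _read_json(path / "meta.json")
    _check_schema(meta, f"decision-value container {path}")
    abs_path = path / "abs_values.npy"
    return SceneDecisionValues(
        np.load(path / "values.npy"), np.load(path / "times.npy"),
        meta["participants"], meta["scenes"], task=meta["task"],
        n_repeats=meta["n_repeats"],
        abs_values=np.load(abs_path) if abs_path.exists() else None)


# -- TSV tables ------------------------------------------------------------

def save_rt_table(rt: RTTable, path: PathLike) -> Path:
    path = Path(path)
    tidy = (rt.rt.reset_index(names="participant")
            .melt(id_vars="participant", var_name="scene", value_name="rt"))
    tidy["task"] = rt.task
    tidy = tidy[["participant", "scene", "task", "rt"]].sort_values(
        ["participant", "scene"], kind="stable")
    tidy.to_csv(path, sep="\t", index=False)
    return path


def load_rt_table(path: PathLike) -> RTTable:
    tidy = pd.read_csv(path, sep="\t")
    need = {"participant", "scene", "task", "rt"}
    if not need.issubset(tidy.columns):
        raise ValueError(f"RT table {path} missing columns "
                         f"{sorted(need - set(tidy.columns))}")
    tasks = tidy["task"].unique()
    if len(tasks) != 1:
        raise ValueError(f"RT table {path} mixes tasks {list(tasks)}")
    wide = tidy.pivot(index="participant", columns="scene", values="rt")
    wide.columns.name = None
    return RTTable(rt=wide, task=str(tasks[0]))


def save_rdm(rdm: np.ndarray, conditions, path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame(rdm, index=list(conditions),
                 columns=list(conditions)).to_csv(path, sep="\t")
    return path


def load_rdm(path: PathLike):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"RDM {path}: row and column conditions differ")
    return df.to_numpy(dtype=float), list(df.columns)


def save_stage_probs(sp, path_prefix: PathLike) -> Path:
    """Stage probabilities as a long TSV plus a JSON sidecar with the
    scene, stage and class ordering."""
    from .readout import StageProbabilities
    assert isinstance(sp, StageProbabilities)
    prefix = Path(path_prefix)
    rows = []
    for si, scene in enumerate(sp.scenes):
        for st in range(sp.n_stages):
            for ci, cls in enumerate(sp.classes):
                rows.append((scene, st + 1, cls, sp.p[si, st, ci]))
    pd.DataFrame(rows, columns=["scene", "stage", "class", "p"]).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False)
    _write_json(prefix.with_suffix(".json"), {
        "schema_version": SCHEMA_VERSION,
        "scenes": list(sp.scenes),
        "classes": list(sp.classes),
        "n_stages": sp.n_stages,
    })
    return prefix.with_suffix(".tsv")


def load_stage_probs(path_prefix: PathLike):
    from .readout import StageProbabilities
    prefix = Path(path_prefix)
    meta = _read_json(prefix.with_suffix(".json"))
    _check_schema(meta, f"stage probabilities {prefix}")
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    p = np.empty((len(meta["scenes"]), meta["n_stages"],
                  len(meta["classes"])))
    s_idx = {s: i for i, s in enumerate(meta["scenes"])}
    c_idx = {c: i for i, c in enumerate(meta["classes"])}
    for scene, stage, cls, pval in df.itertuples(index=False, name=None):
        p[s_idx[scene], stage - 1, c_idx[cls]] = pval
    return StageProbabilities(p=p, scenes=list(meta["scenes"]),
                              classes=tuple(meta["classes"]))


def save_timecourse_tsv(values: np.ndarray, times: np.ndarray,
                        participants, path: PathLike,
                        value_name: str = "value", **labels) -> Path:
    """Tidy participant x time table: one row per (participant, time)."""
    path = Path(path)
    rows = []
    for pi, pid in enumerate(participants):
        for ti, t in enumerate(times):
            rows.append({"participant": pid, "time_ms": t,
                         value_name: values[pi, ti], **labels})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def load_timecourse_tsv(path: PathLike, value_name: str = "value"):
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot(index="participant", columns="time_ms",
                    values=value_name).sort_index()
    times = np.asarray(wide.columns, dtype=float)
    return wide.to_numpy(dtype=float), times, list(wide.index)


# -- run manifests ---------------------------------------------------------

def write_manifest(out_dir: PathLike, stage: str, cfg: dict, seed: int,
                   inputs: list, outputs: list) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"manifest_{stage}.json"

    def _rel(p) -> str:
        p = Path(p)
        try:
            return str(p.relative_to(out_dir))
        except ValueError:
            return str(p)

    _write_json(path, {
        "schema_version": SCHEMA_VERSION,
        "stage": stage,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "inputs": sorted(_rel(p) for p in inputs),
        "outputs": sorted(_rel(p) for p in outputs),
    })
    return path


def read_manifest(out_dir: PathLike, stage: str) -> dict:
    path = Path(out_dir) / f"manifest_{stage}.json"
    if not path.exists():
        raise FileNotFoundError(
            f"missing manifest for stage {stage!r}; run the "
            f"'{stage.replace('_', '-')}' subcommand first")
    return _read_json(path)


def require_artifact(path: PathLike, producer: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; produce it with the "
            f"'{producer}' subcommand")
    return path
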