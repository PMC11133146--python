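"""File formats: event logs (JSON-lines canonical, CSV supported),
cohort specifications (YAML/JSON) and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .agents import AgentParams, CohortSpec, ParticipantLog
from .task_engine import EntryEvent, TaskConfig

__all__ = [
    "write_event_log", "read_event_log", "write_cohort", "read_cohort_dir",
    "load_task_config", "load_cohort_spec", "RunManifest",
]


def write_event_log(log: ParticipantLog, path: Path | str) -> Path:
    """One EntryEvent per line; `.jsonl` or `.csv` by extension."""
    path = Path(path)
    records = [ev.to_record() for ev in log.events]
    if path.suffix == ".csv":
        pd.DataFrame(records).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for r in records:
                fh.write(json.dumps(r) + "\n")
    return path


def read_event_log(path: Path | str, group: Optional[str] = None) -> ParticipantLog:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        records = df.to_dict("records")
    else:
        with open(path) as fh:
            records = [json.loads(line) for line in fh if line.strip()]
    if not records:
        raise ValueError(f"empty event log: {path}")
    events = [EntryEvent.from_record(r) for r in records]
    ts = [ev.timestamp for ev in events]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"event log not time-ordered: {path}")
    pid = events[0].participant_id
    group = group or _group_from_pid(pid)
    return ParticipantLog(participant_id=pid, group=group,
                          params=AgentParams(), events=events)


def _group_from_pid(pid: str) -> str:
    for g in ("extensive_parallel", "extensive", "short"):
        if pid.startswith(g):
            return g
    raise ValueError(f"cannot infer group from participant id {pid!r}; "
                     "pass group explicitly")


def write_cohort(logs: Iterable[ParticipantLog], out_dir: Path | str,
                 fmt: str = "jsonl") -> pd.DataFrame:
    """Write one event-log file per participant plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for log in logs:
        fname = f"{log.participant_id}.{fmt}"
        write_event_log(log, out_dir / fname)
        rows.append({"participant_id": log.participant_id, "group": log.group,
                     "n_entries": len(log.events), "file": fname,
                     "seed": log.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "cohort_manifest.csv", index=False)
    return manifest


def read_cohort_dir(logs_dir: Path | str) -> list[ParticipantLog]:
    logs_dir = Path(logs_dir)
    manifest_path = logs_dir / "cohort_manifest.csv"
    logs = []
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        for r in manifest.itertuples(index=False):
            logs.append(read_event_log(logs_dir / r.file, group=r.group))
    else:
        for path in sorted(logs_dir.glob("*.jsonl")) + sorted(logs_dir.glob("*.csv")):
            logs.append(read_event_log(path))
    if not logs:
        raise ValueError(f"no event logs found in {logs_dir}")
    return logs


def _load_structured(path: Path | str) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def load_task_config(path: Path | str) -> TaskConfig:
    raw = _load_structured(path) or {}
    try:
        return TaskConfig.from_dict(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid task config {path}: {exc}") from exc


def load_cohort_spec(path: Path | str) -> CohortSpec:
    raw = _load_structured(path) or {}
    bp = raw.pop("base_params", {}) or {}
    if "session_window" in bp:
        bp["session_window"] = tuple(bp["session_window"])
    try:
        return CohortSpec(base_params=AgentParams(**bp), **raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid cohort spec {path}: {exc}") from exc


@dataclasses.dataclass
class RunManifest:
    """Provenance record: identical config + seed implies identical outputs."""

    command: str
    master_seed: Optional[int]
    config: dict
    inputs: list[str]
    outputs: list[str]
    created: float = dataclasses.field(default_factory=time.time)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write(self, path: Path | str) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=str)
        return path
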