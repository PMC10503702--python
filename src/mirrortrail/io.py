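"""Plain-text dataset persistence: a JSON manifest plus one CSV per trial.

Mirror-game trial files carry columns ``time_s, position`` (plus
``leader_position`` for leader-follower trials, logged on the same
timestamps).  TMT files carry ``time_ms, target_index, on_target`` where
``target_index`` is the 1-based index of the target hit (-1 for off-target
clicks).  The manifest lists participants, their metadata and trial file
paths, and records provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .records import (
    CohortDataset,
    MGTrial,
    ParticipantRecord,
    SampledSeries,
    TMTClickLog,
)

MANIFEST_NAME = "manifest.json"


def write_dataset(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write the dataset under ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"participants": [], "provenance": dataset.provenance}
    for p in dataset.participants:
        pdir = out / p.id
        pdir.mkdir(exist_ok=True)
        entry = {
            "id": p.id, "cohort": p.cohort, "caarms": p.caarms,
            "age": p.age, "sex": p.sex, "mg_trials": [], "tmt_logs": [],
        }
        for t in p.mg_trials:
            fname = f"mg_{t.game_kind}_s{t.session_index}_r{t.repetition_index}.csv"
            cols = {"time_s": t.follower_series.timestamps,
                    "position": t.follower_series.values}
            if t.leader_series is not None:
                cols["leader_position"] = t.leader_series.values
            pd.DataFrame(cols).to_csv(pdir / fname, index=False)
            entry["mg_trials"].append({
                "file": f"{p.id}/{fname}", "game_kind": t.game_kind,
                "session_index": t.session_index,
                "repetition_index": t.repetition_index,
                "nominal_rate": t.follower_series.nominal_rate,
            })
        for lg in p.tmt_logs:
            fname = f"tmt_{lg.part}_r{lg.repetition}.csv"
            target_index = np.where(lg.on_target, np.cumsum(lg.on_target), -1)
            pd.DataFrame({
                "time_ms": lg.click_times_ms,
                "target_index": target_index,
                "on_target": lg.on_target.astype(int),
            }).to_csv(pdir / fname, index=False)
            entry["tmt_logs"].append({
                "file": f"{p.id}/{fname}", "part": lg.part,
                "repetition": lg.repetition, "n_targets": lg.n_targets,
            })
        manifest["participants"].append(entry)
    path = out / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_manifest(path: str | Path) -> CohortDataset:
    """Load a dataset written by :func:`write_dataset`."""
    path = Path(path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InvalidArgumentError(f"manifest {path} is not valid JSON: {exc}") from exc
    base = path.parent
    participants = []
    for entry in manifest.get("participants", []):
        mg_trials = []
        for t in entry["mg_trials"]:
            f = base / t["file"]
            if not f.exists():
                raise InvalidArgumentError(
                    f"participant {entry['id']}: missing trial file {t['file']}")
            df = pd.read_csv(f)
            follower = SampledSeries(df["time_s"].to_numpy(),
                                     df["position"].to_numpy(), t["nominal_rate"])
            leader = None
            if "leader_position" in df.columns:
                leader = SampledSeries(df["time_s"].to_numpy(),
                                       df["leader_position"].to_numpy(),
                                       t["nominal_rate"])
            mg_trials.append(MGTrial(
                participant_id=entry["id"], game_kind=t["game_kind"],
                session_index=t["session_index"],
                repetition_index=t["repetition_index"],
                follower_series=follower, leader_series=leader))
        tmt_logs = []
        for t in entry["tmt_logs"]:
            f = base / t["file"]
            if not f.exists():
                raise InvalidArgumentError(
                    f"participant {entry['id']}: missing TMT file {t['file']}")
            df = pd.read_csv(f)
            tmt_logs.append(TMTClickLog(
                participant_id=entry["id"], part=t["part"],
                repetition=t["repetition"],
                click_times_ms=df["time_ms"].to_numpy(),
                on_target=df["on_target"].to_numpy().astype(bool),
                n_targets=t.get("n_targets", 25)))
        participants.append(ParticipantRecord(
            id=entry["id"], cohort=entry["cohort"], caarms=entry["caarms"],
            age=entry["age"], sex=entry["sex"],
            mg_trials=mg_trials, tmt_logs=tmt_logs))
    return CohortDataset(participants=participants,
                         provenance=manifest.get("provenance", {}))
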