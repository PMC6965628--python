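"""File interfaces: recordings, events, channel tables, envelopes, results.

Recordings are stored as a flat binary array (little-endian float64 .npy)
with a JSON sidecar carrying the sampling rate, channel ids, condition and
run id.  Event and response logs are TSV; ground truth and run scores are
JSON.  All writers are deterministic (sorted keys, fixed float formatting)
so identical runs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import RunScore, TrialTable
from .preprocess import BandEnvelope
from .synth import GroundTruth, Recording, StimulusSequence

__all__ = [
    "write_recording", "read_recording", "write_events", "read_events",
    "write_responses", "read_responses", "write_channel_table",
    "read_channel_table", "write_ground_truth", "write_envelope",
    "read_envelope", "write_trial_table", "write_run_score", "write_json",
]


def write_json(obj: dict, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


# ---------------------------------------------------------------------------


def write_recording(rec: Recording, stem: Path) -> None:
    """Write ``<stem>.npy`` (channels x samples) and ``<stem>.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), rec.data)
    write_json({"fs": rec.fs, "channels": list(rec.channels),
                "condition": rec.condition, "run_id": rec.run_id},
               stem.with_suffix(".json"))


def read_recording(stem: Path) -> Recording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npy"))
    return Recording(data=data, fs=float(meta["fs"]),
                     channels=list(meta["channels"]),
                     condition=meta["condition"], run_id=meta["run_id"])


def write_events(seq: StimulusSequence, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"onset_s": seq.onsets, "category": seq.categories}
                 ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: Path, transition_ms: float | None = None,
                run_id: str = "run-01") -> StimulusSequence:
    df = pd.read_csv(path, sep="\t")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if transition_ms is None:
        transition_ms = float(np.median(np.diff(onsets)) * 1000.0)
    cats = df["category"].to_numpy(dtype=object)
    rate = float(np.mean(cats == "mountain"))
    return StimulusSequence(run_id=run_id, onsets=onsets, categories=cats,
                            transition_ms=transition_ms, mountain_rate=rate)


def write_responses(presses: np.ndarray, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"press_s": np.asarray(presses, dtype=float)}
                 ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_responses(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["press_s"].to_numpy(dtype=float)


def write_channel_table(table: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_channel_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"channel", "subject", "network"}
    if not required.issubset(df.columns):
        raise ValueError(f"channel table needs columns {sorted(required)}")
    return df


def write_ground_truth(truth: GroundTruth, path: Path) -> None:
    d = asdict(truth)
    d["pair_lag_s"] = {f"{i}|{j}": v for (i, j), v in truth.pair_lag_s.items()}
    d["pair_r"] = {f"{i}|{j}": v for (i, j), v in truth.pair_r.items()}
    if truth.outcomes is not None:
        d["outcomes"] = list(map(str, truth.outcomes))
    write_json(d, path)


def write_envelope(env: BandEnvelope, stem: Path) -> None:
    """Write ``<stem>.npy`` (channels x bands x samples) and sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), env.data)
    meta = {"fs": env.fs, "channels": list(env.channels),
            "bands": list(env.bands), "condition": env.condition,
            "run_id": env.run_id}
    if env.valid is not None:
        meta["valid_start"] = int(np.argmax(env.valid))
        meta["valid_stop"] = int(len(env.valid) - np.argmax(env.valid[::-1]))
    write_json(meta, stem.with_suffix(".json"))


def read_envelope(stem: Path) -> BandEnvelope:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npy"))
    valid = None
    if "valid_start" in meta:
        valid = np.zeros(data.shape[-1], dtype=bool)
        valid[meta["valid_start"]:meta["valid_stop"]] = True
    return BandEnvelope(data=data, fs=float(meta["fs"]),
                        channels=list(meta["channels"]),
                        bands=tuple(meta["bands"]), valid=valid,
                        condition=meta["condition"], run_id=meta["run_id"])


def write_trial_table(table: TrialTable, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_run_score(score: RunScore, path: Path) -> None:
    write_json(asdict(score), path)
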