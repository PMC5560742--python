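"""Serialization: epochs container, classifier bundles, reports, manifests.

The epochs container is an HDF5 array store: datasets ``/data`` (trials x
channels x samples, float64 tesla), ``/time_ms``, ``/channel_ids``, a JSON
table of per-epoch event metadata, and attributes ``fs``, ``alignment`` and
a schema ``version``.  Round trips are lossless: arrays bit-exact, metadata
field-exact.  Every report written by the pipeline carries the config hash
so artifacts from different runs cannot be silently mixed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import SensorEpochs, ValidationError
from .encoding import PairwiseClassifier

SCHEMA_VERSION = 1

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_classifiers",
    "load_classifiers",
    "config_hash",
    "write_json",
    "read_json",
    "file_sha256",
]


def save_epochs(epochs: SensorEpochs, path: str | Path) -> Path:
    """Write a :class:`SensorEpochs` to an HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, dtype="float64")
        f.create_dataset("time_ms", data=epochs.time_ms, dtype="float64")
        f.create_dataset(
            "channel_ids",
            data=np.array(epochs.channel_ids, dtype=h5py.string_dtype()),
        )
        f.create_dataset(
            "events_json",
            data=epochs.events.to_json(orient="table", index=False),
        )
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["alignment"] = epochs.alignment
        f.attrs["version"] = SCHEMA_VERSION
    return path


def load_epochs(path: str | Path) -> SensorEpochs:
    """Read an epochs container; validates shape/metadata consistency."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("version", -1))
        if version != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported epochs container version {version} "
                f"(expected {SCHEMA_VERSION})"
            )
        for name in ("data", "time_ms", "channel_ids", "events_json"):
            if name not in f:
                raise ValidationError(f"malformed container: missing /{name}")
        data = f["data"][()]
        time_ms = f["time_ms"][()]
        channel_ids = [c.decode() if isinstance(c, bytes) else str(c)
                       for c in f["channel_ids"][()]]
        raw = f["events_json"][()]
        events = pd.read_json(
            raw.decode() if isinstance(raw, bytes) else raw, orient="table"
        )
        fs = float(f.attrs["fs"])
        alignment = str(f.attrs["alignment"])
    if len(events) != data.shape[0]:
        raise ValidationError(
            f"events table length {len(events)} != epochs dimension "
            f"{data.shape[0]}"
        )
    return SensorEpochs(
        data=data, time_ms=time_ms, fs=fs, alignment=alignment,
        events=events, channel_ids=channel_ids,
    )


# ---------------------------------------------------------------------------
# classifier bundles
# ---------------------------------------------------------------------------

def save_classifiers(
    classifiers: dict[tuple[str, str], PairwiseClassifier], path: str | Path
) -> Path:
    """Serialize the pairwise-classifier bundle to a versioned ``.npz``."""
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {
        "__version__": np.array([SCHEMA_VERSION]),
    }
    meta = []
    for i, (pair, clf) in enumerate(sorted(classifiers.items())):
        arrays[f"mask_{i}"] = clf.feature_mask
        arrays[f"center_{i}"] = clf.center
        arrays[f"scale_{i}"] = clf.scale
        arrays[f"weights_{i}"] = clf.weights
        meta.append(
            {"pair": list(pair), "bin_center_ms": clf.bin_center_ms,
             "bias": clf.bias}
        )
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    return path


def load_classifiers(path: str | Path) -> dict[tuple[str, str], PairwiseClassifier]:
    with np.load(Path(path), allow_pickle=False) as z:
        version = int(z["__version__"][0])
        if version != SCHEMA_VERSION:
            raise ValidationError(f"unsupported classifier bundle version {version}")
        meta = json.loads(bytes(z["meta_json"]).decode())
        out = {}
        for i, m in enumerate(meta):
            pair = tuple(m["pair"])
            out[pair] = PairwiseClassifier(
                pair=pair,
                bin_center_ms=float(m["bin_center_ms"]),
                feature_mask=z[f"mask_{i}"],
                center=z[f"center_{i}"],
                scale=z[f"scale_{i}"],
                weights=z[f"weights_{i}"],
                bias=float(m["bias"]),
            )
    return out


# ---------------------------------------------------------------------------
# hashing / reports
# ---------------------------------------------------------------------------

def _canonical(obj):
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def config_hash(config: dict) -> str:
    """SHA-256 of a canonical JSON rendering of a config dictionary."""
    payload = json.dumps(_canonical(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def write_json(obj: dict, path: str | Path, cfg_hash: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = dict(_canonical(obj))
    if cfg_hash is not None:
        body["config_hash"] = cfg_hash
    path.write_text(json.dumps(body, indent=1, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path, expect_hash: str | None = None) -> dict:
    obj = json.loads(Path(path).read_text())
    if expect_hash is not None and obj.get("config_hash") != expect_hash:
        raise ValidationError(
            f"{path}: config hash mismatch — artifact comes from a different run"
        )
    return obj


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
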