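"""Artifact persistence: checkpoint archives, reports, predictions.

A checkpoint archive is a zip container holding one ``.npy`` entry per named
array plus a ``meta.json`` block (model config, role, vocabulary, image
statistics, validation accuracy, provenance, config hash).  Zip entries carry
a fixed timestamp so identical content produces byte-identical archives.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
import zipfile
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core_types import Checkpoint, ParameterSet, Provenance
from .encoders import ComponentModel, EncoderConfig, Vocabulary

_EPOCH = (1980, 1, 1, 0, 0, 0)  # fixed zip timestamp -> reproducible bytes


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_entry(zf: zipfile.ZipFile, name: str, payload: bytes) -> None:
    info = zipfile.ZipInfo(name, date_time=_EPOCH)
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, payload)


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "val_accuracy": ckpt.val_accuracy,
        "provenance": ckpt.provenance.to_dict(),
        "shapes": {k: list(v.shape) for k, v in sorted(ckpt.params.entries.items())},
        **ckpt.meta,
    }
    meta["config_hash"] = config_hash(
        {"provenance": meta["provenance"], "config": meta.get("config")}
    )
    with zipfile.ZipFile(path, "w") as zf:
        _write_entry(zf, "meta.json", json.dumps(meta, sort_keys=True).encode())
        for name in sorted(ckpt.params.entries):
            buf = _io.BytesIO()
            np.save(buf, ckpt.params.entries[name], allow_pickle=False)
            _write_entry(zf, f"arrays/{name}.npy", buf.getvalue())


def load_checkpoint(path: str | Path) -> Checkpoint:
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            entries: dict[str, np.ndarray] = {}
            for info in zf.infolist():
                if info.filename.startswith("arrays/") and info.filename.endswith(".npy"):
                    name = info.filename[len("arrays/") : -len(".npy")]
                    entries[name] = np.load(_io.BytesIO(zf.read(info)), allow_pickle=False)
    except (zipfile.BadZipFile, KeyError, EOFError) as exc:
        raise IOError(f"corrupted checkpoint archive: {path}") from exc
    shapes = meta.get("shapes", {})
    for name, shape in shapes.items():
        if name not in entries or list(entries[name].shape) != shape:
            raise IOError(f"checkpoint shape manifest mismatch for entry {name!r}")
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("val_accuracy", "provenance", "shapes", "config_hash")
    }
    return Checkpoint(
        params=ParameterSet(entries),
        val_accuracy=float(meta["val_accuracy"]),
        provenance=Provenance.from_dict(meta["provenance"]),
        meta=extra,
    )


def component_from_checkpoint(ckpt: Checkpoint) -> ComponentModel:
    """Rebuild a runnable ComponentModel from a loaded checkpoint."""
    meta = ckpt.meta
    config = EncoderConfig.from_dict(meta["config"])
    vocab = Vocabulary.from_dict(meta["vocab"])
    return ComponentModel(
        config=config,
        vocab=vocab,
        params=ckpt.params,
        mu=np.asarray(meta["mu"]),
        sigma=np.asarray(meta["sigma"]),
    )


# ---------------------------------------------------------------------------
# Reports and predictions


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


PREDICTION_FIELDS = (
    "id",
    "true_answer",
    "predicted_answer",
    "true_type",
    "predicted_type",
    "routed_model",
)


def write_predictions(rows: Sequence[dict], path: str | Path) -> None:
    seen = set()
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=PREDICTION_FIELDS)
        writer.writeheader()
        for row in rows:
            if row["id"] in seen:
                raise ValueError(f"duplicate prediction id {row['id']!r}")
            seen.add(row["id"])
            writer.writerow({k: row[k] for k in PREDICTION_FIELDS})


def read_predictions(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


# ---------------------------------------------------------------------------
# Assembly descriptors


def write_assembly(
    level1_path: str,
    level2_paths: dict[str, str],
    routing: dict[str, str],
    path: str | Path,
    extra: Optional[dict] = None,
) -> None:
    desc = {
        "level1": level1_path,
        "level2": level2_paths,
        "routing": routing,
    }
    if extra:
        desc.update(extra)
    desc["config_hash"] = config_hash(desc)
    write_json(desc, path)


def read_assembly(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
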