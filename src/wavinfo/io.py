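"""Epoch-matrix file dialect: plain CSV matrices plus a JSON sidecar.

A dataset directory contains one headerless ``<channel>.csv`` matrix per
channel (rows = trials, columns = samples), a ``labels.csv`` with one integer
per line, and ``meta.json`` holding ``fs_hz``, ``t0_ms``, the channel order
and provenance. Formatting is deterministic, so identical TrialSets produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import TrialSet

__all__ = ["read_trials", "write_trials"]

_FLOAT_FMT = "%.17e"  # round-trips float64 exactly


def write_trials(trials: TrialSet, path: str | Path) -> None:
    """Write a TrialSet in the epoch-matrix dialect (deterministic bytes)."""
    if trials.n_trials == 0:
        raise ValueError("refusing to write an empty TrialSet")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, ch in enumerate(trials.channels):
        np.savetxt(path / f"{ch}.csv", trials.data[i], fmt=_FLOAT_FMT,
                   delimiter=",")
    np.savetxt(path / "labels.csv", trials.labels.astype(int), fmt="%d")
    meta = {
        "fs_hz": trials.fs_hz,
        "t0_ms": trials.t0_ms,
        "channels": list(trials.channels),
        "provenance": trials.provenance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True)
                                    + "\n")


def read_trials(path: str | Path) -> TrialSet:
    """Read and validate a dataset directory written by :func:`write_trials`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("fs_hz", "t0_ms", "channels"):
        if key not in meta:
            raise ValueError(f"meta.json is missing required key '{key}'")
    labels_path = path / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"missing labels file {labels_path}")
    try:
        labels = np.loadtxt(labels_path, dtype=int, ndmin=1)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in {labels_path}: {exc}") from exc
    mats = []
    for ch in meta["channels"]:
        ch_path = path / f"{ch}.csv"
        if not ch_path.exists():
            raise FileNotFoundError(f"missing channel matrix {ch_path}")
        try:
            m = np.loadtxt(ch_path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"non-numeric entries in {ch_path}: {exc}") from exc
        mats.append(m)
    data = np.stack(mats)
    if data.shape[1] != len(labels):
        raise ValueError(
            f"labels.csv has {len(labels)} entries but channel matrices have "
            f"{data.shape[1]} trial rows")
    return TrialSet(data=data, labels=labels, fs_hz=float(meta["fs_hz"]),
                    t0_ms=float(meta["t0_ms"]), channels=list(meta["channels"]),
                    provenance=meta.get("provenance", {}))
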