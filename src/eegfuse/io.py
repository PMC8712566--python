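"""CSV/JSON readers and writers plus run manifests.

CSV is the canonical interchange format (signals were exported to ASCII in
the acquisition protocol this pipeline targets); EDF recordings can be read
when ``mne`` is available.  Signal CSVs carry one row per channel with the
electrode name in the first column; feature tables are subjects × features
with a ``label`` column.  Every pipeline run writes a JSON manifest (config,
seed, package versions) sufficient to reproduce it bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from eegfuse.brain_network import EpochSignal

__all__ = [
    "read_table",
    "write_table",
    "read_signals_csv",
    "write_signals_csv",
    "read_signals_edf",
    "write_manifest",
]


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Feature table from CSV; non-numeric cells are named in the error."""
    table = pd.read_csv(path)
    for col in table.columns:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[numeric.isna() & table[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value {table[col].iloc[bad[0]]!r} "
                f"at row {int(bad[0])}, column {col!r} of {path}"
            )
        table[col] = numeric
    return table


def write_signals_csv(path, epoch: EpochSignal) -> None:
    """One row per channel: channel name then the samples."""
    names = epoch.channel_names or tuple(f"ch{i}" for i in range(epoch.n_channels))
    frame = pd.DataFrame(epoch.samples, index=pd.Index(names, name="channel"))
    frame.to_csv(path)


def read_signals_csv(path, fs: float, n_channels: Optional[int] = None) -> EpochSignal:
    frame = pd.read_csv(path, index_col=0)
    data = frame.to_numpy(dtype=float)
    if n_channels is not None and data.shape[0] != n_channels:
        raise ValueError(
            f"{path}: expected {n_channels} channels, found {data.shape[0]}"
        )
    return EpochSignal(data, fs, channel_names=tuple(str(c) for c in frame.index))


def read_signals_edf(path) -> EpochSignal:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("reading EDF requires the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EpochSignal(
        raw.get_data(), float(raw.info["sfreq"]), channel_names=tuple(raw.ch_names)
    )


def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int) -> dict:
    """Record everything needed to reproduce a run."""
    import eegfuse

    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": int(seed),
        "versions": {
            "eegfuse": eegfuse.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
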