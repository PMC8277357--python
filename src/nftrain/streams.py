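"""Single-channel stream files: CSV with header time_s,eeg_uv."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidSignalError


def write_stream_csv(x: np.ndarray, fs: float, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(len(x)) / fs
    pd.DataFrame({"time_s": t, "eeg_uv": x}).to_csv(path, index=False)
    return path


def read_stream_csv(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a stream file; returns (samples µV, fs inferred from timestamps)."""
    df = pd.read_csv(path)
    for col in ("time_s", "eeg_uv"):
        if col not in df.columns:
            raise InvalidSignalError(f"stream file {path}: missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise InvalidSignalError(f"stream file {path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidSignalError(f"stream file {path}: time must be strictly increasing")
    return df["eeg_uv"].to_numpy(float), float(1.0 / np.median(dt))
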