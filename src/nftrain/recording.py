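"""Multichannel EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

PHASES = ("pre", "post")
CONDITIONS = ("eyes_open", "eyes_closed")


@dataclass
class Recording:
    """A multichannel resting-state EEG recording.

    channels maps channel name -> 1-D sample array (µV); all channels share
    one sampling rate and length. phase is 'pre' or 'post' (relative to
    training), condition 'eyes_open' or 'eyes_closed'.
    """

    subject: str
    phase: str
    condition: str
    channels: Mapping[str, np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        chans = {name: np.asarray(x, float) for name, x in self.channels.items()}
        if not chans:
            raise ValueError("recording has no channels")
        lengths = {len(x) for x in chans.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels differ in length: {sorted(lengths)}")
        self.channels = chans

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs
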