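"""Calibration, one-third-rule thresholds, classification, adaptation.

Before a session the engine measures the feedback score under two instructed
mental states — attentive and relaxed — and places the game-control
thresholds a fraction (default 1/3) of the attentive-relaxed difference in
from each end:

    lower = R + f·(A−R),   upper = A − f·(A−R)

Scores at or above the upper threshold reward the player, at or below the
lower threshold penalize, and the band in between is neutral. Because the
score is volatile and drifts with fatigue, a recenter policy continuously
moves the threshold midpoint toward an exponentially weighted average of the
recent scores while conserving the band width, so the reward stays reachable
and the player stays engaged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import CalibrationError
from .feedback import AttentionSample, ema

MIN_CALIBRATION_SCORES = 5
DEFAULT_FRACTION = 1.0 / 3.0
DEFAULT_ADAPT_RATE = 0.2
DEFAULT_ADAPT_HORIZON_S = 15.0
#: Default duration of each instructed calibration state, seconds.
DEFAULT_CALIBRATION_S = 30.0


@dataclass(frozen=True)
class Calibration:
    """Median feedback score under the two instructed states (A > R)."""

    relaxed_level: float
    attentive_level: float
    n_windows: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.relaxed_level) and np.isfinite(self.attentive_level)):
            raise CalibrationError("calibration levels must be finite")
        if self.attentive_level <= self.relaxed_level:
            raise CalibrationError(
                "calibration not separable: attentive level "
                f"{self.attentive_level:g} <= relaxed level {self.relaxed_level:g}"
            )


@dataclass(frozen=True)
class ThresholdState:
    """Lower/upper game thresholds plus the adaptation-policy state.

    policy is 'static' (thresholds fixed after calibration) or 'recenter'
    (width-preserving drift toward the recent score level).
    """

    lower: float
    upper: float
    fraction: float = DEFAULT_FRACTION
    policy: str = "recenter"
    adapt_rate: float = DEFAULT_ADAPT_RATE
    ema_state: float | None = None

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got ({self.lower}, {self.upper})")
        if not 0 < self.fraction < 0.5:
            raise ValueError("fraction must be in (0, 0.5)")
        if not 0 <= self.adapt_rate <= 1:
            raise ValueError("adapt_rate must be in [0, 1]")
        if self.policy not in ("static", "recenter"):
            raise ValueError(f"unknown policy {self.policy!r}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class ControlSignal:
    """Three-way classification of one score against the thresholds."""

    label: str  # {"above", "neutral", "below"}
    t: float


def calibrate(
    attentive_scores: Sequence[float],
    relaxed_scores: Sequence[float],
) -> Calibration:
    """Median score per instructed state; raises if states don't separate.

    The median (not the mean) anchors the levels so a few artifact windows
    in either calibration block cannot skew the thresholds.
    """
    att = np.asarray(attentive_scores, float)
    rel = np.asarray(relaxed_scores, float)
    att = att[np.isfinite(att)]
    rel = rel[np.isfinite(rel)]
    if len(att) < MIN_CALIBRATION_SCORES or len(rel) < MIN_CALIBRATION_SCORES:
        raise CalibrationError(
            f"insufficient calibration data: need >= {MIN_CALIBRATION_SCORES} "
            f"valid scores per state, got {len(att)} attentive / {len(rel)} relaxed"
        )
    return Calibration(
        relaxed_level=float(np.median(rel)),
        attentive_level=float(np.median(att)),
        n_windows=min(len(att), len(rel)),
    )


def init_thresholds(
    cal: Calibration,
    fraction: float = DEFAULT_FRACTION,
    policy: str = "recenter",
    adapt_rate: float = DEFAULT_ADAPT_RATE,
) -> ThresholdState:
    """Place thresholds `fraction` of the A-R difference in from each end.

    fraction must lie strictly inside (0, 0.5): at 0.5 the two thresholds
    coincide and the neutral band vanishes.
    """
    if not 0 < fraction < 0.5:
        raise ValueError(f"invalid fraction {fraction}: must be in (0, 0.5)")
    r, a = cal.relaxed_level, cal.attentive_level
    d = a - r
    return ThresholdState(
        lower=r + fraction * d,
        upper=a - fraction * d,
        fraction=fraction,
        policy=policy,
        adapt_rate=adapt_rate,
    )


def classify(score: AttentionSample, st: ThresholdState) -> ControlSignal:
    """above iff value >= upper; below iff value <= lower; else neutral.

    Ties take the more extreme label so classification is deterministic at
    the boundaries.
    """
    if score.value >= st.upper:
        label = "above"
    elif score.value <= st.lower:
        label = "below"
    else:
        label = "neutral"
    return ControlSignal(label=label, t=score.t)


def adapt(st: ThresholdState, recent: Sequence[AttentionSample]) -> ThresholdState:
    """One width-preserving recentering step toward the recent score level.

    new midpoint = (1-adapt_rate)·old + adapt_rate·EMA(recent values); the
    band width never changes, and the band is shifted up if recentering
    would push the lower threshold below zero. Static policy and empty
    histories return the state unchanged.
    """
    if st.policy == "static" or len(recent) == 0:
        return st
    target = ema([s.value for s in recent])
    mid = (1 - st.adapt_rate) * st.midpoint + st.adapt_rate * target
    half = st.width / 2.0
    mid = max(mid, half)  # keep lower >= 0 without shrinking the band
    return replace(st, lower=mid - half, upper=mid + half, ema_state=target)
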