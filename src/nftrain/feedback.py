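"""Feedback and monitoring indices computed from band powers.

Three dimensionless ratios drive and monitor training:

  attention_original = (K_β·P_β) / (K_α·P_α)
  attention_new      = (K_β·P_βL) / (K_αL·P_αL + K_θ·P_θ)
  cognitive_level    = (K_β·P_βL + K_αh·P_αh) / (K_αL·P_αL + K_θ·P_θ)

where P_β is beta (12-32 Hz) power, P_βL beta-low (12-16 Hz), P_α alpha
(8-12 Hz), P_αL alpha-low (8-10 Hz), P_αh alpha-high (10-12 Hz) and P_θ
theta (4-8 Hz); the K's are nonnegative empirical scaling constants
(all 1 by default). All three are pure ratios: rescaling every band power by
the same factor leaves them unchanged. The revised index rewards beta-low
(attention) against alpha-low + theta (relaxation); the cognitive level adds
upper alpha — the resting marker of cognitive performance — to the numerator
and is logged but never drives the game.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateSpectrumError
from .spectral import BandPowers

#: Weighted denominators below this fraction of total window power are
#: treated as degenerate (flat-lined or artifact-dominated spectra).
DENOMINATOR_FLOOR = 1e-12


@dataclass(frozen=True)
class FeedbackWeights:
    """Empirical scaling constants K for the feedback ratios (all >= 0)."""

    k_beta: float = 1.0
    k_alpha: float = 1.0
    k_alpha_low: float = 1.0
    k_alpha_high: float = 1.0
    k_theta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_beta", "k_alpha", "k_alpha_low", "k_alpha_high", "k_theta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AttentionSample:
    """A timestamped feedback score of one kind."""

    t: float
    value: float
    kind: str = "new"  # {"original", "new", "cognitive"}

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"score must be finite and >= 0, got {self.value}")


def _checked_ratio(num: float, den: float, total: float) -> float:
    if den <= DENOMINATOR_FLOOR * max(total, 1.0):
        raise DegenerateSpectrumError(
            f"degenerate spectrum: weighted denominator {den:g} below floor"
        )
    return num / den


def attention_original(bp: BandPowers, w: FeedbackWeights | None = None) -> float:
    """Beta/alpha attention ratio (the earlier single-band-pair index)."""
    w = w or FeedbackWeights()
    return _checked_ratio(w.k_beta * bp["beta"], w.k_alpha * bp["alpha"], bp.total())


def attention_new(bp: BandPowers, w: FeedbackWeights | None = None) -> float:
    """Revised attention index: beta-low over alpha-low + theta."""
    w = w or FeedbackWeights()
    den = w.k_alpha_low * bp["alpha_low"] + w.k_theta * bp["theta"]
    return _checked_ratio(w.k_beta * bp["beta_low"], den, bp.total())


def cognitive_level(bp: BandPowers, w: FeedbackWeights | None = None) -> float:
    """Monitored cognitive index: (beta-low + alpha-high) over (alpha-low + theta)."""
    w = w or FeedbackWeights()
    num = w.k_beta * bp["beta_low"] + w.k_alpha_high * bp["alpha_high"]
    den = w.k_alpha_low * bp["alpha_low"] + w.k_theta * bp["theta"]
    return _checked_ratio(num, den, bp.total())


#: Default EMA coefficient applied to scores before threshold classification.
DEFAULT_EMA_ALPHA = 0.4


def smooth_score(
    samples: Iterable[AttentionSample], alpha_ema: float = DEFAULT_EMA_ALPHA
) -> list[AttentionSample]:
    """Exponential moving average of a score sequence.

    y[0] = x[0]; y[i] = alpha_ema*x[i] + (1-alpha_ema)*y[i-1].
    alpha_ema = 1 is the identity. Empty input yields empty output.
    """
    if not 0 < alpha_ema <= 1:
        raise ValueError("alpha_ema must be in (0, 1]")
    out: list[AttentionSample] = []
    state: float | None = None
    for s in samples:
        state = s.value if state is None else alpha_ema * s.value + (1 - alpha_ema) * state
        out.append(AttentionSample(t=s.t, value=state, kind=s.kind))
    return out


def ema(values: Sequence[float], alpha_ema: float = DEFAULT_EMA_ALPHA) -> float:
    """Final EMA state of a plain value sequence (helper for the controller)."""
    if not 0 < alpha_ema <= 1:
        raise ValueError("alpha_ema must be in (0, 1]")
    state = float(values[0])
    for v in values[1:]:
        state = alpha_ema * float(v) + (1 - alpha_ema) * state
    return state
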