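"""EEG frequency-band definitions.

The canonical clinical bands plus the alpha/beta sub-bands the feedback
indices use: beta-low (12-16 Hz) as the attentive numerator, alpha-low
(8-10 Hz) and theta (4-8 Hz) as the relaxed denominator, and alpha-high
(10-12 Hz, upper alpha) as the cognitive-performance marker.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )

    @property
    def width(self) -> float:
        return self.f_high - self.f_low

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("alpha_low", 8.0, 10.0),
    BandDefinition("alpha_high", 10.0, 12.0),
    BandDefinition("beta", 12.0, 32.0),
    BandDefinition("beta_low", 12.0, 16.0),
    BandDefinition("gamma", 32.0, 60.0),
)

_BY_NAME = {b.name: b for b in DEFAULT_BANDS}

#: Pairwise-disjoint bands that tile 1-60 Hz; used by the signal generator so
#: per-band oscillation powers add without overlap (alpha and beta are the
#: unions alpha_low+alpha_high and beta_low+beta_high).
GENERATOR_BANDS: tuple[BandDefinition, ...] = (
    _BY_NAME["delta"],
    _BY_NAME["theta"],
    _BY_NAME["alpha_low"],
    _BY_NAME["alpha_high"],
    _BY_NAME["beta_low"],
    BandDefinition("beta_high", 16.0, 32.0),
    _BY_NAME["gamma"],
)


def band_by_name(name: str) -> BandDefinition:
    """Look up a default band by name ('alpha_high', 'beta_low', ...)."""
    try:
        return _BY_NAME[name]
    except KeyError:
        if name == "beta_high":
            return GENERATOR_BANDS[5]
        raise KeyError(f"unknown band {name!r}; known: {sorted(_BY_NAME)}") from None
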