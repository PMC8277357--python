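"""Spectral estimation and band-power extraction.

PSDs are estimated with Welch's method (2-s Hann segments, 50% overlap by
default), giving 0.5 Hz resolution — enough to resolve the 2 Hz-wide alpha
sub-bands. Band power is the trapezoidal integral of the density over the
band, which makes power over adjacent sub-bands exactly additive
(alpha = alpha_low + alpha_high on any shared grid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .bands import BandDefinition, DEFAULT_BANDS
from .errors import (
    BandRangeError,
    InsufficientSamplesError,
    InvalidSignalError,
)

#: Default peak-to-peak artifact ceiling, µV. Windows exceeding it are flagged.
DEFAULT_ARTIFACT_PTP_UV = 200.0


@dataclass(frozen=True)
class EstimatorParams:
    """Welch estimator settings.

    window_s: segment length in seconds (default 2 s -> 0.5 Hz resolution).
    overlap: fractional segment overlap (default 0.5).
    taper: scipy window name (default 'hann').
    """

    window_s: float = 2.0
    overlap: float = 0.5
    taper: str = "hann"

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided power spectral density on [0, fs/2].

    density has units signal-units²/Hz; its integral over a band is the band
    power in signal-units².
    """

    frequencies: np.ndarray
    density: np.ndarray
    fs: float
    params: EstimatorParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))
        object.__setattr__(self, "density", np.asarray(self.density, float))
        if self.frequencies.shape != self.density.shape:
            raise ValueError("frequency grid and density must have equal shape")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def total_power(self) -> float:
        """Integral of the density over the full [0, fs/2] grid."""
        return float(self.density.sum() * self.df)


@dataclass(frozen=True)
class BandPowers:
    """Per-band power of one analysis window.

    powers maps band name -> power (signal-units²); t is the window end-time
    in seconds; artifact marks windows whose peak-to-peak amplitude exceeded
    the configured ceiling.
    """

    powers: Mapping[str, float]
    t: float = 0.0
    artifact: bool = False

    def __getitem__(self, band: str) -> float:
        return self.powers[band]

    def total(self) -> float:
        return float(sum(self.powers.values()))


def _validate_signal(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise InvalidSignalError(f"expected 1-D signal, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidSignalError("invalid signal: non-finite samples")
    return x


def compute_psd(
    x: Sequence[float] | np.ndarray,
    fs: float,
    params: EstimatorParams | None = None,
) -> PSDEstimate:
    """Welch PSD of a single-channel window.

    Raises InsufficientSamplesError if the signal is shorter than one Welch
    segment, InvalidSignalError on non-finite samples.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    params = params or EstimatorParams()
    x = _validate_signal(x)
    nperseg = int(round(params.window_s * fs))
    if len(x) < nperseg:
        raise InsufficientSamplesError(
            f"insufficient samples: {len(x)} < one {params.window_s} s window "
            f"({nperseg} samples at fs={fs})"
        )
    noverlap = int(round(params.overlap * nperseg))
    freqs, dens = sps.welch(
        x, fs=fs, window=params.taper, nperseg=nperseg, noverlap=noverlap,
        detrend="constant",
    )
    return PSDEstimate(frequencies=freqs, density=dens, fs=fs, params=params)


def band_power(psd: PSDEstimate, band: BandDefinition) -> float:
    """Integral of the density over [f_low, f_high).

    The band is resolved against the discrete grid as the half-open bin set
    f_low <= f < f_high (a bin on a shared edge belongs to the upper band),
    so powers over adjacent sub-bands add exactly and a windowed tone's
    near-edge leakage on the lower shared bin is not double-counted.
    """
    nyq = psd.fs / 2.0
    if band.f_low < 0 or band.f_high > nyq + 1e-9:
        raise BandRangeError(
            f"band out of range: {band.name} [{band.f_low}, {band.f_high}] Hz "
            f"vs Nyquist {nyq} Hz"
        )
    f, d = psd.frequencies, psd.density
    eps = psd.df * 1e-6
    mask = (f >= band.f_low - eps) & (f < band.f_high - eps)
    return float(d[mask].sum() * psd.df)


def band_powers(
    psd: PSDEstimate,
    bands: Iterable[BandDefinition] = DEFAULT_BANDS,
    t: float = 0.0,
    artifact: bool = False,
) -> BandPowers:
    """Band powers for every band in `bands` from one PSD estimate."""
    return BandPowers(
        powers={b.name: band_power(psd, b) for b in bands}, t=t, artifact=artifact
    )


def sliding_band_powers(
    stream: Sequence[float] | np.ndarray,
    fs: float,
    window_s: float = 2.0,
    step_s: float = 0.5,
    bands: Iterable[BandDefinition] = DEFAULT_BANDS,
    params: EstimatorParams | None = None,
    artifact_ptp: float = DEFAULT_ARTIFACT_PTP_UV,
) -> Iterator[BandPowers]:
    """Band powers over a sliding window advanced by `step_s`.

    Emits one BandPowers per step once the first full window is available;
    end-times are window_s, window_s+step_s, ... A trailing partial window
    emits nothing. Windows whose peak-to-peak amplitude exceeds artifact_ptp
    are emitted with artifact=True (callers decide whether to drop them).
    """
    if not (window_s >= step_s > 0):
        raise ValueError("need window_s >= step_s > 0")
    x = _validate_signal(stream)
    params = params or EstimatorParams(window_s=min(window_s, 2.0))
    bands = tuple(bands)
    nwin = int(round(window_s * fs))
    nstep = int(round(step_s * fs))
    for start in range(0, len(x) - nwin + 1, nstep):
        seg = x[start:start + nwin]
        psd = compute_psd(seg, fs, params)
        flagged = float(np.ptp(seg)) > artifact_ptp
        yield band_powers(psd, bands, t=(start + nwin) / fs, artifact=flagged)
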