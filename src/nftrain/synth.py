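"""Synthetic EEG generation.

Three generators make the whole pipeline testable without hardware:

* ``simulate_eeg`` — a single channel of 1/f ("pink") background noise with
  constant-amplitude narrowband oscillations embedded at band centers.
  Constant-amplitude sinusoids (rather than filtered noise) make band-power
  expectations exact: an oscillation of amplitude a carries power a²/2.
* ``simulate_attention_stream`` — the same channel driven by a latent
  attention trajectory (attentive / relaxed / fatigued), realized as
  per-band amplitude envelopes that cross-fade between state profiles.
  Attentive states carry strong beta-low; relaxed and fatigued states carry
  strong alpha-low and theta, so the revised attention index separates them.
* ``simulate_prepost_cohort`` — paired pre/post, eyes-open/eyes-closed
  16-channel cohorts with a standardized upper-alpha (10-12 Hz) eyes-open
  log-power increase injected in the occipital channels post-training, and
  zero injected effect everywhere else.

All generators are pure functions of their spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import GENERATOR_BANDS, band_by_name
from .errors import CohortError, NyquistError, TrajectoryError
from .recording import Recording

DEFAULT_FS = 250.0

#: The 16-electrode montage (10-20 positions) used for resting-state
#: recordings.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "P3", "Pz", "P4", "PO7", "PO8", "Oz",
)

#: Channels covering the occipital region (where resting alpha dominates).
OCCIPITAL_CHANNELS: tuple[str, ...] = ("PO7", "PO8", "Oz")


# ---------------------------------------------------------------------------
# single-channel generator


@dataclass(frozen=True)
class EEGSpec:
    """Recipe for one synthetic EEG channel.

    band_amplitudes maps a band name (default band set, or 'beta_high') to
    the µV amplitude of a constant sinusoid placed at the band center;
    one_over_f_exponent is the spectral slope of the background noise
    (power ∝ 1/f^exponent); noise_scale is the noise standard deviation
    in µV.
    """

    fs: float = DEFAULT_FS
    duration: float = 60.0
    band_amplitudes: Mapping[str, float] = field(default_factory=dict)
    one_over_f_exponent: float = 1.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be > 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for name, amp in self.band_amplitudes.items():
            band_by_name(name)  # raises on unknown band
            if amp < 0:
                raise ValueError(f"amplitude for {name} must be >= 0")


def _pink_noise(
    n: int, fs: float, exponent: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectrum ∝ 1/f^exponent, std = scale."""
    if scale == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def simulate_eeg(spec: EEGSpec) -> np.ndarray:
    """One channel of synthetic EEG, µV, deterministic per seed."""
    active = {n: a for n, a in spec.band_amplitudes.items() if a > 0}
    for name in active:
        band = band_by_name(name)
        if spec.fs <= 2 * band.f_high:
            raise NyquistError(
                f"Nyquist violation: fs={spec.fs} Hz cannot carry band "
                f"{name} (up to {band.f_high} Hz)"
            )
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    # draw oscillation phases in sorted band order so the realization does
    # not depend on dict insertion order
    for name in sorted(active):
        band = band_by_name(name)
        phase = rng.uniform(0, 2 * np.pi)
        x += active[name] * np.sin(2 * np.pi * band.center * t + phase)
    x += _pink_noise(n, spec.fs, spec.one_over_f_exponent, spec.noise_scale, rng)
    return x


# ---------------------------------------------------------------------------
# latent attention trajectories

#: Per-state band-amplitude profiles, µV. Attentive: beta-low dominant;
#: relaxed: alpha/theta dominant; fatigued: theta-heavy with depressed
#: beta-low — the drift the adaptive thresholds must absorb.
STATE_PROFILES: dict[str, dict[str, float]] = {
    "attentive": {"beta_low": 8.0, "alpha_low": 3.0, "alpha_high": 4.0, "theta": 3.0},
    "relaxed": {"beta_low": 3.0, "alpha_low": 8.0, "alpha_high": 6.0, "theta": 6.0},
    "fatigued": {"beta_low": 2.0, "alpha_low": 6.0, "alpha_high": 5.0, "theta": 9.0},
}

#: Length of the linear cross-fade between consecutive states, seconds.
STATE_RAMP_S = 2.0


@dataclass(frozen=True)
class TrajectorySegment:
    """One latent-state segment starting at `start` seconds."""

    start: float
    state: str
    profile: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.profile is None and self.state not in STATE_PROFILES:
            raise ValueError(
                f"unknown state {self.state!r}; known: {sorted(STATE_PROFILES)}"
            )

    def amplitudes(self) -> Mapping[str, float]:
        return self.profile if self.profile is not None else STATE_PROFILES[self.state]


@dataclass(frozen=True)
class AttentionTrajectory:
    """Contiguous, non-overlapping latent-state segments starting at t=0."""

    segments: tuple[TrajectorySegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise TrajectoryError("trajectory is empty")
        starts = [s.start for s in self.segments]
        if starts[0] != 0:
            raise TrajectoryError("trajectory not contiguous: must start at t=0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise TrajectoryError("trajectory not contiguous: starts must increase")


def simulate_attention_stream(
    traj: AttentionTrajectory, spec: EEGSpec
) -> np.ndarray:
    """Single-channel EEG whose band amplitudes track a latent trajectory.

    Per-band amplitude envelopes hold each segment's profile and cross-fade
    linearly over STATE_RAMP_S at segment boundaries; background noise comes
    from `spec` (its band_amplitudes field is ignored here).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    band_names = sorted({b for seg in traj.segments for b in seg.amplitudes()})
    starts = [seg.start for seg in traj.segments]
    if starts[-1] >= spec.duration and len(starts) > 1:
        raise TrajectoryError("trajectory segment starts beyond the spec duration")

    x = np.zeros(n)
    for name in band_names:
        band = band_by_name(name)
        if spec.fs <= 2 * band.f_high:
            raise NyquistError(
                f"Nyquist violation: fs={spec.fs} Hz cannot carry band {name}"
            )
        # step envelope through segment targets, then linear cross-fade
        env = np.zeros(n)
        for i, seg in enumerate(traj.segments):
            hi = starts[i + 1] if i + 1 < len(starts) else spec.duration
            mask = (t >= seg.start) & (t < hi)
            env[mask] = seg.amplitudes().get(name, 0.0)
        if STATE_RAMP_S > 0:
            k = max(int(round(STATE_RAMP_S * spec.fs)), 1)
            kernel = np.ones(k) / k
            padded = np.pad(env, k, mode="edge")
            env = np.convolve(padded, kernel, mode="same")[k:-k]
        phase = rng.uniform(0, 2 * np.pi)
        x += env * np.sin(2 * np.pi * band.center * t + phase)
    x += _pink_noise(n, spec.fs, spec.one_over_f_exponent, spec.noise_scale, rng)
    return x


# ---------------------------------------------------------------------------
# pre/post cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Paired pre/post cohort with one localized injected effect.

    effect is the standardized mean change d of the targeted cell on the
    paired-difference scale: mean(post − pre) / sd(post − pre) of eyes-open
    upper-alpha log₁₀ power in the occipital channels. All other
    band × region × condition cells receive no injected change. between_sd
    and within_sd are log₁₀-power standard deviations of the subject random
    effect and of the per-recording (session-level) fluctuation; channel_sd
    is a smaller per-channel jitter.
    """

    n_subjects: int = 35
    effect: float = 0.0
    between_sd: float = 0.30
    within_sd: float = 0.15
    channel_sd: float = 0.05
    seed: int = 0
    fs: float = DEFAULT_FS
    duration: float = 20.0
    noise_scale: float = 1.0
    effect_band: str = "alpha_high"
    effect_condition: str = "eyes_open"
    effect_channels: tuple[str, ...] = OCCIPITAL_CHANNELS

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise CohortError("cohort too small: need n_subjects >= 2")
        if self.between_sd <= 0 or self.within_sd <= 0:
            raise CohortError("between_sd and within_sd must be > 0")


#: Baseline mean log₁₀ band power (µV²) by generator band. Alpha and theta
#: dominate at rest; gamma is weak.
_BASELINE_LOG10 = {
    "delta": 1.2,
    "theta": 1.0,
    "alpha_low": 1.1,
    "alpha_high": 1.1,
    "beta_low": 0.7,
    "beta_high": 0.5,
    "gamma": 0.1,
}
#: Additional alpha log-power with eyes closed (classic alpha blocking).
_EYES_CLOSED_ALPHA_BOOST = 0.3
#: Additional alpha log-power over posterior (parietal/occipital) channels.
_POSTERIOR_ALPHA_BOOST = 0.2
_POSTERIOR = ("P3", "Pz", "P4", "PO7", "PO8", "Oz")


def _cell_mean(band: str, channel: str, condition: str) -> float:
    mu = _BASELINE_LOG10[band]
    if band in ("alpha_low", "alpha_high"):
        if condition == "eyes_closed":
            mu += _EYES_CLOSED_ALPHA_BOOST
        if channel in _POSTERIOR:
            mu += _POSTERIOR_ALPHA_BOOST
    return mu


def _injected_shift(spec: CohortSpec) -> float:
    # d is standardized on the paired difference whose sd is sqrt(2)·within_sd
    return spec.effect * np.sqrt(2.0) * spec.within_sd


def simulate_cohort_band_powers(
    spec: CohortSpec,
    montage: Sequence[str] = DEFAULT_MONTAGE,
) -> pd.DataFrame:
    """Draw the cohort's per-cell log₁₀ band powers without waveforms.

    Returns a tidy frame with columns subject, phase, condition, channel,
    band, log10_power. The per-cell model is

        log₁₀P = µ(band, channel, condition) + b_subject
                 + s(subject, phase, condition, band)   # session level
                 + c(subject, phase, condition, channel, band)  # channel jitter
                 + δ·[targeted cell, post]

    with b ~ N(0, between_sd²), s ~ N(0, within_sd²), c ~ N(0, channel_sd²)
    and δ = d·√2·within_sd. This is the exact distribution the waveform
    generator realizes; Monte-Carlo calibration studies use it directly.
    """
    rng = np.random.default_rng(spec.seed)
    bands = [b.name for b in GENERATOR_BANDS]
    delta = _injected_shift(spec)
    rows = []
    for i in range(spec.n_subjects):
        subj = f"subj{i + 1:02d}"
        b_subj = rng.normal(0, spec.between_sd)
        for phase in ("pre", "post"):
            for condition in ("eyes_open", "eyes_closed"):
                session = rng.normal(0, spec.within_sd, size=len(bands))
                for bi, band in enumerate(bands):
                    jitter = rng.normal(0, spec.channel_sd, size=len(montage))
                    for ci, ch in enumerate(montage):
                        val = (
                            _cell_mean(band, ch, condition)
                            + b_subj + session[bi] + jitter[ci]
                        )
                        if (
                            phase == "post"
                            and band == spec.effect_band
                            and condition == spec.effect_condition
                            and ch in spec.effect_channels
                        ):
                            val += delta
                        rows.append((subj, phase, condition, ch, band, val))
    return pd.DataFrame(
        rows,
        columns=["subject", "phase", "condition", "channel", "band", "log10_power"],
    )


def simulate_prepost_cohort(
    spec: CohortSpec,
    montage: Sequence[str] = DEFAULT_MONTAGE,
) -> list[Recording]:
    """Realize the cohort as waveform Recordings (4 per subject).

    Each drawn cell log-power becomes the power of a constant sinusoid at
    the band center (amplitude √(2·10^logP)) riding on 1/f noise. Returns
    n_subjects × {pre, post} × {eyes_open, eyes_closed} recordings,
    bit-identical for identical specs.
    """
    table = simulate_cohort_band_powers(spec, montage)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    recordings: list[Recording] = []
    for (subj, phase, condition), sub in table.groupby(
        ["subject", "phase", "condition"], sort=True
    ):
        channels: dict[str, np.ndarray] = {}
        for ch in montage:
            chrows = sub[sub["channel"] == ch]
            x = np.zeros(n)
            for band_name, logp in zip(chrows["band"], chrows["log10_power"]):
                band = band_by_name(band_name)
                amp = np.sqrt(2.0 * 10.0 ** logp)
                phase_angle = rng.uniform(0, 2 * np.pi)
                x += amp * np.sin(2 * np.pi * band.center * t + phase_angle)
            x += _pink_noise(n, spec.fs, 1.0, spec.noise_scale, rng)
            channels[ch] = x
        recordings.append(
            Recording(subject=subj, phase=phase, condition=condition,
                      channels=channels, fs=spec.fs)
        )
    return recordings
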