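# Methods

This note documents the models, defaults, and design choices behind
`nftrain`, and what the synthetic-data generators do and do not emulate.

## Spectral estimation and band powers

PSDs are estimated with Welch's method: 2-s Hann segments, 50% overlap,
constant detrend. Two seconds gives 0.5 Hz resolution — the minimum that
resolves the 2 Hz-wide alpha sub-bands (8–10, 10–12 Hz) — while staying
responsive enough for game control; the streaming analysis advances this
window every 0.5 s.

Band power is the integral of the density over the band, resolved against
the discrete grid as the half-open bin set `f_low ≤ f < f_high`: a bin on a
shared edge (10 Hz) belongs to the upper band (alpha-high). This convention
makes sub-band additivity exact up to floating-point rounding
(alpha = alpha_low + alpha_high bit-for-nearly-bit) and captures a Hann
window's near-edge leakage without double counting, so a pure tone at a
band center recovers a²/2 within 5% and places ≥90% of its power inside
any band ≥2 Hz wide. Parseval holds to within ~10% for broadband signals
(taper bias and the dropped Nyquist tail account for the slack).

Artifact policy: windows whose peak-to-peak amplitude exceeds 200 µV
(configurable) are flagged. Offline analysis excludes them; the online loop
holds the previous valid score instead, so a blink cannot yank the game.
Dry-electrode recordings need some such rule; the ceiling is a common
clinical choice, not a fitted value.

## Feedback indices

The three indices (see README) are pure ratios of band powers, hence
invariant under any uniform rescaling of the spectrum — amplifier gain
cannot move the score. The scaling constants K are exposed in config and
default to 1; they exist so a deployment can rebalance numerator and
denominator per user, but nothing in this package fits them.

Degenerate spectra: if a weighted denominator falls below 10⁻¹² of total
window power the index raises `DegenerateSpectrumError`; the session loop
treats this like an artifact window. Scores are smoothed with an EMA
(coefficient 0.4 per 0.5-s step) before classification, because the raw
ratio is volatile at 2-s windows.

The session loop drives the game with `attention_new`; `attention_original`
is retained for comparison and `cognitive_level` is logged per window but
never controls the game.

## Calibration and threshold control

Calibration takes ≥5 valid windows per instructed state (default 30 s
each) and uses the **median** score per state — robust to a few artifact
windows — requiring A > R. Thresholds are placed by the one-third rule with
`fraction` restricted to (0, 0.5) exclusive: at 0.5 the neutral band
collapses. Ties classify to the extreme label (≥ upper → above) so
classification is deterministic.

Adaptation (policy `recenter`) runs once per second: the new midpoint is
`(1 − r)·midpoint + r·EMA(scores of the last 15 s)`, width preserved, band
shifted up if the lower threshold would go negative. The adaptation rate r
defaults to **0.2**. We initially ran r = 0.1, but in closed-loop
simulations with a 50% latent-attention drop the reward-rate transient then
consumed about half the ±10-point recovery tolerance over the following
minute; r = 0.2 halves the transient (mean recovery deficit ≈ 2 points)
while leaving steady-state midpoint jitter acceptable. The engagement
property is evaluated at the score level (latent level plus Gaussian noise
of constant σ) because it is a property of the controller geometry: with
width conserved, the steady-state reward rate is P(score > midpoint + w/2),
which recovers exactly when score variability is unchanged by the drop.

`static` policy freezes the thresholds at their calibrated values — this is
the reference against which the recenter policy's fatigue tolerance is
tested.

## Games and protocol

Games run on discrete 0.5-s ticks matching the analysis step. Four of the
five games are one law: speed += dv on reward, −dv (floored at 0) on
penalty, unchanged on neutral. The shooter averages the smoothed score over
3-s windows against its own threshold; every 10th point raises that
threshold by 5% (configurable — the escalation magnitude and initial
threshold are deployment choices; the engine seeds the initial shoot
threshold from the session's upper threshold).

The scheduler emits `sessions_per_week × weeks` dated sessions, spread
evenly within each week, each packing as many (game + break) pairs as fit:
with the 2.5-min game and 1-min break defaults, a 30-minute session holds
8 game blocks (8 × 3.5 = 28 min). Game duration is constrained to 2–3
minutes.

## Synthetic EEG

`simulate_eeg` embeds constant-amplitude sinusoids at band centers in 1/f^χ
Gaussian noise (χ default 1, realized by spectral shaping, normalized to
the requested standard deviation). Constant amplitudes — rather than
band-filtered noise — are deliberate: they make band-power expectations
exact (a²/2), so spectral tests have closed-form oracles. The cost is
realism: real EEG band power fluctuates strongly window to window, real
oscillations have bandwidth, and no blink/EMG artifacts are generated
beyond what a caller injects. Passing tests therefore demonstrate correct
signal processing and control logic, not performance on hardware
recordings.

`simulate_attention_stream` drives per-band amplitude envelopes through
latent states (attentive: beta-low dominant; relaxed: alpha/theta dominant;
fatigued: theta-heavy), cross-fading linearly over 2 s at boundaries.
Profiles were chosen so the attentive/relaxed medians of `attention_new`
separate decisively (≈3.5 vs ≈0.09 at the defaults) — calibration should
not be the fragile step in a synthetic pipeline.

### Pre/post cohorts

The cohort generator draws per-cell log₁₀ band powers from

```
log₁₀P = µ(band, channel, condition) + b_subject + s_session + c_channel + δ·[target cell, post]
```

with `b ~ N(0, 0.30²)` (between subjects), `s ~ N(0, 0.15²)` per
(subject, phase, condition, band) — a session-level gain/state fluctuation
shared across channels — and `c ~ N(0, 0.05²)` per channel. Baselines give
alpha a +0.3 log₁₀ eyes-closed boost and +0.2 over posterior channels
(classic alpha topography). The injected effect is standardized on the
paired-difference scale: δ = d·√2·0.15, so the targeted cell's paired t has
noncentrality ≈ d·√n and empirical power can be checked against the
noncentral-t closed form. (The small per-channel jitter dilutes realized d
by ~2%, and in pooled regions where only some channels carry the effect —
group 7 — the group-mean dilutes it further; both are physical, not bugs.)

The generator has two faithful modes sharing this one model:
`simulate_cohort_band_powers` returns the drawn log powers directly and is
what Monte-Carlo calibration studies use; `simulate_prepost_cohort`
realizes every cell as a sinusoid of amplitude √(2·10^logP) on 1/f noise
(default 20 s at 250 Hz) and is what end-to-end and file-format tests use.
A consistency test verifies the waveform route reproduces the drawn values
to ≲0.05 log₁₀ units.

The default montage is the 16 electrodes Fp1, Fp2, F3, Fz, F4, T7, C3, Cz,
C4, T8, P3, Pz, P4, PO7, PO8, Oz. The nine regional groups are a
user-editable convention: G1 {Fp1,Fp2} prefrontal, G2 {PO7,PO8,Oz}
occipital, G3 {F3,Fz,F4} frontal, G4 {C3,Cz,C4} central, G5 {P3,Pz,P4}
parietal, G6 = G1∪G3, G7 = G5∪G2, G8 {T7}, G9 {T8}.

## Pre/post analysis choices

Group PSD is the pointwise mean of member-channel PSDs; band power is
integrated from that average (identical, by linearity, to averaging the
channels' band powers). Analysis runs on **log₁₀ power**, which stabilizes
the variance of power ratios across subjects; mean changes in the results
table are therefore in log₁₀ units. Eyes-open and eyes-closed recordings
are analyzed separately, never pooled.

The paired t is computed from the difference-score formula
`t = mean(d)/(sd(d)/√n)`, df = n−1, two-sided p from the t distribution; it
is cross-checked against an independent reference implementation to 10⁻¹⁰
in tests. Primary output reports uncorrected per-cell p at α = .05 —
matching how such tables are conventionally read — with a
Benjamini–Hochberg adjusted column appended because 144 cells at α = .05
yield ~7 chance flags, and the session-level noise makes flags arrive in
correlated blocks (all regions of one band × condition together).
Identical pre/post values return t = 0, p = 1; zero variance with a
nonzero mean change is an error, not a p-value.

Subjects missing any of their four recordings are excluded with a logged
warning; fewer than two complete subjects aborts. Score-table comparison is
pairwise-complete per measure and reports NaN statistics for measures with
fewer than two complete pairs.

## Problem sizes and numerics

Monte-Carlo studies in tests and in `scripts/acceptance.py` use 500
cohorts of 35 subjects (summary mode) for type-I and power, 20 seeds for
closed-loop properties, 50 seeds for the score-separation property, and a
single 35-subject waveform cohort (20-s recordings) for the end-to-end
check — sizes at which the binomial Monte-Carlo error is comfortably
inside each tolerance. All generators are pure functions of their spec
including the seed; named substreams are derived from one root seed.

## File formats

Multichannel recordings travel as plain EDF (16-bit, 1-s records, µV),
written by a self-contained encoder and read back through MNE — which
doubles as an independent conformance check; round-trip error is bounded by
the per-channel quantization step. Cohort files follow
`subj{N}_{pre|post}_{eo|ec}.edf`. Single-channel streams are CSV
(`time_s,eeg_uv`); session logs are JSONL with one record per analysis step
(band powers, scores, control label, thresholds, game state, artifact
flag), and the session summary is a pure function of those records, so
replaying a saved log reproduces it exactly. Configuration is YAML/JSON
validated strictly against the schema in `nftrain.config` — unknown keys
are errors.

## Known limitations

- Constant-amplitude oscillations understate real band-power volatility;
  controller robustness against realistic volatility is tested with
  score-level noise, not waveform noise.
- No individual-alpha-peak adaptation of band edges; bands are fixed.
- No artifact synthesis beyond amplitude outliers, and no ocular/EMG
  templates.
- The EDF writer emits plain EDF (not EDF+): no annotations, single
  continuous segment, integer sampling rates only.
- Group membership of the nine scalp regions is a convention; analyses
  accept any user-supplied grouping map.
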