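"""The closed training loop: calibration → thresholds → game with adaptation.

`run_session` wires the whole engine together the way a training session
runs on hardware, but over arrays: two instructed calibration streams anchor
the thresholds, then the game stream is analyzed in sliding windows whose
feedback scores (EMA-smoothed) are classified against the adaptive
thresholds and drive the abstract game. Every analysis step appends one
JSONL-able record, and the session summary is recomputed from those records
so that replaying a saved log reproduces it exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import RunConfig
from .control import (
    Calibration,
    ControlSignal,
    ThresholdState,
    adapt,
    calibrate,
    classify,
    init_thresholds,
)
from .feedback import (
    AttentionSample,
    FeedbackWeights,
    attention_new,
    attention_original,
    cognitive_level,
)
from .games import GameState, shoot_scorer, speed_controller
from .spectral import EstimatorParams, sliding_band_powers
from .synth import AttentionTrajectory, EEGSpec, TrajectorySegment, simulate_attention_stream


@dataclass
class SessionResult:
    """Outcome of one training session."""

    summary: dict
    records: list[dict]
    calibration: Calibration
    thresholds: ThresholdState


def _weights(cfg: RunConfig) -> FeedbackWeights:
    f = cfg.feedback
    return FeedbackWeights(
        k_beta=f.k_beta, k_alpha=f.k_alpha, k_alpha_low=f.k_alpha_low,
        k_alpha_high=f.k_alpha_high, k_theta=f.k_theta,
    )


def _scores(stream: np.ndarray, cfg: RunConfig) -> list[float]:
    """Raw (unsmoothed) control-formula scores of every clean window."""
    w = _weights(cfg)
    est = cfg.estimator
    params = EstimatorParams(window_s=est.window_s, overlap=est.overlap, taper=est.taper)
    formula = attention_new if cfg.feedback.formula == "new" else attention_original
    out = []
    for bp in sliding_band_powers(
        stream, cfg.synth.fs, est.window_s, est.step_s,
        params=params, artifact_ptp=est.artifact_ptp_uv,
    ):
        if not bp.artifact:
            out.append(formula(bp, w))
    return out


def _substream_seeds(seed: int, n: int = 4) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def default_calibration_streams(cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic attentive and relaxed instructed-state streams."""
    s_att, s_rel, _, _ = _substream_seeds(cfg.seed)
    dur = cfg.controller.calibration_s
    base = dict(fs=cfg.synth.fs, duration=dur, noise_scale=cfg.synth.noise_scale,
                one_over_f_exponent=cfg.synth.one_over_f_exponent)
    att = simulate_attention_stream(
        AttentionTrajectory((TrajectorySegment(0.0, "attentive"),)),
        EEGSpec(seed=s_att, **base),
    )
    rel = simulate_attention_stream(
        AttentionTrajectory((TrajectorySegment(0.0, "relaxed"),)),
        EEGSpec(seed=s_rel, **base),
    )
    return att, rel


def default_game_stream(
    cfg: RunConfig, trajectory: AttentionTrajectory | None = None
) -> np.ndarray:
    """Synthetic game-phase stream following `trajectory` (default: attentive)."""
    _, _, s_game, _ = _substream_seeds(cfg.seed)
    trajectory = trajectory or AttentionTrajectory((TrajectorySegment(0.0, "attentive"),))
    spec = EEGSpec(
        fs=cfg.synth.fs, duration=cfg.synth.game_duration_s,
        noise_scale=cfg.synth.noise_scale,
        one_over_f_exponent=cfg.synth.one_over_f_exponent, seed=s_game,
    )
    return simulate_attention_stream(trajectory, spec)


def summarize(records: Sequence[Mapping]) -> dict:
    """Session summary recomputed purely from the step records."""
    if not records:
        return {"n_steps": 0}
    labels = [r["control"] for r in records]
    n = len(labels)
    att = [r["attention"] for r in records]
    return {
        "n_steps": n,
        "mean_attention": float(np.mean(att)),
        "frac_above": labels.count("above") / n,
        "frac_neutral": labels.count("neutral") / n,
        "frac_below": labels.count("below") / n,
        "final_speed": records[-1]["game"]["speed"],
        "game_score": records[-1]["game"]["score"],
    }


def run_session(
    cfg: RunConfig,
    game_stream: np.ndarray | None = None,
    attentive_stream: np.ndarray | None = None,
    relaxed_stream: np.ndarray | None = None,
    trajectory: AttentionTrajectory | None = None,
    log_path: str | Path | None = None,
) -> SessionResult:
    """Execute calibration, threshold initialization, and the game loop.

    Streams not supplied are synthesized from the config seed. The game
    loop advances one analysis step per estimator step (default 0.5 s),
    smooths the control score with an EMA, classifies it against the
    thresholds, updates the game, and recenters the thresholds once per
    `adapt_every_s` over the last `adapt_horizon_s` of scores. Artifact
    windows repeat the previous valid score.
    """
    if attentive_stream is None or relaxed_stream is None:
        att_default, rel_default = default_calibration_streams(cfg)
        attentive_stream = attentive_stream if attentive_stream is not None else att_default
        relaxed_stream = relaxed_stream if relaxed_stream is not None else rel_default
    if game_stream is None:
        game_stream = default_game_stream(cfg, trajectory)

    cal = calibrate(_scores(attentive_stream, cfg), _scores(relaxed_stream, cfg))
    st = init_thresholds(
        cal, fraction=cfg.controller.fraction, policy=cfg.controller.policy,
        adapt_rate=cfg.controller.adapt_rate,
    )

    w = _weights(cfg)
    est = cfg.estimator
    params = EstimatorParams(window_s=est.window_s, overlap=est.overlap, taper=est.taper)
    formula = attention_new if cfg.feedback.formula == "new" else attention_original
    alpha_ema = cfg.feedback.ema_alpha
    horizon = cfg.controller.adapt_horizon_s
    adapt_every = max(int(round(cfg.controller.adapt_every_s / est.step_s)), 1)

    if cfg.game.game_id == "shoot_321":
        game = GameState(game_id="shoot_321", shoot_threshold=st.upper)
    else:
        game = GameState(game_id=cfg.game.game_id)

    records: list[dict] = []
    smoothed: float | None = None
    last_raw: float | None = None
    recent: list[AttentionSample] = []
    shoot_window: list[AttentionSample] = []
    step_i = 0

    for bp in sliding_band_powers(
        game_stream, cfg.synth.fs, est.window_s, est.step_s,
        params=params, artifact_ptp=est.artifact_ptp_uv,
    ):
        step_i += 1
        if bp.artifact and last_raw is not None:
            raw = last_raw  # hold the last valid score through artifacts
        elif bp.artifact:
            continue
        else:
            raw = formula(bp, w)
        last_raw = raw
        smoothed = raw if smoothed is None else alpha_ema * raw + (1 - alpha_ema) * smoothed
        sample = AttentionSample(t=bp.t, value=smoothed, kind=cfg.feedback.formula)
        sig = classify(sample, st)

        recent.append(sample)
        recent = [s for s in recent if s.t > sample.t - horizon]
        if step_i % adapt_every == 0:
            st = adapt(st, recent)

        if game.game_id == "shoot_321":
            shoot_window.append(sample)
            if sample.t - shoot_window[0].t >= 3.0 - est.step_s / 2:
                game = shoot_scorer(game, shoot_window)
                shoot_window = []
        else:
            game = speed_controller(game, sig, cfg.game.dv)
            if sig.label == "above":
                game = GameState(
                    game_id=game.game_id, speed=game.speed, score=game.score + 1,
                    shoot_threshold=game.shoot_threshold, elapsed=sample.t,
                )

        records.append({
            "t": round(sample.t, 6),
            "band_powers": {k: float(v) for k, v in bp.powers.items()},
            "attention": float(smoothed),
            "attention_raw": float(raw),
            "cognitive_level": float(cognitive_level(bp, w)),
            "control": sig.label,
            "thresholds": {"lower": st.lower, "upper": st.upper},
            "game": {"speed": game.speed, "score": game.score},
            "artifact": bool(bp.artifact),
        })

    summary = summarize(records)
    summary["calibration"] = {
        "relaxed_level": cal.relaxed_level,
        "attentive_level": cal.attentive_level,
    }
    summary["final_thresholds"] = {"lower": st.lower, "upper": st.upper}

    if log_path is not None:
        log_path = Path(log_path)
        with open(log_path, "w") as fh:
            for r in records:
                fh.write(json.dumps(r) + "\n")
        cal_path = log_path.with_suffix(".calibration.json")
        cal_path.write_text(json.dumps(summary["calibration"], indent=2))

    return SessionResult(summary=summary, records=records, calibration=cal, thresholds=st)


def read_session_log(path: str | Path) -> list[dict]:
    """Load a JSONL session log back into step records."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records
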