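"""Renderer-free game-control semantics and the session/protocol scheduler.

Five training games share one control idea: the classified attention signal
drives the main character. Four of them (Run Run, Sunshine Day, Cast Away,
Paper Plane) reduce to a speed controller — reward accelerates, penalty
decelerates, neutral does nothing. 321 Shoot instead averages the attention
score over 3-second windows against a shoot threshold that escalates every
10 points. Sessions follow the training protocol: 30-minute sessions, twice
a week for ten weeks (20 sessions), each session alternating 2-3 minute game
blocks with breaks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .control import ControlSignal
from .feedback import AttentionSample

GAME_IDS = ("run_run", "sunshine", "cast_away", "paper_plane", "shoot_321")

DEFAULT_SHOOT_WINDOW_S = 3.0
DEFAULT_SHOOT_ESCALATION = 0.05  # +5% of current threshold per 10 points
DEFAULT_GAME_MINUTES = 2.5
DEFAULT_BREAK_MINUTES = 1.0
DEFAULT_SESSION_MINUTES = 30
DEFAULT_TICK_S = 0.5


@dataclass(frozen=True)
class GameState:
    """Abstract state of one game: speed, score, shoot threshold, clock."""

    game_id: str
    speed: float = 0.0
    score: int = 0
    shoot_threshold: float = 0.0
    elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.game_id not in GAME_IDS:
            raise ValueError(f"unknown game {self.game_id!r}; known: {GAME_IDS}")
        if self.speed < 0 or self.score < 0:
            raise ValueError("speed and score must be >= 0")


@dataclass(frozen=True)
class SessionBlock:
    """One scheduled block within a session: a game or a break."""

    kind: str  # {"game", "break"}
    minutes: float


@dataclass(frozen=True)
class Session:
    """A dated training session made of alternating game and break blocks."""

    date: dt.date
    blocks: tuple[SessionBlock, ...]

    @property
    def minutes(self) -> float:
        return sum(b.minutes for b in self.blocks)


@dataclass(frozen=True)
class SessionPlan:
    """The full training plan: dated sessions with per-session block layout."""

    sessions: tuple[Session, ...]
    session_minutes: float = DEFAULT_SESSION_MINUTES
    game_minutes: float = DEFAULT_GAME_MINUTES
    break_minutes: float = DEFAULT_BREAK_MINUTES

    def __post_init__(self) -> None:
        if not 2.0 <= self.game_minutes <= 3.0:
            raise ValueError("game blocks must last 2-3 minutes")

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)


def speed_controller(state: GameState, sig: ControlSignal, dv: float) -> GameState:
    """Reward speeds the character up by dv, penalty slows it (floored at
    rest), neutral leaves it untouched."""
    if dv <= 0:
        raise ValueError("dv must be > 0")
    if sig.label == "above":
        speed = state.speed + dv
    elif sig.label == "below":
        speed = max(0.0, state.speed - dv)
    else:
        speed = state.speed
    return replace(state, speed=speed)


def shoot_scorer(
    state: GameState,
    window_scores: Sequence[AttentionSample],
    window_s: float = DEFAULT_SHOOT_WINDOW_S,
    escalation: float = DEFAULT_SHOOT_ESCALATION,
) -> GameState:
    """One 321-Shoot attempt from a 3-second window of attention scores.

    If the window mean clears the shoot threshold the player scores; each
    time the score crosses a multiple of 10 the threshold rises by
    `escalation` (a fraction of its current value). Windows spanning less
    than `window_s` make no attempt.
    """
    if not window_scores:
        return state
    span = window_scores[-1].t - window_scores[0].t
    # a window of k samples at step dt spans (k-1)*dt; accept within one step
    step = span / max(len(window_scores) - 1, 1)
    if span + step < window_s - 1e-9:
        return state
    mean = float(np.mean([s.value for s in window_scores]))
    if mean < state.shoot_threshold:
        return state
    score = state.score + 1
    threshold = state.shoot_threshold
    if score % 10 == 0:
        threshold *= 1.0 + escalation
    return replace(state, score=score, shoot_threshold=threshold)


def schedule_sessions(
    start_date: dt.date,
    sessions_per_week: int = 2,
    weeks: int = 10,
    session_minutes: float = DEFAULT_SESSION_MINUTES,
    game_minutes: float = DEFAULT_GAME_MINUTES,
    break_minutes: float = DEFAULT_BREAK_MINUTES,
) -> SessionPlan:
    """Build the dated training plan.

    Produces exactly sessions_per_week x weeks sessions, spread evenly
    within each week. Each session packs alternating game blocks and breaks:
    as many (game + break) pairs as fit in session_minutes.
    """
    if sessions_per_week <= 0 or weeks <= 0 or session_minutes <= 0:
        raise ValueError("counts and durations must be positive")

    pair = game_minutes + break_minutes
    n_games = int(session_minutes // pair)
    blocks: list[SessionBlock] = []
    for _ in range(n_games):
        blocks.append(SessionBlock("game", game_minutes))
        blocks.append(SessionBlock("break", break_minutes))
    block_tuple = tuple(blocks)

    offsets = [int(np.floor(7 * k / sessions_per_week)) for k in range(sessions_per_week)]
    sessions = tuple(
        Session(date=start_date + dt.timedelta(days=7 * w + off), blocks=block_tuple)
        for w in range(weeks)
        for off in offsets
    )
    return SessionPlan(
        sessions=sessions,
        session_minutes=session_minutes,
        game_minutes=game_minutes,
        break_minutes=break_minutes,
    )
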