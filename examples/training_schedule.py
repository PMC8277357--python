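"""Build the standard training plan: 30-minute sessions, twice a week for
ten weeks, each alternating 2.5-minute game blocks with 1-minute breaks."""

import datetime as dt

from nftrain import schedule_sessions

plan = schedule_sessions(dt.date(2026, 1, 5), sessions_per_week=2, weeks=10)
games = [b for b in plan.sessions[0].blocks if b.kind == "game"]
print(f"{plan.n_sessions} sessions; each fits {len(games)} game blocks "
      f"of {plan.game_minutes:g} min inside {plan.session_minutes:g} min")
for i, s in enumerate(plan.sessions[:4], 1):
    print(f"  session {i}: {s.date.isoformat()}")
print("  ...")
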