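"""The threshold controller in isolation.

Calibrates from two score samples, shows the one-third-rule placement,
classifies a few scores, then feeds a sustained low score history and shows
the width-preserving recentering that keeps the game winnable under fatigue.
"""

from nftrain import AttentionSample, adapt, calibrate, classify, init_thresholds

cal = calibrate(attentive_scores=[0.8, 0.9, 1.0, 0.9, 0.8],
                relaxed_scores=[0.2, 0.3, 0.4, 0.3, 0.2])
print(f"calibration: relaxed R={cal.relaxed_level}, attentive A={cal.attentive_level}")

st = init_thresholds(cal)  # fraction = 1/3
print(f"one-third rule: lower={st.lower:.3f}, upper={st.upper:.3f} (width {st.width:.3f})")

for v in (0.75, 0.6, 0.45):
    sig = classify(AttentionSample(t=0.0, value=v), st)
    print(f"  score {v:.2f} -> {sig.label}")

fatigued = [AttentionSample(t=float(t), value=0.35) for t in range(20)]
for step in range(30):
    st = adapt(st, fatigued)
print(f"after 30 adapt steps at score 0.35: lower={st.lower:.3f}, upper={st.upper:.3f}"
      f" (width still {st.width:.3f})")
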