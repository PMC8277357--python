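"""Calibration, threshold placement, classification, adaptation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nftrain import (
    AttentionSample,
    Calibration,
    CalibrationError,
    ThresholdState,
    adapt,
    calibrate,
    classify,
    init_thresholds,
)


def sample(v, t=0.0):
    return AttentionSample(t=t, value=v)


class TestCalibrate:
    def test_constant_sequences(self):
        cal = calibrate([0.9] * 5, [0.3] * 5)
        assert (cal.attentive_level, cal.relaxed_level) == (0.9, 0.3)

    def test_median_statistic(self):
        cal = calibrate([0.8, 0.9, 1.0, 0.9, 0.8], [0.2, 0.3, 0.4, 0.3, 0.2])
        assert (cal.attentive_level, cal.relaxed_level) == (0.9, 0.3)

    def test_not_separable(self):
        with pytest.raises(CalibrationError, match="not separable"):
            calibrate([0.3] * 5, [0.3] * 5)

    def test_insufficient_data(self):
        with pytest.raises(CalibrationError, match="insufficient"):
            calibrate([0.9] * 3, [0.3] * 5)


class TestInitThresholds:
    def test_one_third_rule(self):
        st_ = init_thresholds(Calibration(0.3, 0.9, 5))
        assert st_.lower == pytest.approx(0.5)
        assert st_.upper == pytest.approx(0.7)

    def test_unit_interval(self):
        st_ = init_thresholds(Calibration(0.0, 1.0, 5))
        assert (st_.lower, st_.upper) == (pytest.approx(1 / 3), pytest.approx(2 / 3))

    @pytest.mark.parametrize("fraction", [0.0, 0.5, 0.7, -0.1])
    def test_degenerate_fraction_rejected(self, fraction):
        with pytest.raises(ValueError, match="fraction"):
            init_thresholds(Calibration(0.0, 1.0, 5), fraction=fraction)


class TestClassify:
    st_ = ThresholdState(lower=0.5, upper=0.7)

    @pytest.mark.parametrize("value,label", [
        (0.8, "above"), (0.6, "neutral"), (0.4, "below"),
        (0.7, "above"), (0.5, "below"),  # ties take the extreme label
    ])
    def test_three_way(self, value, label):
        assert classify(sample(value), self.st_).label == label


class TestAdapt:
    def test_fixed_point_at_midpoint(self):
        st_ = ThresholdState(lower=0.5, upper=0.7)
        out = adapt(st_, [sample(0.6, t) for t in range(20)])
        assert (out.lower, out.upper) == (pytest.approx(0.5), pytest.approx(0.7))

    def test_full_recentering_preserves_width(self):
        st_ = ThresholdState(lower=0.5, upper=0.7, adapt_rate=1.0)
        out = adapt(st_, [sample(0.2, t) for t in range(20)])
        assert (out.lower, out.upper) == (pytest.approx(0.1), pytest.approx(0.3))

    def test_empty_history_unchanged(self):
        st_ = ThresholdState(lower=0.5, upper=0.7)
        assert adapt(st_, []) is st_

    def test_static_policy_never_moves(self):
        st_ = ThresholdState(lower=0.5, upper=0.7, policy="static")
        assert adapt(st_, [sample(5.0)]) is st_

    def test_lower_clamped_at_zero_width_kept(self):
        st_ = ThresholdState(lower=0.05, upper=0.45, adapt_rate=1.0)
        out = adapt(st_, [sample(0.0)])
        assert out.lower == pytest.approx(0.0)
        assert out.upper == pytest.approx(0.4)

    def test_sustained_low_input_drives_upper_down_to_floor(self):
        st_ = ThresholdState(lower=0.5, upper=0.7, adapt_rate=0.2)
        uppers = []
        for _ in range(100):
            st_ = adapt(st_, [sample(0.2, t) for t in range(20)])
            uppers.append(st_.upper)
        assert all(b <= a + 1e-12 for a, b in zip(uppers, uppers[1:]))
        assert uppers[-1] == pytest.approx(0.2 + st_.width / 2, abs=1e-6)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=10),
                    min_size=1, max_size=30))
    def test_width_and_ordering_invariants(self, histories):
        st_ = ThresholdState(lower=0.5, upper=0.7)
        width = st_.width
        for hist in histories:
            st_ = adapt(st_, [sample(v, t) for t, v in enumerate(hist)])
            assert st_.upper - st_.lower == pytest.approx(width, rel=1e-12)
            assert st_.lower < st_.upper
            assert st_.lower >= 0


def closed_loop_above_fractions(seed, drop_factor=0.5, adapt_rate=0.2):
    """Score-level closed loop: latent level drops at t=60 s; returns the
    fraction of 'above' classifications before ([30,60]) and after ((60,120])."""
    rng = np.random.default_rng(seed)
    cal = calibrate(rng.normal(1.0, 0.15, 60), rng.normal(0.4, 0.15, 60))
    st_ = init_thresholds(cal, adapt_rate=adapt_rate)
    sm = None
    recent, labels = [], []
    for i in range(240):  # 0.5 s steps over 120 s
        t = 0.5 * (i + 1)
        level = 1.0 if t <= 60 else drop_factor * 1.0
        raw = max(rng.normal(level, 0.15), 0.0)
        sm = raw if sm is None else 0.4 * raw + 0.6 * sm
        s = AttentionSample(t=t, value=sm)
        labels.append((t, classify(s, st_).label))
        recent = [x for x in recent + [s] if x.t > t - 15]
        if i % 2 == 1:
            st_ = adapt(st_, recent)
    pre = [l for t, l in labels if 30 < t <= 60]
    post = [l for t, l in labels if t > 60]
    return pre.count("above") / len(pre), post.count("above") / len(post)


def test_engagement_recovers_after_attention_drop():
    """After a 50% latent-attention drop the adaptive thresholds restore the
    reward rate: the 'above' fraction over the following 60 s returns to
    within 10 percentage points of the pre-drop fraction (20-seed estimate)."""
    pre, post = np.mean([closed_loop_above_fractions(s) for s in range(20)], axis=0)
    assert pre > 0.02  # the game is winnable before the drop
    assert abs(post - pre) <= 0.10


def test_static_thresholds_do_not_recover():
    # without adaptation the reward rate collapses after the drop
    def frozen(seed):
        rng = np.random.default_rng(seed)
        cal = calibrate(rng.normal(1.0, 0.15, 60), rng.normal(0.4, 0.15, 60))
        st_ = init_thresholds(cal, policy="static")
        labels = []
        sm = None
        for i in range(240):
            t = 0.5 * (i + 1)
            level = 1.0 if t <= 60 else 0.5
            raw = max(rng.normal(level, 0.15), 0.0)
            sm = raw if sm is None else 0.4 * raw + 0.6 * sm
            labels.append((t, classify(AttentionSample(t=t, value=sm), st_).label))
        pre = [l for t, l in labels if 30 < t <= 60]
        post = [l for t, l in labels if t > 60]
        return pre.count("above") / len(pre), post.count("above") / len(post)

    pre, post = np.mean([frozen(s) for s in range(20)], axis=0)
    assert post < pre - 0.10
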