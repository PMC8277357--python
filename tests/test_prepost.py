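"""Channel grouping, group PSD band powers, paired statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nftrain import (
    ChannelGrouping,
    DEFAULT_GROUPING,
    GroupingError,
    Recording,
    band_by_name,
    group_band_power,
    group_channels,
    paired_t,
    prepost_report,
    score_table_compare,
)
from nftrain.errors import CohortError, ZeroVarianceError
from nftrain.synth import DEFAULT_MONTAGE

FS = 250.0


class TestGrouping:
    def test_default_grouping_valid_on_default_montage(self):
        g = group_channels(DEFAULT_MONTAGE, DEFAULT_GROUPING)
        assert set(g.groups) == set(range(1, 10))
        assert all(g[i] for i in range(1, 10))

    def test_group7_is_parietal_union_occipital(self):
        assert set(DEFAULT_GROUPING[7]) == set(DEFAULT_GROUPING[5]) | set(DEFAULT_GROUPING[2])

    def test_group6_is_prefrontal_union_frontal(self):
        assert set(DEFAULT_GROUPING[6]) == set(DEFAULT_GROUPING[1]) | set(DEFAULT_GROUPING[3])

    def test_unknown_channel_rejected(self):
        bad = ChannelGrouping(groups={**{i: DEFAULT_GROUPING[i] for i in range(1, 9)}, 9: ("XX",)})
        with pytest.raises(GroupingError, match="not in montage"):
            group_channels(DEFAULT_MONTAGE, bad)

    def test_wrong_group_count_rejected(self):
        with pytest.raises(GroupingError):
            ChannelGrouping(groups={1: ("Fp1",)})


def make_rec(channels, subject="s1", phase="pre", condition="eyes_open"):
    return Recording(subject=subject, phase=phase, condition=condition,
                     channels=channels, fs=FS)


class TestGroupBandPower:
    def test_identical_channels_equal_single_channel(self):
        t = np.arange(int(10 * FS)) / FS
        x = 5 * np.sin(2 * np.pi * 11 * t)
        rec = make_rec({"PO7": x, "PO8": x.copy(), "Oz": x.copy()})
        single = group_band_power(rec, ["PO7"], band_by_name("alpha_high"))
        grouped = group_band_power(rec, ["PO7", "PO8", "Oz"], band_by_name("alpha_high"))
        assert grouped == pytest.approx(single)

    def test_group_average_is_mean_of_band_powers(self):
        rng = np.random.default_rng(0)
        rec = make_rec({"PO7": rng.standard_normal(int(10 * FS)),
                        "PO8": 3 * rng.standard_normal(int(10 * FS))})
        band = band_by_name("alpha")
        a = 10 ** group_band_power(rec, ["PO7"], band)
        b = 10 ** group_band_power(rec, ["PO8"], band)
        ab = 10 ** group_band_power(rec, ["PO7", "PO8"], band)
        assert ab == pytest.approx((a + b) / 2, rel=1e-9)

    def test_empty_group_rejected(self):
        rec = make_rec({"Oz": np.zeros(int(3 * FS)) + np.sin(np.arange(int(3 * FS)))})
        with pytest.raises(GroupingError):
            group_band_power(rec, [], band_by_name("alpha"))


class TestPairedT:
    def test_identical_pairs_null(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_frozen_oracle_example(self):
        # differences {1,2,3}: t = 2/(1/sqrt(3)) = 3.4641, df=2, p = 0.0742
        t, df, p = paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_negation_symmetry(self):
        t1, _, p1 = paired_t([0, 0, 0, 0], [1.0, 2.5, 0.5, 2.0])
        t2, _, p2 = paired_t([1.0, 2.5, 0.5, 2.0], [0, 0, 0, 0])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_nonzero_mean_rejected(self):
        with pytest.raises(ZeroVarianceError):
            paired_t([0.0, 0.0], [1.0, 1.0])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])

    def test_matches_reference_implementation_on_random_inputs(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n = rng.integers(2, 30)
            pre = rng.normal(0, 2, n)
            post = pre + rng.normal(0.2, 1, n)
            t, df, p = paired_t(pre, post)
            ref = stats.ttest_rel(post, pre)
            assert abs(t - ref.statistic) < 1e-10
            assert abs(p - ref.pvalue) < 1e-8


class TestPrePostReport:
    def test_structural_row_count(self, tiny_cohort):
        rep = prepost_report(tiny_cohort)
        assert len(rep) == 8 * 9 * 2  # bands x groups x conditions
        assert set(rep.columns) >= {"band", "group", "condition", "n", "mean_change",
                                    "sd_diff", "t", "df", "p", "p_bh", "significant"}
        assert (rep["df"] == rep["n"] - 1).all()
        assert rep["p"].between(0, 1).all()

    def test_group7_consistent_with_groups_2_and_5(self, tiny_cohort):
        # group 7 is a pure function of the union of groups 2 and 5 channels
        from nftrain.prepost import band_power_table
        tab = band_power_table(tiny_cohort)
        band = "alpha_high"
        for rec in tiny_cohort[:2]:
            g7 = group_band_power(rec, DEFAULT_GROUPING[7], band_by_name(band))
            manual = group_band_power(rec, tuple(DEFAULT_GROUPING[5]) + tuple(DEFAULT_GROUPING[2]),
                                      band_by_name(band))
            assert g7 == pytest.approx(manual)
            row = tab[(tab.subject == rec.subject) & (tab.phase == rec.phase)
                      & (tab.condition == rec.condition) & (tab.band == band) & (tab.group == 7)]
            assert row["log10_power"].iloc[0] == pytest.approx(g7)

    def test_incomplete_subject_excluded(self, tiny_cohort):
        partial = [r for r in tiny_cohort
                   if not (r.subject == "subj03" and r.condition == "eyes_closed")]
        rep = prepost_report(partial)
        assert (rep["n"] == 2).all()

    def test_fewer_than_two_complete_subjects_aborts(self, tiny_cohort):
        only_one = [r for r in tiny_cohort if r.subject == "subj01"]
        with pytest.raises(CohortError):
            prepost_report(only_one)


class TestScoreTableCompare:
    def toy(self):
        pre = pd.DataFrame({"subject_id": ["a", "b", "c"],
                            "memory": [10.0, 12.0, 11.0],
                            "attention": [5.0, 6.0, 7.0]})
        post = pd.DataFrame({"subject_id": ["a", "b", "c"],
                             "memory": [11.0, 14.0, 14.0],
                             "attention": [5.0, 6.0, 7.0]})
        return pre, post

    def test_hand_computed_toy_table(self):
        pre, post = self.toy()
        out = score_table_compare(pre, post).set_index("measure")
        # memory differences {1,2,3}: mean 2, sd 1, t = 3.4641
        assert out.loc["memory", "t"] == pytest.approx(3.4641, abs=1e-4)
        assert out.loc["memory", "sd_diff"] == pytest.approx(1.0)
        assert out.loc["attention", "t"] == 0.0

    def test_column_permutation_invariance(self):
        pre, post = self.toy()
        out1 = score_table_compare(pre, post)
        out2 = score_table_compare(pre[["subject_id", "attention", "memory"]], post)
        m1 = out1.set_index("measure").loc[["memory", "attention"]]
        m2 = out2.set_index("measure").loc[["memory", "attention"]]
        pd.testing.assert_frame_equal(m1, m2)

    def test_missing_cells_pairwise_complete(self):
        pre, post = self.toy()
        pre.loc[0, "memory"] = np.nan
        out = score_table_compare(pre, post).set_index("measure")
        assert out.loc["memory", "n"] == 2

    def test_single_complete_pair_not_estimable(self):
        pre, post = self.toy()
        pre.loc[[0, 1], "memory"] = np.nan
        out = score_table_compare(pre, post).set_index("measure")
        assert out.loc["memory", "n"] == 1
        assert np.isnan(out.loc["memory", "t"])
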