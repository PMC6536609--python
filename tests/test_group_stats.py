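"""ANOVA, SNK lettering and per-time-point tests against from-scratch oracles."""

import numpy as np
import pytest

from rhythmlab import one_way_anova, per_timepoint_test, snk_posthoc
from rhythmlab.group_stats import studentized_range_crit
from rhythmlab.model import ValidationError

from oracles import anova_oracle, snk_oracle_subsets, welch_oracle


def _tc_from_groups(make_timecourse, groups, condition="control"):
    zt, vals = [], []
    for i, g in enumerate(groups):
        zt.extend([4.0 * i] * len(g))
        vals.extend(g)
    return make_timecourse(zt, vals, condition=condition)


class TestOneWayAnova:
    def test_identical_groups_f_zero(self, make_timecourse):
        tc = _tc_from_groups(make_timecourse, [[1, 2, 3], [1, 2, 3]])
        res = one_way_anova(tc)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_all_values_identical_returns_p1_with_warning(self, make_timecourse, caplog):
        tc = _tc_from_groups(make_timecourse, [[2, 2], [2, 2], [2, 2]])
        with caplog.at_level("WARNING", logger="rhythmlab"):
            res = one_way_anova(tc)
        assert res.p_value == 1.0
        assert "identical" in caplog.text

    def test_separated_means_tiny_variance(self, make_timecourse):
        tc = _tc_from_groups(
            make_timecourse,
            [[0, 0.001, -0.001], [0.001, 0, -0.001], [10, 10.001, 9.999]],
        )
        assert one_way_anova(tc).p_value < 1e-6

    def test_matches_sums_of_squares_oracle(self, make_timecourse, rng):
        """F equals the explicit SS decomposition to 1e-10, many designs."""
        for _ in range(20):
            k = rng.integers(2, 7)
            groups = [rng.normal(rng.normal(0, 1), 1, rng.integers(2, 9)).tolist()
                      for _ in range(k)]
            res = one_way_anova(_tc_from_groups(make_timecourse, groups))
            f, df_b, df_w, p = anova_oracle(groups)
            assert res.f_stat == pytest.approx(f, abs=1e-10)
            assert (res.df_between, res.df_within) == (df_b, df_w)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_invariance_shift_and_scale(self, make_timecourse, rng):
        groups = [rng.normal(m, 1, 5).tolist() for m in (0, 1, 3)]
        base = one_way_anova(_tc_from_groups(make_timecourse, groups)).f_stat
        shifted = [[v + 100.0 for v in g] for g in groups]
        scaled = [[v * 7.5 for v in g] for g in groups]
        assert one_way_anova(_tc_from_groups(make_timecourse, shifted)).f_stat == \
            pytest.approx(base, rel=1e-10)
        assert one_way_anova(_tc_from_groups(make_timecourse, scaled)).f_stat == \
            pytest.approx(base, rel=1e-10)

    def test_requires_replication(self, make_timecourse):
        with pytest.raises(ValidationError):
            one_way_anova(_tc_from_groups(make_timecourse, [[1], [2]]))


class TestStudentizedRange:
    def test_published_q_table_df14(self):
        # alpha=0.05 row for error df=14, number of means p=2..7
        published = [3.03, 3.70, 4.11, 4.41, 4.64, 4.83]
        for p, expected in zip(range(2, 8), published):
            assert studentized_range_crit(0.05, p, 14) == pytest.approx(
                expected, abs=0.01
            )

    def test_published_q_table_df21(self):
        # df=21 values bracket between the classic df=20 and df=24 rows
        expected_21 = [2.94, 3.56, 3.94, 4.21, 4.42, 4.60]
        df20 = [2.95, 3.58, 3.96, 4.23, 4.45, 4.62]
        df24 = [2.92, 3.53, 3.90, 4.17, 4.37, 4.54]
        for p, exp, hi, lo in zip(range(2, 8), expected_21, df20, df24):
            q = studentized_range_crit(0.05, p, 21)
            assert q == pytest.approx(exp, abs=0.01)
            assert lo - 0.01 <= q <= hi + 0.01


class TestSnkPosthoc:
    def test_all_levels_identical_single_letter(self, make_timecourse):
        tc = _tc_from_groups(make_timecourse, [[1, 1.01], [1.005, 0.995], [1, 1.005]])
        snk = snk_posthoc(tc)
        assert set(snk.letters.values()) == {"a"}

    def test_two_far_separated_levels(self, make_timecourse):
        tc = _tc_from_groups(make_timecourse, [[0, 0.1, -0.1, 0.05], [10, 10.1, 9.9, 10.05]])
        snk = snk_posthoc(tc)
        letters = snk.letters
        assert letters[4.0] == "a"  # higher mean gets 'a'
        assert letters[0.0] == "b"

    def test_sharing_relation_symmetric(self, make_timecourse, rng):
        groups = [rng.normal(m, 0.5, 6).tolist() for m in (0, 0.4, 2.0, 2.3)]
        snk = snk_posthoc(_tc_from_groups(make_timecourse, groups))
        levels = list(snk.letters)
        for a in levels:
            for b in levels:
                assert snk.share_letter(a, b) == snk.share_letter(b, a)

    def test_extremes_never_share_when_strongly_separated(self, make_timecourse, rng):
        groups = [rng.normal(m, 0.01, 8).tolist() for m in (0, 1, 2, 5)]
        tc = _tc_from_groups(make_timecourse, groups)
        assert one_way_anova(tc).p_value < 1e-6
        snk = snk_posthoc(tc)
        assert not snk.share_letter(0.0, 12.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_four_level_subsets_match_exhaustive_oracle(self, make_timecourse, seed):
        """Homogeneous subsets equal the exhaustive stretch-enumeration oracle."""
        rng = np.random.default_rng(seed)
        means = rng.uniform(0, 3, 4)
        groups = [rng.normal(m, 0.8, 6).tolist() for m in means]
        tc = _tc_from_groups(make_timecourse, groups)
        snk = snk_posthoc(tc, alpha=0.05)

        order, _, subsets = snk_oracle_subsets(groups, alpha=0.05)
        # oracle positions index groups by ZT index; map to ZT levels
        zt_sorted = [4.0 * i for i in order]
        oracle_letters = {z: "" for z in zt_sorted}
        for li, (lo, hi) in enumerate(subsets):
            for pos in range(lo, hi + 1):
                oracle_letters[zt_sorted[pos]] += "abcdefghij"[li]
        assert snk.letters == {z: oracle_letters[z] for z in snk.letters}

    def test_unbalanced_cells_accepted(self, make_timecourse, rng):
        groups = [rng.normal(0, 1, 3).tolist(), rng.normal(5, 1, 8).tolist(),
                  rng.normal(5.2, 1, 5).tolist()]
        snk = snk_posthoc(_tc_from_groups(make_timecourse, groups))
        assert len(snk.letters) == 3


class TestPerTimepointTest:
    def test_identical_samples_p1(self, make_timecourse):
        c = make_timecourse([4.0] * 4, [1, 1, 1, 1], condition="control")
        s = make_timecourse([4.0] * 4, [1, 1, 1, 1], condition="stress")
        assert per_timepoint_test(c, s, 4.0) == 1.0

    def test_huge_separation(self, make_timecourse, rng):
        c = make_timecourse([4.0] * 8, rng.normal(0, 1, 8), condition="control")
        s = make_timecourse([4.0] * 8, rng.normal(100, 1, 8), condition="stress")
        assert per_timepoint_test(c, s, 4.0) < 1e-9

    def test_matches_welch_oracle(self, make_timecourse, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 2, 6)
        c = make_timecourse([4.0] * 8, a, condition="control")
        s = make_timecourse([4.0] * 6, b, condition="stress")
        _, _, p_oracle = welch_oracle(a, b)
        assert per_timepoint_test(c, s, 4.0) == pytest.approx(p_oracle, abs=1e-10)

    def test_student_variant_pools_variance(self, make_timecourse, rng):
        from scipy import stats

        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 8)
        c = make_timecourse([4.0] * 8, a, condition="control")
        s = make_timecourse([4.0] * 8, b, condition="stress")
        expected = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert per_timepoint_test(c, s, 4.0, method="student_t") == pytest.approx(expected)

    def test_missing_level_error_names_zt(self, make_timecourse):
        c = make_timecourse([4.0] * 4, [1, 2, 3, 4], condition="control")
        s = make_timecourse([8.0] * 4, [1, 2, 3, 4], condition="stress")
        with pytest.raises(ValidationError, match="zt=4"):
            per_timepoint_test(c, s, 4.0)
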