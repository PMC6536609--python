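"""One-way ANOVA across ZT levels, SNK post hoc lettering and per-time-point
two-condition tests.

The Student–Newman–Keuls (SNK) procedure orders the level means and tests
each ordered stretch of p means with the studentized-range critical value
q(alpha, p, df_within), applying the standard non-testing rule: once a
stretch is found non-significant, every pair inside it is declared
non-significant without testing. The homogeneous subsets that survive are
rendered as letters (levels sharing a letter do not differ significantly),
the lettering convention used in chronobiology figures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import TimeCourse, ValidationError

log = logging.getLogger("rhythmlab")


@dataclass
class AnovaResult:
    variable_id: str
    condition: str
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class SnkLettering:
    """SNK homogeneous subsets as letters, one entry per ZT level.

    ``letters`` maps each ZT level to the letters of the homogeneous subsets
    containing it; subsets are lettered a, b, c, ... in order of descending
    mean. Two levels differ significantly iff they share no letter.
    """

    variable_id: str
    condition: str
    letters: dict[float, str] = field(default_factory=dict)
    means: dict[float, float] = field(default_factory=dict)

    def share_letter(self, zt_a: float, zt_b: float) -> bool:
        return bool(set(self.letters[zt_a]) & set(self.letters[zt_b]))


def one_way_anova(tc: TimeCourse) -> AnovaResult:
    """Classical one-way ANOVA of values across ZT levels.

    F = MS_between / MS_within with p from the F distribution. If every
    observation is identical the F statistic is undefined; p = 1 is returned
    with a warning (no evidence of time structure).
    """
    groups = [g for g in tc.groups_by_zt().values()]
    if len(groups) < 2 or not any(len(g) >= 2 for g in groups):
        raise ValidationError(
            f"{tc.variable_id}/{tc.condition}: ANOVA needs >=2 levels and "
            "replication in at least one level"
        )
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0.0:
        log.warning(
            "%s/%s: all values identical, ANOVA F undefined; returning p=1",
            tc.variable_id, tc.condition,
        )
        return AnovaResult(tc.variable_id, tc.condition, 0.0, k - 1, n_total - k, 1.0)
    f_stat, p = stats.f_oneway(*groups)
    return AnovaResult(
        tc.variable_id, tc.condition, float(f_stat), k - 1, n_total - k, float(p)
    )


def _anova_mean_squares(groups: list[np.ndarray]) -> tuple[float, int]:
    """Within-group mean square and its df, for SNK standard errors."""
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_within = n_total - k
    return ss_within / df_within, df_within


def studentized_range_crit(alpha: float, n_means: int, df: int) -> float:
    """Upper critical value q(alpha; n_means, df) of the studentized range."""
    return float(stats.studentized_range.ppf(1.0 - alpha, n_means, df))


def snk_posthoc(tc: TimeCourse, alpha: float = 0.05) -> SnkLettering:
    """Student–Newman–Keuls homogeneous subsets over ZT-level means.

    Means are sorted descending (ties broken by ZT order so output is
    deterministic). Each ordered stretch spanning p means is tested with
    q(alpha, p, df_within); the standard error uses MS_within and, for
    unbalanced cells, the harmonic mean of the two cell sizes compared
    (Kramer adjustment — the reference design is balanced, so this is an
    extension). A stretch inside an already-non-significant stretch is not
    tested.
    """
    by_zt = tc.groups_by_zt()
    levels = list(by_zt.keys())
    groups = [by_zt[z] for z in levels]
    if any(len(g) < 1 for g in groups):
        raise ValidationError("every ZT level needs at least one observation")
    ms_within, df_within = _anova_mean_squares(groups)

    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    # descending mean, ties by ascending ZT
    order = sorted(range(len(levels)), key=lambda i: (-means[i], levels[i]))
    m = means[order]
    n_ord = ns[order]
    lv_ord = [levels[i] for i in order]
    k = len(m)

    if ms_within == 0.0:
        # degenerate: no within-cell noise; any mean difference is significant
        significant = {
            (i, j) for i in range(k) for j in range(i + 1, k) if m[i] != m[j]
        }
    else:
        significant: set[tuple[int, int]] = set()
        nonsig_cover: list[tuple[int, int]] = []
        for span in range(k, 1, -1):
            qcrit = studentized_range_crit(alpha, span, df_within)
            for lo in range(0, k - span + 1):
                hi = lo + span - 1
                if any(c_lo <= lo and hi <= c_hi for c_lo, c_hi in nonsig_cover):
                    continue  # SNK non-testing rule
                n_h = 2.0 / (1.0 / n_ord[lo] + 1.0 / n_ord[hi])
                q_obs = (m[lo] - m[hi]) / math.sqrt(ms_within / n_h)
                if q_obs > qcrit:
                    significant.add((lo, hi))
                else:
                    nonsig_cover.append((lo, hi))

    # maximal intervals containing no significant pair -> homogeneous subsets
    subsets: list[tuple[int, int]] = []
    for lo in range(k):
        hi = lo
        while hi + 1 < k and not any(
            lo <= a and b <= hi + 1 for a, b in significant
        ):
            hi += 1
        if not any(s_lo <= lo and hi <= s_hi for s_lo, s_hi in subsets):
            subsets.append((lo, hi))

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {z: "" for z in lv_ord}
    for letter_idx, (lo, hi) in enumerate(subsets):
        for pos in range(lo, hi + 1):
            letters[lv_ord[pos]] += alphabet[letter_idx]
    return SnkLettering(
        tc.variable_id, tc.condition,
        letters={z: letters[z] for z in levels},
        means={z: float(by_zt[z].mean()) for z in levels},
    )


def per_timepoint_test(
    control: TimeCourse,
    stress: TimeCourse,
    zt: float,
    method: str = "welch_t",
) -> float:
    """Two-sample t-test p-value comparing conditions at one ZT.

    Welch's unequal-variance t by default; classical Student's t with
    ``method="student_t"``. Identical samples give p = 1.
    """
    a = control.groups_by_zt().get(zt)
    b = stress.groups_by_zt().get(zt)
    if a is None or b is None or len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"per-time-point test at zt={zt}: both conditions need >=2 replicates"
        )
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all observations identical: no evidence of a difference
    res = stats.ttest_ind(a, b, equal_var=(method == "student_t"))
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p
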