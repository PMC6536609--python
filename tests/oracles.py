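"""Independent reference implementations used only as test oracles.

Each oracle takes a deliberately different route from the package code it
checks: the cosinor oracle optimizes the direct nonlinear (M, A, phi)
parameterization via grid search plus scipy.optimize.least_squares; the
ANOVA oracle decomposes sums of squares from first principles with Python
loops; the SNK oracle uses the closed-form reading of the non-testing rule
(a pair is significant iff every ordered stretch containing it raw-rejects).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats


def cosinor_nls_oracle(t, y, period=24.0):
    """Direct nonlinear least squares for M + A*cos(w t - phi).

    Grid over the peak hour (linear solve for M, A at each) picks the start;
    least_squares polishes. Returns (mesor, amplitude, peak_h, rss, se) with
    se = (se_M, se_A, se_peak_h) from the Jacobian at the optimum.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    w = 2 * math.pi / period

    best = None
    for peak in np.arange(0.0, period, period / 96):
        X = np.column_stack([np.ones_like(t), np.cos(w * (t - peak))])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        if best is None or rss < best[0]:
            best = (rss, beta[0], beta[1], peak)

    def resid(p):
        m, a, peak = p
        return y - (m + a * np.cos(w * (t - peak)))

    sol = optimize.least_squares(resid, x0=[best[1], best[2], best[3]], method="lm")
    m, a, peak = sol.x
    if a < 0:  # fold the sign into a half-period phase flip
        a = -a
        peak = peak + period / 2
    peak = peak % period
    rss = float(np.sum(resid([m, a, peak]) ** 2))

    J = np.column_stack([
        np.ones_like(t),
        np.cos(w * (t - peak)),
        -a * w * np.sin(w * (t - peak)),
    ])
    dof = len(t) - 3
    cov = rss / dof * np.linalg.inv(J.T @ J)
    se = np.sqrt(np.diag(cov))
    return m, a, peak, rss, (se[0], se[1], se[2])


def anova_oracle(groups):
    """One-way ANOVA from an explicit sums-of-squares decomposition."""
    allvals = [v for g in groups for v in g]
    grand = sum(allvals) / len(allvals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(
        (v - sum(g) / len(g)) ** 2 for g in groups for v in g
    )
    df_b = len(groups) - 1
    df_w = len(allvals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(f, df_b, df_w)
    return f, df_b, df_w, p


def welch_oracle(a, b):
    """Welch t statistic and Satterthwaite df from the textbook formulas."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def snk_oracle_subsets(groups, alpha=0.05):
    """SNK homogeneous subsets by exhaustive stretch enumeration.

    Closed form of the non-testing rule: a sorted pair (lo, hi) is declared
    significant iff *every* ordered stretch containing it exceeds its own
    studentized-range critical value. Returns the list of maximal
    non-significant intervals over positions sorted by descending mean
    (ties by group index).
    """
    means = [float(np.mean(g)) for g in groups]
    order = sorted(range(len(groups)), key=lambda i: (-means[i], i))
    m = [means[i] for i in order]
    n = [len(groups[i]) for i in order]
    k = len(m)
    ss_w = sum(float(np.sum((np.asarray(g) - np.mean(g)) ** 2)) for g in groups)
    df_w = sum(len(g) for g in groups) - k
    ms_w = ss_w / df_w

    def raw_reject(lo, hi):
        span = hi - lo + 1
        n_h = 2.0 / (1.0 / n[lo] + 1.0 / n[hi])
        q_obs = (m[lo] - m[hi]) / math.sqrt(ms_w / n_h)
        qcrit = stats.studentized_range.ppf(1 - alpha, span, df_w)
        return q_obs > qcrit

    def significant(lo, hi):
        return all(
            raw_reject(l2, h2) for l2 in range(0, lo + 1) for h2 in range(hi, k)
        )

    sig_pairs = {
        (lo, hi)
        for lo in range(k)
        for hi in range(lo + 1, k)
        if significant(lo, hi)
    }
    subsets = []
    for lo in range(k):
        hi = lo
        while hi + 1 < k and not any(
            lo <= a and b <= hi + 1 for a, b in sig_pairs
        ):
            hi += 1
        if not any(s_lo <= lo and hi <= s_hi for s_lo, s_hi in subsets):
            subsets.append((lo, hi))
    return order, sig_pairs, subsets
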