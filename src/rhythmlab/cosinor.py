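"""Single-component cosinor regression with a fixed period.

The model is f(t) = M + A·cos(ωt − φ) with ω = 2π/period (π/12 per hour for
the 24-h default): M is the mesor (rhythm-adjusted mean), A the amplitude
(half the peak-to-trough extent) and φ the acrophase (peak timing). The fit
uses the exact linear reparameterization

    f(t) = M + βc·cos(ωt) + βs·sin(ωt),   βc = A·cosφ,  βs = A·sinφ,

so ordinary least squares gives the global optimum; A = √(βc² + βs²) and the
peak time is (period/2π)·atan2(βs, βc) mod period. Standard errors come from
the OLS covariance (residual variance = RSS/(n − 3)) propagated through the
delta method.

A series is accepted as rhythmic only under the dual criterion: one-way ANOVA
across time points rejects at alpha AND the amplitude noise/signal ratio
SE(A)/A stays below 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .group_stats import AnovaResult
from .model import PipelineConfig, TimeCourse


@dataclass
class CosinorFit:
    """Least-squares cosinor estimates with delta-method standard errors.

    ``acrophase_h`` is the fitted peak time in hours in [0, period); it is
    NaN (flagged by ``acrophase_defined``) when the amplitude is numerically
    zero and the peak time is meaningless.
    """

    variable_id: str
    condition: str
    mesor: float
    amplitude: float
    acrophase_h: float
    se_mesor: float
    se_amplitude: float
    se_acrophase_h: float
    rss: float
    n_obs: int
    df_resid: int
    acrophase_defined: bool = True

    @property
    def ns_ratio(self) -> float:
        """Noise/signal ratio SE(A)/A; +inf for a zero-amplitude fit."""
        if self.amplitude <= 0 or not np.isfinite(self.amplitude):
            return math.inf
        return self.se_amplitude / self.amplitude


@dataclass
class RhythmDecision:
    """Outcome of the dual rhythmicity criterion for one series."""

    variable_id: str
    condition: str
    anova_p: float
    ns_ratio: float
    is_rhythmic: bool


_AMP_ZERO_TOL = 1e-12


def acrophase_to_radians(acrophase_h: float, period: float = 24.0) -> float:
    """Convert a peak time in hours to phase radians, principal value [0, 2π)."""
    if period <= 0:
        raise ValueError("period must be positive")
    rad = (2.0 * math.pi * acrophase_h / period) % (2.0 * math.pi)
    # float mod can round a tiny negative argument up to the full circle
    return 0.0 if rad >= 2.0 * math.pi else rad


def fit_cosinor(tc: TimeCourse, period_hours: float = 24.0) -> CosinorFit:
    """Fit M + A·cos(2πt/period − φ) to a time course by least squares.

    Requires at least 3 distinct time points and 4 observations (3 model
    parameters). With a zero fitted amplitude the acrophase is undefined and
    the returned fit carries ``acrophase_defined=False`` and an infinite
    noise/signal ratio.
    """
    tc.require_fit_design()
    t = tc.zt
    y = tc.values
    omega = 2.0 * math.pi / period_hours
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n = len(y)
    df_resid = n - 3
    sigma2 = rss / df_resid if df_resid > 0 else math.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)

    mesor, bc, bs = (float(b) for b in beta)
    amplitude = math.hypot(bc, bs)
    se_mesor = math.sqrt(cov[0, 0])

    if amplitude < _AMP_ZERO_TOL:
        return CosinorFit(
            tc.variable_id, tc.condition,
            mesor=mesor, amplitude=0.0, acrophase_h=math.nan,
            se_mesor=se_mesor, se_amplitude=math.sqrt(cov[1, 1]),
            se_acrophase_h=math.nan, rss=rss, n_obs=n, df_resid=df_resid,
            acrophase_defined=False,
        )

    acrophase_h = (period_hours / (2.0 * math.pi)) * math.atan2(bs, bc) % period_hours

    # delta method on A = sqrt(bc^2+bs^2) and phi = atan2(bs, bc)
    var_bc, var_bs = cov[1, 1], cov[2, 2]
    cov_cs = cov[1, 2]
    var_amp = (bc * bc * var_bc + bs * bs * var_bs + 2 * bc * bs * cov_cs) / amplitude**2
    var_phi = (bs * bs * var_bc + bc * bc * var_bs - 2 * bc * bs * cov_cs) / amplitude**4
    se_amplitude = math.sqrt(max(var_amp, 0.0))
    se_acro_h = (period_hours / (2.0 * math.pi)) * math.sqrt(max(var_phi, 0.0))

    return CosinorFit(
        tc.variable_id, tc.condition,
        mesor=mesor, amplitude=amplitude, acrophase_h=acrophase_h,
        se_mesor=se_mesor, se_amplitude=se_amplitude, se_acrophase_h=se_acro_h,
        rss=rss, n_obs=n, df_resid=df_resid, acrophase_defined=True,
    )


def decide_rhythm(
    fit: CosinorFit, anova: AnovaResult, cfg: PipelineConfig | None = None
) -> RhythmDecision:
    """Apply the dual rhythmicity criterion.

    Rhythmic iff the ANOVA across time points has p below ``cfg.alpha_anova``
    AND the noise/signal ratio SE(A)/A is below ``cfg.ns_ratio_max``. The
    ratio is reported even when the series fails a gate; a zero-amplitude fit
    has an infinite ratio and is never rhythmic.
    """
    cfg = cfg or PipelineConfig()
    ns = fit.ns_ratio
    rhythmic = (anova.p_value < cfg.alpha_anova) and (ns < cfg.ns_ratio_max)
    return RhythmDecision(
        variable_id=fit.variable_id,
        condition=fit.condition,
        anova_p=anova.p_value,
        ns_ratio=ns,
        is_rhythmic=bool(rhythmic),
    )
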