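"""Control-versus-stress rhythm comparison.

Quantifies three kinds of stress effect on a daily rhythm: a level change
(mesor / grand-mean percent change), amplitude damping or outright rhythm
loss, and an acrophase displacement measured on the 24-h circle. The phase
shift is the minimal signed circular displacement: negative = advance (the
peak moves earlier around the circle), positive = delay, and exactly half a
period is antiphase (resolved to +12 h for a 24-h rhythm).

Worked example fixing the sign convention: a peak moving from ZT0 to ZT16 is
an 8-h advance (−8 h), not a 16-h delay — crossing midnight backwards is the
shorter way around the circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cosinor import CosinorFit, RhythmDecision
from .model import TimeCourse

SHIFT_CLASSES = ("none", "advance", "delay", "antiphase", "rhythm_lost", "rhythm_gained")

DEFAULT_SHIFT_TOL_H = 1.0  # quarter of the 4-h sampling interval


@dataclass
class RhythmComparison:
    variable_id: str
    mean_control: float
    mean_stress: float
    pct_change: float
    ratio_pct: float
    amp_ratio: float
    phase_shift_h: float  # NaN when either rhythm is absent
    shift_class: str
    # argmax-of-ZT-means phase shift, for transparency alongside the cosinor one
    phase_shift_argmax_h: float = math.nan


def circular_phase_shift(
    acro_control_h: float, acro_stress_h: float, period: float = 24.0
) -> float:
    """Minimal signed circular displacement from control to stress acrophase.

    Result lies in (−period/2, period/2]; negative = advance (stress peaks
    earlier on the circle), positive = delay. An exact half-period
    displacement returns +period/2 (antiphase).
    """
    if not (math.isfinite(acro_control_h) and math.isfinite(acro_stress_h)):
        raise ValueError(
            "undefined acrophase (zero-amplitude fit); classify the pair as "
            "rhythm_lost/rhythm_gained instead of computing a shift"
        )
    half = period / 2.0
    # wrap to (-period/2, period/2]; exactly half a period resolves to +half
    return -(((acro_control_h - acro_stress_h + half) % period) - half)


def classify_shift(
    shift_h: float | None,
    rhythmic_control: bool,
    rhythmic_stress: bool,
    tol_h: float = DEFAULT_SHIFT_TOL_H,
    period: float = 24.0,
) -> str:
    """Classify a phase displacement between two rhythm decisions.

    Rhythm presence takes priority: control-only rhythmic is ``rhythm_lost``,
    stress-only is ``rhythm_gained``, neither is ``none``. Otherwise shifts
    within ``tol_h`` of zero are ``none``, within ``tol_h`` of a half period
    ``antiphase``, and the rest ``advance``/``delay`` by sign.
    """
    if rhythmic_control and not rhythmic_stress:
        return "rhythm_lost"
    if rhythmic_stress and not rhythmic_control:
        return "rhythm_gained"
    if not rhythmic_control and not rhythmic_stress:
        return "none"
    if shift_h is None or not math.isfinite(shift_h):
        raise ValueError("both series rhythmic but shift undefined")
    half = period / 2.0
    if abs(shift_h) <= tol_h:
        return "none"
    if abs(shift_h) >= half - tol_h:
        return "antiphase"
    return "advance" if shift_h < 0 else "delay"


def mean_change(control: TimeCourse, stress: TimeCourse) -> tuple[float, float]:
    """Percent change and percent ratio of grand means (stress vs control).

    Means pool every observation (all ZTs, all replicates). Returns
    ``(pct_change, ratio_pct)`` where pct_change = 100·(stress−control)/control
    and ratio_pct = 100·stress/control. A zero control mean leaves both NaN.
    """
    if len(control) == 0 or len(stress) == 0:
        raise ValueError("mean_change needs non-empty series for both conditions")
    mc = float(control.values.mean())
    ms = float(stress.values.mean())
    if mc == 0.0:
        return math.nan, math.nan
    return 100.0 * (ms - mc) / mc, 100.0 * ms / mc


def argmax_phase(tc: TimeCourse) -> float:
    """Peak ZT by the argmax of per-ZT means (zt=24 folded onto 0)."""
    by_zt = tc.groups_by_zt()
    means = {(0.0 if z == 24.0 else z): [] for z in by_zt}
    for z, vals in by_zt.items():
        means[0.0 if z == 24.0 else z].extend(vals.tolist())
    folded = {z: float(np.mean(v)) for z, v in means.items()}
    return max(sorted(folded), key=lambda z: folded[z])


def compare_rhythms(
    control: TimeCourse,
    stress: TimeCourse,
    fit_control: CosinorFit,
    fit_stress: CosinorFit,
    decision_control: RhythmDecision,
    decision_stress: RhythmDecision,
    tol_h: float = DEFAULT_SHIFT_TOL_H,
    period: float = 24.0,
) -> RhythmComparison:
    """Assemble the full control-vs-stress comparison for one variable."""
    pct, ratio_pct = mean_change(control, stress)
    amp_ratio = (
        fit_stress.amplitude / fit_control.amplitude
        if fit_control.amplitude > 0
        else math.inf if fit_stress.amplitude > 0 else math.nan
    )
    both_defined = fit_control.acrophase_defined and fit_stress.acrophase_defined
    both_rhythmic = decision_control.is_rhythmic and decision_stress.is_rhythmic
    if both_defined and both_rhythmic:
        shift = circular_phase_shift(
            fit_control.acrophase_h, fit_stress.acrophase_h, period
        )
    else:
        shift = math.nan
    cls = classify_shift(
        shift if math.isfinite(shift) else None,
        decision_control.is_rhythmic,
        decision_stress.is_rhythmic,
        tol_h=tol_h,
        period=period,
    )
    shift_argmax = circular_phase_shift(
        argmax_phase(control), argmax_phase(stress), period
    )
    return RhythmComparison(
        variable_id=control.variable_id,
        mean_control=float(control.values.mean()),
        mean_stress=float(stress.values.mean()),
        pct_change=pct,
        ratio_pct=ratio_pct,
        amp_ratio=amp_ratio,
        phase_shift_h=shift,
        shift_class=cls,
        phase_shift_argmax_h=shift_argmax,
    )
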