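"""Synthetic time-course and qPCR-plate generation.

The generator emulates the sampling design of a 24-h stocking-density stress
study in rainbow trout: animals sampled every 4 h over one light-dark cycle
(ZT0, 4, 8, 12, 16, 20 and the dawn repeat at t = 24 h), n = 8 fish per
group for plasma/liver metabolites and enzyme activities and n = 4 for gene
expression, with each variable following a 24-h cosine plus additive
Gaussian noise. Stress effects are expressed exactly as the analysis models
them: mesor scaling, amplitude damping (down to outright loss), and
acrophase displacement on the circle.

No raw per-animal data exist for the original study, so scenario amplitudes
and noise levels are plausible settings chosen once (documented in the
methods note), while mesor magnitudes and peak times follow the printed
group means and peak ZTs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DEFAULT_ZT_GRID, Measurement, TimeCourse


@dataclass
class RhythmSpec:
    """Ground-truth cosine parameters for one simulated variable."""

    mesor: float
    amplitude: float
    peak_zt: float
    sigma: float
    n_per_zt: int = 8
    zt_grid: tuple[float, ...] = DEFAULT_ZT_GRID
    variable_id: str = "var"
    units: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.peak_zt < 24.0):
            raise ValueError("peak_zt must be in [0, 24)")
        if self.n_per_zt < 1:
            raise ValueError("n_per_zt must be positive")
        grid = np.asarray(self.zt_grid, dtype=float)
        if np.any(np.diff(grid) <= 0) or grid[0] < 0 or grid[-1] > 24:
            raise ValueError("zt_grid must be strictly increasing within [0, 24]")


@dataclass
class StressEffect:
    """Multiplicative/phase transformation a stressor applies to a rhythm."""

    mesor_factor: float = 1.0
    amplitude_factor: float = 1.0
    phase_shift_h: float = 0.0
    blunt: bool = False

    def __post_init__(self) -> None:
        if self.mesor_factor <= 0:
            raise ValueError("mesor_factor must be > 0")
        if self.amplitude_factor < 0:
            raise ValueError("amplitude_factor must be >= 0")
        if not (-12.0 < self.phase_shift_h <= 12.0):
            raise ValueError("phase_shift_h must be in (-12, 12]")

    def apply(self, spec: RhythmSpec) -> RhythmSpec:
        amp_factor = 0.0 if self.blunt else self.amplitude_factor
        return RhythmSpec(
            mesor=spec.mesor * self.mesor_factor,
            amplitude=spec.amplitude * amp_factor,
            peak_zt=(spec.peak_zt + self.phase_shift_h) % 24.0,
            sigma=spec.sigma,
            n_per_zt=spec.n_per_zt,
            zt_grid=spec.zt_grid,
            variable_id=spec.variable_id,
            units=spec.units,
        )


@dataclass
class QpcrSimSpec:
    """Ground truth for a simulated qPCR plate."""

    baseline_ct_ref: float = 18.0
    baseline_ct_target: float = 24.0
    efficiency_target: float = 0.95
    efficiency_ref: float = 0.95
    ct_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficiency_target <= 1.0):
            raise ValueError("efficiency_target must be in [0, 1]")
        if not (0.0 <= self.efficiency_ref <= 1.0):
            raise ValueError("efficiency_ref must be in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")


def cosine_value(t, mesor: float, amplitude: float, peak_zt: float, period: float = 24.0):
    """Deterministic cosine M + A·cos(2π(t − peak)/period)."""
    t = np.asarray(t, dtype=float)
    return mesor + amplitude * np.cos(2.0 * math.pi * (t - peak_zt) / period)


def simulate_timecourse(
    spec: RhythmSpec,
    effect: StressEffect | None = None,
    seed: int | np.random.Generator = 0,
    clamp_at_zero: bool = False,
) -> TimeCourse | tuple[TimeCourse, TimeCourse]:
    """Simulate one TimeCourse (or a control/stress pair when given an effect).

    Each observation is M' + A'·cos(2π(t − peak')/24) + ε with ε ~ N(0, σ)
    and primed parameters after applying the stress effect. Identical seeds
    reproduce identical datasets. Negative values are kept by default (the
    Gaussian model stays exact for estimator tests); ``clamp_at_zero`` trades
    that exactness for realism with concentration-like variables.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if effect is not None:
        ctrl = _simulate_one(spec, "control", rng, clamp_at_zero)
        stressed = _simulate_one(effect.apply(spec), "stress", rng, clamp_at_zero)
        return ctrl, stressed
    return _simulate_one(spec, "control", rng, clamp_at_zero)


def _simulate_one(
    spec: RhythmSpec, condition: str, rng: np.random.Generator, clamp: bool
) -> TimeCourse:
    samples = []
    for zt in spec.zt_grid:
        mean = float(cosine_value(zt, spec.mesor, spec.amplitude, spec.peak_zt))
        noise = rng.normal(0.0, spec.sigma, size=spec.n_per_zt) if spec.sigma > 0 else np.zeros(spec.n_per_zt)
        for rep, eps in enumerate(noise, start=1):
            value = mean + float(eps)
            if clamp:
                value = max(value, 0.0)
            samples.append(
                Measurement(spec.variable_id, condition, float(zt), rep, value, spec.units)
            )
    return TimeCourse(spec.variable_id, condition, samples)


def simulate_qpcr_plate(
    spec: QpcrSimSpec,
    true_ratios: dict[str, float],
    n: int,
    seed: int | np.random.Generator = 0,
    reference_gene: str = "b_actin",
) -> pd.DataFrame:
    """Simulate a qPCR plate whose Pfaffl analysis recovers ``true_ratios``.

    For each target gene, ``n`` calibrator samples amplify at the baseline Ct
    and ``n`` test samples start with ``ratio``-fold more template, lowering
    their Ct by log(ratio)/log(1+E_target). The reference-gene Ct is
    independent of group (a stably expressed housekeeping gene). Columns match the qPCR
    table schema: sample_id, gene, role, ct, efficiency, r2, group.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if any(r <= 0 for r in true_ratios.values()):
        raise ValueError("true ratios must be positive")
    rows = []
    sample_ids = [f"cal{i+1}" for i in range(n)] + [f"test{i+1}" for i in range(n)]
    groups = ["calibrator"] * n + ["test"] * n
    # one shared reference-gene well per sample
    for sid, grp in zip(sample_ids, groups):
        ct = spec.baseline_ct_ref + (rng.normal(0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0)
        rows.append((sid, reference_gene, "reference", ct, spec.efficiency_ref, 0.999, grp))
    for gene, ratio in sorted(true_ratios.items()):
        base = math.log(1.0 + spec.efficiency_target)
        delta = math.log(ratio) / base
        for sid, grp in zip(sample_ids, groups):
            mean_ct = spec.baseline_ct_target - (delta if grp == "test" else 0.0)
            ct = mean_ct + (rng.normal(0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0)
            rows.append((sid, gene, "target", ct, spec.efficiency_target, 0.999, grp))
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "role", "ct", "efficiency", "r2", "group"]
    )


# ---------------------------------------------------------------------------
# Reference scenario: every qualitative stress regime in one dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioVariable:
    spec: RhythmSpec
    effect: StressEffect
    note: str = ""


def stress_study_scenario() -> dict[str, ScenarioVariable]:
    """The reference synthetic study: one variable per qualitative regime.

    Mesors and peak ZTs follow the printed group means of the source study
    (e.g. plasma cortisol 29.01 ng/mL in controls vs 58.53 ng/mL under
    stress); amplitudes are set to a plausible fraction of the mesor and the
    noise SD to roughly half the amplitude, since no per-animal raw values
    were ever published. Gene-expression variables use n = 4/group, all
    others n = 8/group.
    """
    def rv(var, mesor, amp, peak, sigma, n, units):
        return RhythmSpec(
            mesor=mesor, amplitude=amp, peak_zt=peak, sigma=sigma,
            n_per_zt=n, variable_id=var, units=units,
        )

    scenario: dict[str, ScenarioVariable] = {
        # intact rhythm with mesor up and 12h phase displacement: peak ZT4 -> ZT16
        "cortisol": ScenarioVariable(
            rv("cortisol", 29.01, 12.0, 4.0, 6.0, 8, "ng/mL"),
            StressEffect(mesor_factor=58.53 / 29.01, phase_shift_h=12.0),
            "mesor-up, peak moved from ZT4 to ZT16",
        ),
        # rhythm abolished, mean up
        "glucose_plasma": ScenarioVariable(
            rv("glucose_plasma", 4.60, 1.2, 4.0, 0.6, 8, "mM"),
            StressEffect(mesor_factor=6.86 / 4.60, blunt=True),
            "oscillation disappears under stress",
        ),
        # 4-h delay, mean up
        "lactate_plasma": ScenarioVariable(
            rv("lactate_plasma", 1.77, 0.5, 8.0, 0.25, 8, "mM"),
            StressEffect(mesor_factor=2.14 / 1.77, phase_shift_h=4.0),
            "4-h delay (peak ZT8 to ZT12)",
        ),
        # rhythm abolished, mean down ~20%
        "glycogen": ScenarioVariable(
            rv("glycogen", 156.4, 40.0, 0.0, 20.0, 8, "umol/g"),
            StressEffect(mesor_factor=125.6 / 156.4, blunt=True),
            "20% decrease and loss of the daily fluctuation",
        ),
        # mesor up ~25%, fluctuation lost
        "gk_activity": ScenarioVariable(
            rv("gk_activity", 2.71, 0.8, 4.0, 0.4, 8, "mU/mg prot"),
            StressEffect(mesor_factor=3.41 / 2.71, blunt=True),
            "25% activity increase, rhythm below significance",
        ),
        # 4-h advance, mean up ~45%
        "gk_mrna": ScenarioVariable(
            rv("gk_mrna", 26.8, 10.0, 4.0, 5.0, 4, "fold"),
            StressEffect(mesor_factor=38.6 / 26.8, phase_shift_h=-4.0),
            "4-h advance (peak ZT4 to ZT0)",
        ),
        # 8-h advance, strong induction
        "pepck_mrna": ScenarioVariable(
            rv("pepck_mrna", 2.5, 1.0, 0.0, 0.45, 4, "fold"),
            StressEffect(mesor_factor=11.1 / 2.5, amplitude_factor=4.0,
                         phase_shift_h=-8.0),
            "8-h advance (peak ZT0 to ZT16)",
        ),
        # 8-h delay, induction
        "g6pase_mrna": ScenarioVariable(
            rv("g6pase_mrna", 1.8, 0.7, 12.0, 0.3, 4, "fold"),
            StressEffect(mesor_factor=4.1 / 1.8, amplitude_factor=2.0,
                         phase_shift_h=8.0),
            "8-h delay (peak ZT12 to ZT20)",
        ),
        # antiphase, induction
        "glut2_mrna": ScenarioVariable(
            rv("glut2_mrna", 2.1, 0.8, 8.0, 0.35, 4, "fold"),
            StressEffect(mesor_factor=11.4 / 2.1, amplitude_factor=3.0,
                         phase_shift_h=12.0),
            "antiphase (peak ZT8 to ZT20)",
        ),
        # intact phase, mesor down to 60%
        "clock1a_mrna": ScenarioVariable(
            rv("clock1a_mrna", 2.5, 1.0, 12.0, 0.4, 4, "fold"),
            StressEffect(mesor_factor=1.5 / 2.5, amplitude_factor=0.6),
            "expression reduced to 60% of control, phase intact",
        ),
        # intact phase, mesor down
        "bmal1_mrna": ScenarioVariable(
            rv("bmal1_mrna", 2.3, 0.9, 12.0, 0.35, 4, "fold"),
            StressEffect(mesor_factor=1.7 / 2.3, amplitude_factor=0.7),
            "damped, phase intact",
        ),
        # 8-h advance (peak ZT4 -> ZT20), slight mean increase
        "per1_mrna": ScenarioVariable(
            rv("per1_mrna", 1.6, 0.6, 4.0, 0.25, 4, "fold"),
            StressEffect(mesor_factor=1.9 / 1.6, phase_shift_h=-8.0),
            "8-h advance (peak ZT4 to ZT20)",
        ),
        # intact phase, mesor up ~33%
        "reverb_mrna": ScenarioVariable(
            rv("reverb_mrna", 1.8, 0.7, 20.0, 0.3, 4, "fold"),
            StressEffect(mesor_factor=2.4 / 1.8),
            "33% increase, phase intact (peak ZT20)",
        ),
    }
    return scenario


def simulate_scenario(
    seed: int = 0, names: list[str] | None = None
) -> list[TimeCourse]:
    """Simulate the full reference study as a flat list of TimeCourse pairs."""
    scenario = stress_study_scenario()
    rng = np.random.default_rng(seed)
    courses: list[TimeCourse] = []
    for name, sv in sorted(scenario.items()):
        if names is not None and name not in names:
            continue
        ctrl, stressed = simulate_timecourse(sv.spec, sv.effect, seed=rng)
        courses.extend([ctrl, stressed])
    return courses
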