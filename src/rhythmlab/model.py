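"""Domain types shared by every pipeline stage.

The central container is :class:`TimeCourse`: replicate measurements of one
variable in one condition over a grid of zeitgeber times (ZT, hours since
lights-on in a 12:12 light-dark cycle). The repeated dawn sample taken 24 h
after the first (often written ZT0') is stored as ``zt = 24``: it is
phase-equivalent to ZT0 for a 24-h cosine but is a distinct observation and a
distinct ANOVA level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np

CONDITIONS = ("control", "stress")

DEFAULT_ZT_GRID = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. ZT outside [0, 24])."""


@dataclass(frozen=True)
class Measurement:
    """One observation: one animal at one time point for one variable."""

    variable_id: str
    condition: str
    zt: float
    replicate: int
    value: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not math.isfinite(self.zt) or not (0.0 <= self.zt <= 24.0):
            raise ValidationError(f"zt must be finite and in [0, 24], got {self.zt}")
        if not math.isfinite(self.value):
            raise ValidationError(f"value must be finite, got {self.value}")
        if self.replicate < 1:
            raise ValidationError(f"replicate id must be >= 1, got {self.replicate}")


@dataclass
class TimeCourse:
    """Replicate measurements of one variable in one condition.

    Parameters
    ----------
    variable_id, condition
        Identity of the series; all samples must share both.
    samples
        The individual measurements. Replicate counts may differ across ZT
        levels (unbalanced designs are accepted; statistics use per-cell n).
    """

    variable_id: str
    condition: str
    samples: list[Measurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.samples:
            if m.variable_id != self.variable_id or m.condition != self.condition:
                raise ValidationError(
                    f"sample ({m.variable_id}, {m.condition}) does not belong to "
                    f"time course ({self.variable_id}, {self.condition})"
                )
        seen = set()
        for m in self.samples:
            key = (m.zt, m.replicate)
            if key in seen:
                raise ValidationError(
                    f"duplicate sample (zt={m.zt}, replicate={m.replicate}) in "
                    f"{self.variable_id}/{self.condition}"
                )
            seen.add(key)

    @property
    def zt(self) -> np.ndarray:
        return np.array([m.zt for m in self.samples], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([m.value for m in self.samples], dtype=float)

    @property
    def zt_levels(self) -> np.ndarray:
        """Ordered distinct ZT values present in the series."""
        return np.unique(self.zt)

    @property
    def units(self) -> str:
        return self.samples[0].units if self.samples else ""

    def __len__(self) -> int:
        return len(self.samples)

    def groups_by_zt(self) -> dict[float, np.ndarray]:
        """Values grouped by ZT level, keyed in ascending ZT order."""
        zt = self.zt
        vals = self.values
        return {lev: vals[zt == lev] for lev in self.zt_levels}

    def require_fit_design(self) -> None:
        """Reject designs too degenerate for a 3-parameter cosinor fit."""
        if len(self.zt_levels) < 3:
            raise ValidationError(
                f"{self.variable_id}/{self.condition}: need >=3 distinct ZT "
                f"levels for a cosinor fit, got {len(self.zt_levels)}"
            )
        if len(self) < 4:
            raise ValidationError(
                f"{self.variable_id}/{self.condition}: need >=4 observations, "
                f"got {len(self)}"
            )

    def merged_zt_prime(self) -> "TimeCourse":
        """Return a copy with the zt=24 dawn repeat folded onto zt=0."""
        merged = []
        max_rep: dict[float, int] = {}
        for m in self.samples:
            max_rep[0.0 if m.zt == 24.0 else m.zt] = 0
        for m in self.samples:
            if m.zt == 24.0:
                # renumber to avoid colliding with the true ZT0 replicates
                base = max((x.replicate for x in self.samples if x.zt == 0.0), default=0)
                merged.append(replace(m, zt=0.0, replicate=base + m.replicate))
            else:
                merged.append(m)
        return TimeCourse(self.variable_id, self.condition, merged)


@dataclass
class PipelineConfig:
    """Tunable decisions shared across stages.

    ``alpha_anova`` and ``ns_ratio_max`` implement the dual rhythmicity
    criterion (ANOVA P below alpha AND amplitude noise/signal ratio SE(A)/A
    below the maximum); the remaining fields are plumbing choices.
    """

    alpha_anova: float = 0.05
    ns_ratio_max: float = 0.3
    period_hours: float = 24.0
    zt_prime_policy: str = "as_24h"  # or "merge_with_zt0"
    per_timepoint_test: str = "welch_t"  # or "student_t"
    fit_on: str = "individual"  # or "zt_means"
    shift_tol_h: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_anova < 1.0):
            raise ValidationError("alpha_anova must be in (0, 1)")
        if self.ns_ratio_max <= 0:
            raise ValidationError("ns_ratio_max must be positive")
        if self.period_hours <= 0:
            raise ValidationError("period_hours must be positive")
        if self.zt_prime_policy not in ("as_24h", "merge_with_zt0"):
            raise ValidationError(f"unknown zt_prime_policy {self.zt_prime_policy!r}")
        if self.per_timepoint_test not in ("welch_t", "student_t"):
            raise ValidationError(
                f"unknown per_timepoint_test {self.per_timepoint_test!r}"
            )
        if self.fit_on not in ("individual", "zt_means"):
            raise ValidationError(f"unknown fit_on {self.fit_on!r}")

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "PipelineConfig":
        kwargs: dict[str, object] = {}
        valid = {f.name: f.type for f in fields(cls)}
        for key, raw in mapping.items():
            if key not in valid:
                raise SchemaError(f"unknown config key {key!r}")
            if key in ("zt_prime_policy", "per_timepoint_test", "fit_on"):
                kwargs[key] = str(raw)
            elif key == "seed":
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


def build_timecourses(rows: Iterable[Measurement]) -> list[TimeCourse]:
    """Group measurements into one TimeCourse per (variable, condition)."""
    buckets: dict[tuple[str, str], list[Measurement]] = {}
    for m in rows:
        buckets.setdefault((m.variable_id, m.condition), []).append(m)
    return [
        TimeCourse(var, cond, samples)
        for (var, cond), samples in sorted(buckets.items())
    ]


def timecourse_from_arrays(
    variable_id: str,
    condition: str,
    zt: Sequence[float],
    values: Sequence[float],
    units: str = "",
    replicates: Sequence[int] | None = None,
) -> TimeCourse:
    """Convenience constructor from parallel arrays.

    When ``replicates`` is omitted, ids are assigned 1..n within each ZT level.
    """
    zt = np.asarray(zt, dtype=float)
    values = np.asarray(values, dtype=float)
    if replicates is None:
        counter: dict[float, int] = {}
        reps = []
        for t in zt:
            counter[t] = counter.get(t, 0) + 1
            reps.append(counter[t])
    else:
        reps = list(replicates)
    samples = [
        Measurement(variable_id, condition, float(t), int(r), float(v), units)
        for t, r, v in zip(zt, reps, values)
    ]
    return TimeCourse(variable_id, condition, samples)
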