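"""Relative qPCR quantification from Ct values.

Two routes are provided: efficiency-corrected Pfaffl ratios (the pipeline
default) and the comparative 2^(−ΔΔCt) method, which is the Pfaffl special
case at 100% efficiency for both genes.

Efficiency convention: efficiencies are stored as fractions e in [0, 1] and
the amplification base is (1 + e), so a "85% to 100%" acceptance window maps
to bases 1.85–2.00. This is stated once, here, to prevent the classic
E-versus-(E+1) confusion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("rhythmlab")

EFF_RANGE_DEFAULT = (0.85, 1.00)
R2_MIN_DEFAULT = 0.985


@dataclass(frozen=True)
class QpcrRecord:
    """One well (or averaged technical replicate) of a qPCR run."""

    sample_id: str
    gene: str
    role: str  # "target" or "reference"
    ct: float
    efficiency: float
    standard_curve_r2: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("target", "reference"):
            raise ValueError(f"role must be target|reference, got {self.role!r}")
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"ct must be a positive finite cycle count, got {self.ct}")
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValueError(
                f"efficiency must be a fraction in [0, 1], got {self.efficiency}"
            )


@dataclass(frozen=True)
class ExpressionRatio:
    """Reference-normalized fold change of one sample versus the calibrator."""

    sample_id: str
    gene: str
    ratio: float

    def __post_init__(self) -> None:
        if not (self.ratio > 0):
            raise ValueError(f"ratio must be positive, got {self.ratio}")


def pfaffl_ratio(
    ct_target_cal: float,
    ct_target_s: float,
    ct_ref_cal: float,
    ct_ref_s: float,
    eff_target: float,
    eff_ref: float,
) -> float:
    """Efficiency-corrected relative expression ratio.

    ratio = (1+E_target)^(Ct_target,cal − Ct_target,sample)
          / (1+E_ref)^(Ct_ref,cal − Ct_ref,sample)

    with per-gene efficiencies E as fractions (1.0 = perfect doubling).
    """
    cts = (ct_target_cal, ct_target_s, ct_ref_cal, ct_ref_s)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError(f"non-finite Ct value in {cts}")
    if not (0.0 <= eff_target <= 1.0 and 0.0 <= eff_ref <= 1.0):
        raise ValueError("efficiencies must be fractions in [0, 1]")
    num = (1.0 + eff_target) ** (ct_target_cal - ct_target_s)
    den = (1.0 + eff_ref) ** (ct_ref_cal - ct_ref_s)
    return num / den


def delta_delta_ct(
    ct_target_cal: float,
    ct_target_s: float,
    ct_ref_cal: float,
    ct_ref_s: float,
) -> float:
    """Comparative 2^(−ΔΔCt) ratio (both genes assumed 100% efficient)."""
    cts = (ct_target_cal, ct_target_s, ct_ref_cal, ct_ref_s)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError(f"non-finite Ct value in {cts}")
    ddct = (ct_target_s - ct_ref_s) - (ct_target_cal - ct_ref_cal)
    return 2.0 ** (-ddct)


def qc_filter(
    records: Iterable[QpcrRecord],
    eff_range: tuple[float, float] = EFF_RANGE_DEFAULT,
    r2_min: float = R2_MIN_DEFAULT,
) -> tuple[list[QpcrRecord], list[tuple[QpcrRecord, str]]]:
    """Apply the efficiency and standard-curve quality gates.

    A record is accepted iff its efficiency lies in the closed ``eff_range``
    and its standard-curve R² (when present) is strictly greater than
    ``r2_min``. Returns (accepted, rejected-with-reasons); each rejection is
    also logged.
    """
    lo, hi = eff_range
    accepted: list[QpcrRecord] = []
    rejected: list[tuple[QpcrRecord, str]] = []
    for rec in records:
        if not (lo <= rec.efficiency <= hi):
            reason = (
                f"efficiency {rec.efficiency:.3f} outside [{lo:.2f}, {hi:.2f}]"
            )
        elif rec.standard_curve_r2 is not None and not (
            rec.standard_curve_r2 > r2_min
        ):
            reason = f"standard-curve r2 {rec.standard_curve_r2} not > {r2_min}"
        else:
            accepted.append(rec)
            continue
        log.warning("qPCR QC rejected %s/%s: %s", rec.sample_id, rec.gene, reason)
        rejected.append((rec, reason))
    return accepted, rejected


def average_technical_replicates(records: Sequence[QpcrRecord]) -> list[QpcrRecord]:
    """Average technical replicates on the Ct scale.

    Wells sharing (sample_id, gene, role) are collapsed to one record with
    the mean Ct; efficiency and R² are per-gene properties and must agree.
    """
    buckets: dict[tuple[str, str, str], list[QpcrRecord]] = {}
    for rec in records:
        buckets.setdefault((rec.sample_id, rec.gene, rec.role), []).append(rec)
    out = []
    for recs in buckets.values():
        mean_ct = float(np.mean([r.ct for r in recs]))
        out.append(replace(recs[0], ct=mean_ct))
    return out


def ratios_from_table(
    table: pd.DataFrame,
    calibrator_samples: Sequence[str],
    method: str = "pfaffl",
    apply_qc: bool = True,
) -> list[ExpressionRatio]:
    """Compute per-sample relative expression from a tidy qPCR table.

    Parameters
    ----------
    table
        Columns ``sample_id, gene, role, ct, efficiency`` and optionally
        ``r2``. One reference gene is expected per sample.
    calibrator_samples
        Sample ids whose mean Ct (per gene) defines the calibrator; typically
        the control group at the matching time point, so each calibrator
        group averages to a ratio of 1.
    method
        ``"pfaffl"`` (efficiency-corrected, default) or ``"ddct"``.
    """
    records = [
        QpcrRecord(
            sample_id=str(r.sample_id),
            gene=str(r.gene),
            role=str(r.role),
            ct=float(r.ct),
            efficiency=float(r.efficiency),
            standard_curve_r2=float(r.r2) if "r2" in table.columns else None,
        )
        for r in table.itertuples()
    ]
    records = average_technical_replicates(records)
    if apply_qc:
        records, _ = qc_filter(records)

    ref = [r for r in records if r.role == "reference"]
    targets = [r for r in records if r.role == "target"]
    if not ref:
        raise ValueError("no reference-gene records survive QC")
    ref_by_sample = {r.sample_id: r for r in ref}
    cal_ids = set(calibrator_samples)

    ratios: list[ExpressionRatio] = []
    for gene in sorted({r.gene for r in targets}):
        gene_recs = [r for r in targets if r.gene == gene]
        by_sample = {r.sample_id: r for r in gene_recs}
        cal_target = [by_sample[s].ct for s in by_sample if s in cal_ids]
        cal_ref = [ref_by_sample[s].ct for s in by_sample if s in cal_ids]
        if not cal_target:
            raise ValueError(f"gene {gene}: no calibrator samples present")
        ct_t_cal = float(np.mean(cal_target))
        ct_r_cal = float(np.mean(cal_ref))
        for rec in gene_recs:
            ref_rec = ref_by_sample.get(rec.sample_id)
            if ref_rec is None:
                log.warning("sample %s lacks a reference gene; skipped", rec.sample_id)
                continue
            if method == "pfaffl":
                ratio = pfaffl_ratio(
                    ct_t_cal, rec.ct, ct_r_cal, ref_rec.ct,
                    rec.efficiency, ref_rec.efficiency,
                )
            elif method == "ddct":
                ratio = delta_delta_ct(ct_t_cal, rec.ct, ct_r_cal, ref_rec.ct)
            else:
                raise ValueError(f"unknown method {method!r}")
            ratios.append(ExpressionRatio(rec.sample_id, gene, ratio))
    return ratios
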