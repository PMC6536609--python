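"""Tidy-CSV readers and writers.

One dialect only: comma-separated, UTF-8, header required, "." decimal.
Input schema: ``variable,condition,zt,replicate,value,units``; a column map
can rename any of them. All numeric round-trips are lossless to 1e-9 (values
are written with ``repr`` precision).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    Measurement,
    PipelineConfig,
    SchemaError,
    TimeCourse,
    ValidationError,
    build_timecourses,
)

log = logging.getLogger("rhythmlab")

TIMECOURSE_COLUMNS = ("variable", "condition", "zt", "replicate", "value", "units")


def read_timecourse_csv(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[TimeCourse]:
    """Read a tidy time-course CSV into one TimeCourse per (variable, condition).

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from canonical column name (``variable``, ``condition``,
        ``zt``, ``replicate``, ``value``, ``units``) to the column name used
        in the file.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If a row has ZT outside [0, 24] (the offending row is named).
    """
    schema = dict(schema or {})
    colmap = {canon: schema.get(canon, canon) for canon in TIMECOURSE_COLUMNS}
    df = pd.read_csv(path)
    if df.empty and not set(colmap.values()) <= set(df.columns):
        log.warning("empty time-course file %s", path)
        return []
    required = [colmap[c] for c in ("variable", "condition", "zt", "replicate", "value")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    units_col = colmap["units"] if colmap["units"] in df.columns else None

    rows: list[Measurement] = []
    n_dropped = 0
    for idx, rec in df.iterrows():
        zt = float(rec[colmap["zt"]])
        value = rec[colmap["value"]]
        if not np.isfinite(zt) or not np.isfinite(value):
            n_dropped += 1
            continue
        if not (0.0 <= zt <= 24.0):
            raise ValidationError(
                f"{path}: row {idx + 2} has zt={zt} outside [0, 24]"
            )
        rows.append(
            Measurement(
                variable_id=str(rec[colmap["variable"]]),
                condition=str(rec[colmap["condition"]]),
                zt=zt,
                replicate=int(rec[colmap["replicate"]]),
                value=float(value),
                units=str(rec[units_col]) if units_col is not None else "",
            )
        )
    if n_dropped:
        log.warning("%s: dropped %d row(s) with non-finite values", path, n_dropped)
    if not rows:
        log.warning("%s: no usable rows", path)
    return build_timecourses(rows)


def write_timecourse_csv(courses: Sequence[TimeCourse], path: str | Path) -> None:
    """Write TimeCourse objects back to the tidy schema."""
    rows = [
        {
            "variable": m.variable_id,
            "condition": m.condition,
            "zt": m.zt,
            "replicate": m.replicate,
            "value": m.value,
            "units": m.units,
        }
        for tc in courses
        for m in tc.samples
    ]
    pd.DataFrame(rows, columns=list(TIMECOURSE_COLUMNS)).to_csv(path, index=False)


def write_results_csv(results: Sequence, path: str | Path) -> None:
    """Write a sequence of result records (dataclasses or dicts) as CSV.

    An empty sequence yields a header-only file when the records' schema is
    known (pandas cannot infer columns from nothing, so an empty file gets an
    empty header line).
    """
    dicts = [asdict(r) if is_dataclass(r) else dict(r) for r in results]
    df = pd.DataFrame(dicts)
    df.to_csv(path, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key=value`` config file mirroring PipelineConfig."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SchemaError(f"{path}: line {lineno} is not key=value: {line!r}")
        key, _, value = line.partition("=")
        mapping[key.strip()] = value.strip()
    return PipelineConfig.from_mapping(mapping)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = [f"{k}={v}" for k, v in asdict(cfg).items()]
    Path(path).write_text("\n".join(lines) + "\n")
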