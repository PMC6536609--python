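"""End-to-end orchestration.

``run_pipeline`` ingests a tidy time-course CSV (or a named synthetic
scenario), runs ANOVA + SNK, the cosinor fit, the dual rhythmicity decision
and the control-vs-stress comparison for every variable, and writes all
result tables plus a JSON run manifest. Stage order is enforced by data
dependencies: a decision needs both the ANOVA and the cosinor fit of its
series, and a comparison needs the decisions of both conditions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import RhythmComparison, compare_rhythms
from .cosinor import decide_rhythm, fit_cosinor
from .group_stats import one_way_anova, per_timepoint_test, snk_posthoc
from .io import read_timecourse_csv, write_timecourse_csv
from .model import PipelineConfig, TimeCourse, timecourse_from_arrays
from .simulate import simulate_scenario, stress_study_scenario

log = logging.getLogger("rhythmlab")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the variable."""


@dataclass
class RunManifest:
    config: dict
    input_source: str
    input_sha256: str | None
    seed: int
    version: str
    stage_rows: dict[str, int] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _prepare(tc: TimeCourse, cfg: PipelineConfig) -> TimeCourse:
    tc = tc.merged_zt_prime() if cfg.zt_prime_policy == "merge_with_zt0" else tc
    if cfg.fit_on == "zt_means":
        by_zt = tc.groups_by_zt()
        zts = list(by_zt.keys())
        return timecourse_from_arrays(
            tc.variable_id, tc.condition, zts,
            [float(v.mean()) for v in by_zt.values()], tc.units,
        )
    return tc


def run_pipeline(
    source: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path = "results",
) -> RunManifest:
    """Run the full analysis and write all result CSVs.

    ``source`` is either a tidy CSV path or the scenario name ``"scenario"``
    (the built-in synthetic study, simulated with ``config.seed``).
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    input_sha = None
    if str(source) == "scenario":
        courses = simulate_scenario(seed=cfg.seed)
        write_timecourse_csv(courses, outdir / "input_timecourse.csv")
    else:
        courses = read_timecourse_csv(source)
        input_sha = hashlib.sha256(Path(source).read_bytes()).hexdigest()
    if not courses:
        raise PipelineError("ingest: no time courses in input")

    by_key = {(tc.variable_id, tc.condition): tc for tc in courses}
    variables = sorted({tc.variable_id for tc in courses})

    anova_rows, snk_rows, fit_rows, decision_rows = [], [], [], []
    pointwise_rows, comparison_rows = [], []
    fits, decisions = {}, {}

    for var in variables:
        for cond in ("control", "stress"):
            tc = by_key.get((var, cond))
            if tc is None:
                continue
            tc = _prepare(tc, cfg)
            try:
                anova = one_way_anova(tc)
                snk = snk_posthoc(tc, alpha=cfg.alpha_anova)
                fit = fit_cosinor(tc, period_hours=cfg.period_hours)
                decision = decide_rhythm(fit, anova, cfg)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stats stage failed for {var}/{cond}: {exc}") from exc
            fits[(var, cond)] = fit
            decisions[(var, cond)] = decision
            anova_rows.append({
                "variable": var, "condition": cond, "F": anova.f_stat,
                "df1": anova.df_between, "df2": anova.df_within, "p": anova.p_value,
            })
            snk_rows.extend(
                {"variable": var, "condition": cond, "zt": z, "mean": snk.means[z],
                 "letters": snk.letters[z]}
                for z in snk.letters
            )
            fit_rows.append({
                "variable": var, "condition": cond, "mesor": fit.mesor,
                "amplitude": fit.amplitude, "acrophase_h": fit.acrophase_h,
                "se_mesor": fit.se_mesor, "se_amplitude": fit.se_amplitude,
                "se_acrophase_h": fit.se_acrophase_h, "rss": fit.rss,
                "n": fit.n_obs, "ns_ratio": fit.ns_ratio,
            })
            decision_rows.append({
                "variable": var, "condition": cond, "anova_p": decision.anova_p,
                "ns_ratio": decision.ns_ratio, "is_rhythmic": decision.is_rhythmic,
            })

        ctrl = by_key.get((var, "control"))
        stressed = by_key.get((var, "stress"))
        if ctrl is None or stressed is None:
            log.warning("%s: only one condition present, comparison skipped", var)
            continue
        ctrl_p, stress_p = _prepare(ctrl, cfg), _prepare(stressed, cfg)
        comp = compare_rhythms(
            ctrl_p, stress_p,
            fits[(var, "control")], fits[(var, "stress")],
            decisions[(var, "control")], decisions[(var, "stress")],
            tol_h=cfg.shift_tol_h, period=cfg.period_hours,
        )
        comparison_rows.append({"variable": var, **{
            k: v for k, v in asdict(comp).items() if k != "variable_id"
        }})
        for zt in sorted(set(ctrl_p.zt_levels) & set(stress_p.zt_levels)):
            try:
                p = per_timepoint_test(ctrl_p, stress_p, zt, cfg.per_timepoint_test)
            except Exception:  # unreplicated level: skip, not fatal
                continue
            pointwise_rows.append({
                "variable": var, "zt": zt, "p": p,
                "significant": bool(p < cfg.alpha_anova),
            })

    schemas = {
        "anova.csv": ["variable", "condition", "F", "df1", "df2", "p"],
        "snk.csv": ["variable", "condition", "zt", "mean", "letters"],
        "cosinor_fits.csv": [
            "variable", "condition", "mesor", "amplitude", "acrophase_h",
            "se_mesor", "se_amplitude", "se_acrophase_h", "rss", "n", "ns_ratio",
        ],
        "rhythm_decisions.csv": [
            "variable", "condition", "anova_p", "ns_ratio", "is_rhythmic",
        ],
        "pointwise.csv": ["variable", "zt", "p", "significant"],
        "comparisons.csv": [
            "variable", "mean_control", "mean_stress", "pct_change", "ratio_pct",
            "amp_ratio", "phase_shift_h", "shift_class", "phase_shift_argmax_h",
        ],
    }
    tables = {
        "anova.csv": anova_rows,
        "snk.csv": snk_rows,
        "cosinor_fits.csv": fit_rows,
        "rhythm_decisions.csv": decision_rows,
        "pointwise.csv": pointwise_rows,
        "comparisons.csv": comparison_rows,
    }
    for name, rows in tables.items():
        pd.DataFrame(rows, columns=schemas[name]).to_csv(outdir / name, index=False)

    manifest = RunManifest(
        config=asdict(cfg),
        input_source=str(source),
        input_sha256=input_sha,
        seed=cfg.seed,
        version=__version__,
        stage_rows={name: len(rows) for name, rows in tables.items()},
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def summarize(outdir: str | Path) -> str:
    """One narrative line per variable from the written result tables."""
    outdir = Path(outdir)
    dec_path = outdir / "rhythm_decisions.csv"
    comp_path = outdir / "comparisons.csv"
    if not dec_path.exists():
        raise PipelineError(f"summarize: no pipeline outputs in {outdir}")
    decisions = pd.read_csv(dec_path)
    comps = pd.read_csv(comp_path) if comp_path.exists() else pd.DataFrame()

    lines = []
    for var in sorted(decisions["variable"].unique()):
        sub = decisions[decisions["variable"] == var].set_index("condition")
        rhythm = "/".join(
            "yes" if (c in sub.index and bool(sub.loc[c, "is_rhythmic"])) else "no"
            for c in ("control", "stress")
            if c in sub.index
        )
        line = f"{var}: rhythmic (control/stress): {rhythm}"
        if not comps.empty and var in set(comps["variable"]):
            row = comps[comps["variable"] == var].iloc[0]
            line += (
                f"; means {row['mean_control']:.3g} -> {row['mean_stress']:.3g}"
                f" ({row['pct_change']:+.1f}%)"
            )
            shift = float(row["phase_shift_h"])
            if math.isfinite(shift):
                line += f"; phase shift {shift:+.1f} h"
            line += f"; {row['shift_class']}"
        lines.append(line)
    return "\n".join(lines)
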