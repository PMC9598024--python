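"""End-to-end validation-study runs.

``run_validation_study`` orchestrates, for one population: item
descriptives for both questionnaire parts, optional subscale derivation by
factor analysis, internal consistency, PBI scoring with score-distribution
summary, and the convergent-validity battery.  All results are written as
CSV next to a JSON run manifest, and a run is byte-identical when repeated
with the same inputs and seed.  Children and adolescents are always
analysed separately; there is deliberately no pooled mode.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .instrument import (
    Cohort,
    Population,
    SubscaleMap,
    builtin_subscale_map,
    read_cohort,
)
from .psychometrics import assign_items, cronbach_alpha, efa_varimax, loading_table
from .scoring import item_descriptives, recode_importance, relevant_benefit_rate, score_cohort
from .simulate import SimulationConfig, simulate_cohort
from .validity import ConvergentValidityBattery

__all__ = ["RunManifest", "run_validation_study", "render_report", "REPORT_FILES"]

REPORT_FILES = (
    "item_descriptives.csv",
    "reliability.csv",
    "scores.csv",
    "score_summary.csv",
    "validity.csv",
)


@dataclass
class RunManifest:
    version: str
    population: str
    seed: Optional[int]
    source: str                      # input CSV path or "simulated"
    config: Optional[dict]
    n_parsed: int = 0
    n_population: int = 0
    fa_n_used: Optional[int] = None
    fa_n_retained: Optional[int] = None
    battery_cell_n: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)
    status: str = "ok"
    failed_stage: Optional[str] = None
    error: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def write(self, path: Path) -> None:
        path.write_text(self.to_json() + "\n", "utf-8")


def _log(message: str, quiet: bool) -> None:
    if not quiet:
        print(message, file=sys.stderr)


def run_validation_study(
    source: Union[str, Path, Cohort, SimulationConfig],
    population: Union[Population, str],
    outdir: Union[str, Path],
    seed: Optional[int] = None,
    derive_subscales: bool = False,
    overrides: Sequence[tuple[int, str, str]] = (),
    factor_subscales: Optional[dict] = None,
    quiet: bool = True,
) -> RunManifest:
    """Run the full analysis for one population and write the report bundle.

    ``source`` is a cohort CSV path, an in-memory :class:`Cohort`, or a
    :class:`SimulationConfig` (simulated on the fly; ``seed`` overrides the
    config seed).  With ``derive_subscales`` the subscale map comes from
    EFA + item assignment (``overrides``/``factor_subscales`` feed the
    content-based assignment rules) and a loading table is written;
    otherwise the bundled published map is used and EFA is skipped.
    """
    population = Population(population) if isinstance(population, str) else population
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if isinstance(source, SimulationConfig):
        if seed is not None:
            source = SimulationConfig(**{**source.__dict__, "seed": seed})
        manifest = RunManifest(
            version=__version__,
            population=population.value,
            seed=source.seed,
            source="simulated",
            config=json.loads(source.to_json()),
        )
    else:
        manifest = RunManifest(
            version=__version__,
            population=population.value,
            seed=seed,
            source="cohort" if isinstance(source, Cohort) else str(source),
            config=None,
        )

    stage = "load"
    try:
        t0 = time.perf_counter()
        if isinstance(source, Cohort):
            cohort = source
        elif isinstance(source, SimulationConfig):
            cohort = simulate_cohort(source)
        else:
            cohort = read_cohort(source)
        manifest.n_parsed = len(cohort)
        cohort = cohort.subset(population)
        manifest.n_population = len(cohort)
        if len(cohort) == 0:
            raise ValueError(f"no {population.value} in the cohort")
        _log(f"[load] {manifest.n_population} {population.value} "
             f"({time.perf_counter() - t0:.2f}s)", quiet)

        stage = "descriptives"
        t0 = time.perf_counter()
        desc = pd.concat(
            [
                item_descriptives(cohort, "pnq").assign(part="pnq"),
                item_descriptives(cohort, "pbq").assign(part="pbq"),
            ],
            ignore_index=True,
        )
        _write(desc, outdir / "item_descriptives.csv", manifest)
        _log(f"[descriptives] ({time.perf_counter() - t0:.2f}s)", quiet)

        stage = "subscales"
        t0 = time.perf_counter()
        importance = recode_importance(cohort.pnq_raw_matrix())
        if derive_subscales:
            solution = efa_varimax(importance, item_ids=cohort.instrument.item_ids)
            manifest.fa_n_used = solution.n_used
            manifest.fa_n_retained = solution.n_retained
            _write(loading_table(solution), outdir / "loading_table.csv", manifest)
            assignment = assign_items(
                solution, overrides=overrides, factor_subscales=factor_subscales
            )
            subscale_map = assignment.to_subscale_map(population)
        else:
            subscale_map = builtin_subscale_map(population)
        _log(f"[subscales] {len(subscale_map.names)} subscales "
             f"({time.perf_counter() - t0:.2f}s)", quiet)

        stage = "reliability"
        t0 = time.perf_counter()
        rel_rows = []
        for scale, items in [("global", range(1, 20))] + [
            (name, sorted(subscale_map.items_of(name))) for name in subscale_map.names
        ]:
            idx = [i - 1 for i in items]
            r = cronbach_alpha(importance[:, idx], scale=scale)
            rel_rows.append({"scale": r.scale, "k": r.k, "n_used": r.n_used, "alpha": r.alpha})
        _write(pd.DataFrame(rel_rows), outdir / "reliability.csv", manifest)
        _log(f"[reliability] ({time.perf_counter() - t0:.2f}s)", quiet)

        stage = "scoring"
        t0 = time.perf_counter()
        scores = score_cohort(cohort, subscale_map)
        _write(scores, outdir / "scores.csv", manifest)
        summary_rows = []
        for scale in ("global",) + subscale_map.names:
            vals = scores[scale].dropna()
            rate = relevant_benefit_rate(scores[scale].tolist())
            summary_rows.append(
                {
                    "scale": scale,
                    "n_defined": rate["n_defined"],
                    "n_undefined": rate["n_undefined"],
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "median": vals.median() if len(vals) else np.nan,
                    "relevant_rate": rate["rate"],
                }
            )
        _write(pd.DataFrame(summary_rows), outdir / "score_summary.csv", manifest)
        _log(f"[scoring] ({time.perf_counter() - t0:.2f}s)", quiet)

        stage = "validity"
        t0 = time.perf_counter()
        battery = ConvergentValidityBattery(subscale_map=subscale_map).fit(cohort, scores)
        _write(battery.frame_, outdir / "validity.csv", manifest)
        manifest.battery_cell_n = {
            f"{r.variable}|{r.scale}": r.n for r in battery.results_
        }
        _log(f"[validity] {len(battery.results_)} cells "
             f"({time.perf_counter() - t0:.2f}s)", quiet)
    except Exception as exc:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    return manifest


def _write(frame: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")
    manifest.artifacts.append(path.name)


def render_report(outdir: Union[str, Path]) -> str:
    """Human-readable one-page-per-table summary of a run bundle."""
    outdir = Path(outdir)
    missing = [f for f in REPORT_FILES + ("manifest.json",) if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete bundle; missing artifacts: {missing}")
    manifest = json.loads((outdir / "manifest.json").read_text("utf-8"))
    lines = [
        f"PBI-AR-K validation run ({manifest['population']}, "
        f"seed {manifest['seed']}, v{manifest['version']})",
        f"Respondents analysed: {manifest['n_population']} of {manifest['n_parsed']} parsed",
        "",
    ]

    desc = pd.read_csv(outdir / "item_descriptives.csv")
    for part, title in (("pnq", "Item importance (needs questionnaire)"),
                        ("pbq", "Item benefit (benefit questionnaire)")):
        sub = desc[desc["part"] == part]
        lines.append(title)
        header = f"{'item':>4} {'N':>4} {'mean (SD)':>12} {'quite/very %':>13}"
        if part == "pbq":
            header += f" {'did apply %':>12}"
        lines.append(header)
        for _, row in sub.iterrows():
            line = (f"{int(row['item_id']):>4} {int(row['N']):>4} "
                    f"{row['mean']:>6.2f} ({row['sd']:.2f}) {row['pct_quite_or_very']:>12.1f}")
            if part == "pbq":
                line += f" {row['pct_did_apply']:>12.1f}"
            lines.append(line)
        lines.append("")

    if (outdir / "loading_table.csv").exists():
        load = pd.read_csv(outdir / "loading_table.csv", dtype=str, keep_default_na=False)
        lines.append("Rotated factor loadings (|loading| < 0.3 suppressed; * = highest)")
        lines.append("  ".join(f"{c:>10}" for c in load.columns))
        for _, row in load.iterrows():
            lines.append("  ".join(f"{row[c]:>10}" for c in load.columns))
        lines.append("")

    rel = pd.read_csv(outdir / "reliability.csv")
    lines.append("Internal consistency (Cronbach's alpha, PNQ items)")
    for _, row in rel.iterrows():
        lines.append(f"  {row['scale']:<22} k={int(row['k']):>2} "
                     f"n={int(row['n_used']):>4} alpha={row['alpha']:.3f}")
    lines.append("")

    summ = pd.read_csv(outdir / "score_summary.csv")
    lines.append("Weighted PBI score distribution")
    lines.append(f"  {'scale':<22} {'n':>4} {'mean':>6} {'SD':>6} {'median':>7} {'>=1 %':>7}")
    for _, row in summ.iterrows():
        rate = 100 * row["relevant_rate"] if pd.notna(row["relevant_rate"]) else float("nan")
        lines.append(
            f"  {row['scale']:<22} {int(row['n_defined']):>4} {row['mean']:>6.2f} "
            f"{row['sd']:>6.2f} {row['median']:>7.2f} {rate:>7.1f}"
        )
    lines.append("")

    val = pd.read_csv(outdir / "validity.csv")
    lines.append("Convergent validity (statistic, p, effect size, N; * = p < 0.05)")
    for variable in val["variable"].unique():
        lines.append(f"  {variable}")
        for _, row in val[val["variable"] == variable].iterrows():
            if not row["estimable"]:
                lines.append(f"    {row['scale']:<22} not estimable (N={int(row['N'])})")
                continue
            star = "*" if row["significant"] else " "
            lines.append(
                f"    {row['scale']:<22} {row['test']:<8} stat={row['statistic']:>8.3f} "
                f"p={row['p']:.3f}{star} {row['effect_kind']}={row['effect_size']:>7.3f} "
                f"({row['effect_label']}) N={int(row['N'])}"
            )
    return "\n".join(lines) + "\n"
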