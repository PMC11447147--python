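"""End-to-end orchestration: ingest -> filters -> dyads -> models -> report,
plus the Monte-Carlo calibration harness for the dyad-comparison test.

Reports are plain TSV/JSON: a rounded matrix TSV mirroring the published
layout sits beside a full-precision JSON twin.  Existing outputs are never
silently overwritten (``force=True`` is explicit).  Logging is one
machine-parsable line per event on standard error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import __version__
from .cohort_io import (
    CohortTable,
    apply_control_eligibility,
    read_cohort,
    write_cohort,
)
from .dyad_stats import (
    DyadSpec,
    TABLE2_SPECS,
    apoe_by_birthplace,
    build_dyad_table,
    compare_dyads,
    describe_groups,
    dyad_matrix,
)
from .errors import (
    DegenerateEstimateError,
    DegenerateTableError,
    DyadscanError,
    SimulationError,
)
from .risk_models import fit_ad_logistic, fit_endophenotype_models
from .synthetic_cohort import generate_cohort, scenario_preset

logger = logging.getLogger("dyadscan")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("dyadscan %(levelname)s %(message)s"))
    logger.addHandler(_h)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` / ``scenario`` must be set.
    """

    input_path: str | None = None
    scenario: str | None = None
    out_dir: str = "dyadscan_out"
    seed: int = 0
    mode: str = "risk_ratio"
    variance_rule: str = "pooled_woolf"
    analyses: tuple[str, ...] = ("dyads", "descriptives", "models", "apoe_birthplace")
    n_cases: int = 907
    n_controls: int = 2183
    force: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ValueError("set exactly one of input_path / scenario")


@dataclass
class CalibrationResult:
    """Monte-Carlo rejection rate of the dyad-comparison test."""

    scenario: str
    alpha: float
    reps: int
    n_rejected: int
    rejection_rate: float
    mc_ci95: tuple[float, float]
    n_degenerate: int = 0
    contrast: tuple[str, str] = ("mother -> son", "mother -> daughter")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mc_ci95"] = list(self.mc_ci95)
        d["contrast"] = list(self.contrast)
        return d


def _load_cohort(config: RunConfig) -> CohortTable:
    if config.input_path is not None:
        cohort = read_cohort(config.input_path)
    else:
        sim = scenario_preset(
            config.scenario,
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            seed=config.seed,
        )
        cohort = generate_cohort(sim)
    return apply_control_eligibility(cohort)


def _output_path(out_dir: Path, name: str, force: bool) -> Path:
    path = out_dir / name
    if path.exists() and not force:
        raise DyadscanError(
            f"refusing to overwrite existing output {path}; pass force=True/--force"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analyses and write the report bundle.

    Returns a manifest dict with output paths, per-stage status and the
    filter audit.  Stage failures are recorded (stage name + message) and
    flagged as partial rather than aborting the whole run.
    """
    logger.setLevel(config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort(config)
    logger.info(
        "cohort loaded n=%d cases=%d controls=%d", len(cohort), cohort.n_cases,
        cohort.n_controls,
    )
    for f in cohort.provenance.get("filters", []):
        logger.info("filter %(filter)s removed=%(removed)d retained=%(retained)d", f)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if v is not None
        },
        "filters": cohort.provenance.get("filters", []),
        "outputs": {},
        "errors": {},
    }

    cohort_path = _output_path(out_dir, "cohort.tsv", config.force)
    write_cohort(cohort, cohort_path)
    manifest["outputs"]["cohort"] = str(cohort_path)

    if "dyads" in config.analyses:
        try:
            matrix = dyad_matrix(
                cohort, TABLE2_SPECS, mode=config.mode,
                variance_rule=config.variance_rule,
            )
            tsv = _output_path(out_dir, "matrix.tsv", config.force)
            matrix.to_frame().to_csv(tsv, sep="\t", index=False)
            js = _output_path(out_dir, "matrix.json", config.force)
            js.write_text(json.dumps(matrix.to_dict(), indent=2))
            manifest["outputs"]["matrix"] = str(tsv)
            manifest["outputs"]["matrix_json"] = str(js)
        except DyadscanError as exc:
            manifest["errors"]["dyads"] = str(exc)
            logger.error("stage=dyads error=%s", exc)

    if "descriptives" in config.analyses:
        try:
            rows = []
            for grouping in ("case_vs_control", "eoad_vs_load"):
                try:
                    comps = describe_groups(cohort, grouping)
                except (DegenerateTableError, ValueError) as exc:
                    logger.warning("grouping=%s skipped: %s", grouping, exc)
                    continue
                for c in comps:
                    rows.append(
                        {
                            "grouping": grouping,
                            "variable": c.variable,
                            "test": c.test,
                            "statistic": c.statistic,
                            "p": c.p,
                            "groups": json.dumps(c.groups),
                            "note": c.note,
                        }
                    )
            import pandas as pd

            tsv = _output_path(out_dir, "descriptives.tsv", config.force)
            pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
            manifest["outputs"]["descriptives"] = str(tsv)
        except DyadscanError as exc:
            manifest["errors"]["descriptives"] = str(exc)
            logger.error("stage=descriptives error=%s", exc)

    if "apoe_birthplace" in config.analyses:
        try:
            comp = apoe_by_birthplace(cohort)
            path = _output_path(out_dir, "apoe_by_birthplace.json", config.force)
            path.write_text(
                json.dumps(
                    {
                        "variable": comp.variable,
                        "test": comp.test,
                        "statistic": comp.statistic,
                        "p": comp.p,
                        "groups": comp.groups,
                        "note": comp.note,
                    },
                    indent=2,
                )
            )
            manifest["outputs"]["apoe_by_birthplace"] = str(path)
        except DyadscanError as exc:
            manifest["errors"]["apoe_birthplace"] = str(exc)
            logger.error("stage=apoe_birthplace error=%s", exc)

    if "models" in config.analyses:
        fits: dict = {}
        try:
            endo = fit_endophenotype_models(cohort)
            fits["endophenotypes"] = {k: v.to_dict() for k, v in endo.items()}
        except DyadscanError as exc:
            manifest["errors"]["endophenotype_models"] = str(exc)
            logger.error("stage=endophenotype_models error=%s", exc)
        try:
            fits["ad_logistic"] = fit_ad_logistic(cohort).to_dict()
        except DyadscanError as exc:
            manifest["errors"]["ad_logistic"] = str(exc)
            logger.error("stage=ad_logistic error=%s", exc)
        if fits:
            path = _output_path(out_dir, "fits.json", config.force)
            path.write_text(json.dumps(fits, indent=2))
            manifest["outputs"]["fits"] = str(path)

    manifest["partial"] = bool(manifest["errors"])
    log_path = _output_path(out_dir, "run_log.json", config.force)
    log_path.write_text(json.dumps(manifest, indent=2))
    manifest["outputs"]["run_log"] = str(log_path)
    return manifest


def calibrate(
    scenario: str,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
    n_cases: int = 500,
    n_controls: int = 1000,
    contrast: tuple[DyadSpec, DyadSpec] = (
        DyadSpec("mother", "male"),
        DyadSpec("mother", "female"),
    ),
    mode: str = "risk_ratio",
    variance_rule: str = "pooled_woolf",
) -> CalibrationResult:
    """Monte-Carlo rejection rate of the dyad-comparison test on a preset.

    Simulates ``reps`` cohorts (replicate r uses child seed ``seed + r``),
    applies the comparison for ``contrast`` and counts two-sided rejections
    at ``alpha``.  Returns the rate with its exact (Clopper-Pearson)
    binomial 95% CI.  Aborts if more than 5% of replicates are degenerate.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    rejected = degenerate = 0
    tested = 0
    for r in range(reps):
        cfg = scenario_preset(
            scenario, n_cases=n_cases, n_controls=n_controls, seed=seed + r
        )
        cohort = generate_cohort(cfg)
        try:
            t1 = build_dyad_table(cohort, contrast[0])
            t2 = build_dyad_table(cohort, contrast[1])
            cmp_ = compare_dyads(t1, t2, mode=mode, variance_rule=variance_rule)
        except (DegenerateTableError, DegenerateEstimateError):
            degenerate += 1
            continue
        tested += 1
        if cmp_.p_two_sided < alpha:
            rejected += 1
    if degenerate > 0.05 * reps:
        raise SimulationError(
            f"{degenerate}/{reps} replicates degenerate for contrast "
            f"{contrast[0].label!r} vs {contrast[1].label!r}"
        )
    rate = rejected / tested if tested else float("nan")
    ci = stats.binomtest(rejected, tested).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return CalibrationResult(
        scenario=scenario,
        alpha=alpha,
        reps=reps,
        n_rejected=rejected,
        rejection_rate=rate,
        mc_ci95=(float(ci.low), float(ci.high)),
        n_degenerate=degenerate,
        contrast=(contrast[0].label, contrast[1].label),
    )
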