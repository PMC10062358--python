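"""Pipeline orchestration: simulate -> process -> segment -> analyze ->
correct, with deterministic outputs and stage-level accounting.

Patients are simulated and processed one at a time (raw waveforms are
memory-heavy); only minute-level tables are retained. All outputs embed
the RunConfig hash so a result file can be traced to its scenario.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from afpulse.agreement import (
    per_patient_summary,
    patient_level_agreement,
    stratified_report,
    summarize_agreement,
)
from afpulse.config import RunConfig
from afpulse.fixtures import FixtureSet
from afpulse.models import ModelSpec, cross_validate
from afpulse.ppg import process_record
from afpulse.segmentation import apply_inclusion, build_segment_table, exclusion_counts
from afpulse.synth import simulate_patient

log = logging.getLogger("afpulse")


def build_cohort_table(config: RunConfig) -> pd.DataFrame:
    """Simulate + process + segment the whole cohort into one table."""
    tables = []
    for i in range(config.sim.n_patients):
        record = simulate_patient(config.sim, i)
        est = process_record(record, config.proc)
        tables.append(build_segment_table(record, est))
        log.info("patient %d/%d processed", i + 1, config.sim.n_patients)
    table = pd.concat(tables, ignore_index=True)
    boundaries = (
        "empirical" if config.motion_boundaries == "empirical" else config.motion_boundaries
    )
    table = apply_inclusion(table, boundaries)
    table.attrs["config_hash"] = config.config_hash()
    return table


def _summary_to_dict(s) -> dict:
    return {
        "rmse": s.rmse,
        "bias": s.bland_altman.bias,
        "loa_lower": s.bland_altman.lower_limit,
        "loa_upper": s.bland_altman.upper_limit,
        "pct_within_10": s.pct_within_10,
        "rough_accuracy": s.confusion.rough_accuracy(),
        "n_segments": s.n_segments,
    }


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages; optionally write the report bundle to ``outdir``.

    Returns a dict with the segment table, exclusion accounting,
    agreement report, per-patient summaries, and CV results for the
    requested correction models.
    """
    table = build_cohort_table(config)
    counts = exclusion_counts(table)
    log.info(
        "segments: %d total, %d included (%.0f%%), excluded ECG-only %d / "
        "PPG-only %d / both %d",
        counts["total"],
        counts["included"],
        100.0 * counts["included"] / max(counts["total"], 1),
        counts["ecg_only"],
        counts["ppg_only"],
        counts["both"],
    )
    report = stratified_report(table)
    patients = per_patient_summary(table)
    cohort = patient_level_agreement(patients)

    cv_results = {}
    for short in config.run_models:
        spec = ModelSpec(short, seed=config.seed)
        cv_results[spec.kind] = cross_validate(
            table,
            spec,
            k=config.cv_folds,
            grouping=config.cv_grouping,
            seed=config.seed,
        )

    bundle = {
        "config_hash": config.config_hash(),
        "table": table,
        "exclusion_counts": counts,
        "agreement": report,
        "patient_summaries": patients,
        "patient_level": cohort,
        "cv_results": cv_results,
    }
    if outdir is not None:
        write_bundle(bundle, outdir, config)
    return bundle


def write_bundle(bundle: dict, outdir: str | Path, config: RunConfig) -> None:
    """Write the report bundle as CSV/JSON (deterministic content)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["table"].to_csv(out / "segments.csv", index=False, float_format="%.6g")
    summary = {
        "config_hash": bundle["config_hash"],
        "config": config.to_dict(),
        "exclusion_counts": bundle["exclusion_counts"],
        "strata": {
            k: _summary_to_dict(v) for k, v in bundle["agreement"]["strata"].items()
        },
        "comparisons": {
            k: {
                "table": np.asarray(v["table"]).tolist(),
                "fisher_p": v["fisher_p"],
                "clustered_p": v["clustered_p"],
            }
            for k, v in bundle["agreement"]["comparisons"].items()
        },
        "patient_level": bundle["patient_level"],
        "cv": {
            kind: {
                "fold_rmse": r.fold_rmse,
                "rmse": r.rmse,
                "ci95": list(r.ci95),
                "loa": [r.bland_altman.lower_limit, r.bland_altman.upper_limit],
            }
            for kind, r in bundle["cv_results"].items()
        },
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    rows = [vars(s).copy() for s in bundle["patient_summaries"]]
    pd.DataFrame(rows).to_csv(out / "patients.csv", index=False, float_format="%.6g")


def build_fixtures() -> FixtureSet:
    """The published-count fixtures (clinical 2x2, confusion matrices,
    segment accounting) as one bundle."""
    return FixtureSet()
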