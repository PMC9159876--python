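"""End-to-end workflow: simulate -> process -> spatial stats -> fit -> report.

Each stage is a plain function over in-memory objects; the CLI wraps these
with file I/O. One seed in the configuration fixes every downstream
artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    SyntheticCohort,
    config_from_dict,
    config_to_dict,
    generate_cohort,
    load_cohort,
    patients_dataframe,
    write_cohort,
)
from .geometry import PHASE_NAMES
from .glmm import FitReport, MCMCSettings, fit_all_models
from .processing import (
    DEFAULT_EXCLUSION_THRESHOLD_MAD,
    DEFAULT_FILTER_ORDER,
    exclude_noisy,
    extension_activity,
    normalize_rms,
    rms_map,
)
from .spatial import bilateral_trial_centroid, compute_distance

logger = logging.getLogger("painmap")


@dataclass
class ProcessingOptions:
    filter_order: int = DEFAULT_FILTER_ORDER
    exclusion_threshold_mad: float = DEFAULT_EXCLUSION_THRESHOLD_MAD


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    processing: ProcessingOptions = field(default_factory=ProcessingOptions)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration (missing sections take defaults)."""
    raw: Mapping = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(
        cohort=config_from_dict(raw.get("cohort", {})),
        mcmc=MCMCSettings(**raw.get("mcmc", {})),
        processing=ProcessingOptions(**raw.get("processing", {})),
    )


def config_to_yaml(config: PipelineConfig) -> str:
    return yaml.safe_dump(
        {
            "cohort": config_to_dict(config.cohort),
            "mcmc": asdict(config.mcmc),
            "processing": asdict(config.processing),
        },
        sort_keys=False,
    )


@dataclass
class ProcessedCohort:
    """Tabular outputs of the signal-processing and spatial stages."""

    trial_outcomes: pd.DataFrame  # one row per (patient, experimental trial)
    patient_outcomes: pd.DataFrame  # one row per patient (trial-averaged)
    rms_long: pd.DataFrame  # tidy per-cell RMS values


def process_cohort(
    cohort: SyntheticCohort, options: ProcessingOptions | None = None
) -> ProcessedCohort:
    """Raw recordings -> normalized RMS maps -> activity/centroid/DISTANCE.

    Per patient: each trial is filtered, segmented, reduced to a raw RMS map
    and screened for noisy cells; experimental maps are normalized by the
    reference trial's extension-phase RMS (per channel). Trial-level
    outcomes feed the mixed models; patient-level outcomes (mean over the
    experimental trials, the study's summary convention) feed the cohort
    descriptives.
    """
    options = options or ProcessingOptions()
    trial_rows, patient_rows, rms_rows = [], [], []
    for patient in cohort.patients:
        trials = sorted(
            tid for (pid, tid) in cohort.recordings if pid == patient.patient_id
        )
        if 0 not in trials:
            raise ValueError(f"patient {patient.patient_id} has no reference trial")
        maps = {}
        for tid in trials:
            rec = cohort.recordings[(patient.patient_id, tid)]
            m = rms_map(rec, filter_order=options.filter_order)
            maps[tid] = exclude_noisy(m, options.exclusion_threshold_mad)
        ref = maps[0]
        exp_tids = [t for t in trials if t != 0]
        exp_maps = [maps[t] for t in exp_tids]

        for tid in trials:
            m = maps[tid]
            norm = normalize_rms([m], ref)
            for p, phase in enumerate(PHASE_NAMES):
                for c in range(m.n_channels):
                    rms_rows.append(
                        {
                            "patient_id": patient.patient_id,
                            "trial_id": tid,
                            "role": "reference" if tid == 0 else "experimental",
                            "side": m.channel_sides[c],
                            "phase": phase,
                            "channel_index": c,
                            "channel_y_cm": m.channel_y_cm[c],
                            "rms_raw": m.values[p, c],
                            "rms_normalized": norm.values[p, c],
                            "excluded": bool(norm.excluded[p, c]),
                        }
                    )

        for tid in exp_tids:
            norm_t = normalize_rms([maps[tid]], ref)
            centroid_t = bilateral_trial_centroid([maps[tid]])
            dist_t = compute_distance(centroid_t, patient.pain_site_cm)
            trial_rows.append(
                {
                    "patient_id": patient.patient_id,
                    "trial_id": tid,
                    "extension_activity": extension_activity(norm_t),
                    "centroid_y_cm": centroid_t.y_mean_cm,
                    "pain_site_cm": patient.pain_site_cm,
                    "distance_cm": dist_t.distance_cm,
                }
            )

        norm = normalize_rms(exp_maps, ref)
        centroid = bilateral_trial_centroid(exp_maps)
        dist = compute_distance(centroid, patient.pain_site_cm)
        patient_rows.append(
            {
                "patient_id": patient.patient_id,
                "extension_activity": extension_activity(norm),
                "centroid_y_cm": centroid.y_mean_cm,
                "pain_site_cm": patient.pain_site_cm,
                "distance_cm": dist.distance_cm,
            }
        )
    return ProcessedCohort(
        trial_outcomes=pd.DataFrame(trial_rows),
        patient_outcomes=pd.DataFrame(patient_rows),
        rms_long=pd.DataFrame(rms_rows),
    )


def simulate_to_dir(config: CohortConfig, outdir: str | Path) -> Path:
    cohort = generate_cohort(config)
    path = write_cohort(cohort, outdir)
    (Path(path) / "config.yaml").write_text(
        yaml.safe_dump({"cohort": config_to_dict(config)}, sort_keys=False)
    )
    logger.info(
        "simulated cohort: %d patients x %d trials (+reference) -> %s",
        config.n_patients, config.n_trials, path,
    )
    return path


def process_dir(
    cohort_dir: str | Path, options: ProcessingOptions | None = None
) -> ProcessedCohort:
    return process_cohort(load_cohort(cohort_dir), options)


def fit(
    processed: ProcessedCohort | pd.DataFrame,
    patients: pd.DataFrame,
    settings: MCMCSettings,
    include_nrs_covariate: bool = False,
) -> FitReport:
    trial_outcomes = (
        processed.trial_outcomes
        if isinstance(processed, ProcessedCohort)
        else processed
    )
    return fit_all_models(
        trial_outcomes, patients, settings, include_nrs_covariate=include_nrs_covariate
    )


def report_text(fit_report: FitReport, provenance: Mapping | None = None) -> str:
    """Human-readable summary: credible associations per model + provenance."""
    lines = ["Credibly nonzero associations (95% CI excludes 0)", ""]
    for dep, label in (
        ("extension_activity", "Muscle activity (extension phase)"),
        ("distance_cm", "DISTANCE (centroid to pain site)"),
    ):
        lines.append(f"## {label}")
        sub = fit_report.summary.query("dependent == @dep and credibly_nonzero")
        if sub.empty:
            lines.append("  (none)")
        for _, r in sub.iterrows():
            lines.append(
                f"  {r['model_name']:>12} model: {r['parameter']:<24} "
                f"estimate={r['estimate']:+.2f} "
                f"95% CI [{r['ci_low']:+.2f}, {r['ci_high']:+.2f}] "
                f"Rhat={r['rhat']:.2f}"
            )
        lines.append("")
    bad = [res for res in fit_report.results if not res.converged]
    if bad:
        lines.append("Convergence warnings (some Rhat >= 1.1):")
        for res in bad:
            lines.append(
                f"  {res.spec.model_name}/{res.spec.dependent}: max Rhat {res.max_rhat:.3f}"
            )
        lines.append("")
    if provenance:
        lines.append("Provenance: " + json.dumps(provenance, sort_keys=True))
    return "\n".join(lines)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> tuple[ProcessedCohort, FitReport]:
    """simulate -> process -> fit; optionally persisting all artifacts."""
    cohort = generate_cohort(config.cohort)
    processed = process_cohort(cohort, config.processing)
    fit_report = fit(processed, patients_dataframe(cohort.patients), config.mcmc)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_outputs(processed, fit_report, outdir, config)
    return processed, fit_report


def write_outputs(
    processed: ProcessedCohort,
    fit_report: FitReport,
    outdir: Path,
    config: PipelineConfig | None = None,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    processed.trial_outcomes.to_csv(
        outdir / "trial_outcomes.csv", index=False, float_format="%.8g"
    )
    processed.patient_outcomes.to_csv(
        outdir / "patient_outcomes.csv", index=False, float_format="%.8g"
    )
    processed.rms_long.to_csv(outdir / "rms_maps.csv", index=False, float_format="%.8g")
    for dep, table in fit_report.tables.items():
        formatted = table.copy()
        for col in ("Estimate", "Lower CI", "Upper CI", "Rhat"):
            formatted[col] = formatted[col].map(lambda v: f"{v:.2f}")
        formatted.to_csv(outdir / f"report_{dep}.csv", index=False)
    fit_report.summary.to_csv(
        outdir / "model_summaries.csv", index=False, float_format="%.8g"
    )
    provenance = {"painmap_version": __version__}
    if config is not None:
        provenance["config"] = yaml.safe_load(config_to_yaml(config))
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (outdir / "report.txt").write_text(report_text(fit_report, provenance={"painmap_version": __version__}))
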