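"""End-to-end workflow orchestration.

Runs the fixed stage order — simulate/ingest -> blank+detection filter ->
drift correction -> RSD filter -> per-contrast selection -> trend patterns ->
annotation -> clinical outcomes — writing every stage's output as CSV/JSON
into a run directory, and collecting a machine-readable ``RunReport`` whose
feature counts are monotone non-increasing through the filters.  All
randomness derives from one master seed (per-stage seeds are spawned
deterministically), so a rerun with the same config is reproducible and any
stage can be re-entered from the artifacts on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .feature_table import (
    FeatureTable,
    StudyDesign,
    read_feature_table,
    write_feature_table,
    write_sample_sheet,
)
from .synthetic import SimulationConfig, simulate
from .qc_filtering import blank_filter, detection_filter, rsd_filter, apply_filters
from .drift_correction import correct_table
from .selection import select_contrast, intersect_contrasts, rf_mds, unsupervised_rf, CONTRASTS
from .trends_annotation import trend_table, annotate_features, load_reference_list
from .outcomes import weight_groups, remission_strata, outcome_tests

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_all", "load_config"]

__version__ = "0.1.0"

logger = logging.getLogger("metadrift")

STAGES = ("data", "filter", "correct", "rsd", "select", "trends", "annotate", "outcomes")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Workflow parameters; defaults are the workflow's standard settings
    (tau 0.5, df 16, RSD 0.30, 300 trees, mtry 30, alpha 0.01)."""

    seed: int = 0
    simulation: SimulationConfig | None = None
    feature_table_path: str | None = None
    sample_sheet_path: str | None = None
    blank_ratio_threshold: float = 0.5
    min_qc_detect_fraction: float = 0.8
    rsd_threshold: float = 0.30
    tau: float = 0.5
    df: int = 16
    alpha: float = 0.01
    n_trees: int = 300
    mtry: int = 30
    combine: str = "and"
    log_transform: bool = True
    trend_epsilon: float = 0.03
    ppm_tol: float = 10.0
    rt_tol: float = 0.5
    outcome_test: str = "welch"
    reference_list_path: str | None = None

    def __post_init__(self):
        if self.simulation is None and self.feature_table_path is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)

    def to_dict(self) -> dict:
        # via JSON so nested tuples become plain lists (YAML-safe)
        return json.loads(json.dumps(asdict(self), default=str))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    return RunConfig(**raw)


@dataclass
class RunReport:
    """Per-stage counts and summary statistics of one workflow run."""

    config_hash: str = ""
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    median_qc_cv_before: float | None = None
    median_qc_cv_after: float | None = None
    oob_error: dict = field(default_factory=dict)
    pattern_counts: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, sort_keys=True, default=float)

    @classmethod
    def from_json(cls, path) -> "RunReport":
        with open(path) as handle:
            return cls(**json.load(handle))


def _stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from the master seed (< 2^31)."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def run_all(config: RunConfig, out_dir) -> RunReport:
    """Execute the full workflow; returns the run report.

    Any stage error aborts with the stage name while the partial report is
    preserved at ``<out_dir>/run_report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    if not logger.handlers:
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    seeds = _stage_seeds(config.seed)
    report = RunReport(config_hash=config.content_hash(), seeds=seeds)
    report_path = out / "run_report.json"

    def finish_stage(stage: str, **info):
        report.completed_stages.append(stage)
        report.to_json(report_path)
        logger.info("stage %-8s %s", stage, " ".join(f"{k}={v}" for k, v in info.items()))

    try:
        stage = "data"
        if config.feature_table_path is not None:
            table, design = read_feature_table(
                config.feature_table_path, config.sample_sheet_path
            )
            truth = None
        else:
            sim_config = config.simulation
            table, design, truth = simulate(sim_config)
            truth.features.to_csv(out / "ground_truth_features.csv")
            truth.patients.to_csv(out / "ground_truth_patients.csv")
        write_feature_table(table, out / "feature_table.csv")
        write_sample_sheet(design, out / "sample_sheet.csv")
        report.counts["n_detected"] = table.n_features
        finish_stage(stage, n_features=table.n_features, n_injections=len(table.injections))

        stage = "filter"
        blank_rep = blank_filter(table, design, config.blank_ratio_threshold)
        detect_rep = detection_filter(table, design, config.min_qc_detect_fraction)
        filtered = apply_filters(table, blank_rep, detect_rep)
        merged = blank_rep.merge(detect_rep)
        with open(out / "filter_report.json", "w") as fh:
            json.dump(merged.to_dict(), fh, indent=2)
        report.counts["n_after_blank_detection"] = filtered.n_features
        finish_stage(stage, kept=filtered.n_features)

        stage = "correct"
        corrected, drift_report, _ = correct_table(
            filtered, design, tau=config.tau, df=config.df
        )
        write_feature_table(corrected, out / "corrected_table.csv")
        drift_report.cv.to_csv(out / "drift_cv.csv")
        with open(out / "drift_report.json", "w") as fh:
            json.dump(drift_report.to_dict(), fh, indent=2)
        report.median_qc_cv_before = drift_report.median_cv_before
        report.median_qc_cv_after = drift_report.median_cv_after
        finish_stage(
            stage,
            cv_before=round(drift_report.median_cv_before, 4),
            cv_after=round(drift_report.median_cv_after, 4),
            failed=len(drift_report.failed),
        )

        stage = "rsd"
        rsd_rep = rsd_filter(corrected, design, config.rsd_threshold)
        analysis_table = apply_filters(corrected, rsd_rep)
        write_feature_table(analysis_table, out / "analysis_table.csv")
        with open(out / "rsd_report.json", "w") as fh:
            json.dump(rsd_rep.to_dict(), fh, indent=2)
        report.counts["n_after_rsd"] = analysis_table.n_features
        finish_stage(stage, kept=analysis_table.n_features)

        stage = "select"
        results = {}
        for contrast in CONTRASTS:
            res = select_contrast(
                analysis_table,
                design,
                contrast,
                alpha=config.alpha,
                n_trees=config.n_trees,
                mtry=config.mtry,
                seed=seeds["select"],
                combine=config.combine,
                log_transform=config.log_transform,
            )
            results[contrast] = res
            res.stats.to_csv(out / f"selection_{contrast}.csv")
            coords = rf_mds(res.proximity)
            pd.DataFrame(
                coords,
                index=res.sample_ids,
                columns=[f"dim{i + 1}" for i in range(coords.shape[1])],
            ).assign(timepoint=res.labels).to_csv(out / f"mds_{contrast}.csv")
            report.counts[f"n_selected_{contrast}"] = len(res.selected_ids)
            report.oob_error[contrast] = res.oob_error
        final = intersect_contrasts(results["PRE_POST"], results["PRE_FU"])
        pd.Series(final, name="feature_id").to_csv(out / "final_features.csv", index=False)
        report.counts["n_final"] = len(final)
        finish_stage(
            stage,
            **{f"selected_{c}": len(r.selected_ids) for c, r in results.items()},
            final=len(final),
        )

        stage = "trends"
        if final:
            trends = trend_table(
                analysis_table, design, final, epsilon=config.trend_epsilon
            )
            trends.to_csv(out / "trends.csv")
            report.pattern_counts = trends["pattern"].value_counts().to_dict()
        finish_stage(stage, patterns=report.pattern_counts)

        stage = "annotate"
        reference = load_reference_list(config.reference_list_path)
        if final:
            annotations = annotate_features(
                analysis_table, reference, final,
                ppm_tol=config.ppm_tol, rt_tol=config.rt_tol,
            )
            annotations.to_csv(out / "annotations.csv")
            n_annotated = int((annotations["level"] != "unannotated").sum())
        else:
            n_annotated = 0
        report.counts["n_annotated"] = n_annotated
        finish_stage(stage, annotated=n_annotated)

        stage = "outcomes"
        pats = design.patients
        have_weights = {"weight_pre", "weight_fu"}.issubset(pats.columns)
        if have_weights and len(pats):
            groups = weight_groups(design)
            groups.patients.to_csv(out / "outcome_groups.csv")
            if final:
                wtest = outcome_tests(
                    analysis_table, design, final,
                    groups.patients["group"], mode="fu_level", test=config.outcome_test,
                )
                wtest.to_csv(out / "outcome_weight_tests.csv")
            if "diabetic_at_baseline" in pats.columns and final:
                strata = remission_strata(design)
                rn = strata[strata.isin(["R", "N-R"])]
                if (rn == "R").sum() >= 3 and (rn == "N-R").sum() >= 3:
                    rtest = outcome_tests(
                        analysis_table, design, final,
                        rn, mode="decline", test=config.outcome_test,
                    )
                    rtest.to_csv(out / "outcome_remission_tests.csv")
        finish_stage(stage)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        report.to_json(report_path)
        raise PipelineError(stage, exc) from exc

    report.to_json(report_path)
    return report
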