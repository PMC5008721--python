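"""Blank/QC-based feature filters.

Three filters remove junk from the grouped feature matrix:

* ``blank_filter`` — *system peaks* (measurement-system impurities visible in
  solvent blanks): flagged when mean blank intensity exceeds half the mean
  pooled-QC intensity (a scale-free ratio rule).
* ``detection_filter`` — *poorly detected* features: flagged when detected in
  fewer than 80% of the pooled QCs, which are technical replicates of one
  pool, so absence there indicates unreliable detection.
* ``rsd_filter`` — applied *after* drift correction: only features whose
  pooled-QC relative standard deviation is at most 30% are kept as well
  measured or well corrected.

Blank and detection filters run before drift correction so the spline fits
are not polluted by junk features; the RSD filter runs after, per the
workflow's explicit ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, StudyDesign, FeatureTableError

__all__ = ["FilterReport", "qc_cv", "qc_cv_table", "blank_filter", "detection_filter", "rsd_filter", "apply_filters"]

_FLAG_COLUMNS = ["system_peak", "poorly_detected", "high_rsd"]


@dataclass
class FilterReport:
    """Per-feature filter flags plus the thresholds and counts behind them."""

    flags: pd.DataFrame  # boolean columns: system_peak, poorly_detected, high_rsd
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        for col in _FLAG_COLUMNS:
            if col not in self.flags.columns:
                self.flags[col] = False
        self.flags = self.flags[_FLAG_COLUMNS].astype(bool)

    @property
    def removed_ids(self) -> list[str]:
        return list(self.flags.index[self.flags.any(axis=1)])

    @property
    def kept_ids(self) -> list[str]:
        return list(self.flags.index[~self.flags.any(axis=1)])

    @property
    def counts(self) -> dict:
        out = {"n_input": int(len(self.flags))}
        for col in _FLAG_COLUMNS:
            out[f"n_{col}"] = int(self.flags[col].sum())
        out["n_removed"] = len(self.removed_ids)
        out["n_kept"] = len(self.kept_ids)
        return out

    def merge(self, other: "FilterReport") -> "FilterReport":
        """Union of flags from two reports over the same feature index."""
        flags = self.flags.reindex(self.flags.index.union(other.flags.index), fill_value=False)
        oflags = other.flags.reindex(flags.index, fill_value=False)
        return FilterReport(flags | oflags, {**self.thresholds, **other.thresholds})

    def to_dict(self) -> dict:
        return {"thresholds": self.thresholds, "counts": self.counts,
                "removed": self.removed_ids}


def qc_cv(values) -> float:
    """Coefficient of variation (sample sd / mean) over non-missing QC values.

    Returns NaN (the undefined-CV signal) when fewer than 2 non-missing
    values are available; such features are routed to the poorly-detected
    flag by the callers.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    mean = v.mean()
    if mean == 0:
        return float("inf")
    return float(v.std(ddof=1) / mean)


def qc_cv_table(table: FeatureTable, design: StudyDesign) -> pd.Series:
    """Per-feature QC CV; NaN where fewer than 2 QC intensities exist."""
    qc = table.intensities[design.qc_ids].to_numpy(dtype=float)
    n = (~np.isnan(qc)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(np.where(n[:, None] >= 2, qc, np.nan), axis=1)
        sd = np.nanstd(np.where(n[:, None] >= 2, qc, np.nan), axis=1, ddof=1)
        cv = np.where(n >= 2, sd / mean, np.nan)
    return pd.Series(cv, index=table.features.index, name="qc_cv")


def _require_qcs(design: StudyDesign) -> list[str]:
    ids = design.qc_ids
    if not ids:
        raise FeatureTableError("filter requires at least one QC injection")
    return ids


def blank_filter(
    table: FeatureTable, design: StudyDesign, blank_ratio_threshold: float = 0.5
) -> FilterReport:
    """Flag system peaks: mean(blank) / mean(QC) above the threshold.

    Features missing in all blanks are never flagged.
    """
    blank_ids = design.blank_ids
    if not blank_ids:
        raise FeatureTableError("blank filter requires blanks")
    qc_ids = _require_qcs(design)
    with np.errstate(invalid="ignore", divide="ignore"):
        blank_mean = np.nanmean(table.intensities[blank_ids].to_numpy(float), axis=1)
        qc_mean = np.nanmean(table.intensities[qc_ids].to_numpy(float), axis=1)
        ratio = blank_mean / qc_mean
    flagged = np.where(np.isnan(ratio), False, ratio > blank_ratio_threshold)
    flags = pd.DataFrame({"system_peak": flagged}, index=table.features.index)
    return FilterReport(flags, {"blank_ratio_threshold": blank_ratio_threshold})


def detection_filter(
    table: FeatureTable, design: StudyDesign, min_qc_detect_fraction: float = 0.8
) -> FilterReport:
    """Flag poorly detected features: non-missing in < the given fraction of QCs."""
    qc_ids = _require_qcs(design)
    qc = table.intensities[qc_ids].to_numpy(float)
    detect_frac = (~np.isnan(qc)).sum(axis=1) / qc.shape[1]
    flags = pd.DataFrame(
        {"poorly_detected": detect_frac < min_qc_detect_fraction},
        index=table.features.index,
    )
    return FilterReport(flags, {"min_qc_detect_fraction": min_qc_detect_fraction})


def rsd_filter(
    corrected_table: FeatureTable, design: StudyDesign, rsd_threshold: float = 0.30
) -> FilterReport:
    """Flag features whose post-correction QC CV exceeds the RSD threshold.

    Features with an undefined CV (fewer than 2 QC values) are flagged
    poorly detected rather than high-RSD.
    """
    cv = qc_cv_table(corrected_table, design)
    flags = pd.DataFrame(
        {
            "high_rsd": (cv > rsd_threshold).fillna(False),
            "poorly_detected": cv.isna(),
        },
        index=corrected_table.features.index,
    )
    return FilterReport(flags, {"rsd_threshold": rsd_threshold})


def apply_filters(table: FeatureTable, *reports: FilterReport) -> FeatureTable:
    """Drop every feature flagged by any of the reports."""
    removed: set[str] = set()
    for report in reports:
        removed |= set(report.removed_ids)
    keep = [f for f in table.feature_ids if f not in removed]
    return table.subset(keep)
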