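"""Linking metabolite changes to clinical outcomes.

Two groupings are supported:

* **Weight loss** — the weight-loss ratio is weight at one-year follow-up
  over weight at baseline (FU/PRE).  Patients below the cohort median ratio
  form the high-weight-loss (HWL) group, the rest (ties included) the
  low-weight-loss (LWL) group.
* **Diabetes remission** — patients are stratified into remission (R),
  non-remission (N-R) and non-diabetic (N-DM) from precomputed flags
  (remission = HbA1c < 6.5% without pharmacological treatment, adjudicated
  upstream).

The per-metabolite comparison uses the per-patient decline
``d = log(intensity_FU / intensity_PRE)`` — scale-free, so rescaling
intensities cannot change the test — compared between two groups with
Welch's t-test (Mann-Whitney optionally).  A comparison of absolute FU
levels between weight groups is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable, StudyDesign, FeatureTableError

__all__ = ["OutcomeGroups", "weight_groups", "remission_strata", "group_metabolite_test", "outcome_tests"]


@dataclass
class OutcomeGroups:
    """Per-patient outcome grouping plus cohort-level weight summaries."""

    patients: pd.DataFrame  # columns: weight_loss_ratio, group, stratum
    median_ratio: float
    median_reduction_kg: float
    iqr_reduction_kg: float

    def group_members(self, group: str) -> list[str]:
        return list(self.patients.index[self.patients["group"] == group])

    def stratum_members(self, stratum: str) -> list[str]:
        return list(self.patients.index[self.patients["stratum"] == stratum])


def remission_strata(design: StudyDesign) -> pd.Series:
    """Stratum per patient: R (remission), N-R (diabetic, no remission), N-DM."""
    pats = design.patients
    if "diabetic_at_baseline" not in pats.columns:
        raise FeatureTableError("patient records lack diabetes status")
    diabetic = pats["diabetic_at_baseline"].astype(bool)
    remission = pats.get("remission")
    out = pd.Series("N-DM", index=pats.index, name="stratum")
    out[diabetic] = "N-R"
    if remission is not None:
        out[diabetic & (remission == True)] = "R"  # noqa: E712 - nullable flag
    return out


def weight_groups(design: StudyDesign) -> OutcomeGroups:
    """Median split of the weight-loss ratio FU/PRE (ties go to LWL).

    Patients with a missing weight are excluded with a warning.  Also reports
    the cohort median and interquartile range of the absolute reduction
    (weight_pre - weight_fu, kg).
    """
    pats = design.patients
    for col in ("weight_pre", "weight_fu"):
        if col not in pats.columns:
            raise FeatureTableError(f"patient records lack {col}")
    usable = pats.dropna(subset=["weight_pre", "weight_fu"])
    dropped = set(pats.index) - set(usable.index)
    if dropped:
        warnings.warn(f"excluding patients with missing weights: {sorted(dropped)}")
    if (usable["weight_pre"] <= 0).any() or (usable["weight_fu"] <= 0).any():
        raise FeatureTableError("weights must be positive")
    ratio = usable["weight_fu"] / usable["weight_pre"]
    median_ratio = float(ratio.median())
    group = np.where(ratio < median_ratio, "HWL", "LWL")
    reduction = usable["weight_pre"] - usable["weight_fu"]
    q1, q3 = reduction.quantile([0.25, 0.75])
    if "diabetic_at_baseline" in pats.columns:
        stratum = remission_strata(design).reindex(usable.index)
    else:
        stratum = pd.Series(pd.NA, index=usable.index)
    frame = pd.DataFrame(
        {"weight_loss_ratio": ratio, "group": group, "stratum": stratum}
    )
    if (frame["group"] == "HWL").sum() == 0:
        warnings.warn("HWL group is empty (all ratios at or above the median)")
    return OutcomeGroups(
        patients=frame,
        median_ratio=median_ratio,
        median_reduction_kg=float(reduction.median()),
        iqr_reduction_kg=float(q3 - q1),
    )


def _patient_values(
    feature_id: str, table: FeatureTable, design: StudyDesign, timepoint: str
) -> pd.Series:
    serum = design.serum_frame()
    ids = serum.index[serum["timepoint"] == timepoint]
    vals = table.intensities.loc[feature_id, ids]
    vals.index = serum.loc[ids, "patient_id"]
    return vals.astype(float)


def group_metabolite_test(
    feature_id: str,
    table: FeatureTable,
    design: StudyDesign,
    grouping: pd.Series,
    mode: str = "decline",
    test: str = "welch",
) -> tuple[float, float]:
    """Compare one metabolite between two patient groups.

    ``grouping`` maps patient_id to exactly two group labels.  In 'decline'
    mode the compared quantity is d = log(FU/PRE) per patient; in 'fu_level'
    mode it is log(FU).  Returns (statistic, two-sided p).  Requires >= 3
    usable patients per group.
    """
    if test not in ("welch", "mannwhitney"):
        raise FeatureTableError("test must be 'welch' or 'mannwhitney'")
    labels = pd.Series(grouping).dropna()
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise FeatureTableError(f"grouping must have exactly 2 labels, got {groups}")
    fu = _patient_values(feature_id, table, design, "FU")
    if mode == "decline":
        pre = _patient_values(feature_id, table, design, "PRE")
        common = fu.index.intersection(pre.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            quantity = np.log(fu.loc[common] / pre.loc[common])
    elif mode == "fu_level":
        with np.errstate(divide="ignore", invalid="ignore"):
            quantity = np.log(fu)
    else:
        raise FeatureTableError("mode must be 'decline' or 'fu_level'")
    quantity = quantity.replace([np.inf, -np.inf], np.nan).dropna()

    samples = []
    for g in groups:
        members = labels.index[labels == g]
        vals = quantity.reindex(members.intersection(quantity.index)).dropna()
        if len(vals) < 3:
            raise FeatureTableError(
                f"group {g!r} has {len(vals)} usable patients (need >= 3)"
            )
        samples.append(vals.to_numpy())
    a, b = samples
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return 0.0, 1.0
    if test == "welch":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)


def outcome_tests(
    table: FeatureTable,
    design: StudyDesign,
    feature_ids,
    grouping: pd.Series,
    mode: str = "decline",
    test: str = "welch",
) -> pd.DataFrame:
    """Run group_metabolite_test over a feature list into one frame."""
    rows = []
    for fid in feature_ids:
        stat, p = group_metabolite_test(fid, table, design, grouping, mode=mode, test=test)
        rows.append({"feature_id": fid, "statistic": stat, "p": p})
    return pd.DataFrame(rows).set_index("feature_id")
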