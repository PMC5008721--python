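"""Trend-pattern classification and accurate-mass annotation.

Each selected feature's trajectory over the three sampling points (PRE,
POST, FU) is summarized by the median intensity per timepoint across
patients and classified into one of four trend patterns:

* increasing / decreasing — unidirectional change,
* V — drop shortly after surgery, recovery after one year,
* Lambda — rise shortly after surgery, decline after one year,

plus 'flat' when neither step moves.  A step (POST/PRE or FU/POST ratio of
medians) counts as a move only when it leaves the band ``[1 - eps, 1 + eps]``;
the small default tolerance (3%) absorbs sampling noise in the medians
without flattening genuine moves.  The mean-based ratio triple
(POST/PRE, FU/POST, FU/PRE) is reported alongside.

Annotation is by accurate mass only: a feature matches a reference entry
when the observed m/z is within a ppm tolerance of the theoretical adduct
m/z (monoisotopic mass +- a proton for [M+H]+ / [M-H]-) and the adduct
polarity matches the feature's ionization mode.  Confidence follows the
Metabolomics Standards Initiative: level 1 (identified) requires an expected
retention time within tolerance, otherwise level 2 (putatively annotated).
The bundled reference list covers 36 serum metabolites with a cardiovascular
risk (CVR) flag for the markers among them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .feature_table import (
    FeatureTable,
    StudyDesign,
    FeatureTableError,
    parse_formula_mass,
    PROTON_MASS,
)

__all__ = [
    "classify_trend",
    "timepoint_stats",
    "trend_table",
    "load_reference_list",
    "adduct_mz",
    "annotate_mz",
    "annotate_features",
    "TrendCall",
]

TIMEPOINT_ORDER = ("PRE", "POST", "FU")
ADDUCTS = {"[M+H]+": ("positive", +PROTON_MASS), "[M-H]-": ("negative", -PROTON_MASS)}


@dataclass
class TrendCall:
    feature_id: str
    medians: tuple[float, float, float]  # (PRE, POST, FU)
    means: tuple[float, float, float]
    ratios: tuple[float, float, float]  # mean POST/PRE, FU/POST, FU/PRE
    pattern: str


def classify_trend(m_pre: float, m_post: float, m_fu: float, epsilon: float = 0.03) -> str:
    """Classify a median trajectory into increasing/decreasing/V/Lambda/flat."""
    if m_pre <= 0 or m_post <= 0 or m_fu <= 0:
        raise FeatureTableError("classify_trend requires positive medians")
    if epsilon < 0:
        raise FeatureTableError("epsilon must be >= 0")

    def step(ratio: float) -> str:
        if ratio > 1.0 + epsilon:
            return "up"
        if ratio < 1.0 - epsilon:
            return "down"
        return "flat"

    s1, s2 = step(m_post / m_pre), step(m_fu / m_post)
    if (s1, s2) == ("down", "up"):
        return "V"
    if (s1, s2) == ("up", "down"):
        return "Lambda"
    if "up" in (s1, s2):
        return "increasing"
    if "down" in (s1, s2):
        return "decreasing"
    return "flat"


def timepoint_stats(
    feature_id: str, table: FeatureTable, design: StudyDesign
) -> tuple[tuple[float, float, float], tuple[float, float, float], tuple[float, float, float]]:
    """Medians, means and mean-based ratios of a feature across timepoints.

    Statistics are over all serum samples of each timepoint (non-missing
    values); ratios are mean POST/PRE, FU/POST and FU/PRE.
    """
    serum = design.serum_frame()
    row = table.intensities.loc[feature_id]
    medians, means = [], []
    for tp in TIMEPOINT_ORDER:
        vals = row[serum.index[serum["timepoint"] == tp]].dropna()
        if vals.empty:
            raise FeatureTableError(f"{feature_id}: no values at timepoint {tp}")
        medians.append(float(vals.median()))
        means.append(float(vals.mean()))
    ratios = (means[1] / means[0], means[2] / means[1], means[2] / means[0])
    return tuple(medians), tuple(means), ratios


def trend_table(
    table: FeatureTable,
    design: StudyDesign,
    feature_ids=None,
    epsilon: float = 0.03,
) -> pd.DataFrame:
    """Per-feature medians, mean ratios and trend pattern."""
    ids = list(feature_ids) if feature_ids is not None else table.feature_ids
    rows = []
    for fid in ids:
        medians, means, ratios = timepoint_stats(fid, table, design)
        pattern = classify_trend(*medians, epsilon=epsilon)
        rows.append(
            {
                "feature_id": fid,
                "median_pre": medians[0],
                "median_post": medians[1],
                "median_fu": medians[2],
                "ratio_pre_post": ratios[0],
                "ratio_post_fu": ratios[1],
                "ratio_pre_fu": ratios[2],
                "pattern": pattern,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# accurate-mass annotation
# ---------------------------------------------------------------------------

def load_reference_list(path=None) -> pd.DataFrame:
    """Reference metabolite list (bundled 36-metabolite serum panel by default).

    Columns: name, formula, adducts (semicolon-separated), expected_rt
    (minutes, may be missing), cvr_flag.  Each formula is validated.
    """
    if path is None:
        with resources.files("metadrift").joinpath(
            "data/reference_metabolites.csv"
        ).open() as handle:
            ref = pd.read_csv(handle)
    else:
        ref = pd.read_csv(path)
    required = {"name", "formula", "adducts"}
    missing = required - set(ref.columns)
    if missing:
        raise FeatureTableError(f"reference list missing columns: {sorted(missing)}")
    if "expected_rt" not in ref.columns:
        ref["expected_rt"] = np.nan
    if "cvr_flag" not in ref.columns:
        ref["cvr_flag"] = False
    ref["cvr_flag"] = ref["cvr_flag"].astype(bool)
    ref["monoisotopic_mass"] = ref["formula"].map(parse_formula_mass)
    bad = ref.loc[ref["monoisotopic_mass"] <= 0, "name"].tolist()
    if bad:
        raise FeatureTableError(f"non-positive monoisotopic mass for {bad}")
    return ref


def adduct_mz(monoisotopic_mass: float, adduct: str) -> float:
    """Theoretical m/z of a singly charged protonation/deprotonation adduct."""
    if adduct not in ADDUCTS:
        raise FeatureTableError(f"unsupported adduct {adduct!r}")
    return monoisotopic_mass + ADDUCTS[adduct][1]


def annotate_mz(
    mz_obs: float,
    ion_mode: str,
    reference: pd.DataFrame,
    rt_obs: float | None = None,
    ppm_tol: float = 10.0,
    rt_tol: float = 0.5,
) -> list[dict]:
    """Accurate-mass candidates for one observed m/z.

    A candidate is reported iff |mz_obs - mz_theo| / mz_theo * 1e6 <= ppm_tol
    and the adduct polarity matches the ionization mode.  Level 1 requires an
    expected RT within rt_tol minutes; otherwise level 2.
    """
    candidates = []
    for _, entry in reference.iterrows():
        for adduct in str(entry["adducts"]).split(";"):
            adduct = adduct.strip()
            if not adduct:
                continue
            polarity, _ = ADDUCTS.get(adduct, (None, None))
            if polarity is None:
                raise FeatureTableError(f"unsupported adduct {adduct!r} in reference list")
            if polarity != ion_mode:
                continue
            mz_theo = adduct_mz(entry["monoisotopic_mass"], adduct)
            ppm = (mz_obs - mz_theo) / mz_theo * 1e6
            if abs(ppm) > ppm_tol:
                continue
            rt_err = None
            level = 2
            if pd.notna(entry["expected_rt"]) and rt_obs is not None:
                rt_err = rt_obs - float(entry["expected_rt"])
                if abs(rt_err) <= rt_tol:
                    level = 1
            candidates.append(
                {
                    "name": entry["name"],
                    "adduct": adduct,
                    "mz_theo": mz_theo,
                    "ppm_error": ppm,
                    "rt_error": rt_err,
                    "level": level,
                    "cvr_flag": bool(entry["cvr_flag"]),
                }
            )
    candidates.sort(key=lambda c: abs(c["ppm_error"]))
    return candidates


def annotate_features(
    table: FeatureTable,
    reference: pd.DataFrame,
    feature_ids=None,
    ppm_tol: float = 10.0,
    rt_tol: float = 0.5,
) -> pd.DataFrame:
    """Best accurate-mass candidate per feature ('unannotated' when none)."""
    ids = list(feature_ids) if feature_ids is not None else table.feature_ids
    rows = []
    for fid in ids:
        meta = table.features.loc[fid]
        cands = annotate_mz(
            float(meta["mz_med"]),
            str(meta["ion_mode"]),
            reference,
            rt_obs=float(meta["rt_med"]),
            ppm_tol=ppm_tol,
            rt_tol=rt_tol,
        )
        if cands:
            best = cands[0]
            rows.append({"feature_id": fid, **best,
                         "n_candidates": len(cands)})
        else:
            rows.append(
                {
                    "feature_id": fid,
                    "name": None,
                    "adduct": None,
                    "mz_theo": np.nan,
                    "ppm_error": np.nan,
                    "rt_error": None,
                    "level": "unannotated",
                    "cvr_flag": False,
                    "n_candidates": 0,
                }
            )
    return pd.DataFrame(rows).set_index("feature_id")
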