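"""Data model and I/O for LC-HRMS feature matrices, sample sheets and reference lists.

A *metabolic feature* is a unique (median m/z, median retention time, ionization
mode) triple produced by peak grouping; its per-injection peak areas (AUCs) form
one row of the feature table.  Injections are serum samples, pooled quality
controls (QCs) or solvent blanks (BLs), ordered by their position in the run
sequence.  All file formats are plain CSV (UTF-8, '.' decimal); missing
intensities are empty cells, never zeros — a zero is a legitimate AUC floor
while missingness feeds the detection filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTableError",
    "FeatureTable",
    "StudyDesign",
    "read_feature_table",
    "write_feature_table",
    "write_sample_sheet",
    "read_sample_sheet",
    "parse_formula_mass",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
]

SAMPLE_TYPES = ("serum", "qc", "blank")
TIMEPOINTS = ("PRE", "POST", "FU")
ION_MODES = ("positive", "negative")

#: monoisotopic atomic masses (Da) for the CHNOPS elements
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: mass of a proton (Da), used for [M+H]+ / [M-H]- adduct arithmetic
PROTON_MASS = 1.00727646

_FEATURE_COLS = ["feature_id", "mz_med", "rt_med", "ion_mode"]
_INJECTION_COLS = ["injection_id", "order", "sample_type", "patient_id", "timepoint"]
_PATIENT_COLS = [
    "center",
    "weight_pre",
    "weight_fu",
    "diabetic_at_baseline",
    "remission",
    "hba1c_pre",
    "hba1c_fu",
]


class FeatureTableError(ValueError):
    """Structured parse/validation error for feature tables and sample sheets."""


@dataclass
class FeatureTable:
    """Intensity matrix plus per-feature metadata.

    Attributes
    ----------
    features : pd.DataFrame
        Indexed by ``feature_id`` with columns ``mz_med`` (Th), ``rt_med``
        (minutes) and ``ion_mode`` ('positive'/'negative').
    intensities : pd.DataFrame
        Features x injections matrix of non-negative AUCs; NaN marks a
        missing (undetected) value.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def injections(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset(self, feature_ids) -> "FeatureTable":
        """Return a new table restricted to ``feature_ids`` (order preserved)."""
        ids = [f for f in self.feature_ids if f in set(feature_ids)]
        return FeatureTable(self.features.loc[ids].copy(), self.intensities.loc[ids].copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.intensities.copy())

    def validate(self) -> None:
        if self.features.index.duplicated().any():
            dup = self.features.index[self.features.index.duplicated()][0]
            raise FeatureTableError(f"duplicate feature_id: {dup!r}")
        if not self.features.index.equals(self.intensities.index):
            raise FeatureTableError("feature metadata and intensity matrix rows disagree")
        if pd.Index(self.intensities.columns).duplicated().any():
            raise FeatureTableError("duplicate injection_id in intensity matrix")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FeatureTableError("negative intensity values")
        if (self.features["mz_med"] <= 0).any():
            raise FeatureTableError("mz_med must be positive")
        if (self.features["rt_med"] < 0).any():
            raise FeatureTableError("rt_med must be non-negative")
        bad = set(self.features["ion_mode"]) - set(ION_MODES)
        if bad:
            raise FeatureTableError(f"unknown ion_mode values: {sorted(bad)}")


@dataclass
class StudyDesign:
    """Per-injection run metadata plus per-patient clinical covariates.

    ``injections`` is indexed by ``injection_id`` with columns ``order``
    (1-based position in the run sequence), ``sample_type`` in
    {'serum','qc','blank'}, and, for serum rows only, ``patient_id`` and
    ``timepoint`` in {'PRE','POST','FU'}.  ``patients`` is indexed by
    ``patient_id``; clinical columns may be absent for purely technical runs.
    """

    injections: pd.DataFrame
    patients: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        inj = self.injections
        if inj.index.duplicated().any():
            dup = inj.index[inj.index.duplicated()][0]
            raise FeatureTableError(f"duplicate injection_id: {dup!r}")
        if inj["order"].duplicated().any():
            dup = int(inj["order"][inj["order"].duplicated()].iloc[0])
            raise FeatureTableError(f"duplicate injection order: {dup}")
        if (inj["order"] < 1).any():
            raise FeatureTableError("injection order must be a positive integer")
        bad = set(inj["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise FeatureTableError(f"unknown sample_type values: {sorted(bad)}")
        serum = inj[inj["sample_type"] == "serum"]
        if serum["patient_id"].isna().any() or serum["timepoint"].isna().any():
            off = serum.index[serum["patient_id"].isna() | serum["timepoint"].isna()][0]
            raise FeatureTableError(
                f"serum injection {off!r} lacks patient_id and/or timepoint"
            )
        bad_tp = set(serum["timepoint"].dropna()) - set(TIMEPOINTS)
        if bad_tp:
            raise FeatureTableError(f"unknown timepoint values: {sorted(bad_tp)}")

    # -- convenience selections ------------------------------------------
    def ids_of_type(self, sample_type: str) -> list[str]:
        return list(self.injections.index[self.injections["sample_type"] == sample_type])

    @property
    def qc_ids(self) -> list[str]:
        return self.ids_of_type("qc")

    @property
    def blank_ids(self) -> list[str]:
        return self.ids_of_type("blank")

    @property
    def serum_ids(self) -> list[str]:
        return self.ids_of_type("serum")

    def orders(self, injection_ids) -> np.ndarray:
        return self.injections.loc[list(injection_ids), "order"].to_numpy(dtype=float)

    @property
    def run_range(self) -> tuple[float, float]:
        o = self.injections["order"]
        return float(o.min()), float(o.max())

    def serum_frame(self) -> pd.DataFrame:
        """Serum injections with patient_id/timepoint, ordered by run order."""
        s = self.injections[self.injections["sample_type"] == "serum"]
        return s.sort_values("order")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, sample_sheet_path) -> tuple[FeatureTable, StudyDesign]:
    """Read a feature-table CSV and its sample sheet; cross-validate them.

    The feature CSV has columns ``feature_id, mz_med, rt_med, ion_mode``
    followed by one column per injection.  Every intensity column must have a
    matching row in the sample sheet.
    """
    raw = pd.read_csv(path, dtype={"feature_id": str})
    missing = [c for c in _FEATURE_COLS if c not in raw.columns]
    if missing:
        raise FeatureTableError(f"feature table missing columns: {missing}")
    features = raw[_FEATURE_COLS].set_index("feature_id")
    inten = raw.drop(columns=_FEATURE_COLS[1:]).set_index("feature_id").astype(float)
    table = FeatureTable(features, inten)
    design = read_sample_sheet(sample_sheet_path)
    unknown = [c for c in table.injections if c not in design.injections.index]
    if unknown:
        raise FeatureTableError(
            f"intensity columns without a sample-sheet record: {unknown[:5]}"
        )
    return table, design


def read_sample_sheet(path) -> StudyDesign:
    sheet = pd.read_csv(path, dtype={"injection_id": str, "patient_id": str})
    missing = [c for c in _INJECTION_COLS if c not in sheet.columns]
    if missing:
        raise FeatureTableError(f"sample sheet missing columns: {missing}")
    inj = sheet[_INJECTION_COLS].set_index("injection_id")
    inj["order"] = inj["order"].astype(int)
    patient_cols = [c for c in _PATIENT_COLS if c in sheet.columns]
    patients = pd.DataFrame()
    if patient_cols and sheet["patient_id"].notna().any():
        patients = (
            sheet.dropna(subset=["patient_id"])
            .drop_duplicates("patient_id")
            .set_index("patient_id")[patient_cols]
        )
    return StudyDesign(inj, patients)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.features.reset_index().merge(
        table.intensities.reset_index(), on="feature_id"
    )
    out.to_csv(path, index=False)


def write_sample_sheet(design: StudyDesign, path) -> None:
    out = design.injections.reset_index()
    if len(design.patients):
        out = out.merge(
            design.patients.reset_index(), on="patient_id", how="left"
        )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a CHNOPS elemental formula like ``'C3H9NO'``."""
    if not formula or not formula.strip():
        raise FeatureTableError("empty formula")
    formula = formula.strip()
    pos = 0
    mass = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FeatureTableError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        element, count = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise FeatureTableError(f"unknown element symbol {element!r} in {formula!r}")
        mass += MONOISOTOPIC_MASS[element] * (int(count) if count else 1)
    if pos != len(formula):
        raise FeatureTableError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return mass
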