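"""Synthetic LC-HRMS feature tables with known ground truth.

Emulates the study design the downstream statistics assume: 44 patients
sampled at three timepoints (PRE / POST / FU) giving 132 serum injections,
interleaved in a single batch with solvent blanks and pooled QCs — a BL+QC
pair opens the run, another follows every third serum sample, and a final
pair closes it (46 blanks + 46 QCs at the default design).  Serum order is
randomized.

The signal model for feature *f* in injection *i* is multiplicative:

    intensity = baseline_f * drift_f(order_i) * pattern_f(timepoint, patient) * exp(eps)

with ``eps ~ Normal(0, sigma)``, ``sigma = sqrt(ln(1 + noise_cv^2))``
(log-normal noise keeps intensities positive and CV-stable).  Drift is a
smooth per-feature mixture of 2-4 low-frequency cosine components drawn from
a small pool shared across features (instrument sensitivity drift), scaled
so the curve stays within ``[1 - a, 1 + a]`` where the amplitude ``a`` is
drawn per feature from ``drift_amplitude_range``; with the default range the
raw pooled-QC CV lands near the 0.2 observed on real runs.  QCs and blanks
carry no pattern term; blanks are near-zero except for *system peaks*
(measurement-system impurities) where blank ~ QC level.  *Poorly detected*
features are missing at random in over half of all injections.  Differential
features follow one of four trend patterns (increasing, decreasing, V,
Lambda) with a configurable maximum |log2 fold change|, modulated per patient
by a median-1 log-normal random effect (individual responses).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, StudyDesign, FeatureTableError

__all__ = [
    "DifferentialSpec",
    "SimulationConfig",
    "GroundTruth",
    "build_injection_sequence",
    "simulate",
]

PATTERNS = ("increasing", "decreasing", "V", "Lambda")

#: log2 multipliers at (PRE, POST, FU) per unit effect size
_PATTERN_SHAPES = {
    "increasing": (0.0, 0.5, 1.0),
    "decreasing": (0.0, -0.5, -1.0),
    "V": (0.0, -1.0, 0.0),
    "Lambda": (0.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class DifferentialSpec:
    """A block of truly differential features sharing one trend pattern."""

    pattern: str
    n_features: int
    effect: float  # max |log2 fold change| relative to PRE

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise FeatureTableError(f"unknown pattern {self.pattern!r}")
        if self.effect <= 0:
            raise FeatureTableError("effect size must be > 0")
        if self.n_features < 0:
            raise FeatureTableError("n_features must be >= 0")


def _default_differential() -> tuple[DifferentialSpec, ...]:
    return tuple(DifferentialSpec(p, 40, 1.0) for p in PATTERNS)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    seed: int = 0
    n_patients: int = 44
    n_features: int = 923
    block_size: int = 3  # serum samples per interleaved BL+QC pair
    drift_amplitude_range: tuple[float, float] = (0.15, 0.45)
    noise_cv: float = 0.08
    frac_system_peaks: float = 0.05
    frac_poorly_detected: float = 0.05
    differential_spec: tuple[DifferentialSpec, ...] = field(
        default_factory=_default_differential
    )
    patient_effect_cv: float = 0.2
    blank_level: float = 0.01  # blank/baseline ratio for non-system-peak features
    poor_missing_rate: float = 0.6  # per-injection missingness of poorly detected features

    def __post_init__(self):
        if isinstance(self.differential_spec, (list, tuple)):
            self.differential_spec = tuple(
                d if isinstance(d, DifferentialSpec) else DifferentialSpec(**d)
                for d in self.differential_spec
            )
        self.drift_amplitude_range = tuple(float(v) for v in self.drift_amplitude_range)
        for frac in (self.frac_system_peaks, self.frac_poorly_detected):
            if not 0.0 <= frac <= 1.0:
                raise FeatureTableError("fractions must lie in [0, 1]")
        if self.block_size < 1:
            raise FeatureTableError("block_size must be >= 1")
        lo, hi = self.drift_amplitude_range
        if not 0.0 <= lo <= hi < 1.0:
            raise FeatureTableError("drift_amplitude_range must satisfy 0 <= lo <= hi < 1")
        if self.noise_cv < 0 or self.patient_effect_cv < 0:
            raise FeatureTableError("coefficients of variation must be >= 0")
        n_special = self.n_system + self.n_poor + self.n_differential
        if n_special > self.n_features:
            raise FeatureTableError(
                f"differential/system/poor features ({n_special}) exceed n_features "
                f"({self.n_features})"
            )

    @property
    def n_system(self) -> int:
        return int(round(self.frac_system_peaks * self.n_features))

    @property
    def n_poor(self) -> int:
        return int(round(self.frac_poorly_detected * self.n_features))

    @property
    def n_differential(self) -> int:
        return sum(d.n_features for d in self.differential_spec)


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline has to recover.

    ``features``: per-feature baseline intensity, role flags, true pattern
    (None for null features), effect size, and analytic per-timepoint medians.
    ``drift``: features x injections matrix of drift multipliers.
    ``patients``: per-patient true weight-loss ratio and remission flag.
    """

    features: pd.DataFrame
    drift: pd.DataFrame
    patients: pd.DataFrame

    @property
    def system_peak_ids(self) -> list[str]:
        return list(self.features.index[self.features["is_system_peak"]])

    @property
    def poorly_detected_ids(self) -> list[str]:
        return list(self.features.index[self.features["is_poorly_detected"]])

    @property
    def differential_ids(self) -> list[str]:
        return list(self.features.index[self.features["pattern"].notna()])

    def ids_with_pattern(self, pattern: str) -> list[str]:
        return list(self.features.index[self.features["pattern"] == pattern])


def build_injection_sequence(
    n_patients: int, block_size: int = 3, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Ordered injection records for one batch.

    Opens with a BL+QC pair, repeats ``[block_size serum, BL, QC]``, and closes
    with one final BL+QC pair, so that 44 patients x 3 timepoints at block
    size 3 give exactly 132 serum, 46 blank and 46 QC injections.  Serum slots
    are a seeded random permutation of all (patient, timepoint) pairs, so run
    order is independent of timepoint.
    """
    if n_patients < 1:
        raise FeatureTableError("n_patients must be >= 1")
    rng = np.random.default_rng(rng)
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    slots = [(p, tp) for p in patients for tp in ("PRE", "POST", "FU")]
    perm = rng.permutation(len(slots))
    slots = [slots[i] for i in perm]

    rows: list[tuple] = []
    counters = {"blank": 0, "qc": 0, "serum": 0}

    def pair():
        counters["blank"] += 1
        rows.append((f"B{counters['blank']:03d}", "blank", np.nan, np.nan))
        counters["qc"] += 1
        rows.append((f"Q{counters['qc']:03d}", "qc", np.nan, np.nan))

    pair()
    for start in range(0, len(slots), block_size):
        for patient, tp in slots[start : start + block_size]:
            counters["serum"] += 1
            rows.append((f"S{counters['serum']:03d}", "serum", patient, tp))
        pair()
    pair()

    frame = pd.DataFrame(rows, columns=["injection_id", "sample_type", "patient_id", "timepoint"])
    frame.insert(1, "order", np.arange(1, len(frame) + 1))
    return frame.set_index("injection_id")


def _simulate_patients(config: SimulationConfig, patients: list[str], rng) -> pd.DataFrame:
    n = len(patients)
    center = rng.choice(["A", "B"], size=n, p=[25 / 44, 19 / 44])
    weight_pre = np.clip(rng.normal(126.4, 19.5, n), 75.0, 200.0)
    ratio = np.clip(rng.normal(0.70, 0.06, n), 0.50, 0.92)
    weight_fu = weight_pre * ratio
    n_diab = int(round(24 / 44 * n))
    diabetic = np.zeros(n, bool)
    diabetic[rng.choice(n, size=n_diab, replace=False)] = True
    remission = np.full(n, np.nan, dtype=object)
    diab_idx = np.flatnonzero(diabetic)
    n_rem = int(round(9 / 24 * n_diab))
    rem_idx = rng.choice(diab_idx, size=n_rem, replace=False) if n_diab else np.array([], int)
    for i in diab_idx:
        remission[i] = bool(i in set(rem_idx))
    hba1c_pre = np.where(diabetic, rng.normal(7.4, 1.0, n), rng.normal(5.6, 0.4, n))
    hba1c_fu = np.where(
        [r is True for r in remission],
        rng.uniform(5.0, 6.4, n),
        np.where(diabetic, rng.normal(7.0, 0.8, n), rng.normal(5.5, 0.4, n)),
    )
    return pd.DataFrame(
        {
            "center": center,
            "weight_pre": np.round(weight_pre, 1),
            "weight_fu": np.round(weight_fu, 1),
            "diabetic_at_baseline": diabetic,
            "remission": remission,
            "hba1c_pre": np.round(hba1c_pre, 2),
            "hba1c_fu": np.round(hba1c_fu, 2),
        },
        index=pd.Index(patients, name="patient_id"),
    )


def _drift_profiles(config: SimulationConfig, orders: np.ndarray, rng) -> np.ndarray:
    """Smooth multiplicative drift curves, one row per feature.

    Each curve is a 2-4 term mixture drawn from a pool of low-frequency cosine
    components shared across features, rescaled to span exactly
    ``[1 - a, 1 + a]`` with amplitude ``a ~ U(drift_amplitude_range)``.
    """
    n_feat = config.n_features
    span = orders.max() - orders.min() if len(orders) > 1 else 1.0
    t = (orders - orders.min()) / span
    n_pool = 4
    freqs = rng.uniform(0.5, 2.0, n_pool)
    phases = rng.uniform(0.0, 2 * np.pi, n_pool)
    pool = np.cos(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])

    weights = rng.normal(size=(n_feat, n_pool))
    n_terms = rng.integers(2, 5, size=n_feat)
    for j in range(n_feat):  # zero out pool components beyond this feature's term count
        drop = rng.permutation(n_pool)[n_terms[j] :]
        weights[j, drop] = 0.0
    curves = weights @ pool
    lo = curves.min(axis=1, keepdims=True)
    hi = curves.max(axis=1, keepdims=True)
    half = np.maximum((hi - lo) / 2.0, 1e-12)
    normalized = (curves - (lo + hi) / 2.0) / half  # spans [-1, 1]
    amp = rng.uniform(*config.drift_amplitude_range, size=(n_feat, 1))
    if config.drift_amplitude_range == (0.0, 0.0):
        return np.ones_like(curves)
    return 1.0 + amp * normalized


def simulate(config: SimulationConfig) -> tuple[FeatureTable, StudyDesign, GroundTruth]:
    """Generate a feature table, study design and full ground truth.

    Deterministic given ``config`` (all randomness flows from ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    injections = build_injection_sequence(config.n_patients, config.block_size, rng)
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    patient_frame = _simulate_patients(config, patients, rng)
    design = StudyDesign(injections, patient_frame)

    n_feat = config.n_features
    feature_ids = [f"F{i + 1:04d}" for i in range(n_feat)]
    mz = np.round(rng.uniform(70.0, 1050.0, n_feat), 4)
    rt = np.round(rng.uniform(1.0, 20.0, n_feat), 2)
    ion_mode = rng.choice(["positive", "negative"], size=n_feat)
    baseline = 10.0 ** rng.uniform(4.0, 7.0, n_feat)

    # assign roles: system peaks, poorly detected, then differential blocks
    perm = rng.permutation(n_feat)
    cursor = 0
    system_idx = perm[cursor : cursor + config.n_system]
    cursor += config.n_system
    poor_idx = perm[cursor : cursor + config.n_poor]
    cursor += config.n_poor
    pattern = np.full(n_feat, None, dtype=object)
    effect = np.zeros(n_feat)
    for spec in config.differential_spec:
        idx = perm[cursor : cursor + spec.n_features]
        cursor += spec.n_features
        pattern[idx] = spec.pattern
        effect[idx] = spec.effect

    orders = injections["order"].to_numpy(dtype=float)
    drift = _drift_profiles(config, orders, rng)

    # log2 multiplier per feature per timepoint
    log2_mult = np.zeros((n_feat, 3))
    for j in range(n_feat):
        if pattern[j] is not None:
            shape = _PATTERN_SHAPES[pattern[j]]
            log2_mult[j] = np.array(shape) * effect[j]

    # per-patient median-1 log-normal random effect on the pattern exponent
    if config.patient_effect_cv > 0:
        sigma_g = np.sqrt(np.log1p(config.patient_effect_cv**2))
        g = rng.lognormal(0.0, sigma_g, size=(n_feat, config.n_patients))
    else:
        g = np.ones((n_feat, config.n_patients))

    sigma = np.sqrt(np.log1p(config.noise_cv**2))
    noise = (
        np.exp(rng.normal(0.0, sigma, size=(n_feat, len(injections))))
        if sigma > 0
        else np.ones((n_feat, len(injections)))
    )

    tp_index = {"PRE": 0, "POST": 1, "FU": 2}
    patient_pos = {p: i for i, p in enumerate(patients)}
    matrix = baseline[:, None] * drift * noise
    sample_type = injections["sample_type"].to_numpy()
    is_system = np.zeros(n_feat, bool)
    is_system[system_idx] = True
    blank_scale = np.where(is_system, 1.0, config.blank_level)
    for col, (stype, pid, tp) in enumerate(
        zip(sample_type, injections["patient_id"], injections["timepoint"])
    ):
        if stype == "serum":
            expo = log2_mult[:, tp_index[tp]] * g[:, patient_pos[pid]]
            matrix[:, col] *= np.exp2(expo)
        elif stype == "blank":
            matrix[:, col] *= blank_scale

    # poorly detected features: missing at random in >= half of all injections
    if len(poor_idx):
        miss = rng.random((len(poor_idx), len(injections))) < config.poor_missing_rate
        sub = matrix[poor_idx]
        sub[miss] = np.nan
        matrix[poor_idx] = sub

    features = pd.DataFrame(
        {"mz_med": mz, "rt_med": rt, "ion_mode": ion_mode},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    table = FeatureTable(
        features, pd.DataFrame(matrix, index=features.index, columns=injections.index)
    )

    medians = baseline[:, None] * np.exp2(log2_mult)
    truth_features = pd.DataFrame(
        {
            "baseline": baseline,
            "is_system_peak": is_system,
            "is_poorly_detected": np.isin(np.arange(n_feat), poor_idx),
            "pattern": pattern,
            "effect": effect,
            "median_pre": medians[:, 0],
            "median_post": medians[:, 1],
            "median_fu": medians[:, 2],
        },
        index=features.index,
    )
    truth_patients = pd.DataFrame(
        {
            "weight_loss_ratio": patient_frame["weight_fu"] / patient_frame["weight_pre"],
            "remission": patient_frame["remission"],
        }
    )
    truth = GroundTruth(
        truth_features,
        pd.DataFrame(drift, index=features.index, columns=injections.index),
        truth_patients,
    )
    return table, design, truth
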