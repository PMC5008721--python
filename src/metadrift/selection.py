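"""Feature selection: supervised Random Forests + paired t-tests per contrast.

Two time contrasts are analyzed — PRE vs POST (short-term) and PRE vs FU
(long-term).  Within a contrast a feature is selected when *both* criteria
bind: its out-of-bag permutation importance (mean decrease accuracy, MDA) in
a supervised Random Forest of the two timepoints is positive, and its
Benjamini-Hochberg-adjusted paired-t p-value is below alpha (0.01 by
default).  The final set is the intersection of the two contrasts' selected
sets: features carrying both short- and long-term information.  Intensities
are natural-log transformed by default (multiplicative noise), and only
serum samples enter the statistics — QCs and blanks never do.

Classical metric MDS of the forest's proximity matrix (fraction of trees in
which two samples share a terminal node) provides the visual check that
samples separate by timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable, StudyDesign, FeatureTableError

__all__ = [
    "paired_t",
    "bh_adjust",
    "train_rf",
    "RandomForestResult",
    "ContrastResult",
    "select_contrast",
    "intersect_contrasts",
    "rf_mds",
    "unsupervised_rf",
    "CONTRASTS",
]

CONTRASTS = {"PRE_POST": ("PRE", "POST"), "PRE_FU": ("PRE", "FU")}


# ---------------------------------------------------------------------------
# univariate statistics
# ---------------------------------------------------------------------------

def paired_t(pre, post) -> tuple[float, float]:
    """Paired t-test on differences d = post - pre (two-sided).

    Pairs with any missing value are dropped; at least 3 complete pairs are
    required.  Degenerate cases: sd(d)=0 with mean(d)=0 gives (0, 1) by
    convention; sd(d)=0 with mean(d)!=0 gives (+-inf, 0) as the limit.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise FeatureTableError("paired_t requires equal-length vectors")
    keep = ~(np.isnan(pre) | np.isnan(post))
    d = post[keep] - pre[keep]
    n = d.size
    if n < 3:
        raise FeatureTableError(f"paired_t requires >= 3 complete pairs, got {n}")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise FeatureTableError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# random forests
# ---------------------------------------------------------------------------

@dataclass
class RandomForestResult:
    oob_error: float
    mda: pd.Series  # out-of-bag permutation importance per feature
    proximity: np.ndarray  # samples x samples, fraction of shared terminal nodes
    classes: np.ndarray
    model: RandomForestClassifier


def train_rf(
    X: pd.DataFrame,
    labels,
    n_trees: int = 300,
    mtry: int = 30,
    seed: int = 0,
) -> RandomForestResult:
    """Bagged CART ensemble with OOB error, OOB permutation MDA and proximity.

    MDA of feature f is the mean over trees of (OOB accuracy - OOB accuracy
    with f permuted among the tree's OOB rows); features a tree never splits
    on contribute exactly zero for that tree.  Proximity(i, j) is the
    fraction of trees in which samples i and j land in the same leaf.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise FeatureTableError("train_rf requires at least 2 classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise FeatureTableError("train_rf requires >= 2 samples per class")
    values = np.asarray(X, float)
    if np.isnan(values).any():
        raise FeatureTableError("train_rf requires a complete matrix (impute first)")
    n_samples, n_features = values.shape
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(mtry, n_features),
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when some rows lack OOB votes
        model.fit(values, y)
    oob_error = 1.0 - float(model.oob_score_)

    n_bootstrap = _get_n_samples_bootstrap(n_samples, model.max_samples, None)
    perm_rng = np.random.default_rng(int(seed))
    mda = np.zeros(n_features)
    # trees predict encoded class indices, so compare against the encoded labels
    y_encoded = np.searchsorted(model.classes_, y).astype(float)
    for tree in model.estimators_:
        oob_idx = _generate_unsampled_indices(tree.random_state, n_samples, n_bootstrap, None)
        if oob_idx.size == 0:
            continue
        x_oob = values[oob_idx]
        y_oob = y_encoded[oob_idx]
        acc = np.mean(tree.predict(x_oob) == y_oob)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            x_perm = x_oob.copy()
            x_perm[:, f] = perm_rng.permutation(x_perm[:, f])
            acc_perm = np.mean(tree.predict(x_perm) == y_oob)
            mda[f] += acc - acc_perm
    mda /= n_trees

    leaves = model.apply(values)  # samples x trees
    proximity = np.zeros((n_samples, n_samples))
    for t in range(leaves.shape[1]):
        col = leaves[:, t]
        proximity += col[:, None] == col[None, :]
    proximity /= leaves.shape[1]

    index = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(n_features)
    return RandomForestResult(
        oob_error=oob_error,
        mda=pd.Series(mda, index=index, name="mda"),
        proximity=proximity,
        classes=classes,
        model=model,
    )


def rf_mds(proximity: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical metric MDS of the dissimilarity 1 - proximity.

    Double-centers the squared dissimilarities and returns the top-k
    eigenvectors scaled by sqrt(eigenvalue); if fewer than k eigenvalues are
    positive the available dimensions are returned with a warning.
    """
    proximity = np.asarray(proximity, float)
    if proximity.ndim != 2 or proximity.shape[0] != proximity.shape[1]:
        raise FeatureTableError("proximity must be a square matrix")
    if not np.allclose(proximity, proximity.T, atol=1e-10):
        raise FeatureTableError("proximity must be symmetric")
    d = 1.0 - proximity
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    avail = int(min(k, positive.sum()))
    if avail < k:
        warnings.warn(f"only {avail} positive eigenvalues; returning {avail} dimensions")
    return eigvec[:, :avail] * np.sqrt(eigval[:avail])


def unsupervised_rf(
    X: pd.DataFrame, n_trees: int = 300, mtry: int = 30, seed: int = 0
) -> RandomForestResult:
    """Unsupervised forest: classify real rows against column-permuted copies.

    The standard construction — a synthetic class is made by permuting each
    feature independently (destroying the joint structure), and the forest
    proximity among the real rows captures unsupervised similarity.  The
    returned proximity is restricted to the real samples.
    """
    values = np.asarray(X, float)
    rng = np.random.default_rng(int(seed))
    synthetic = np.column_stack(
        [rng.permutation(values[:, f]) for f in range(values.shape[1])]
    )
    stacked = np.vstack([values, synthetic])
    labels = np.array(["real"] * len(values) + ["synthetic"] * len(values))
    frame = pd.DataFrame(
        stacked, columns=X.columns if isinstance(X, pd.DataFrame) else None
    )
    result = train_rf(frame, labels, n_trees=n_trees, mtry=mtry, seed=seed)
    result.proximity = result.proximity[: len(values), : len(values)]
    return result


# ---------------------------------------------------------------------------
# per-contrast selection
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """Per-feature statistics and the selected set for one time contrast."""

    contrast: str
    stats: pd.DataFrame  # columns: t, p, p_adj, mda, selected
    oob_error: float
    proximity: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray
    alpha: float

    @property
    def selected_ids(self) -> list[str]:
        return list(self.stats.index[self.stats["selected"]])


def _contrast_matrix(
    table: FeatureTable, design: StudyDesign, timepoints: tuple[str, str], log_transform: bool
):
    """Samples x features matrix for the two timepoints, plus pairing info."""
    serum = design.serum_frame()
    mask = serum["timepoint"].isin(timepoints)
    serum = serum[mask]
    sample_ids = list(serum.index)
    if not sample_ids:
        raise FeatureTableError(f"no serum samples for timepoints {timepoints}")
    x = table.intensities[sample_ids].T.astype(float)  # samples x features
    if log_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.log(x.where(x > 0))
    return x, serum


def select_contrast(
    table: FeatureTable,
    design: StudyDesign,
    contrast: str,
    alpha: float = 0.01,
    n_trees: int = 300,
    mtry: int = 30,
    seed: int = 0,
    combine: str = "and",
    log_transform: bool = True,
) -> ContrastResult:
    """Run the RF + paired-t selection for one contrast (PRE_POST or PRE_FU).

    Expects a drift-corrected, RSD-filtered table.  Missing values are
    dropped pairwise for the t-tests and imputed with half the feature's
    minimum observed value for the forest.
    """
    if contrast not in CONTRASTS:
        raise FeatureTableError(f"unknown contrast {contrast!r}")
    if combine not in ("and", "or"):
        raise FeatureTableError("combine must be 'and' or 'or'")
    tp_a, tp_b = CONTRASTS[contrast]
    x, serum = _contrast_matrix(table, design, (tp_a, tp_b), log_transform)

    # paired t per feature on per-patient values
    t_stats = np.full(table.n_features, np.nan)
    p_vals = np.ones(table.n_features)
    pivot_a = x[serum["timepoint"] == tp_a].set_axis(
        serum.loc[serum["timepoint"] == tp_a, "patient_id"], axis=0
    )
    pivot_b = x[serum["timepoint"] == tp_b].set_axis(
        serum.loc[serum["timepoint"] == tp_b, "patient_id"], axis=0
    )
    common = pivot_a.index.intersection(pivot_b.index)
    a = pivot_a.loc[common].to_numpy(float)
    b = pivot_b.loc[common].to_numpy(float)
    for jf in range(table.n_features):
        try:
            t_stats[jf], p_vals[jf] = paired_t(a[:, jf], b[:, jf])
        except FeatureTableError:  # too few complete pairs: untestable feature
            t_stats[jf], p_vals[jf] = np.nan, 1.0
    p_adj = bh_adjust(p_vals)

    # random forest on imputed matrix: half the minimum observed value
    fill = x.min(axis=0, skipna=True)
    fill = (fill - np.log(2.0)) if log_transform else (fill / 2.0)
    x_rf = x.fillna(fill.fillna(0.0))
    labels = serum["timepoint"].to_numpy()
    rf = train_rf(x_rf, labels, n_trees=n_trees, mtry=mtry, seed=seed)

    mda = rf.mda.to_numpy()
    if combine == "and":
        selected = (mda > 0) & (p_adj < alpha)
    else:
        selected = (mda > 0) | (p_adj < alpha)
    stats_frame = pd.DataFrame(
        {"t": t_stats, "p": p_vals, "p_adj": p_adj, "mda": mda, "selected": selected},
        index=table.features.index,
    )
    return ContrastResult(
        contrast=contrast,
        stats=stats_frame,
        oob_error=rf.oob_error,
        proximity=rf.proximity,
        sample_ids=list(serum.index),
        labels=labels,
        alpha=alpha,
    )


def intersect_contrasts(result_a: ContrastResult, result_b: ContrastResult) -> list[str]:
    """Features selected in both contrasts (short- AND long-term change)."""
    final = sorted(set(result_a.selected_ids) & set(result_b.selected_ids))
    if not final and (result_a.selected_ids or result_b.selected_ids):
        warnings.warn("contrast selections are disjoint; final set is empty")
    return final
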