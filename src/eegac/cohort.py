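"""Cohort comparison machinery.

Three pieces:

* summed band intensity ("spectral intensity analysis", SIA) with the
  per-subject relative normalization that cancels electrode-conductance
  scaling;
* paired significance testing per (lead, filter) cell — a one-sample
  t-test on within-subject condition differences — with an optional
  max-T bootstrap family-wise multiple-comparison correction;
* a K-nearest-neighbour harness that scores two feature sets of equal
  dimensionality on the same labels under identical cross-validation,
  reporting confusion matrices and accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intensity import IntensityStack

__all__ = [
    "FeatureTable",
    "TestResult",
    "KNNComparison",
    "summed_band_intensity",
    "normalize_subject",
    "paired_tests",
    "bootstrap_mcc",
    "knn_compare",
]


@dataclass
class FeatureTable:
    """Subject-by-condition feature matrix.

    ``values`` is a DataFrame indexed by (subject, condition) whose
    columns identify (lead, filter) cells; ``feature_kind`` is either
    ``"ac"`` or ``"summed_intensity"``.
    """

    values: pd.DataFrame
    feature_kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated (subject, condition) rows")


def summed_band_intensity(stack: IntensityStack) -> np.ndarray:
    """Total smoothed intensity per filter over the valid span."""
    return np.array([float(s.valid_values.sum()) for s in stack.series])


def normalize_subject(features: FeatureTable) -> FeatureTable:
    """Relative intensity per lead: each filter divided by the lead's total.

    Cancels any multiplicative per-recording gain (electrode conductance
    varies between subjects and sessions), so only the *profile* across
    filters is compared.  Rows sum to 1 within each lead.  Requires
    summed-intensity features; a zero lead total is flagged.
    """
    if features.feature_kind != "summed_intensity":
        raise ValueError("subject normalization applies to summed-intensity features")
    df = features.values.copy()
    if isinstance(df.columns, pd.MultiIndex):
        leads = df.columns.get_level_values(0)
        for lead in leads.unique():
            cols = df.columns[leads == lead]
            total = df[cols].sum(axis=1)
            if (total == 0).any():
                raise ValueError(f"zero total intensity for lead {lead!r}")
            df[cols] = df[cols].div(total, axis=0)
    else:
        total = df.sum(axis=1)
        if (total == 0).any():
            raise ValueError("zero total intensity row")
        df = df.div(total, axis=0)
    return FeatureTable(values=df, feature_kind=features.feature_kind, metadata=dict(features.metadata))


@dataclass
class TestResult:
    """Per-cell paired test results, Table-style."""

    table: pd.DataFrame  # columns: cell, mean_a, se_a, mean_b, se_b, t, p_raw, p_corrected, direction
    n_subjects: int

    def significant(self, alpha: float = 0.05, corrected: bool = False) -> pd.DataFrame:
        col = "p_corrected" if corrected else "p_raw"
        return self.table[self.table[col] <= alpha]


def _paired_differences(
    features: FeatureTable, condition_a: str, condition_b: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    df = features.values
    conds = df.index.get_level_values(1)
    a = df[conds == condition_a].droplevel(1)
    b = df[conds == condition_b].droplevel(1)
    common = a.index.intersection(b.index)
    dropped = set(a.index.symmetric_difference(b.index))
    if dropped:
        import warnings

        warnings.warn(
            f"dropping {len(dropped)} subject(s) without both conditions: "
            f"{sorted(map(str, dropped))[:5]}",
            UserWarning,
            stacklevel=3,
        )
    a, b = a.loc[common], b.loc[common]
    return a, b, a - b


def paired_tests(
    features: FeatureTable,
    condition_a: str,
    condition_b: str,
    *,
    mcc: str | None = None,
    B: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """One-sample t-test of within-subject condition differences per cell.

    Reports per-cohort means and standard errors, the two-sided raw
    p-value, and (when ``mcc='bootstrap'``) the max-T family-wise
    corrected p-value.  Zero-variance nonzero differences degenerate to
    p = 0 by convention and are flagged in the ``degenerate`` column.
    """
    a, b, d = _paired_differences(features, condition_a, condition_b)
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    dv = d.to_numpy(dtype=float)
    t_stat, p_raw = stats.ttest_1samp(dv, 0.0, axis=0)
    degenerate = (dv.std(axis=0, ddof=1) == 0) & (np.abs(dv.mean(axis=0)) > 0)
    p_raw = np.where(degenerate, 0.0, p_raw)
    t_stat = np.where(degenerate, np.inf * np.sign(dv.mean(axis=0)), t_stat)
    # identical cohorts: t = 0/0 -> p := 1
    null_cells = np.all(dv == 0, axis=0)
    p_raw = np.where(null_cells, 1.0, p_raw)
    t_stat = np.where(null_cells, 0.0, t_stat)

    if mcc == "bootstrap":
        p_corr = bootstrap_mcc(dv, B=B, seed=seed)
        p_corr = np.maximum(p_corr, p_raw)
    elif mcc is None:
        p_corr = np.full_like(p_raw, np.nan)
    else:
        raise ValueError(f"unknown mcc method {mcc!r}")

    table = pd.DataFrame(
        {
            "cell": list(d.columns),
            "mean_a": a.mean(axis=0).to_numpy(),
            "se_a": a.sem(axis=0).to_numpy(),
            "mean_b": b.mean(axis=0).to_numpy(),
            "se_b": b.sem(axis=0).to_numpy(),
            "t": t_stat,
            "p_raw": p_raw,
            "p_corrected": p_corr,
            "direction": np.sign(dv.mean(axis=0)).astype(int),
            "degenerate": degenerate,
        }
    )
    return TestResult(table=table, n_subjects=n)


def bootstrap_mcc(
    differences: np.ndarray, B: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Max-T family-wise bootstrap correction over all cells.

    Subjects are resampled with replacement ``B`` times from the
    *centered* differences (the null), the maximum |t| across cells is
    recorded per replicate, and each cell's corrected p is the fraction
    of replicates whose max |t| reaches its observed |t|.  Controls the
    family-wise error rate over the whole (lead x filter) grid.
    """
    if B < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    d = np.asarray(differences, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    n, n_cells = d.shape
    sd = d.std(axis=0, ddof=1)
    safe_sd = np.where(sd == 0, 1.0, sd)
    t_obs = np.abs(d.mean(axis=0) / (safe_sd / np.sqrt(n)))
    t_obs = np.where(sd == 0, np.where(np.abs(d.mean(axis=0)) > 0, np.inf, 0.0), t_obs)

    centered = d - d.mean(axis=0)
    rng = np.random.default_rng(seed)
    max_t = np.empty(B)
    # chunk replicates to bound peak memory on wide grids
    chunk = max(1, int(5e6 // max(n * n_cells, 1)))
    done = 0
    while done < B:
        nb = min(chunk, B - done)
        idx = rng.integers(0, n, size=(nb, n))
        s = centered[idx]  # (nb, n, n_cells)
        m = s.mean(axis=1)
        ssd = s.std(axis=1, ddof=1)
        tb = np.abs(m / (np.where(ssd == 0, np.inf, ssd) / np.sqrt(n)))
        max_t[done : done + nb] = tb.max(axis=1)
        done += nb
    p_corr = (max_t[:, None] >= t_obs[None, :]).mean(axis=0)
    p_corr[np.isinf(t_obs)] = 0.0
    return p_corr


@dataclass
class KNNComparison:
    """Cross-validated comparison of two feature sets on shared labels."""

    confusion_a: np.ndarray
    confusion_b: np.ndarray
    accuracy_a: float
    accuracy_b: float
    labels: list
    k: int
    folds: int


def _knn_cv(X: np.ndarray, y: np.ndarray, k: int, folds: int, seed: int):
    from sklearn.metrics import confusion_matrix
    from sklearn.model_selection import StratifiedKFold, cross_val_predict
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        import warnings

        warnings.warn(
            f"smallest class has {counts.min()} members < k={k}", UserWarning, stacklevel=3
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=k))
    pred = cross_val_predict(clf, X, y, cv=cv)
    cm = confusion_matrix(y, pred, labels=classes)
    return cm, float(np.trace(cm) / cm.sum()), classes


def knn_compare(
    features_a: np.ndarray,
    features_b: np.ndarray,
    labels: np.ndarray,
    *,
    k: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> KNNComparison:
    """Score two equal-dimensionality feature sets with the same KNN setup.

    Stratified ``folds``-fold cross-validation with standardized
    features and Euclidean KNN; rows of the confusion matrices are the
    actual classes, columns the predictions.
    """
    Xa = np.asarray(features_a, dtype=float)
    Xb = np.asarray(features_b, dtype=float)
    y = np.asarray(labels)
    if Xa.shape[0] != Xb.shape[0] or Xa.shape[0] != len(y):
        raise ValueError("feature sets and labels must share rows")
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError(
            f"feature sets must have identical dimensionality, got {Xa.shape[1]} vs {Xb.shape[1]}"
        )
    cm_a, acc_a, classes = _knn_cv(Xa, y, k, folds, seed)
    cm_b, acc_b, _ = _knn_cv(Xb, y, k, folds, seed)
    return KNNComparison(
        confusion_a=cm_a,
        confusion_b=cm_b,
        accuracy_a=acc_a,
        accuracy_b=acc_b,
        labels=list(classes),
        k=k,
        folds=folds,
    )
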