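"""Progressive-sampling sample-size estimation.

Answers "how many subjects are enough?" for a case-control molecular
readout: using normalized gene expression restricted to disease-definition
genes, a two-feature linear classifier is trained on balanced subsets of
growing size, its 10-fold cross-validated accuracy recorded over repeated
draws, and the accuracy distribution per sample size converted — assuming
normality — into the expected percentage of the maximum achievable
accuracy at 95% and 99% statistical power.  The required sample size is
the smallest n whose power-quantile curve clears a threshold (85% of the
maximum accuracy by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ExpressionDataset",
    "PowerCurve",
    "normalize_expression",
    "max_accuracy",
    "progressive_curve",
    "required_sample_size",
    "read_expression",
]

_Z_ONE_SIDED = {95: stats.norm.ppf(0.95), 99: stats.norm.ppf(0.99)}


@dataclass
class ExpressionDataset:
    """Normalized genes x samples expression with case/control labels."""

    matrix: pd.DataFrame  # genes x samples
    labels: pd.Series  # per sample: 'control' or 'case'

    def __post_init__(self):
        if not set(self.labels.unique()) <= {"control", "case"}:
            raise ValueError("labels must be 'control' or 'case'")
        if (self.labels == "control").sum() == 0 or (self.labels == "case").sum() == 0:
            raise ValueError("both cohorts must be non-empty")
        if self.matrix.isna().any().any():
            raise ValueError("matrix must hold no missing values")
        if list(self.matrix.columns) != list(self.labels.index):
            raise ValueError("matrix columns and label index must align")

    @property
    def cohort_sizes(self) -> tuple[int, int]:
        return int((self.labels == "control").sum()), int((self.labels == "case").sum())

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        present = [g for g in genes if g in self.matrix.index]
        if not present:
            raise KeyError("none of the requested genes are in the matrix")
        return ExpressionDataset(self.matrix.loc[present], self.labels)


@dataclass
class PowerCurve:
    """Accuracy distribution and % of max accuracy per sample size."""

    sizes: np.ndarray  # total (balanced) sample sizes, even, from 8
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    max_accuracy: float
    repetitions: int

    def pct_of_max(self, power: int) -> np.ndarray:
        """Power-quantile accuracy as % of the ceiling (one-sided normal)."""
        z = _Z_ONE_SIDED[power]
        quantile = self.mean_accuracy - z * self.sd_accuracy
        return 100.0 * quantile / self.max_accuracy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_total": self.sizes,
                "mean_accuracy": self.mean_accuracy,
                "sd_accuracy": self.sd_accuracy,
                "pct_of_max_power95": self.pct_of_max(95),
                "pct_of_max_power99": self.pct_of_max(99),
            }
        )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_expression(
    raw: pd.DataFrame, labels: pd.Series, prior: float = 0.5
) -> ExpressionDataset:
    """Library-size normalization with a log2(cpm + prior) transform.

    A deterministic stand-in for a limma-voom-style preprocessing chain:
    counts are scaled to counts-per-million per sample and log2-transformed
    with a small prior.  All-zero samples are dropped with a warning.
    """
    if (raw < 0).any().any():
        raise ValueError("raw values must be non-negative")
    lib = raw.sum(axis=0)
    dead = lib[lib == 0].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} all-zero sample(s)", stacklevel=2)
        raw = raw.drop(columns=dead)
        labels = labels.drop(index=dead)
        lib = lib.drop(index=dead)
    cpm = raw.div(lib, axis=1) * 1e6
    return ExpressionDataset(np.log2(cpm + prior), labels.astype(str))


# ---------------------------------------------------------------------------
# Two-feature linear classifier machinery
# ---------------------------------------------------------------------------


def _select_feature_pair(x: np.ndarray, y: np.ndarray, screen: int = 6) -> tuple[int, int]:
    """Univariate-t screen, then best pair by training accuracy."""
    n1, n0 = y.sum(), (1 - y).sum()
    m1 = x[:, y == 1].mean(axis=1)
    m0 = x[:, y == 0].mean(axis=1)
    v1 = x[:, y == 1].var(axis=1, ddof=1) if n1 > 1 else np.zeros(x.shape[0])
    v0 = x[:, y == 0].var(axis=1, ddof=1) if n0 > 1 else np.zeros(x.shape[0])
    se = np.sqrt(v1 / max(n1, 1) + v0 / max(n0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m0) / se
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf)
    top = np.argsort(-t, kind="stable")[: min(screen, x.shape[0])]
    if len(top) == 1:
        return int(top[0]), int(top[0])
    best_pair, best_acc = (int(top[0]), int(top[1])), -1.0
    for a in range(len(top)):
        for b in range(a + 1, len(top)):
            pair = (int(top[a]), int(top[b]))
            acc = _train_accuracy(x[list(pair)].T, y)
            if acc > best_acc:
                best_pair, best_acc = pair, acc
    return best_pair


def _fit_linear(features: np.ndarray, y: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), features])
    beta, *_ = np.linalg.lstsq(design, y.astype(float), rcond=None)
    return beta


def _train_accuracy(features: np.ndarray, y: np.ndarray) -> float:
    beta = _fit_linear(features, y)
    pred = (np.column_stack([np.ones(len(y)), features]) @ beta) >= 0.5
    return float(np.mean(pred == y.astype(bool)))


def _cv_accuracy(x: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """Cross-validated accuracy of the selected-pair linear classifier.

    Feature-pair selection runs inside each training fold, so the held-out
    estimate carries no selection bias (label-permuted data score ~0.5).
    """
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        pair = _select_feature_pair(x, y)
        return _train_accuracy(x[list(pair)].T, y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    hits = 0
    for train, test in skf.split(x.T, y):
        pair = _select_feature_pair(x[:, train], y[train])
        features = x[list(pair)].T
        beta = _fit_linear(features[train], y[train])
        pred = (np.column_stack([np.ones(len(test)), features[test]]) @ beta) >= 0.5
        hits += int(np.sum(pred == y[test].astype(bool)))
    return hits / len(y)


def _as_arrays(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    x = dataset.matrix.to_numpy(dtype=float)
    y = (dataset.labels == "case").to_numpy().astype(int)
    return x, y


# ---------------------------------------------------------------------------
# Ceiling accuracy and the progressive curve
# ---------------------------------------------------------------------------


def max_accuracy(dataset: ExpressionDataset, seed: int = 0, folds: int = 10) -> float:
    """Ceiling accuracy: best feature pair on all samples, 10-fold CV."""
    n_control, n_case = dataset.cohort_sizes
    if min(n_control, n_case) < 10:
        raise ValueError("each cohort needs >= 10 samples")
    x, y = _as_arrays(dataset)
    if np.allclose(x.var(axis=1), 0.0):
        raise ValueError("degenerate features: no gene varies")
    return _cv_accuracy(x, y, folds, seed)


def progressive_curve(
    dataset: ExpressionDataset,
    reps: int = 100,
    seed: int = 0,
    folds: int = 10,
    n_min: int = 8,
) -> PowerCurve:
    """Accuracy vs sample size by repeated balanced subsampling.

    For every even total n from 8 up to twice the smallest cohort, ``reps``
    balanced subsets (n/2 per cohort, drawn without replacement) are used to
    select a fresh feature pair, train the two-feature linear classifier and
    record its 10-fold cross-validated accuracy.  A normal distribution is
    fitted to the per-n accuracies; its one-sided 95%/99% power quantiles,
    relative to the ceiling accuracy, form the power curves.
    """
    n_control, n_case = dataset.cohort_sizes
    smallest = min(n_control, n_case)
    if smallest < n_min:
        raise ValueError(f"smallest cohort must hold >= {n_min} samples")
    ceiling = max_accuracy(dataset, seed=seed, folds=folds)
    x, y = _as_arrays(dataset)
    control_idx = np.flatnonzero(y == 0)
    case_idx = np.flatnonzero(y == 1)
    rng = np.random.default_rng(seed)
    sizes = np.arange(n_min, 2 * smallest + 1, 2)
    means, sds = [], []
    for n_total in sizes:
        half = n_total // 2
        if half > smallest:
            warnings.warn(f"skipping n={n_total}: exceeds cohort", stacklevel=2)
            continue
        accs = np.empty(reps)
        for rep in range(reps):
            pick = np.concatenate(
                [
                    rng.choice(control_idx, size=half, replace=False),
                    rng.choice(case_idx, size=half, replace=False),
                ]
            )
            xs, ys = x[:, pick], y[pick]
            accs[rep] = _cv_accuracy(xs, ys, folds, int(rng.integers(2**31 - 1)))
        means.append(accs.mean())
        sds.append(accs.std(ddof=1))
    return PowerCurve(
        sizes=sizes[: len(means)],
        mean_accuracy=np.array(means),
        sd_accuracy=np.array(sds),
        max_accuracy=ceiling,
        repetitions=reps,
    )


def required_sample_size(
    curve: PowerCurve, threshold: float = 85.0, power: int = 95
) -> tuple[int, int] | None:
    """Smallest total n whose power-quantile % of max accuracy >= threshold.

    Returns (total n, per-cohort n/2), or None when the curve never crosses
    the threshold.
    """
    if power not in _Z_ONE_SIDED:
        raise ValueError("power must be 95 or 99")
    pct = curve.pct_of_max(power)
    crossing = np.flatnonzero(pct >= threshold)
    if crossing.size == 0:
        return None
    n = int(curve.sizes[crossing[0]])
    return n, n // 2


def read_expression(
    matrix_path: str | Path, labels_path: str | Path, sep: str = "\t"
) -> tuple[pd.DataFrame, pd.Series]:
    """Read a genes x samples matrix and a two-column (sample, label) file."""
    matrix = pd.read_csv(matrix_path, sep=sep, index_col=0)
    lab = pd.read_csv(labels_path, sep=sep)
    labels = pd.Series(lab.iloc[:, 1].astype(str).values, index=lab.iloc[:, 0].astype(str))
    return matrix, labels.loc[matrix.columns]
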