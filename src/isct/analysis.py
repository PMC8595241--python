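"""Model analytics: sensitivity, clustering validation, group comparison.

Three analysis families applied to mechanism-of-action models:

* **Local sensitivity** — a one-at-a-time sweep: each protein's activity is
  clamped across a grid spanning (-1, 1), the model re-solved, and the mean
  absolute tSignal shift reported as a percentage of the maximal possible
  variation (2 minus the baseline tSignal).  Proteins above a 15% threshold
  are flagged as having real impact.

* **Cluster validation** — k-means on 5-dimensional PCA scores over a range
  of k, with Hopkins statistic (cluster tendency), mean silhouette
  (cohesion) and a bootstrap Jaccard index (stability) as quality measures;
  heavily unbalanced clusterings are filtered by a size-ratio rule.

* **Group comparison** — per-variable one-way ANOVA across clusters plus
  per-cluster tests against the pooled rest, with Benjamini-Hochberg FDR
  control within each variable family and an automatic non-parametric
  fallback (Kruskal-Wallis / Mann-Whitney) when any group has fewer than
  30 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .qsp import DiseaseDefinition, ProteinNetwork, QSPConfig, compute_tsignal, propagate_activity

__all__ = [
    "IMPACT_THRESHOLD_PCT",
    "SensitivityResult",
    "ClusteringResult",
    "ComparisonReport",
    "NoValidClusteringError",
    "default_sensitivity_grid",
    "local_sensitivity",
    "sensitivity_profile",
    "rank_sensitive_proteins",
    "hopkins",
    "silhouette_index",
    "jaccard_bootstrap",
    "select_optimal_k",
    "compare_clusters",
]

#: A protein is flagged as having real impact when its sensitivity exceeds
#: this percentage of the maximal possible tSignal variation.
IMPACT_THRESHOLD_PCT = 15.0


class NoValidClusteringError(RuntimeError):
    """Every candidate k was filtered out or the data are degenerate."""


@dataclass
class SensitivityResult:
    """Per-protein sensitivity as % of the maximal tSignal variation."""

    percentages: dict[str, float]
    baseline_tsignal: float
    grid: np.ndarray

    def __post_init__(self):
        for protein, pct in self.percentages.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"sensitivity of {protein!r} outside [0, 100]")


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray  # values in 1..k
    pca_components: np.ndarray  # (5, n_features) basis
    explained_variance: np.ndarray  # fractions, non-increasing
    hopkins: float
    silhouette: float
    jaccard: np.ndarray  # per-cluster bootstrap stability
    composition: pd.DataFrame | None = None  # per-cluster counts by drug
    all_k_silhouette: dict[int, float] = field(default_factory=dict)


@dataclass
class ComparisonReport:
    """ANOVA + per-cluster tests with BH-adjusted q-values."""

    anova: pd.DataFrame  # per variable: statistic, p, test, defined
    per_cluster: pd.DataFrame  # variable, cluster, statistic, p, q, test
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Local sensitivity (one-at-a-time sweep)
# ---------------------------------------------------------------------------


def default_sensitivity_grid(points: int = 21) -> np.ndarray:
    return np.linspace(-0.99, 0.99, points)


def local_sensitivity(
    network: ProteinNetwork,
    stimulus: np.ndarray | Mapping[str, float],
    definition: DiseaseDefinition,
    protein: str,
    grid: np.ndarray | None = None,
    config: QSPConfig = QSPConfig(),
    perturbation: np.ndarray | None = None,
    baseline_tsignal: float | None = None,
) -> float:
    """Sensitivity of tSignal to one protein, as % of maximal variation.

    The protein's activity is clamped to each grid value, the propagation
    re-solved, and the mean |tSignal - baseline| reported relative to
    (2 - baseline tSignal), the maximal achievable variation.
    """
    if protein not in network:
        raise KeyError(f"protein {protein!r} not in network")
    if grid is None:
        grid = default_sensitivity_grid()
    if len(grid) < 5 or np.min(grid) <= -1.0 or np.max(grid) >= 1.0:
        raise ValueError("grid must hold >= 5 points strictly inside (-1, 1)")
    if baseline_tsignal is None:
        base = propagate_activity(network, stimulus, config, perturbation)
        baseline_tsignal = compute_tsignal(base, definition)
    deltas = []
    for value in grid:
        clamped = propagate_activity(
            network, stimulus, config, perturbation, clamp={protein: float(value)}
        )
        deltas.append(abs(compute_tsignal(clamped, definition) - baseline_tsignal))
    max_variation = 2.0 - baseline_tsignal
    pct = 100.0 * float(np.mean(deltas)) / max_variation
    return float(min(pct, 100.0))


def sensitivity_profile(
    network: ProteinNetwork,
    stimulus: np.ndarray | Mapping[str, float],
    definition: DiseaseDefinition,
    proteins: Sequence[str] | None = None,
    grid: np.ndarray | None = None,
    config: QSPConfig = QSPConfig(),
    perturbation: np.ndarray | None = None,
) -> SensitivityResult:
    """Sweep every requested protein (default: all network nodes)."""
    if grid is None:
        grid = default_sensitivity_grid()
    base = propagate_activity(network, stimulus, config, perturbation)
    baseline = compute_tsignal(base, definition)
    targets = tuple(proteins) if proteins is not None else network.nodes
    pct = {
        p: local_sensitivity(
            network, stimulus, definition, p, grid, config, perturbation, baseline
        )
        for p in targets
    }
    return SensitivityResult(percentages=pct, baseline_tsignal=baseline, grid=np.asarray(grid))


def rank_sensitive_proteins(
    result: SensitivityResult | Mapping[str, float],
    top: int | None = None,
    impact_threshold: float = IMPACT_THRESHOLD_PCT,
) -> list[tuple[str, float, bool]]:
    """Proteins ordered by descending sensitivity with real-impact flags.

    Ties break deterministically on protein id; ``top`` limits the list to
    the m most sensitive proteins.
    """
    pct = result.percentages if isinstance(result, SensitivityResult) else dict(result)
    if not pct:
        raise ValueError("empty sensitivity result")
    ranked = sorted(pct.items(), key=lambda kv: (-kv[1], kv[0]))
    if top is not None:
        ranked = ranked[:top]
    return [(p, v, v > impact_threshold) for p, v in ranked]


# ---------------------------------------------------------------------------
# Cluster tendency and quality indices
# ---------------------------------------------------------------------------


def hopkins(
    data: np.ndarray, sample_fraction: float = 0.1, seed: int = 0
) -> float:
    """Hopkins statistic of cluster tendency in [0, 1].

    Compares nearest-neighbour distances of uniform reference points (drawn
    over the data's bounding box) with those of sampled data points;
    distances enter at the d-th power so spatially uniform data give an
    expectation of exactly 0.5.  Values near 1 indicate strong clustering.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 10:
        raise ValueError("need a 2-D matrix with >= 10 rows")
    ranges = x.max(axis=0) - x.min(axis=0)
    keep = ranges > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-range dimension(s)", stacklevel=2)
        x = x[:, keep]
        if x.shape[1] == 0:
            raise ValueError("all dimensions degenerate")
    n, d = x.shape
    m = max(1, int(round(sample_fraction * n)))
    # keyed stream: stays independent of data that a caller generated from
    # default_rng(seed), which would otherwise replay the same draws and
    # place every reference point exactly on a data row
    rng = np.random.default_rng([seed, 0x486F70])
    sample_idx = rng.choice(n, size=m, replace=False)
    uniform = rng.uniform(x.min(axis=0), x.max(axis=0), size=(m, d))
    tree = cKDTree(x)
    u_dist, _ = tree.query(uniform, k=1)
    w_dist, _ = tree.query(x[sample_idx], k=2)  # first hit is the point itself
    u = float(np.sum(u_dist**d))
    w = float(np.sum(w_dist[:, 1] ** d))
    return u / (u + w) if (u + w) > 0 else 0.5


def silhouette_index(data: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over all points (singleton clusters score 0)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(silhouette_score(np.asarray(data, dtype=float), labels))


def jaccard_bootstrap(
    data: np.ndarray,
    labels: np.ndarray,
    b: int = 100,
    seed: int = 0,
    n_init: int = 5,
) -> np.ndarray:
    """Per-cluster stability: mean best-match Jaccard over B bootstrap runs.

    Each bootstrap resamples rows with replacement, re-clusters them with
    k-means at the same k, and greedily matches every original cluster to
    the re-clustered group maximizing the Jaccard overlap on the resampled
    points.
    """
    x = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("jaccard bootstrap undefined for a single cluster")
    rng = np.random.default_rng(seed)
    scores = np.zeros((b, clusters.size))
    for rep in range(b):
        idx = rng.integers(0, x.shape[0], size=x.shape[0])
        km = KMeans(
            n_clusters=clusters.size, n_init=n_init,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(x[idx])
        new_labels = km.labels_
        orig_on_boot = labels[idx]
        for ci, c in enumerate(clusters):
            members = orig_on_boot == c
            if not members.any():
                scores[rep, ci] = 0.0
                continue
            best = 0.0
            for nc in np.unique(new_labels):
                other = new_labels == nc
                inter = float(np.sum(members & other))
                union = float(np.sum(members | other))
                best = max(best, inter / union if union else 0.0)
            scores[rep, ci] = best
    return scores.mean(axis=0)


# ---------------------------------------------------------------------------
# Optimal-k selection
# ---------------------------------------------------------------------------


def select_optimal_k(
    data: np.ndarray,
    k_range: Sequence[int] = range(2, 8),
    pca_dims: int = 5,
    seed: int = 0,
    n_init: int = 25,
    size_ratio_min: float = 0.05,
    jaccard_b: int = 100,
    composition: Sequence[str] | None = None,
) -> ClusteringResult:
    """K-means over a k range on 5-dim PCA scores; silhouette picks k.

    Candidate clusterings whose smallest/largest cluster-size ratio falls
    below ``size_ratio_min`` are discarded as heavily unbalanced; among the
    survivors the k with maximal mean silhouette wins, with the bootstrap
    Jaccard mean as tie-break.  The returned labels are 1-based.
    """
    x = np.asarray(data, dtype=float)
    k_range = list(k_range)
    if x.shape[0] < 2 * max(k_range):
        raise ValueError("need at least 2 * k_max rows")
    if np.allclose(x.var(axis=0), 0.0):
        raise NoValidClusteringError("degenerate data: all rows identical")
    dims = min(pca_dims, x.shape[1], x.shape[0] - 1)
    pca = PCA(n_components=dims, random_state=seed)
    scores = pca.fit_transform(x)
    candidates: dict[int, tuple[np.ndarray, float]] = {}
    sil_by_k: dict[int, float] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
        counts = np.bincount(km.labels_, minlength=k)
        if counts.min() == 0 or counts.min() / counts.max() < size_ratio_min:
            continue
        try:
            sil = silhouette_index(scores, km.labels_)
        except ValueError:
            continue
        candidates[k] = (km.labels_, sil)
        sil_by_k[k] = sil
    if not candidates:
        raise NoValidClusteringError("no k passed the balance/validity filters")
    best_sil = max(s for _, s in candidates.values())
    tied = [k for k, (_, s) in candidates.items() if s >= best_sil - 1e-9]
    if len(tied) > 1:
        tied.sort(
            key=lambda k: -float(
                np.mean(jaccard_bootstrap(scores, candidates[k][0], b=max(10, jaccard_b // 5), seed=seed))
            )
        )
    k_best = tied[0]
    labels0, sil = candidates[k_best]
    jac = jaccard_bootstrap(scores, labels0, b=jaccard_b, seed=seed)
    hop = hopkins(scores, seed=seed)
    comp = None
    if composition is not None:
        comp = (
            pd.DataFrame({"cluster": labels0 + 1, "group": list(composition)})
            .value_counts()
            .unstack(fill_value=0)
        )
    return ClusteringResult(
        k=k_best,
        labels=labels0 + 1,
        pca_components=pca.components_,
        explained_variance=pca.explained_variance_ratio_,
        hopkins=hop,
        silhouette=sil,
        jaccard=jac,
        composition=comp,
        all_k_silhouette=sil_by_k,
    )


# ---------------------------------------------------------------------------
# Cluster comparison statistics
# ---------------------------------------------------------------------------


def _family_tests(values: np.ndarray, labels: np.ndarray, parametric: bool):
    clusters = np.unique(labels)
    groups = [values[labels == c] for c in clusters]
    if parametric:
        stat, p = stats.f_oneway(*groups)
        omnibus = "anova"
    else:
        stat, p = stats.kruskal(*groups)
        omnibus = "kruskal"
    rows = []
    for c in clusters:
        inside = values[labels == c]
        outside = values[labels != c]
        if parametric:
            t, tp = stats.ttest_ind(inside, outside, equal_var=False)
            test = "t"
        else:
            t, tp = stats.mannwhitneyu(inside, outside, alternative="two-sided")
            test = "mannwhitney"
        rows.append({"cluster": int(c), "statistic": float(t), "p": float(tp), "test": test})
    return omnibus, float(stat), float(p), rows


def compare_clusters(
    values: pd.DataFrame | Mapping[str, np.ndarray],
    labels: np.ndarray,
    alpha: float = 0.05,
    nonparametric_below: int = 30,
) -> ComparisonReport:
    """Per-variable omnibus + per-cluster comparisons with BH correction.

    Each variable gets a one-way ANOVA across clusters and, per cluster, a
    two-sided test against the pooled rest; q-values are BH-adjusted within
    the variable's family.  When any cluster holds fewer than
    ``nonparametric_below`` samples the non-parametric pair
    (Kruskal-Wallis / Mann-Whitney) replaces the parametric tests.
    Variables with zero within-group variance are flagged undefined.
    """
    frame = pd.DataFrame(values)
    labels = np.asarray(labels)
    clusters, counts = np.unique(labels, return_counts=True)
    if clusters.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 clusters with >= 2 members each")
    parametric = counts.min() >= nonparametric_below
    anova_rows, cluster_rows = [], []
    for variable in frame.columns:
        x = frame[variable].to_numpy(dtype=float)
        within_var = [np.var(x[labels == c]) for c in clusters]
        if all(v == 0 for v in within_var):
            anova_rows.append(
                {"variable": variable, "test": "undefined", "statistic": np.nan,
                 "p": np.nan, "defined": False}
            )
            continue
        omnibus, stat, p, rows = _family_tests(x, labels, parametric)
        anova_rows.append(
            {"variable": variable, "test": omnibus, "statistic": stat, "p": p,
             "defined": True}
        )
        pvals = [r["p"] for r in rows]
        _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for r, q in zip(rows, qvals):
            cluster_rows.append({"variable": variable, **r, "q": float(q)})
    return ComparisonReport(
        anova=pd.DataFrame(anova_rows),
        per_cluster=pd.DataFrame(cluster_rows),
        alpha=alpha,
    )
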