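"""Clinical-efficacy outcome mapping.

Links the model-derived tSignal statistic to a real clinical efficacy
endpoint (ADHD-RS-IV change from baseline; negative = improvement).  The
disease molecular definition is optimized by correlation-driven trimming:
proteins are removed greedily while the removal keeps improving the Pearson
correlation between per-drug mean tSignal and the per-drug pooled clinical
efficacy.  A final ordinary-least-squares mapping converts tSignal into
predicted score change.

Because higher tSignal means more reversion of the disease signature and
improvement is a negative score change, the expected correlation is
negative; a positive achieved correlation is reported with a warning, not
an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pathlib import Path
from scipy import stats

from .qsp import DiseaseDefinition, SolutionEnsemble, compute_tsignal

__all__ = [
    "EfficacyRecord",
    "TrimmedDefinition",
    "EfficacyMapping",
    "TrimConfig",
    "CorrelationUndefinedError",
    "drug_level_tsignal",
    "mean_activity_by_drug",
    "efficacy_correlation",
    "trim_definition",
    "fit_efficacy_mapping",
    "predict",
    "read_efficacy_records",
]


class CorrelationUndefinedError(ValueError):
    """Pearson correlation undefined (zero variance or too few drugs)."""


@dataclass(frozen=True)
class EfficacyRecord:
    """One trial's reported efficacy for one drug and population."""

    trial_id: str
    drug: str
    population: str  # 'adult' or 'pediatric'
    adhd_rs_change: float  # score units; negative = improvement

    def __post_init__(self):
        if not np.isfinite(self.adhd_rs_change):
            raise ValueError("adhd_rs_change must be finite")
        if self.population not in ("adult", "pediatric"):
            raise ValueError("population must be 'adult' or 'pediatric'")


@dataclass
class TrimmedDefinition:
    """Result of correlation-driven backward elimination."""

    definition: DiseaseDefinition
    rho: float
    rho_full: float
    removal_trace: list[tuple[str, float]] = field(default_factory=list)

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.definition.proteins)


@dataclass(frozen=True)
class EfficacyMapping:
    """Affine map from mean tSignal to predicted clinical score change."""

    slope: float
    intercept: float
    rho: float
    residual_sd: float

    def __post_init__(self):
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("mapping coefficients must be finite")


@dataclass(frozen=True)
class TrimConfig:
    improvement_threshold: float = 1e-4
    floor_fraction: float = 0.5  # never trim below this fraction of proteins


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def mean_activity_by_drug(
    ensembles: Sequence[SolutionEnsemble],
) -> dict[str, dict[str, float]]:
    """Per-drug mean protein activity: solutions first, then patients."""
    by_drug: dict[str, list[dict[str, float]]] = {}
    for ens in ensembles:
        if not ens.solutions:
            raise ValueError(f"empty ensemble for patient {ens.patient_id}")
        frame = pd.DataFrame([dict(s.values) for s in ens.solutions])
        by_drug.setdefault(ens.drug, []).append(frame.mean().to_dict())
    return {
        drug: pd.DataFrame(patient_means).mean().to_dict()
        for drug, patient_means in by_drug.items()
    }


def drug_level_tsignal(
    ensembles: Sequence[SolutionEnsemble], definition: DiseaseDefinition
) -> dict[str, float]:
    """Mean tSignal per drug (mean over solutions, then over patients)."""
    per_drug: dict[str, list[float]] = {}
    for ens in ensembles:
        if not ens.solutions:
            raise ValueError(f"empty ensemble for patient {ens.patient_id}")
        per_drug.setdefault(ens.drug, []).append(ens.mean_tsignal(definition))
    return {drug: float(np.mean(vals)) for drug, vals in per_drug.items()}


def _pooled_efficacy(records: Sequence[EfficacyRecord]) -> dict[str, float]:
    # naive pooling: trials of the same drug are plainly averaged
    by_drug: dict[str, list[float]] = {}
    for r in records:
        by_drug.setdefault(r.drug, []).append(r.adhd_rs_change)
    return {d: float(np.mean(v)) for d, v in by_drug.items()}


def efficacy_correlation(
    tsignals: Mapping[str, float], records: Sequence[EfficacyRecord]
) -> float:
    """Pearson correlation of per-drug mean tSignal vs pooled efficacy."""
    pooled = _pooled_efficacy(records)
    drugs = sorted(set(tsignals) & set(pooled))
    if len(drugs) < 3:
        raise CorrelationUndefinedError(
            f"need >= 3 drugs with both quantities, have {len(drugs)}"
        )
    x = np.array([tsignals[d] for d in drugs])
    y = np.array([pooled[d] for d in drugs])
    if np.std(x) == 0 or np.std(y) == 0:
        raise CorrelationUndefinedError("zero variance in tSignal or efficacy")
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# Definition trimming
# ---------------------------------------------------------------------------


def _subset_tsignals(
    activity: Mapping[str, Mapping[str, float]],
    proteins: Sequence[tuple[str, int]],
) -> dict[str, float]:
    n = len(proteins)
    return {
        drug: -sum(sign * values.get(p, 0.0) for p, sign in proteins) / n
        for drug, values in activity.items()
    }


def trim_definition(
    definition: DiseaseDefinition,
    ensembles: Sequence[SolutionEnsemble],
    records: Sequence[EfficacyRecord],
    config: TrimConfig = TrimConfig(),
) -> TrimmedDefinition:
    """Greedy backward elimination of definition proteins.

    Repeatedly removes the single protein whose removal most increases the
    absolute Pearson correlation between per-drug tSignal (computed on the
    retained subset) and pooled clinical efficacy; stops when no removal
    improves |rho| by more than the threshold or the size floor is reached.
    Ties break lexicographically on protein id, so the trace is replayable.
    """
    if len(definition.proteins) < 2:
        raise ValueError("definition must hold at least 2 proteins")
    activity = mean_activity_by_drug(ensembles)
    pooled = _pooled_efficacy(records)

    def rho_of(proteins: Sequence[tuple[str, int]]) -> float:
        ts = _subset_tsignals(activity, proteins)
        drugs = sorted(set(ts) & set(pooled))
        if len(drugs) < 3:
            raise CorrelationUndefinedError("fewer than 3 drugs")
        x = np.array([ts[d] for d in drugs])
        y = np.array([pooled[d] for d in drugs])
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    current = list(definition.proteins)
    rho_full = rho_of(current)
    if not np.isfinite(rho_full):
        raise CorrelationUndefinedError("correlation undefined on the full definition")
    floor = max(2, int(np.ceil(config.floor_fraction * len(current))))
    rho_current = rho_full
    trace: list[tuple[str, float]] = []
    while len(current) > floor:
        best_protein, best_rho = None, rho_current
        for protein, _ in sorted(current):
            subset = [(p, s) for p, s in current if p != protein]
            r = rho_of(subset)
            if np.isfinite(r) and abs(r) > abs(best_rho) + config.improvement_threshold:
                best_protein, best_rho = protein, r
        if best_protein is None:
            break
        current = [(p, s) for p, s in current if p != best_protein]
        rho_current = best_rho
        trace.append((best_protein, rho_current))
    if rho_current > 0:
        warnings.warn(
            "achieved correlation is positive; expected negative (higher tSignal "
            "= more reversion, improvement = negative score change)",
            stacklevel=2,
        )
    return TrimmedDefinition(
        definition=DiseaseDefinition(name=definition.name, proteins=tuple(current)),
        rho=rho_current,
        rho_full=rho_full,
        removal_trace=trace,
    )


# ---------------------------------------------------------------------------
# tSignal -> clinical scale
# ---------------------------------------------------------------------------


def fit_efficacy_mapping(
    tsignals: Mapping[str, float], records: Sequence[EfficacyRecord]
) -> EfficacyMapping:
    """OLS regression of pooled ADHD-RS change on per-drug mean tSignal."""
    pooled = _pooled_efficacy(records)
    drugs = sorted(set(tsignals) & set(pooled))
    if len(drugs) < 3:
        raise ValueError("need >= 3 paired points for the mapping")
    x = np.array([tsignals[d] for d in drugs])
    y = np.array([pooled[d] for d in drugs])
    if np.std(x) == 0:
        raise ValueError("rank-deficient fit: tSignal has zero variance")
    slope, intercept, rho, _, _ = stats.linregress(x, y)
    residuals = y - (slope * x + intercept)
    residual_sd = float(np.std(residuals, ddof=2)) if len(drugs) > 2 else 0.0
    return EfficacyMapping(
        slope=float(slope), intercept=float(intercept), rho=float(rho),
        residual_sd=residual_sd,
    )


def predict(mapping: EfficacyMapping, tsignal: float) -> float:
    """Predicted clinical score change for a tSignal value."""
    return mapping.slope * tsignal + mapping.intercept


def read_efficacy_records(path: str | Path, sep: str = "\t") -> list[EfficacyRecord]:
    frame = pd.read_csv(path, sep=sep)
    return [
        EfficacyRecord(
            trial_id=str(r["trial_id"]),
            drug=str(r["drug"]),
            population=str(r["population"]),
            adhd_rs_change=float(r["adhd_rs_change"]),
        )
        for _, r in frame.iterrows()
    ]
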