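"""Quantitative systems pharmacology: exposure -> protein activity -> tSignal.

Converts brain drug exposure into per-target modulation through an Emax
(EC50) relationship, propagates the modulation over a signed weighted
protein functional network into bounded activity vectors, and scores the
result against a signed disease definition with the tSignal statistic

    tSignal = -(1/n) * sum_i v_i * y_i

where v_i is the disease sign of protein i and y_i its modeled activity in
(-1, 1): +1 means complete reversion of the disease signature, -1 a fully
expressed signature.

The activity model here is a transparent surrogate for supervised
mechanism-of-action training systems: a damped signed propagation
x <- tanh(lambda * W x + stimulus) run to a fixed point, with a per-solution
Gaussian perturbation (held fixed within each solution as both the initial
state and a weak persistent input) providing intra-patient variability.
Ensembles keep only solutions whose training-set accuracy clears a floor,
mirroring the published interface constraints (activities in (-1,1),
>= 50 solutions per patient, accuracy >= 85%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteinNetwork",
    "DrugTargetProfile",
    "DiseaseDefinition",
    "ActivityVector",
    "TrainingEntry",
    "TrainingSet",
    "SolutionEnsemble",
    "QSPConfig",
    "EnsembleInfeasibleError",
    "target_modulation",
    "build_stimulus",
    "propagate_activity",
    "solution_accuracy",
    "sample_ensemble",
    "compute_tsignal",
    "read_network",
    "read_signed_proteins",
]


class EnsembleInfeasibleError(RuntimeError):
    def __init__(self, message: str, best_accuracy: float):
        super().__init__(message)
        self.best_accuracy = best_accuracy


class ProteinNetwork:
    """Directed signed weighted protein functional network.

    Stored as a dense matrix ``W`` with ``W[i, j]`` the signed weight of the
    edge j -> i, so that propagation is the matrix-vector product ``W @ x``.
    """

    def __init__(self, nodes: Sequence[str], edges: Sequence[tuple[str, str, int, float]]):
        self.nodes = tuple(nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.w = np.zeros((n, n))
        for source, target, sign, weight in edges:
            if source == target:
                raise ValueError(f"self-loop on {source!r}")
            if sign not in (1, -1):
                raise ValueError("edge sign must be +1 or -1")
            if not (weight > 0 and math.isfinite(weight)):
                raise ValueError("edge weight must be finite and positive")
            self.w[self.index[target], self.index[source]] = sign * weight
        self.edges = tuple(edges)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, protein: str) -> bool:
        return protein in self.index

    def spectral_bound(self) -> float:
        """Spectral norm of |W|; lambda below 1/bound guarantees contraction."""
        return float(np.linalg.norm(np.abs(self.w), 2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProteinNetwork":
        frame = pd.read_csv(path, sep="\t")
        edges = [
            (str(r.iloc[0]), str(r.iloc[1]), int(r.iloc[2]), float(r.iloc[3]))
            for _, r in frame.iterrows()
        ]
        nodes = sorted({e[0] for e in edges} | {e[1] for e in edges})
        return cls(nodes, edges)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["source", "target", "sign", "weight"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class DrugTargetProfile:
    """A drug's protein targets with activation (+1) / inhibition (-1) signs."""

    drug: str
    targets: tuple[tuple[str, int], ...]

    def __post_init__(self):
        for _, effect in self.targets:
            if effect not in (1, -1):
                raise ValueError("target effect must be +1 or -1")


@dataclass(frozen=True)
class DiseaseDefinition:
    """Signed protein set defining a disease or comorbidity signature."""

    name: str
    proteins: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.proteins:
            raise ValueError("disease definition must be non-empty")
        names = [p for p, _ in self.proteins]
        if len(set(names)) != len(names):
            raise ValueError("duplicate proteins in definition")
        for _, sign in self.proteins:
            if sign not in (1, -1):
                raise ValueError("protein signs must be +1 or -1")


@dataclass
class ActivityVector:
    """One mathematical solution: protein -> activity in (-1, 1)."""

    values: Mapping[str, float]
    solution_id: str = ""
    converged: bool = True
    perturbation: np.ndarray | None = None  # per-solution noise, kept for replay

    def __post_init__(self):
        for protein, y in self.values.items():
            if not -1.0 < y < 1.0:
                raise ValueError(f"activity of {protein!r} outside (-1, 1)")


@dataclass(frozen=True)
class TrainingEntry:
    stimulus: DrugTargetProfile
    condition: DiseaseDefinition
    expected_direction: int  # +1: tSignal increases under the stimulus

    def __post_init__(self):
        if self.expected_direction not in (1, -1):
            raise ValueError("expected_direction must be +1 or -1")


@dataclass(frozen=True)
class TrainingSet:
    entries: tuple[TrainingEntry, ...]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("training set must be non-empty")


@dataclass
class SolutionEnsemble:
    """>= ensemble_min retained solutions for one (patient, drug) pair."""

    patient_id: str
    drug: str
    solutions: list[ActivityVector]
    accuracies: list[float]
    target_modulation: Mapping[str, float]
    rejected: int = 0

    def mean_tsignal(self, definition: DiseaseDefinition) -> float:
        return float(np.mean([compute_tsignal(s, definition) for s in self.solutions]))


@dataclass(frozen=True)
class QSPConfig:
    """Tunables of the propagation surrogate and ensemble sampling."""

    damping: float = 0.5  # lambda; < 1/spectral bound gives contraction
    max_iterations: int = 200
    tolerance: float = 1e-6
    noise_scale: float = 0.1
    ensemble_min: int = 50
    accuracy_floor: float = 85.0
    attempt_budget: int = 1000
    comorbidity_weight: float = 0.25
    hill: float = 1.0
    aggregate: str = "mean"  # how concentration timepoints are pooled


# ---------------------------------------------------------------------------
# Exposure -> target modulation
# ---------------------------------------------------------------------------


def target_modulation(
    brain_timepoints: Sequence[float],
    profile: DrugTargetProfile,
    ec50: Mapping[str, float],
    hill: float = 1.0,
    aggregate: str = "mean",
) -> dict[str, float]:
    """Signed per-target modulation from tissue exposure (Emax form).

    Each target's magnitude is the aggregate over timepoints of
    c^h / (c^h + EC50^h), signed by the drug's effect on that target.
    """
    c = np.asarray(brain_timepoints, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    out = {}
    for protein, effect in profile.targets:
        if protein not in ec50:
            raise KeyError(f"missing EC50 for target {protein!r}")
        e = ec50[protein]
        if e <= 0:
            raise ValueError(f"EC50 for {protein!r} must be positive")
        occupancy = c**hill / (c**hill + e**hill)
        if aggregate == "mean":
            magnitude = float(occupancy.mean())
        elif aggregate == "max":
            magnitude = float(occupancy.max())
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        out[protein] = effect * magnitude
    return out


def build_stimulus(
    network: ProteinNetwork,
    modulation: Mapping[str, float],
    comorbidities: Sequence[DiseaseDefinition] = (),
    comorbidity_weight: float = 0.25,
) -> np.ndarray:
    """Stimulus vector: drug modulation plus weak persistent comorbidity inputs."""
    s = np.zeros(len(network))
    for protein, m in modulation.items():
        if protein not in network:
            raise KeyError(f"modulation target {protein!r} not in network")
        s[network.index[protein]] += m
    for definition in comorbidities:
        for protein, sign in definition.proteins:
            if protein in network:
                s[network.index[protein]] += comorbidity_weight * sign
    return s


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------


def propagate_activity(
    network: ProteinNetwork,
    stimulus: np.ndarray | Mapping[str, float],
    config: QSPConfig = QSPConfig(),
    perturbation: np.ndarray | None = None,
    solution_id: str = "",
    clamp: Mapping[str, float] | None = None,
) -> ActivityVector:
    """Damped signed propagation to a bounded fixed point.

    Iterates x <- tanh(damping * W x + stimulus + perturbation) from
    x0 = perturbation until the max change drops below the tolerance or the
    iteration budget runs out (the vector is then flagged non-converged).
    The perturbation is this solution's frozen heterogeneity term: using it
    both as the start point and as a persistent input gives each solution
    its own fixed point while zero noise stays fully deterministic.
    ``clamp`` holds the named proteins at fixed activities throughout the
    iteration (used by the local sensitivity sweep).
    """
    if not isinstance(stimulus, np.ndarray):
        stimulus = build_stimulus(network, stimulus)
    n = len(network)
    eta = np.zeros(n) if perturbation is None else np.asarray(perturbation, dtype=float)
    drive = stimulus + eta
    clamp_idx = clamp_val = None
    if clamp:
        clamp_idx = np.array([network.index[p] for p in clamp])
        clamp_val = np.array([float(v) for v in clamp.values()])
    x = np.tanh(eta)
    if clamp_idx is not None:
        x[clamp_idx] = clamp_val
    converged = False
    for _ in range(config.max_iterations):
        x_new = np.tanh(config.damping * (network.w @ x) + drive)
        if clamp_idx is not None:
            x_new[clamp_idx] = clamp_val
        if np.max(np.abs(x_new - x)) < config.tolerance:
            x = x_new
            converged = True
            break
        x = x_new
    values = {p: float(x[i]) for p, i in network.index.items()}
    return ActivityVector(
        values=values, solution_id=solution_id, converged=converged, perturbation=eta
    )


# ---------------------------------------------------------------------------
# tSignal
# ---------------------------------------------------------------------------


def compute_tsignal(
    solution: ActivityVector | Mapping[str, float], definition: DiseaseDefinition
) -> float:
    """tSignal = -(1/n) sum_i v_i y_i over the definition's proteins.

    Proteins absent from the solution contribute y = 0 (neutral) so the
    definition size n stays fixed.
    """
    values = solution.values if isinstance(solution, ActivityVector) else solution
    total = 0.0
    for protein, sign in definition.proteins:
        total += sign * float(values.get(protein, 0.0))
    return -total / len(definition.proteins)


# ---------------------------------------------------------------------------
# Training-set accuracy and ensemble sampling
# ---------------------------------------------------------------------------


def solution_accuracy(
    solution: ActivityVector,
    training: TrainingSet,
    network: ProteinNetwork,
    config: QSPConfig = QSPConfig(),
    baselines: Mapping[str, float] | None = None,
) -> float:
    """Percent of training relationships whose tSignal change direction matches.

    Each relationship is replayed under this solution's frozen perturbation:
    the stimulus-on tSignal is compared with the stimulus-off (baseline)
    tSignal of the same condition, and compliance means the sign of the
    change equals the expected direction.  ``baselines`` may carry
    precomputed baseline tSignals per condition name (shared across arms).
    """
    eta = solution.perturbation
    baseline_cache: dict[str, float] = dict(baselines or {})
    base_solution: ActivityVector | None = None
    stimulus_cache: dict[tuple, ActivityVector] = {}
    hits = 0
    for entry in training.entries:
        name = entry.condition.name
        if name not in baseline_cache:
            if base_solution is None:
                base_solution = propagate_activity(
                    network, np.zeros(len(network)), config, eta
                )
            baseline_cache[name] = compute_tsignal(base_solution, entry.condition)
        key = entry.stimulus.targets
        if key not in stimulus_cache:
            stim = build_stimulus(network, {p: float(e) for p, e in key})
            stimulus_cache[key] = propagate_activity(network, stim, config, eta)
        change = compute_tsignal(stimulus_cache[key], entry.condition) - baseline_cache[name]
        if change * entry.expected_direction > 0:
            hits += 1
    return 100.0 * hits / len(training.entries)


def sample_ensemble(
    patient_id: str,
    drug: str,
    network: ProteinNetwork,
    training: TrainingSet,
    modulation: Mapping[str, float],
    config: QSPConfig = QSPConfig(),
    seed: int = 0,
    comorbidities: Sequence[DiseaseDefinition] = (),
) -> SolutionEnsemble:
    """Draw perturbed solutions until the ensemble constraints are met.

    Seeded Gaussian perturbations are drawn one per attempt; a solution is
    retained iff its training-set accuracy reaches the floor.  Sampling
    stops at ``ensemble_min`` retained solutions or fails with the best
    accuracy seen once the attempt budget is exhausted.
    """
    if config.accuracy_floor > 100.0:
        raise EnsembleInfeasibleError(
            f"accuracy floor {config.accuracy_floor} is unattainable", best_accuracy=0.0
        )
    rng = np.random.default_rng(seed)
    stimulus = build_stimulus(network, modulation, comorbidities, config.comorbidity_weight)
    solutions: list[ActivityVector] = []
    accuracies: list[float] = []
    rejected = 0
    best = 0.0
    for attempt in range(config.attempt_budget):
        eta = rng.normal(0.0, config.noise_scale, size=len(network))
        sol = propagate_activity(
            network, stimulus, config, eta, solution_id=f"{patient_id}:{drug}:{attempt}"
        )
        acc = solution_accuracy(sol, training, network, config)
        best = max(best, acc)
        if acc >= config.accuracy_floor:
            solutions.append(sol)
            accuracies.append(acc)
            if len(solutions) >= config.ensemble_min:
                break
        else:
            rejected += 1
    if len(solutions) < config.ensemble_min:
        raise EnsembleInfeasibleError(
            f"only {len(solutions)}/{config.ensemble_min} solutions met the "
            f"{config.accuracy_floor}% floor within {config.attempt_budget} attempts",
            best_accuracy=best,
        )
    return SolutionEnsemble(
        patient_id=patient_id,
        drug=drug,
        solutions=solutions,
        accuracies=accuracies,
        target_modulation=dict(modulation),
        rejected=rejected,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_network(path: str | Path) -> ProteinNetwork:
    return ProteinNetwork.from_tsv(path)


def read_signed_proteins(path: str | Path, name: str | None = None) -> DiseaseDefinition:
    """Read a (protein, sign) TSV into a disease/comorbidity definition."""
    frame = pd.read_csv(path, sep="\t")
    proteins = tuple(
        (str(r.iloc[0]), int(r.iloc[1])) for _, r in frame.iterrows()
    )
    return DiseaseDefinition(name=name or Path(path).stem, proteins=proteins)
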