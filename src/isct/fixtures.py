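"""Seeded synthetic-data generators.

Every other module is testable offline through these generators: synthetic
case/control expression matrices, satisfiable signed protein networks with
matching disease definitions and drug target profiles, closed-form
pharmacokinetic observations, and packaged reference demographics with a
synthetic growth grid.

All generators are pure functions of (parameters, seed).  The packaged
demographic defaults embed only published summary numbers (reference means,
SDs and sex proportions of the source trials, drug bioavailabilities and
target signs); everything else — the growth grid, EC50 values, networks,
expression matrices — is synthetic and labeled as such.
"""

from __future__ import annotations

import math
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .pbpk import DrugConfig, PKObservations
from .qsp import (
    DiseaseDefinition,
    DrugTargetProfile,
    ProteinNetwork,
    QSPConfig,
    TrainingEntry,
    TrainingSet,
    propagate_activity,
)
from .samplesize import ExpressionDataset
from .vpop import (
    DemographicReference,
    GrowthReferenceTable,
    StandardDistributionTable,
    VariableSummary,
)

__all__ = [
    "synth_expression",
    "synth_network_with_definitions",
    "synth_pk_observations",
    "synth_reference_population",
    "bateman",
    "bateman_tmax",
    "standard_adult_fill",
    "reference_drug_configs",
]


# ---------------------------------------------------------------------------
# Expression data (case/control cohorts)
# ---------------------------------------------------------------------------


def synth_expression(
    n_control: int,
    n_case: int,
    n_genes: int = 200,
    n_informative: int = 20,
    effect: float = 1.0,
    seed: int = 0,
) -> ExpressionDataset:
    """Synthetic normalized expression with a planted case/control effect.

    Gene baselines are log-normal on the raw scale (normal on the log2
    scale); the first ``n_informative`` genes are shifted by ``effect``
    within-gene SDs in the case cohort.  ``effect = 0`` makes the cohorts
    exchangeable.
    """
    if n_informative > n_genes:
        raise ValueError("n_informative must not exceed n_genes")
    rng = np.random.default_rng(seed)
    mu = rng.normal(8.0, 2.0, size=n_genes)
    sigma = rng.uniform(0.5, 1.5, size=n_genes)
    n = n_control + n_case
    x = mu[:, None] + sigma[:, None] * rng.standard_normal((n_genes, n))
    x[:n_informative, n_control:] += effect * sigma[:n_informative, None]
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n)]
    labels = pd.Series(["control"] * n_control + ["case"] * n_case, index=samples)
    return ExpressionDataset(pd.DataFrame(x, index=genes, columns=samples), labels)


# ---------------------------------------------------------------------------
# Satisfiable network + definitions + training set
# ---------------------------------------------------------------------------


def synth_network_with_definitions(
    n_nodes: int = 60,
    n_edges: int = 120,
    n_effectors: int = 12,
    training_size: int = 4,
    n_targets: int = 3,
    seed: int = 0,
    spectral_target: float = 1.5,
    config: QSPConfig = QSPConfig(),
) -> tuple[ProteinNetwork, DiseaseDefinition, DrugTargetProfile, DrugTargetProfile, TrainingSet]:
    """Connected random signed network with a satisfiable training set.

    Drug 1 stimulates a few targets; the disease definition signs are set
    opposite to the noiseless propagation of drug 1, so drug 1 reverses the
    signature (tSignal > 0) by construction, drug 2 — the sign-flipped
    profile — expresses it, and every training relationship is satisfiable
    in the noiseless limit.  Edge weights are rescaled so the spectral bound
    of |W| stays below 1/damping, guaranteeing convergence.
    """
    if n_effectors >= n_nodes:
        raise ValueError("n_effectors must be < n_nodes")
    rng = np.random.default_rng(seed)
    graph = nx.random_labeled_tree(n_nodes, seed=int(rng.integers(2**31 - 1)))
    nodes = [f"P{i:03d}" for i in range(n_nodes)]
    edges: set[tuple[int, int]] = set()
    for u, v in graph.edges:
        edges.add((u, v))
    while len(edges) < n_edges:
        u, v = rng.integers(n_nodes, size=2)
        if u != v:
            edges.add((int(u), int(v)))
    edge_list = [
        (nodes[u], nodes[v], int(rng.choice([1, -1])), float(rng.uniform(0.5, 1.5)))
        for u, v in sorted(edges)
    ]
    net = ProteinNetwork(nodes, edge_list)
    bound = net.spectral_bound()
    scale = spectral_target / bound if bound > 0 else 1.0
    edge_list = [(s, t, sg, w * scale) for s, t, sg, w in edge_list]
    net = ProteinNetwork(nodes, edge_list)

    target_idx = rng.choice(n_nodes, size=n_targets, replace=False)
    drug1 = DrugTargetProfile(
        drug="drugA",
        targets=tuple(
            (nodes[i], int(rng.choice([1, -1]))) for i in sorted(target_idx)
        ),
    )
    drug2 = DrugTargetProfile(
        drug="drugB", targets=tuple((p, -e) for p, e in drug1.targets)
    )

    noiseless = propagate_activity(
        net, {p: float(e) for p, e in drug1.targets}, config
    )
    activity = np.array([noiseless.values[p] for p in nodes])
    order = np.argsort(-np.abs(activity), kind="stable")
    effector_idx = [int(i) for i in order[:n_effectors] if abs(activity[i]) > 1e-6]
    if len(effector_idx) < n_effectors:
        raise RuntimeError("network too sparse: not enough responsive effectors")
    definition = DiseaseDefinition(
        name="disease",
        proteins=tuple(
            (nodes[i], -int(np.sign(activity[i]))) for i in sorted(effector_idx)
        ),
    )

    entries = [
        TrainingEntry(stimulus=drug1, condition=definition, expected_direction=1),
        TrainingEntry(stimulus=drug2, condition=definition, expected_direction=-1),
    ]
    chunk = max(2, len(effector_idx) // max(1, training_size - 2))
    proteins = list(definition.proteins)
    for start in range(0, len(proteins), chunk):
        if len(entries) >= training_size:
            break
        sub = tuple(proteins[start : start + chunk])
        if sub:
            entries.append(
                TrainingEntry(
                    stimulus=drug1,
                    condition=DiseaseDefinition(name=f"disease_part{start}", proteins=sub),
                    expected_direction=1,
                )
            )
    return net, definition, drug1, drug2, TrainingSet(tuple(entries[:max(training_size, 2)]))


# ---------------------------------------------------------------------------
# Pharmacokinetic observations (one-compartment closed form)
# ---------------------------------------------------------------------------


def bateman(
    t: np.ndarray | float,
    k_a: float,
    cl: float,
    volume: float,
    f: float,
    dose: float,
) -> np.ndarray:
    """One-compartment oral-absorption concentration curve.

    C(t) = F D k_a / (V (k_a - k_e)) * (exp(-k_e t) - exp(-k_a t)),
    with k_e = CL / V; the k_a = k_e limit is handled by its analytic form.
    """
    t = np.asarray(t, dtype=float)
    k_e = cl / volume
    if math.isclose(k_a, k_e, rel_tol=1e-9):
        return f * dose * k_a * t * np.exp(-k_a * t) / volume
    return (
        f * dose * k_a / (volume * (k_a - k_e)) * (np.exp(-k_e * t) - np.exp(-k_a * t))
    )


def bateman_tmax(k_a: float, cl: float, volume: float) -> float:
    """Time of peak concentration: ln(k_a/k_e) / (k_a - k_e)."""
    k_e = cl / volume
    if math.isclose(k_a, k_e, rel_tol=1e-9):
        return 1.0 / k_a
    return math.log(k_a / k_e) / (k_a - k_e)


def synth_pk_observations(
    k_a: float = 1.2,
    cl: float = 0.3,
    volume: float = 5.0,
    f: float = 0.9,
    dose: float = 70.0,
    times: Sequence[float] = (0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24),
    noise: float = 0.0,
    seed: int = 0,
    drug: str = "synthetic",
) -> PKObservations:
    """Closed-form PK datapoints with multiplicative log-normal noise."""
    if min(k_a, cl, volume, f, dose) <= 0:
        raise ValueError("all parameters must be positive")
    t = np.asarray(times, dtype=float)
    c = bateman(t, k_a, cl, volume, f, dose)
    if noise > 0:
        rng = np.random.default_rng(seed)
        c = c * np.exp(rng.normal(0.0, noise, size=c.size))
    return PKObservations(times=tuple(t), concentrations=tuple(float(v) for v in c), drug=drug)


# ---------------------------------------------------------------------------
# Reference demographics + synthetic growth grid
# ---------------------------------------------------------------------------

# Published reference columns of the source trials (summary numbers only).
_ADULT_REFERENCE = {
    "age": (36.58, 10.10),
    "height": (171.7, 9.4),
    "weight": (78.75, 17.20),
    "sex_female_fraction": 0.416,
    "n_reference": 511,
}
_PEDIATRIC_REFERENCE = {
    "age": (10.90, 2.80),
    "weight": (43.60, 15.10),
    "bmi": (19.1, 3.4),
    "sex_female_fraction": 0.20,
    "n_reference": 111,
}

_HEIGHT_SD = 7.0
_BMI_SD = 2.5


def _height_curve(age: float, sex: str) -> float:
    """Synthetic mean height (cm) by age and sex, monotone in age."""
    anchors_m = {6: 116, 7: 122, 8: 128, 9: 133, 10: 138, 11: 143, 12: 149,
                 13: 156, 14: 163, 15: 169, 16: 173, 17: 175}
    anchors_f = {6: 115, 7: 121, 8: 127, 9: 132, 10: 138, 11: 144, 12: 151,
                 13: 156, 14: 159, 15: 161, 16: 162, 17: 163}
    return float((anchors_m if sex == "M" else anchors_f)[int(age)])


def _bmi_curve(age: float) -> float:
    # centered so the age-marginal mean matches the pediatric reference BMI
    return 19.1 + 0.45 * (age - 11.1)


def _pediatric_age_weights(mean: float, sd: float) -> np.ndarray:
    """Probability mass of the truncated-normal age over integer-age cells."""
    lo, hi = 6.0, 18.0
    edges = np.arange(6.0, 19.0)
    cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
    mass = np.diff(cdf)
    mass /= mass.sum()
    return mass


def synth_reference_population(
    kind: str, seed: int = 0
) -> tuple[DemographicReference, GrowthReferenceTable | None]:
    """Packaged reference summary plus (for pediatric) a synthetic growth grid.

    The adult reference carries the published adult trial column; the
    pediatric reference carries the published pediatric column together
    with a synthetic WHO-style growth grid whose height scale is calibrated
    deterministically so that the grid-implied population mean weight under
    the reference age distribution equals the reference mean weight.
    """
    if kind == "adult":
        ref = _ADULT_REFERENCE
        variables = {
            v: VariableSummary(v, *ref[v]) for v in ("age", "height", "weight")
        }
        return (
            DemographicReference(
                variables=variables,
                sex_female_fraction=ref["sex_female_fraction"],
                n_reference=ref["n_reference"],
                name="adult_reference",
            ),
            None,
        )
    if kind != "pediatric":
        raise ValueError("kind must be 'adult' or 'pediatric'")
    ref = _PEDIATRIC_REFERENCE
    variables = {v: VariableSummary(v, *ref[v]) for v in ("age", "weight", "bmi")}
    reference = DemographicReference(
        variables=variables,
        sex_female_fraction=ref["sex_female_fraction"],
        n_reference=ref["n_reference"],
        name="pediatric_reference",
    )
    # grid-implied mean weight under the reference age/sex distribution,
    # before calibration (within-cell height variance enters the BMI*h^2 product)
    ages = np.arange(6, 18)
    age_mass = _pediatric_age_weights(*ref["age"])
    sex_mix = {"F": ref["sex_female_fraction"], "M": 1 - ref["sex_female_fraction"]}
    expected_w = 0.0
    for sex, p_sex in sex_mix.items():
        for a, p_age in zip(ages, age_mass):
            h = _height_curve(a, sex)
            expected_w += p_sex * p_age * _bmi_curve(a) * (
                (h / 100.0) ** 2 + (_HEIGHT_SD / 100.0) ** 2
            )
    height_scale = math.sqrt(ref["weight"][0] / expected_w)
    rows = []
    for sex in ("F", "M"):
        for a in ages:
            h = _height_curve(a, sex) * height_scale
            b = _bmi_curve(a)
            w = b * (h / 100.0) ** 2
            w_sd = math.sqrt(
                (_BMI_SD * (h / 100.0) ** 2) ** 2
                + (b * 2 * (h / 100.0) * (_HEIGHT_SD * height_scale / 100.0)) ** 2
            )
            rows.extend(
                [
                    {"age": a, "sex": sex, "variable": "height", "mean": h,
                     "sd": _HEIGHT_SD * height_scale},
                    {"age": a, "sex": sex, "variable": "bmi", "mean": b, "sd": _BMI_SD},
                    {"age": a, "sex": sex, "variable": "weight", "mean": w, "sd": w_sd},
                ]
            )
    return reference, GrowthReferenceTable(pd.DataFrame(rows))


def standard_adult_fill() -> StandardDistributionTable:
    """European-style standard population moments used to fill gaps."""
    return StandardDistributionTable(
        {"age": (41.0, 12.0), "height": (170.0, 10.0), "weight": (75.0, 15.0),
         "bmi": (25.5, 4.5)}
    )


# ---------------------------------------------------------------------------
# Drug configurations (published dose/bioavailability/target signs;
# PK constants and EC50 values are synthetic placeholders to be fitted)
# ---------------------------------------------------------------------------

_LDX_TARGETS = (
    ("TAAR1", 1), ("SLC18A2", -1), ("SLC6A3", -1), ("SLC6A2", -1),
    ("SLC6A4", -1), ("MAOA", -1), ("MAOB", -1),
)
_MPH_TARGETS = (("SLC6A3", -1), ("SLC6A2", -1), ("HTR1A", 1))


def reference_drug_configs() -> dict[str, DrugConfig]:
    """The four study formulations with published dose/F/release values.

    EC50 values (mg/L, brain) and absorption/clearance constants are
    synthetic defaults meant to be replaced by fitted values.
    """
    ldx_ec50 = {p: 0.01 for p, _ in _LDX_TARGETS}
    mph_ec50 = {p: 0.005 for p, _ in _MPH_TARGETS}
    return {
        "ldx_adult": DrugConfig(
            name="ldx_adult", dose_mg=70.0, bioavailability=0.964,
            release="immediate", k_a=1.0, clearance_l_per_h_per_kg=0.3,
            targets=_LDX_TARGETS, ec50_mg_per_l=ldx_ec50,
        ),
        "ldx_pediatric": DrugConfig(
            name="ldx_pediatric", dose_mg=50.0, bioavailability=0.964,
            release="immediate", k_a=1.0, clearance_l_per_h_per_kg=0.3,
            targets=_LDX_TARGETS, ec50_mg_per_l=ldx_ec50,
        ),
        "mph_medikinet": DrugConfig(
            name="mph_medikinet", dose_mg=60.0, bioavailability=0.30,
            release="biphasic", release_interval_h=4.0, k_a=1.5,
            clearance_l_per_h_per_kg=0.6, targets=_MPH_TARGETS,
            ec50_mg_per_l=mph_ec50,
        ),
        "mph_concerta": DrugConfig(
            name="mph_concerta", dose_mg=36.0, bioavailability=0.32,
            release="osmotic", release_interval_h=4.0, k_a=1.5,
            clearance_l_per_h_per_kg=0.6, targets=_MPH_TARGETS,
            ec50_mg_per_l=mph_ec50,
        ),
    }
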