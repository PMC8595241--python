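"""End-to-end in-silico trial driver.

Reproduces the three-phase protocol on packaged or synthetic inputs:

* Phase I  — trial design: reference demographics, arm plan, drug configs,
  molecular definitions (network, disease signature, training set).
* Phase II — modeling: virtual populations, per-patient PBPK exposure,
  per-patient solution ensembles for both drugs under a crossover-like
  design (both drugs start from the same cloned baseline state; carryover
  is zero by construction).
* Phase III — analysis: per-drug tSignal distributions, unsupervised
  clustering of mechanism-of-action models with quality indices, local
  sensitivity ranking, and the progressive-sampling power curve.

The global seed fans out deterministically to per-stage seeds; no stage
consumes OS entropy, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import analysis as an
from . import fixtures as fx
from . import pbpk, qsp, samplesize, vpop

log = logging.getLogger("isct")

__all__ = [
    "TrialConfig",
    "TrialBundle",
    "standard_arm_plan",
    "stage_seed",
    "run_trial",
    "summarize",
]

#: Comorbidity sets of the eight comorbidity arms (synthetic stand-ins for
#: the study's psychiatric comorbidity branches).
COMORBIDITY_ARMS: tuple[frozenset[str], ...] = (
    frozenset({"depression"}),
    frozenset({"anxiety"}),
    frozenset({"bipolar"}),
    frozenset({"tics"}),
    frozenset({"binge_eating"}),
    frozenset({"depression", "anxiety"}),
    frozenset({"anxiety", "tics"}),
    frozenset({"depression", "binge_eating"}),
)


def standard_arm_plan(n_disease: int = 500, n_comorbid: int = 100) -> list[vpop.ArmSpec]:
    """Nine arms: one disease-only arm plus eight comorbidity arms."""
    arms = [vpop.ArmSpec("arm_adhd", frozenset(), n_disease)]
    for i, tags in enumerate(COMORBIDITY_ARMS, start=1):
        arms.append(vpop.ArmSpec(f"arm_comorbid_{i}", tags, n_comorbid))
    return arms


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class TrialConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    populations: tuple[str, ...] = ("adult", "pediatric")
    n_disease_arm: int = 500
    n_comorbid_arm: int = 100
    # exposure sampling
    t_end_h: float = 24.0
    brain_timepoints: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0, 12.0)
    # molecular fixture sizes
    network_nodes: int = 60
    network_edges: int = 120
    n_effectors: int = 12
    training_size: int = 4
    qsp: qsp.QSPConfig = field(default_factory=qsp.QSPConfig)
    # analysis
    cluster_k_range: tuple[int, ...] = tuple(range(2, 8))
    sensitivity_top: int = 30
    # sample-size stage (synthetic expression scale)
    expression_cohort: int = 30
    expression_genes: int = 120
    expression_informative: int = 15
    expression_effect: float = 1.5
    power_reps: int = 100
    out_dir: str | None = None

    @classmethod
    def demo(cls, seed: int = 0) -> "TrialConfig":
        """Desk-scale configuration: small arms, small ensembles."""
        return cls(
            seed=seed,
            n_disease_arm=10,
            n_comorbid_arm=2,
            qsp=qsp.QSPConfig(ensemble_min=8, attempt_budget=200),
            expression_cohort=16,
            power_reps=20,
        )

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "qsp"}
            | {"qsp": self.qsp.__dict__},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrialBundle:
    """All artifacts of one run, keyed by population."""

    config: TrialConfig
    populations: dict[str, vpop.VirtualPopulation]
    network: qsp.ProteinNetwork
    definition: qsp.DiseaseDefinition
    drugs: dict[str, tuple[qsp.DrugTargetProfile, qsp.DrugTargetProfile]]
    ensembles: dict[str, list[qsp.SolutionEnsemble]]
    tsignals: pd.DataFrame  # columns: population, patient_id, drug, tsignal
    clustering: dict[str, an.ClusteringResult]
    comparisons: dict[str, an.ComparisonReport]
    sensitivity: dict[str, list[tuple[str, float, bool]]]
    power_curve: samplesize.PowerCurve
    required_n: dict[int, tuple[int, int] | None]


def _simulate_exposure(
    patient: vpop.VirtualPatient,
    drug_cfg: pbpk.DrugConfig,
    timepoints: Sequence[float],
    t_end: float,
) -> np.ndarray:
    params = pbpk.individualize_parameters(patient, drug_cfg)
    scheme = pbpk.expand_extended_release(drug_cfg)
    profile = pbpk.simulate(params, scheme, t_end, rtol=1e-6, atol=1e-9, grid_step=0.25)
    return pbpk.tissue_timepoints(profile, "brain", timepoints)


def run_trial(config: TrialConfig) -> TrialBundle:
    """Execute the full three-phase protocol for the configured populations."""
    t0 = time.time()
    arms = standard_arm_plan(config.n_disease_arm, config.n_comorbid_arm)
    n_per_pop = sum(a.size for a in arms)

    # Phase I: molecular characterization (synthetic satisfiable fixture)
    net, definition, drug_a, drug_b, training = fx.synth_network_with_definitions(
        n_nodes=config.network_nodes,
        n_edges=config.network_edges,
        n_effectors=config.n_effectors,
        training_size=config.training_size,
        seed=stage_seed(config.seed, "network"),
        config=config.qsp,
    )
    comorbidity_defs = _comorbidity_definitions(net, definition)
    drug_cfgs = fx.reference_drug_configs()
    pairing = {
        "adult": ("ldx_adult", "mph_medikinet"),
        "pediatric": ("ldx_pediatric", "mph_concerta"),
    }
    profiles = {"drugA": drug_a, "drugB": drug_b}

    # Phase II: populations, exposure, ensembles
    populations: dict[str, vpop.VirtualPopulation] = {}
    ensembles: dict[str, list[qsp.SolutionEnsemble]] = {}
    ts_rows = []
    for kind in config.populations:
        reference, growth = fx.synth_reference_population(kind)
        pop_seed = stage_seed(config.seed, f"vpop:{kind}")
        if kind == "adult":
            pop = vpop.generate_adult_vpop(reference, n=n_per_pop, seed=pop_seed)
        else:
            pop = vpop.generate_pediatric_vpop(reference, growth, n=n_per_pop, seed=pop_seed)
        pop = vpop.assign_arms(pop, arms, seed=stage_seed(config.seed, f"arms:{kind}"))
        populations[kind] = pop
        log.info("phase II: %s population of %d generated (%.1fs)",
                 kind, len(pop), time.time() - t0)

        pop_ensembles: list[qsp.SolutionEnsemble] = []
        for patient in pop.patients:
            patient_seed = stage_seed(config.seed, f"qsp:{kind}:{patient.id}")
            comorbid = [comorbidity_defs[t] for t in sorted(patient.comorbidity_tags)
                        if t in comorbidity_defs]
            for drug_key, profile in profiles.items():
                cfg_name = pairing[kind][0 if drug_key == "drugA" else 1]
                drug_cfg = drug_cfgs[cfg_name]
                exposure = _simulate_exposure(
                    patient, drug_cfg, config.brain_timepoints, config.t_end_h
                )
                ec50 = {p: 0.5 * max(exposure.max(), 1e-9) for p, _ in profile.targets}
                modulation = qsp.target_modulation(
                    exposure,
                    profile,
                    ec50,
                    hill=config.qsp.hill,
                    aggregate=config.qsp.aggregate,
                )
                # crossover-like design: both drugs replay the identical
                # per-patient perturbation stream (cloned baseline state)
                ens = qsp.sample_ensemble(
                    patient.id, drug_key, net, training, modulation,
                    config=config.qsp, seed=patient_seed, comorbidities=comorbid,
                )
                pop_ensembles.append(ens)
                ts_rows.append(
                    {
                        "population": kind,
                        "patient_id": patient.id,
                        "drug": drug_key,
                        "tsignal": ens.mean_tsignal(definition),
                    }
                )
        ensembles[kind] = pop_ensembles
        log.info("phase II: %s ensembles done (%.1fs)", kind, time.time() - t0)

    tsignals = pd.DataFrame(ts_rows)

    # Phase III: clustering, comparisons, sensitivity, power curve
    clustering: dict[str, an.ClusteringResult] = {}
    comparisons: dict[str, an.ComparisonReport] = {}
    effectors = [p for p, _ in definition.proteins]
    for kind in config.populations:
        rows, drugs_of_rows, demo_rows, ts_of_rows = [], [], [], []
        by_patient = {p.id: p for p in populations[kind].patients}
        for ens in ensembles[kind]:
            mean_activity = pd.DataFrame(
                [dict(s.values) for s in ens.solutions]
            ).mean()
            rows.append(mean_activity[effectors].to_numpy())
            drugs_of_rows.append(ens.drug)
            patient = by_patient[ens.patient_id]
            demo_rows.append(
                {"age": patient.age, "height": patient.height,
                 "weight": patient.weight, "bmi": patient.bmi}
            )
            ts_of_rows.append(ens.mean_tsignal(definition))
        matrix = np.vstack(rows)
        try:
            result = an.select_optimal_k(
                matrix,
                k_range=config.cluster_k_range,
                seed=stage_seed(config.seed, f"cluster:{kind}"),
                composition=drugs_of_rows,
            )
            clustering[kind] = result
            values = pd.DataFrame(demo_rows)
            values["tsignal"] = ts_of_rows
            comparisons[kind] = an.compare_clusters(values, result.labels)
        except (an.NoValidClusteringError, ValueError) as err:
            log.warning("phase III: clustering skipped for %s: %s", kind, err)

    sensitivity: dict[str, list[tuple[str, float, bool]]] = {}
    for drug_key, profile in profiles.items():
        stim = {p: float(e) for p, e in profile.targets}
        sens = an.sensitivity_profile(net, stim, definition, config=config.qsp)
        sensitivity[drug_key] = an.rank_sensitive_proteins(
            sens, top=config.sensitivity_top
        )

    expr = fx.synth_expression(
        n_control=config.expression_cohort,
        n_case=config.expression_cohort,
        n_genes=config.expression_genes,
        n_informative=config.expression_informative,
        effect=config.expression_effect,
        seed=stage_seed(config.seed, "expression"),
    )
    curve = samplesize.progressive_curve(
        expr, reps=config.power_reps, seed=stage_seed(config.seed, "power")
    )
    required = {p: samplesize.required_sample_size(curve, power=p) for p in (95, 99)}
    log.info("phase III done (%.1fs)", time.time() - t0)

    bundle = TrialBundle(
        config=config,
        populations=populations,
        network=net,
        definition=definition,
        drugs={k: (drug_a, drug_b) for k in config.populations},
        ensembles=ensembles,
        tsignals=tsignals,
        clustering=clustering,
        comparisons=comparisons,
        sensitivity=sensitivity,
        power_curve=curve,
        required_n=required,
    )
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _comorbidity_definitions(
    network: qsp.ProteinNetwork, definition: qsp.DiseaseDefinition
) -> dict[str, qsp.DiseaseDefinition]:
    """Synthetic comorbidity signatures on nodes outside the disease set."""
    used = {p for p, _ in definition.proteins}
    free = [n for n in network.nodes if n not in used]
    out = {}
    names = sorted({t for tags in COMORBIDITY_ARMS for t in tags})
    for i, name in enumerate(names):
        chunk = free[3 * i : 3 * i + 3]
        if not chunk:
            break
        out[name] = qsp.DiseaseDefinition(
            name=name, proteins=tuple((p, 1 if j % 2 == 0 else -1) for j, p in enumerate(chunk))
        )
    return out


def _write_bundle(bundle: TrialBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": bundle.config.content_hash(), "seed": bundle.config.seed}
    for kind, pop in bundle.populations.items():
        vpop.write_population(pop, out / f"population_{kind}.tsv")
    bundle.tsignals.to_csv(out / "tsignals.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps({**stamp, **summarize(bundle)},
                                                indent=2, default=str))


def summarize(bundle: TrialBundle) -> dict:
    """Machine-readable trial report; flags any missing analysis stage."""
    report: dict = {
        "n_patients_total": sum(len(p) for p in bundle.populations.values()),
        "arms": {
            kind: dict(pd.Series([p.arm_id for p in pop.patients]).value_counts())
            for kind, pop in bundle.populations.items()
        },
        "tsignal_by_drug": {},
        "clusters": {},
        "sensitivity_top": {},
        "power": {},
        "warnings": [],
    }
    if len(bundle.tsignals):
        grouped = bundle.tsignals.groupby(["population", "drug"])["tsignal"]
        report["tsignal_by_drug"] = {
            f"{pop}:{drug}": {"mean": float(g.mean()), "sd": float(g.std(ddof=0))}
            for (pop, drug), g in grouped
        }
    else:
        report["warnings"].append("no tSignal table")
    for kind, res in bundle.clustering.items():
        report["clusters"][kind] = {
            "k": res.k,
            "hopkins": res.hopkins,
            "silhouette": res.silhouette,
            "jaccard": [float(j) for j in res.jaccard],
            "explained_variance": [float(v) for v in res.explained_variance],
        }
    if not bundle.clustering:
        report["warnings"].append("clustering section empty")
    for drug, ranked in bundle.sensitivity.items():
        report["sensitivity_top"][drug] = [
            {"protein": p, "pct": v, "real_impact": flag} for p, v, flag in ranked
        ]
    if not bundle.sensitivity:
        report["warnings"].append("sensitivity section empty")
    report["power"] = {
        "max_accuracy": bundle.power_curve.max_accuracy,
        "required_n": {
            str(p): (list(v) if v is not None else None)
            for p, v in bundle.required_n.items()
        },
    }
    return report
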