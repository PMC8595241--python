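"""Virtual population synthesis.

Generates adult and pediatric-adolescent virtual populations whose joint
demographics (age, height, weight, BMI, sex) mimic a reference population
summary (means/SDs/sex proportion), and allocates patients to trial arms.

Adults are drawn from a multivariate normal built on the reference moments
and polished with simulated annealing until a one-sample z-test cannot
distinguish the sample from the reference.  Pediatric-adolescent patients
are sampled with a Metropolis-Hastings random walk whose target couples the
reference summary with an age-sex growth reference table, so that height
and weight stay anthropometrically consistent with age.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MORPHOMETRIC_VARIABLES",
    "VariableSummary",
    "DemographicReference",
    "StandardDistributionTable",
    "GrowthReferenceTable",
    "VirtualPatient",
    "VirtualPopulation",
    "ArmSpec",
    "MVNDSpec",
    "AnnealConfig",
    "MHConfig",
    "UnresolvableVariableError",
    "NonConvergenceError",
    "AllocationError",
    "build_mvnd",
    "generate_adult_vpop",
    "generate_pediatric_vpop",
    "validate_population",
    "assign_arms",
    "population_to_frame",
    "write_population",
    "read_reference",
    "read_growth_table",
]

#: Morphometric variables a reference summary may constrain.  BMI is always
#: derived from height and weight, never sampled independently.
MORPHOMETRIC_VARIABLES = ("age", "height", "weight", "bmi")

#: Variables that enter the sampling state; BMI is a function of the others
#: for adults (pediatric sampling carries BMI in the state and derives weight).
SAMPLED_VARIABLES = ("age", "height", "weight")

ADULT_MIN_AGE = 18.0
PEDIATRIC_AGE_RANGE = (6.0, 18.0)


class UnresolvableVariableError(ValueError):
    """A targeted variable has moments in neither the reference nor the fill."""


class NonConvergenceError(RuntimeError):
    """The acceptance loop exhausted its restarts without passing validation."""

    def __init__(self, message: str, best_cost: float):
        super().__init__(message)
        self.best_cost = best_cost


class AllocationError(ValueError):
    """Arm sizes do not partition the population."""


class CoverageError(KeyError):
    """Growth reference table does not cover a requested age-sex cell."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableSummary:
    """Mean/SD summary of one morphometric variable."""

    name: str
    mean: float
    sd: float
    available: bool = True
    filled: bool = False

    def __post_init__(self):
        if self.name not in MORPHOMETRIC_VARIABLES:
            raise ValueError(f"unknown variable {self.name!r}")
        if self.available and not (self.sd >= 0 and math.isfinite(self.sd)):
            raise ValueError(f"{self.name}: sd must be finite and >= 0")


@dataclass(frozen=True)
class DemographicReference:
    """Reference population summary to be mimicked.

    ``variables`` maps variable name to its :class:`VariableSummary`;
    unavailable variables may be listed with ``available=False`` or simply
    omitted.  ``sex_female_fraction`` is matched exactly by quota.
    """

    variables: Mapping[str, VariableSummary]
    sex_female_fraction: float
    n_reference: int = 0
    name: str = "reference"

    def __post_init__(self):
        if not 0.0 <= self.sex_female_fraction <= 1.0:
            raise ValueError("sex_female_fraction must lie in [0, 1]")
        if not any(v.available for v in self.variables.values()):
            raise ValueError("at least one variable must be available")

    @property
    def available(self) -> tuple[str, ...]:
        return tuple(
            v for v in MORPHOMETRIC_VARIABLES
            if v in self.variables and self.variables[v].available
        )

    def summary(self, name: str) -> VariableSummary:
        return self.variables[name]

    @classmethod
    def from_dict(cls, d: Mapping) -> "DemographicReference":
        variables = {
            v["name"]: VariableSummary(v["name"], float(v["mean"]), float(v["sd"]))
            for v in d["variables"]
        }
        return cls(
            variables=variables,
            sex_female_fraction=float(d["sex_female_fraction"]),
            n_reference=int(d.get("n_reference", 0)),
            name=str(d.get("name", "reference")),
        )

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "variables": {
                    k: (v.mean, v.sd, v.available) for k, v in sorted(self.variables.items())
                },
                "sex_female_fraction": self.sex_female_fraction,
                "n_reference": self.n_reference,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class StandardDistributionTable:
    """Fallback moments used to fill variables missing from a reference."""

    moments: Mapping[str, tuple[float, float]]  # name -> (mean, sd)

    def lookup(self, name: str) -> tuple[float, float]:
        try:
            return self.moments[name]
        except KeyError:
            raise UnresolvableVariableError(
                f"variable {name!r} absent from both reference and fill table"
            ) from None


class GrowthReferenceTable:
    """Age-sex growth reference (WHO-style mean/SD per morphometric variable).

    Backed by a tidy DataFrame with columns (age, sex, variable, mean, sd);
    lookups condition on sex and the nearest integer age.
    """

    REQUIRED_AGES = range(6, 18)

    def __init__(self, frame: pd.DataFrame):
        required = {"age", "sex", "variable", "mean", "sd"}
        if not required.issubset(frame.columns):
            raise ValueError(f"growth table needs columns {sorted(required)}")
        if (frame["sd"] <= 0).any():
            raise ValueError("growth table sd must be > 0")
        self.frame = frame.copy()
        self._cells = {
            (int(r.age), str(r.sex), str(r.variable)): (float(r["mean"]), float(r.sd))
            for _, r in frame.iterrows()
        }

    def check_coverage(self, variables: Iterable[str] = ("height", "weight", "bmi")):
        for age in self.REQUIRED_AGES:
            for sex in ("F", "M"):
                for var in variables:
                    if (age, sex, var) not in self._cells:
                        raise CoverageError(
                            f"growth table missing cell age={age} sex={sex} variable={var}"
                        )

    def cell(self, age: float, sex: str, variable: str) -> tuple[float, float]:
        # nearest integer age, clamped into the covered 6-17 band so that
        # continuous ages just under 18 use the oldest cell
        age_key = min(max(int(round(age)), self.REQUIRED_AGES[0]), self.REQUIRED_AGES[-1])
        key = (age_key, sex, variable)
        if key not in self._cells:
            raise CoverageError(f"growth table missing cell {key}")
        return self._cells[key]


@dataclass(frozen=True)
class VirtualPatient:
    """One simulated individual; the unit of all downstream modeling."""

    id: str
    sex: str  # 'F' or 'M'
    age: float  # years
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2, always weight / (height/100)^2
    comorbidity_tags: frozenset[str] = frozenset()
    arm_id: str = ""

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        expected = self.weight / (self.height / 100.0) ** 2
        if abs(self.bmi - expected) > 1e-6 * max(1.0, abs(expected)):
            raise ValueError("bmi inconsistent with height and weight")


@dataclass
class VirtualPopulation:
    """A set of virtual patients plus generation provenance."""

    patients: list[VirtualPatient]
    population_kind: str  # 'adult' or 'pediatric'
    seed: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.patients:
            raise ValueError("population must be non-empty")
        if self.population_kind not in ("adult", "pediatric"):
            raise ValueError("population_kind must be 'adult' or 'pediatric'")
        lo, hi = (ADULT_MIN_AGE, math.inf) if self.population_kind == "adult" else PEDIATRIC_AGE_RANGE
        for p in self.patients:
            if not (lo <= p.age < hi if math.isfinite(hi) else p.age > lo):
                raise ValueError(
                    f"patient {p.id} age {p.age:.2f} outside {self.population_kind} bounds"
                )

    def __len__(self) -> int:
        return len(self.patients)

    def values(self, variable: str) -> np.ndarray:
        return np.array([getattr(p, variable) for p in self.patients], dtype=float)


@dataclass(frozen=True)
class ArmSpec:
    """One trial arm: its comorbidity set (empty = disease-only) and size."""

    arm_id: str
    comorbidity_set: frozenset[str]
    size: int

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("arm size must be > 0")


@dataclass(frozen=True)
class MVNDSpec:
    """Multivariate normal over the sampled variables (age, height, weight).

    BMI never enters the MVND; if the reference constrains BMI its moments
    are kept as a derived-variable constraint used by the annealing cost.
    """

    variables: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    filled: tuple[str, ...] = ()
    bmi_constraint: tuple[float, float] | None = None

    def __post_init__(self):
        cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-9 * max(1.0, eigvals.max()):
            raise ValueError("covariance must be positive semi-definite")


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing schedule for the adult generator."""

    iterations: int = 200
    max_restarts: int = 20
    t_initial: float = 1.0
    cooling: float = 0.95
    height_weight_corr: float = 0.5
    alpha: float = 0.05


@dataclass(frozen=True)
class MHConfig:
    """Metropolis-Hastings settings for the pediatric generator."""

    burn_in: int = 1000
    thinning: int = 10
    step_frac: float = 0.5  # proposal step as a fraction of each variable's sd
    max_restarts: int = 20
    growth_sd_bound: float = 4.0  # hard consistency bound vs the age-sex cell
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# MVND construction
# ---------------------------------------------------------------------------


def build_mvnd(
    reference: DemographicReference,
    fill: StandardDistributionTable | None = None,
    height_weight_corr: float = 0.5,
) -> MVNDSpec:
    """Build the sampling MVND from reference moments, filling gaps.

    Missing sampled variables take their moments from ``fill`` and are
    flagged as filled.  The reference's BMI moments, if present, become a
    derived-variable constraint rather than an MVND dimension.  Cross
    correlations default to 0 except height-weight.
    """
    means, sds, filled = [], [], []
    for name in SAMPLED_VARIABLES:
        if name in reference.variables and reference.variables[name].available:
            s = reference.variables[name]
            means.append(s.mean)
            sds.append(s.sd)
        else:
            if fill is None:
                raise UnresolvableVariableError(
                    f"variable {name!r} absent from reference and no fill table given"
                )
            m, sd = fill.lookup(name)
            means.append(m)
            sds.append(sd)
            filled.append(name)
    sds = np.array(sds, dtype=float)
    corr = np.eye(len(SAMPLED_VARIABLES))
    ih, iw = SAMPLED_VARIABLES.index("height"), SAMPLED_VARIABLES.index("weight")
    corr[ih, iw] = corr[iw, ih] = height_weight_corr
    cov = corr * np.outer(sds, sds)
    bmi_constraint = None
    if "bmi" in reference.variables and reference.variables["bmi"].available:
        s = reference.variables["bmi"]
        bmi_constraint = (s.mean, s.sd)
    return MVNDSpec(
        variables=SAMPLED_VARIABLES,
        mean=np.array(means, dtype=float),
        cov=cov,
        filled=tuple(filled),
        bmi_constraint=bmi_constraint,
    )


# ---------------------------------------------------------------------------
# Validation (one-sample z-test acceptance rule)
# ---------------------------------------------------------------------------


def validate_population(
    pop: VirtualPopulation | Mapping[str, np.ndarray],
    reference: DemographicReference,
    alpha: float = 0.05,
) -> dict:
    """One-sample z-test of each available reference variable.

    z = (x_bar - mu) / (sigma / sqrt(n)) with two-sided normal p-value;
    a variable passes iff p > alpha, the population iff all variables pass.
    """
    results: dict = {"variables": {}, "alpha": alpha}
    overall = True
    for name in reference.available:
        x = pop.values(name) if isinstance(pop, VirtualPopulation) else np.asarray(pop[name])
        n = x.size
        if n == 0:
            raise ValueError("empty population")
        s = reference.summary(name)
        if s.sd == 0:
            z = 0.0 if np.allclose(x.mean(), s.mean) else math.inf
        else:
            z = (x.mean() - s.mean) / (s.sd / math.sqrt(n))
        p = 2.0 * stats.norm.sf(abs(z))
        ok = bool(p > alpha)
        results["variables"][name] = {"z": float(z), "p": float(p), "pass": ok}
        overall &= ok
    results["pass"] = overall
    return results


def _population_cost(
    samples: np.ndarray, reference: DemographicReference, variables: tuple[str, ...]
) -> float:
    """Sum of squared standardized deviations of sample means and SDs.

    Means are standardized by sigma/sqrt(n) and SDs by their asymptotic
    standard error sigma/sqrt(2n); BMI is evaluated on the derived column.
    """
    n = samples.shape[0]
    cost = 0.0
    cols = dict(zip(SAMPLED_VARIABLES, samples.T))
    cols["bmi"] = cols["weight"] / (cols["height"] / 100.0) ** 2
    for name in reference.available:
        s = reference.summary(name)
        x = cols[name]
        if s.sd == 0:
            if not np.allclose(x, s.mean):
                cost += 1e12
            continue
        cost += ((x.mean() - s.mean) / (s.sd / math.sqrt(n))) ** 2
        cost += ((x.std(ddof=1) - s.sd) / (s.sd / math.sqrt(2 * n))) ** 2 if n > 1 else 0.0
    return cost


# ---------------------------------------------------------------------------
# Adult generator: MVND draws + simulated annealing
# ---------------------------------------------------------------------------


def _draw_adult(rng: np.random.Generator, spec: MVNDSpec, size: int) -> np.ndarray:
    """Draw from the MVND truncated to physically admissible adults."""
    out = np.empty((size, len(spec.variables)))
    have = 0
    degenerate = np.allclose(spec.cov, 0.0)
    while have < size:
        block = rng.multivariate_normal(spec.mean, spec.cov, size=max(size - have, 16),
                                        method="cholesky" if not degenerate else "svd")
        ok = (block[:, 0] > ADULT_MIN_AGE) & (block[:, 1] > 50.0) & (block[:, 2] > 20.0)
        if degenerate:
            ok = np.ones(block.shape[0], dtype=bool)
        take = block[ok][: size - have]
        out[have : have + take.shape[0]] = take
        have += take.shape[0]
    return out


def _quota_female(n: int, fraction: float) -> int:
    # round-half-up sex quota
    return int(math.floor(n * fraction + 0.5))


def _assemble_patients(
    samples: np.ndarray, rng: np.random.Generator, female_fraction: float, prefix: str
) -> list[VirtualPatient]:
    n = samples.shape[0]
    n_f = _quota_female(n, female_fraction)
    sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sexes)
    patients = []
    width = max(4, len(str(n)))
    for i, ((age, height, weight), sex) in enumerate(zip(samples, sexes)):
        patients.append(
            VirtualPatient(
                id=f"{prefix}{i + 1:0{width}d}",
                sex=str(sex),
                age=float(age),
                height=float(height),
                weight=float(weight),
                bmi=float(weight / (height / 100.0) ** 2),
            )
        )
    return patients


def generate_adult_vpop(
    reference: DemographicReference,
    fill: StandardDistributionTable | None = None,
    n: int = 500,
    seed: int = 0,
    config: AnnealConfig = AnnealConfig(),
) -> VirtualPopulation:
    """Generate ``n`` adults matching the reference summary.

    Draws a candidate population from the MVND, then runs simulated
    annealing on patient-replacement moves to minimize the standardized
    moment-mismatch cost.  A candidate is returned only once every targeted
    variable passes the one-sample z-test at ``config.alpha``; otherwise the
    whole population is resampled, up to ``config.max_restarts`` times.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = build_mvnd(reference, fill, config.height_weight_corr)
    rng = np.random.default_rng(seed)
    best_cost = math.inf
    for _restart in range(config.max_restarts):
        samples = _draw_adult(rng, spec, n)
        cost = _population_cost(samples, reference, spec.variables)
        temperature = config.t_initial
        for _ in range(config.iterations):
            idx = rng.integers(n)
            proposal = samples.copy()
            proposal[idx] = _draw_adult(rng, spec, 1)[0]
            new_cost = _population_cost(proposal, reference, spec.variables)
            delta = new_cost - cost
            if delta <= 0 or rng.random() < math.exp(-delta / max(temperature, 1e-12)):
                samples, cost = proposal, new_cost
            temperature *= config.cooling
        best_cost = min(best_cost, cost)
        check = validate_population(
            {
                "age": samples[:, 0],
                "height": samples[:, 1],
                "weight": samples[:, 2],
                "bmi": samples[:, 2] / (samples[:, 1] / 100.0) ** 2,
            },
            reference,
            config.alpha,
        )
        if check["pass"]:
            patients = _assemble_patients(samples, rng, reference.sex_female_fraction, "A")
            return VirtualPopulation(
                patients=patients,
                population_kind="adult",
                seed=seed,
                provenance={
                    "reference": reference.name,
                    "reference_hash": reference.content_hash(),
                    "filled_variables": list(spec.filled),
                    "validation": check,
                    "anneal_cost": cost,
                    "restarts_used": _restart + 1,
                },
            )
    raise NonConvergenceError(
        f"adult generator failed validation after {config.max_restarts} restarts",
        best_cost=best_cost,
    )


# ---------------------------------------------------------------------------
# Pediatric generator: Metropolis-Hastings on (age, height, bmi)
# ---------------------------------------------------------------------------


def _pediatric_logpdf(
    state: np.ndarray,
    sex: str,
    reference: DemographicReference,
    growth: GrowthReferenceTable,
    bound: float,
) -> float:
    """Unnormalized log target density for one pediatric patient.

    The target multiplies (i) Gaussian terms for every available reference
    variable evaluated on the state's realized values, and (ii) Gaussian
    growth-consistency terms for height and BMI conditioned on the nearest
    integer age and the patient's sex, truncated at ``bound`` SDs.
    """
    age, height, bmi = state
    lo, hi = PEDIATRIC_AGE_RANGE
    if not (lo <= age < hi) or height <= 0 or bmi <= 0:
        return -math.inf
    weight = bmi * (height / 100.0) ** 2
    realized = {"age": age, "height": height, "weight": weight, "bmi": bmi}
    logp = 0.0
    for name in reference.available:
        s = reference.summary(name)
        if s.sd > 0:
            logp += -0.5 * ((realized[name] - s.mean) / s.sd) ** 2
    for var, value in (("height", height), ("bmi", bmi)):
        m, sd = growth.cell(age, sex, var)
        zc = (value - m) / sd
        if abs(zc) > bound:
            return -math.inf
        logp += -0.5 * zc ** 2
    wm, wsd = growth.cell(age, sex, "weight")
    if abs(weight - wm) > bound * wsd:
        return -math.inf
    return logp


def _compensate_age_truncation(reference: DemographicReference) -> DemographicReference:
    """Shift the age target so its [6, 18)-truncated mean equals the reference.

    The pediatric age window clips the upper tail of a wide reference
    normal, which would bias the realized mean upward; the chain therefore
    targets a normal whose truncated mean matches the reference mean.
    """
    if "age" not in reference.variables or not reference.variables["age"].available:
        return reference
    s = reference.summary("age")
    if s.sd <= 0:
        return reference
    lo, hi = PEDIATRIC_AGE_RANGE

    def truncated_mean(mu: float) -> float:
        a, b = (lo - mu) / s.sd, (hi - mu) / s.sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=s.sd))

    from scipy.optimize import brentq

    try:
        mu_adj = brentq(
            lambda m: truncated_mean(m) - s.mean, s.mean - 2 * s.sd, s.mean + s.sd
        )
    except ValueError:
        return reference
    variables = dict(reference.variables)
    variables["age"] = VariableSummary("age", float(mu_adj), s.sd)
    return replace(reference, variables=variables)


def _run_pediatric_chain(
    rng: np.random.Generator,
    sex: str,
    n_keep: int,
    reference: DemographicReference,
    growth: GrowthReferenceTable,
    config: MHConfig,
) -> np.ndarray:
    """Random-walk MH chain for one sex; returns kept (age, height, bmi) rows."""
    age_ref = reference.summary("age") if "age" in reference.variables else None
    age0 = age_ref.mean if age_ref is not None else 11.0
    age0 = min(max(age0, PEDIATRIC_AGE_RANGE[0] + 0.5), PEDIATRIC_AGE_RANGE[1] - 0.5)
    h0, hsd = growth.cell(age0, sex, "height")
    b0, bsd = growth.cell(age0, sex, "bmi")
    state = np.array([age0, h0, b0])
    steps = config.step_frac * np.array(
        [age_ref.sd if age_ref is not None and age_ref.sd > 0 else 2.0, hsd, bsd]
    )
    logp = _pediatric_logpdf(state, sex, reference, growth, config.growth_sd_bound)
    kept = np.empty((n_keep, 3))
    have = 0
    total = config.burn_in + n_keep * config.thinning
    for step in range(total):
        j = rng.integers(3)
        proposal = state.copy()
        proposal[j] += rng.normal(0.0, steps[j])
        logp_new = _pediatric_logpdf(proposal, sex, reference, growth, config.growth_sd_bound)
        if logp_new - logp > math.log(rng.random() + 1e-300):
            state, logp = proposal, logp_new
        if step >= config.burn_in and (step - config.burn_in) % config.thinning == 0:
            kept[have] = state
            have += 1
            if have == n_keep:
                break
    return kept[:have]


def generate_pediatric_vpop(
    reference: DemographicReference,
    growth: GrowthReferenceTable,
    n: int = 500,
    seed: int = 0,
    config: MHConfig = MHConfig(),
) -> VirtualPopulation:
    """Generate ``n`` pediatric-adolescent patients aged 6-17.

    Sex is fixed by quota first; a Metropolis-Hastings chain per sex samples
    (age, height, BMI) from the coupled reference/growth target, weight being
    derived as BMI x (height/100)^2.  The population is accepted only when
    every targeted variable passes the one-sample z-test; otherwise the
    chains are re-run with fresh randomness, up to ``config.max_restarts``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    growth.check_coverage()
    best_cost = math.inf
    rng = np.random.default_rng(seed)
    n_f = _quota_female(n, reference.sex_female_fraction)
    chain_target = _compensate_age_truncation(reference)
    for _restart in range(config.max_restarts):
        rows, sexes = [], []
        for sex, count in (("F", n_f), ("M", n - n_f)):
            if count == 0:
                continue
            kept = _run_pediatric_chain(rng, sex, count, chain_target, growth, config)
            if kept.shape[0] < count:
                raise NonConvergenceError("pediatric chain too short", best_cost=math.inf)
            rows.append(kept)
            sexes.extend([sex] * count)
        states = np.vstack(rows)
        age = states[:, 0]
        height = states[:, 1]
        bmi = states[:, 2]
        weight = bmi * (height / 100.0) ** 2
        columns = {"age": age, "height": height, "weight": weight, "bmi": bmi}
        check = validate_population(columns, reference, config.alpha)
        cost = sum(v["z"] ** 2 for v in check["variables"].values())
        best_cost = min(best_cost, cost)
        if check["pass"]:
            order = rng.permutation(n)
            width = max(4, len(str(n)))
            patients = [
                VirtualPatient(
                    id=f"P{i + 1:0{width}d}",
                    sex=sexes[k],
                    age=float(age[k]),
                    height=float(height[k]),
                    weight=float(weight[k]),
                    bmi=float(bmi[k]),
                )
                for i, k in enumerate(order)
            ]
            return VirtualPopulation(
                patients=patients,
                population_kind="pediatric",
                seed=seed,
                provenance={
                    "reference": reference.name,
                    "reference_hash": reference.content_hash(),
                    "validation": check,
                    "restarts_used": _restart + 1,
                },
            )
    raise NonConvergenceError(
        f"pediatric generator failed validation after {config.max_restarts} restarts",
        best_cost=best_cost,
    )


# ---------------------------------------------------------------------------
# Arm allocation
# ---------------------------------------------------------------------------


def assign_arms(
    pop: VirtualPopulation, arms: Sequence[ArmSpec], seed: int = 0
) -> VirtualPopulation:
    """Randomly partition the population into the given arms.

    A partition without replacement: each patient lands in exactly one arm,
    arm sizes are met exactly, and the arm's comorbidity set is copied onto
    the patient as tags.
    """
    total = sum(a.size for a in arms)
    if total != len(pop):
        raise AllocationError(
            f"arm sizes sum to {total} but population has {len(pop)} patients"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pop))
    assigned: list[VirtualPatient | None] = [None] * len(pop)
    cursor = 0
    for arm in arms:
        for k in order[cursor : cursor + arm.size]:
            p = pop.patients[k]
            assigned[k] = replace(
                p, arm_id=arm.arm_id, comorbidity_tags=frozenset(arm.comorbidity_set)
            )
        cursor += arm.size
    return VirtualPopulation(
        patients=[p for p in assigned if p is not None],
        population_kind=pop.population_kind,
        seed=pop.seed,
        provenance={**pop.provenance, "arms": {a.arm_id: a.size for a in arms},
                    "arm_seed": seed},
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def population_to_frame(pop: VirtualPopulation) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in pop.patients],
            "sex": [p.sex for p in pop.patients],
            "age": [p.age for p in pop.patients],
            "height_cm": [p.height for p in pop.patients],
            "weight_kg": [p.weight for p in pop.patients],
            "bmi": [p.bmi for p in pop.patients],
            "arm_id": [p.arm_id for p in pop.patients],
            "tags": [";".join(sorted(p.comorbidity_tags)) for p in pop.patients],
        }
    )


def write_population(pop: VirtualPopulation, path: str | Path, sep: str = "\t") -> None:
    """Write the population table plus a JSON provenance sidecar."""
    path = Path(path)
    population_to_frame(pop).to_csv(path, sep=sep, index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(
        json.dumps(
            {"seed": pop.seed, "population_kind": pop.population_kind, **pop.provenance},
            indent=2,
            default=str,
        )
    )


def read_reference(path: str | Path) -> DemographicReference:
    """Read a demographic reference from a JSON (or YAML) config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return DemographicReference.from_dict(data)


def read_growth_table(path: str | Path, sep: str = "\t") -> GrowthReferenceTable:
    return GrowthReferenceTable(pd.read_csv(path, sep=sep))
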