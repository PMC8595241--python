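"""Individualized physiologically based pharmacokinetics.

A 14-compartment whole-body model with blood as the unique central hub:
every organ exchanges drug with blood through its blood flow, dosing enters
at gut (oral), blood (intravenous) or skin (subcutaneous), and elimination
is restricted to gut, liver and kidneys.  Organ volumes and flows are
scaled allometrically from each virtual patient's weight, age and sex, so
that every patient owns a personal parameter set.

The kinetics are linear: a first-order absorption depot feeds blood, organs
equilibrate with blood flow-limited (unit partitioning by default), and the
three clearance sites remove drug at a rate proportional to blood
concentration (plasma-clearance convention), each site's cumulative cleared
amount being tracked for mass balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .vpop import VirtualPatient

__all__ = [
    "DEFAULT_COMPARTMENTS",
    "DEFAULT_ALLOMETRIC_TABLE",
    "CompartmentModelSpec",
    "AllometricTable",
    "DrugConfig",
    "IndividualPBPKParams",
    "DosingScheme",
    "ConcentrationProfile",
    "PKObservations",
    "FitResult",
    "IntegrationError",
    "FitError",
    "individualize_parameters",
    "expand_extended_release",
    "simulate",
    "fit_absorption_clearance",
    "tissue_timepoints",
    "read_pk_observations",
]

DEFAULT_COMPARTMENTS = (
    "blood", "gut", "liver", "kidneys", "brain", "heart", "lungs",
    "muscle", "adipose", "skin", "bone", "spleen", "pancreas", "rest",
)
CLEARANCE_SITES = ("gut", "liver", "kidneys")
DOSING_SITES = ("gut", "blood", "skin")


class IntegrationError(RuntimeError):
    pass


class FitError(RuntimeError):
    pass


class CoverageError(KeyError):
    """Patient demographics fall outside the allometric table."""


@dataclass(frozen=True)
class CompartmentModelSpec:
    """Hub-and-spoke topology: blood exchanges with every other compartment."""

    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    dosing_sites: tuple[str, ...] = DOSING_SITES
    clearance_sites: tuple[str, ...] = CLEARANCE_SITES

    def __post_init__(self):
        if "blood" not in self.compartments:
            raise ValueError("spec must contain a 'blood' hub compartment")
        if len(set(self.compartments)) != len(self.compartments):
            raise ValueError("duplicate compartment names")
        missing = set(self.clearance_sites) - set(self.compartments)
        if missing:
            raise ValueError(f"clearance sites {missing} not among compartments")

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(c for c in self.compartments if c != "blood")


# Volume fractions of body weight (L/kg at unit density) and blood-flow
# fractions of cardiac output for the default organ set; resting cardiac
# frequency by age band.  Values are textbook-order physiological fractions;
# the table is plain data and fully user-replaceable.
DEFAULT_ALLOMETRIC_TABLE: dict = {
    "volume_fraction": {
        "blood": 0.075, "gut": 0.017, "liver": 0.026, "kidneys": 0.004,
        "brain": 0.020, "heart": 0.005, "lungs": 0.008, "muscle": 0.400,
        "adipose": 0.190, "skin": 0.037, "bone": 0.140, "spleen": 0.0026,
        "pancreas": 0.0014, "rest": 0.060,
    },
    "flow_fraction": {
        "gut": 0.150, "liver": 0.065, "kidneys": 0.190, "brain": 0.120,
        "heart": 0.040, "lungs": 0.025, "muscle": 0.170, "adipose": 0.050,
        "skin": 0.050, "bone": 0.050, "spleen": 0.030, "pancreas": 0.010,
        "rest": 0.050,
    },
    # (age_lo, age_hi, sex or None) -> resting heart rate, beats/min
    "cardiac_frequency": [
        (0.0, 12.0, None, 90.0),
        (12.0, 18.0, None, 78.0),
        (18.0, 120.0, None, 70.0),
    ],
    "stroke_volume_ml_per_kg": 1.0,
}


@dataclass(frozen=True)
class AllometricTable:
    """Configurable anthropometric scaling table."""

    data: Mapping = field(default_factory=lambda: DEFAULT_ALLOMETRIC_TABLE)

    def cardiac_frequency(self, age: float, sex: str) -> float:
        for lo, hi, s, hr in self.data["cardiac_frequency"]:
            if lo <= age < hi and (s is None or s == sex):
                return hr
        raise CoverageError(f"no cardiac-frequency band covers age {age}")

    def cardiac_output(self, age: float, sex: str, weight: float) -> float:
        """Cardiac output, L/h = HR x stroke volume (scaled by weight)."""
        hr = self.cardiac_frequency(age, sex)
        sv_l = self.data["stroke_volume_ml_per_kg"] * weight / 1000.0
        return hr * sv_l * 60.0


@dataclass(frozen=True)
class DrugConfig:
    """Per-drug dosing, PK and target information.

    ``release`` selects the extended-release approximation: 'immediate'
    (one event), 'biphasic' (two events of half the dose, Medikinet-style)
    or 'osmotic' (three events of one third, Concerta/OROS-style).
    EC50 values are mg/L in the target tissue; effects are +1 (activation)
    or -1 (inhibition).
    """

    name: str
    dose_mg: float
    bioavailability: float  # F in (0, 1]
    release: str = "immediate"
    release_interval_h: float = 4.0
    k_a: float = 1.0  # absorption constant, 1/h
    clearance_l_per_h_per_kg: float = 0.2
    clearance_split: Mapping[str, float] = field(
        default_factory=lambda: {"gut": 0.05, "liver": 0.15, "kidneys": 0.80}
    )
    partition_coefficients: Mapping[str, float] = field(default_factory=dict)
    targets: tuple[tuple[str, int], ...] = ()
    ec50_mg_per_l: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.bioavailability <= 1.0:
            raise ValueError("bioavailability must lie in (0, 1]")
        if self.release not in ("immediate", "biphasic", "osmotic"):
            raise ValueError(f"unknown release type {self.release!r}")
        for _, effect in self.targets:
            if effect not in (1, -1):
                raise ValueError("target effects must be +1 or -1")


@dataclass(frozen=True)
class IndividualPBPKParams:
    """One patient's PBPK parameter set."""

    volumes: Mapping[str, float]  # L
    flows: Mapping[str, float]  # L/h, blood <-> organ
    cardiac_frequency: float  # beats/min
    k_a: float  # 1/h
    clearance: Mapping[str, float]  # L/h per clearance site
    bioavailability: float
    blood_volume_adjustment: float = 1.0
    partition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("volumes must be positive")
        if any(q <= 0 for q in self.flows.values()):
            raise ValueError("flows must be positive")
        if not 0.0 < self.bioavailability <= 1.0:
            raise ValueError("bioavailability must lie in (0, 1]")


@dataclass(frozen=True)
class DosingScheme:
    """Administration events: (time h, amount mg) at one route."""

    route: str
    events: tuple[tuple[float, float], ...]
    drug: str = ""

    def __post_init__(self):
        if self.route not in DOSING_SITES:
            raise ValueError(f"route must be one of {DOSING_SITES}")
        times = [t for t, _ in self.events]
        if any(a <= 0 for _, a in self.events):
            raise ValueError("dose amounts must be positive")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")

    @property
    def total_dose(self) -> float:
        return sum(a for _, a in self.events)


@dataclass
class ConcentrationProfile:
    """Simulated per-compartment concentration over a time grid."""

    times: np.ndarray  # h
    concentrations: pd.DataFrame  # columns = compartments, mg/L
    cleared: pd.DataFrame  # columns = clearance sites, cumulative mg
    depot: np.ndarray  # unabsorbed amount remaining, mg
    administered: np.ndarray  # cumulative F-corrected dose, mg
    volumes: Mapping[str, float]

    def mass_balance_error(self) -> float:
        """Max relative deviation of depot + organs + cleared from F x dose."""
        amounts = (self.concentrations * pd.Series(self.volumes)).sum(axis=1)
        total = self.depot + amounts.to_numpy() + self.cleared.sum(axis=1).to_numpy()
        scale = max(self.administered.max(), 1e-12)
        return float(np.max(np.abs(total - self.administered)) / scale)


@dataclass(frozen=True)
class PKObservations:
    """Observed blood concentration datapoints used for model fitting."""

    times: tuple[float, ...]  # h
    concentrations: tuple[float, ...]  # mg/L
    drug: str = ""
    subject: str = ""

    def __post_init__(self):
        t = np.asarray(self.times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")


@dataclass
class FitResult:
    k_a: float
    clearance_scale: float
    blood_volume_adjustment: float
    rmse: float
    r_squared: float
    degenerate: bool = False
    params: IndividualPBPKParams | None = None


# ---------------------------------------------------------------------------
# Parameter individualization
# ---------------------------------------------------------------------------


def individualize_parameters(
    patient: VirtualPatient,
    drug: DrugConfig,
    table: AllometricTable = AllometricTable(),
    spec: CompartmentModelSpec = CompartmentModelSpec(),
) -> IndividualPBPKParams:
    """Scale organ volumes and flows to one patient's anthropometry.

    Volumes are fixed fractions of body weight; flows are fractions of the
    patient's cardiac output (heart rate x weight-scaled stroke volume).
    Absorption, clearance and bioavailability come from the drug config.
    """
    vol_frac = table.data["volume_fraction"]
    flow_frac = table.data["flow_fraction"]
    volumes = {c: vol_frac[c] * patient.weight for c in spec.compartments}
    co = table.cardiac_output(patient.age, patient.sex, patient.weight)
    flows = {c: flow_frac[c] * co for c in spec.organs}
    if sum(flows.values()) > co + 1e-9:
        raise ValueError("organ flows exceed cardiac output")
    clearance = {
        site: drug.clearance_split.get(site, 0.0)
        * drug.clearance_l_per_h_per_kg
        * patient.weight
        for site in spec.clearance_sites
    }
    return IndividualPBPKParams(
        volumes=volumes,
        flows=flows,
        cardiac_frequency=table.cardiac_frequency(patient.age, patient.sex),
        k_a=drug.k_a,
        clearance=clearance,
        bioavailability=drug.bioavailability,
        partition=dict(drug.partition_coefficients),
    )


# ---------------------------------------------------------------------------
# Dosing schemes
# ---------------------------------------------------------------------------


def expand_extended_release(drug: DrugConfig, total_dose: float | None = None) -> DosingScheme:
    """Approximate extended release by repeated lower doses.

    Biphasic (Medikinet-style) formulations become two events of half the
    dose; osmotic (Concerta/OROS-style) become three events of one third;
    immediate release is a single event at t=0.  Events are spaced by the
    drug's release interval (default 4 h).
    """
    dose = drug.dose_mg if total_dose is None else total_dose
    if dose <= 0:
        raise ValueError("total dose must be positive")
    dt = drug.release_interval_h
    if drug.release == "immediate":
        events = ((0.0, dose),)
    elif drug.release == "biphasic":
        events = ((0.0, dose / 2), (dt, dose / 2))
    else:  # osmotic
        events = ((0.0, dose / 3), (dt, dose / 3), (2 * dt, dose / 3))
    return DosingScheme(route="gut", events=events, drug=drug.name)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _build_matrix(params: IndividualPBPKParams, spec: CompartmentModelSpec) -> np.ndarray:
    """System matrix for states [depot, compartments..., cleared sites...]."""
    organs = spec.organs
    comps = spec.compartments
    n = 1 + len(comps) + len(spec.clearance_sites)
    idx = {c: 1 + i for i, c in enumerate(comps)}
    ib = idx["blood"]
    vb = params.volumes["blood"] * params.blood_volume_adjustment
    a = np.zeros((n, n))
    a[0, 0] = -params.k_a
    a[ib, 0] = params.k_a
    for organ in organs:
        q = params.flows[organ]
        v = params.volumes[organ] * params.partition.get(organ, 1.0)
        io = idx[organ]
        a[io, ib] += q / vb
        a[io, io] += -q / v
        a[ib, io] += q / v
        a[ib, ib] += -q / vb
    for j, site in enumerate(spec.clearance_sites):
        cl = params.clearance.get(site, 0.0)
        a[ib, ib] += -cl / vb
        a[1 + len(comps) + j, ib] = cl / vb
    return a


def simulate(
    params: IndividualPBPKParams,
    scheme: DosingScheme,
    t_end: float,
    spec: CompartmentModelSpec = CompartmentModelSpec(),
    grid_step: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationProfile:
    """Integrate the linear PBPK system over repeated dose events.

    Bioavailability is applied at administration: each event adds F x amount
    to the absorption depot (oral/subcutaneous) or directly to blood
    (intravenous).  Integration is piecewise between events with a
    stiff-capable solver.
    """
    if scheme.events and t_end < scheme.events[-1][0]:
        raise ValueError("t_end must not precede the last dosing event")
    comps = spec.compartments
    n_state = 1 + len(comps) + len(spec.clearance_sites)
    matrix = _build_matrix(params, spec)
    rhs = lambda t, y: matrix @ y  # noqa: E731

    times = np.arange(0.0, t_end + grid_step / 2, grid_step)
    state = np.zeros(n_state)
    solution = np.zeros((times.size, n_state))
    administered = np.zeros(times.size)
    ib = 1 + comps.index("blood")

    event_times = sorted({t for t, _ in scheme.events})
    boundaries = [0.0] + [t for t in event_times if 0.0 < t <= t_end] + [t_end]
    boundaries = sorted(set(boundaries))
    dosed = 0.0

    def apply_doses(t: float):
        nonlocal dosed
        for et, amount in scheme.events:
            if math.isclose(et, t, abs_tol=1e-12):
                bio = params.bioavailability * amount
                if scheme.route == "blood":
                    state[ib] += bio
                else:
                    state[0] += bio
                dosed += bio

    apply_doses(0.0)
    mask0 = np.isclose(times, 0.0)
    solution[mask0] = state
    administered[mask0] = dosed
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if hi > lo:
            t_eval = times[(times > lo + 1e-12) & (times <= hi + 1e-12)]
            sol = solve_ivp(
                rhs, (lo, hi), state, method="LSODA",
                t_eval=t_eval if t_eval.size else None,
                rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise IntegrationError(sol.message)
            if t_eval.size:
                sel = (times > lo + 1e-12) & (times <= hi + 1e-12)
                solution[sel] = sol.y.T
                administered[sel] = dosed
            state = sol.y[:, -1].copy()
        apply_doses(hi)
        at_hi = np.isclose(times, hi)
        solution[at_hi] = state
        administered[at_hi] = dosed

    if solution.min() < -atol * 1e3:
        raise IntegrationError("negative state beyond tolerance")
    solution = np.clip(solution, 0.0, None)

    eff_volumes = {
        c: params.volumes[c]
        * (params.blood_volume_adjustment if c == "blood" else params.partition.get(c, 1.0))
        for c in comps
    }
    conc = pd.DataFrame(
        {c: solution[:, 1 + i] / eff_volumes[c] for i, c in enumerate(comps)},
        index=times,
    )
    cleared = pd.DataFrame(
        {s: solution[:, 1 + len(comps) + j] for j, s in enumerate(spec.clearance_sites)},
        index=times,
    )
    return ConcentrationProfile(
        times=times,
        concentrations=conc,
        cleared=cleared,
        depot=solution[:, 0],
        administered=administered,
        volumes=eff_volumes,
    )


def tissue_timepoints(
    profile: ConcentrationProfile, compartment: str, times: Sequence[float]
) -> np.ndarray:
    """Concentration in one compartment at arbitrary times (linear interp)."""
    if compartment not in profile.concentrations.columns:
        raise KeyError(f"unknown compartment {compartment!r}")
    t = np.asarray(times, dtype=float)
    if t.min() < profile.times[0] - 1e-9 or t.max() > profile.times[-1] + 1e-9:
        raise ValueError("query times outside the simulated window")
    return np.interp(t, profile.times, profile.concentrations[compartment].to_numpy())


# ---------------------------------------------------------------------------
# Fitting to observed PK data
# ---------------------------------------------------------------------------


def fit_absorption_clearance(
    params: IndividualPBPKParams,
    scheme: DosingScheme,
    obs: PKObservations,
    spec: CompartmentModelSpec = CompartmentModelSpec(),
    x0: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> FitResult:
    """Least-squares fit of (k_a, clearance scale, blood volume adjustment).

    The fit works on blood concentration at the observation times, with the
    three parameters optimized in log space to stay positive.  Deterministic
    given the fixed starting point.
    """
    y = np.asarray(obs.concentrations, dtype=float)
    if len(y) < 4:
        raise FitError("need at least 4 observation points")
    if np.allclose(y, 0.0):
        raise FitError("observations carry no signal (all zero)")
    t_end = max(obs.times[-1], scheme.events[-1][0]) + 1e-6

    def with_params(x: np.ndarray) -> IndividualPBPKParams:
        k_a, cl_scale, bva = np.exp(x)
        return replace(
            params,
            k_a=float(k_a * params.k_a),
            clearance={s: cl_scale * v for s, v in params.clearance.items()},
            blood_volume_adjustment=float(bva),
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        profile = simulate(with_params(x), scheme, t_end, spec=spec,
                           grid_step=0.05, rtol=1e-6, atol=1e-9)
        pred = tissue_timepoints(profile, "blood", obs.times)
        return pred - y

    result = least_squares(residuals, np.log(np.asarray(x0)), method="lm", xtol=1e-10)
    k_a, cl_scale, bva = np.exp(result.x)
    res = result.fun
    rmse = float(np.sqrt(np.mean(res**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res**2)) / ss_tot if ss_tot > 0 else float("nan")
    col_norms = np.linalg.norm(result.jac, axis=0)
    degenerate = bool(np.any(col_norms < 1e-8 * max(np.linalg.norm(y), 1e-12)))
    return FitResult(
        k_a=float(k_a * params.k_a),
        clearance_scale=float(cl_scale),
        blood_volume_adjustment=float(bva),
        rmse=rmse,
        r_squared=r2,
        degenerate=degenerate,
        params=with_params(result.x),
    )


def read_pk_observations(path: str | Path, sep: str = "\t", drug: str = "") -> PKObservations:
    frame = pd.read_csv(path, sep=sep)
    return PKObservations(
        times=tuple(frame.iloc[:, 0].astype(float)),
        concentrations=tuple(frame.iloc[:, 1].astype(float)),
        drug=drug,
    )
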