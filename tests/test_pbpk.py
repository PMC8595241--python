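"""PBPK model: allometric individualization, dosing expansion, ODE
integration against the closed-form one-compartment limit, mass balance,
linearity, and parameter recovery from synthetic observations."""

from dataclasses import replace

import numpy as np
import pytest

from isct import fixtures as fx
from isct import pbpk
from isct.pbpk import DosingScheme, DrugConfig
from isct.vpop import VirtualPatient


def patient(weight=70.0, age=40.0, height=175.0, sex="M"):
    return VirtualPatient(
        id="p", sex=sex, age=age, height=height, weight=weight,
        bmi=weight / (height / 100) ** 2,
    )


@pytest.fixture(scope="module")
def base_params():
    drug = DrugConfig(name="d", dose_mg=70, bioavailability=0.9, k_a=1.2,
                      clearance_l_per_h_per_kg=0.3 / 70)
    return pbpk.individualize_parameters(patient(), drug)


def one_compartment(params):
    """Isolate blood: negligible organ flows, renal clearance only."""
    return replace(
        params,
        flows={k: 1e-12 for k in params.flows},
        clearance={"gut": 0.0, "liver": 0.0, "kidneys": 0.3},
    )


class TestIndividualization:
    def test_bioavailability_taken_from_drug_config(self):
        drug = DrugConfig(name="ldx", dose_mg=70, bioavailability=0.964)
        params = pbpk.individualize_parameters(patient(), drug)
        assert params.bioavailability == 0.964

    def test_identical_demographics_identical_parameters(self):
        drug = DrugConfig(name="d", dose_mg=10, bioavailability=0.5)
        a = pbpk.individualize_parameters(patient(), drug)
        b = pbpk.individualize_parameters(patient(), drug)
        assert a.volumes == b.volumes and a.flows == b.flows

    def test_linear_scaling_doubles_volumes_with_weight(self):
        drug = DrugConfig(name="d", dose_mg=10, bioavailability=0.5)
        light = pbpk.individualize_parameters(patient(weight=60.0), drug)
        heavy = pbpk.individualize_parameters(patient(weight=120.0), drug)
        for organ in light.volumes:
            assert heavy.volumes[organ] == pytest.approx(2 * light.volumes[organ])

    def test_flows_bounded_by_cardiac_output(self, base_params):
        table = pbpk.AllometricTable()
        co = table.cardiac_output(40.0, "M", 70.0)
        assert sum(base_params.flows.values()) <= co + 1e-9


class TestExtendedRelease:
    @pytest.mark.parametrize(
        "release,dose,expected",
        [
            ("immediate", 70.0, ((0.0, 70.0),)),
            ("biphasic", 20.0, ((0.0, 10.0), (4.0, 10.0))),
            ("osmotic", 36.0, ((0.0, 12.0), (4.0, 12.0), (8.0, 12.0))),
        ],
    )
    def test_expansion_rules(self, release, dose, expected):
        drug = DrugConfig(name="d", dose_mg=dose, bioavailability=0.5, release=release)
        scheme = pbpk.expand_extended_release(drug)
        assert scheme.events == expected

    def test_nonpositive_dose_rejected(self):
        drug = DrugConfig(name="d", dose_mg=10, bioavailability=0.5)
        with pytest.raises(ValueError):
            pbpk.expand_extended_release(drug, total_dose=0.0)


class TestSimulation:
    def test_zero_dose_gives_flat_zero_profile(self, base_params):
        profile = pbpk.simulate(base_params, DosingScheme(route="gut", events=()), 12.0)
        assert np.allclose(profile.concentrations.to_numpy(), 0.0)

    def test_one_compartment_limit_matches_bateman(self, base_params):
        p1 = one_compartment(base_params)
        scheme = DosingScheme(route="gut", events=((0.0, 70.0),))
        profile = pbpk.simulate(p1, scheme, 24.0)
        t = profile.times[1:]
        v = base_params.volumes["blood"]
        expected = fx.bateman(t, 1.2, 0.3, v, 0.9, 70.0)
        observed = profile.concentrations["blood"].to_numpy()[1:]
        assert np.max(np.abs(observed - expected)) <= 0.005 * expected.max()

    def test_mass_balance_within_tolerance(self, base_params):
        drug = DrugConfig(name="c", dose_mg=36, bioavailability=0.32, release="osmotic")
        scheme = pbpk.expand_extended_release(drug)
        profile = pbpk.simulate(base_params, scheme, 24.0)
        assert profile.mass_balance_error() < 1e-3

    def test_states_nonnegative_and_clearance_monotone(self, base_params):
        scheme = DosingScheme(route="gut", events=((0.0, 70.0),))
        profile = pbpk.simulate(base_params, scheme, 24.0)
        assert (profile.concentrations.to_numpy() >= 0).all()
        cleared = profile.cleared.to_numpy()
        assert (np.diff(cleared, axis=0) >= -1e-9).all()

    def test_dose_linearity(self, base_params):
        s1 = DosingScheme(route="gut", events=((0.0, 35.0),))
        s2 = DosingScheme(route="gut", events=((0.0, 70.0),))
        p1 = pbpk.simulate(base_params, s1, 24.0).concentrations["blood"].to_numpy()
        p2 = pbpk.simulate(base_params, s2, 24.0).concentrations["blood"].to_numpy()
        assert np.allclose(2 * p1, p2, rtol=1e-6, atol=1e-10)

    def test_repeated_doses_superpose(self, base_params):
        single_0 = pbpk.simulate(
            base_params, DosingScheme(route="gut", events=((0.0, 10.0),)), 24.0
        ).concentrations["blood"].to_numpy()
        both = pbpk.simulate(
            base_params, DosingScheme(route="gut", events=((0.0, 10.0), (4.0, 10.0))), 24.0
        ).concentrations["blood"].to_numpy()
        times = pbpk.simulate(
            base_params, DosingScheme(route="gut", events=((0.0, 10.0),)), 24.0
        ).times
        shifted = np.interp(times - 4.0, times, single_0, left=0.0)
        assert np.allclose(both, single_0 + shifted, atol=1e-6 * single_0.max() + 1e-12, rtol=1e-3)

    def test_t_end_before_last_event_rejected(self, base_params):
        scheme = DosingScheme(route="gut", events=((0.0, 10.0), (8.0, 10.0)))
        with pytest.raises(ValueError):
            pbpk.simulate(base_params, scheme, 4.0)


@pytest.fixture(scope="module")
def profile(base_params):
    return pbpk.simulate(
        base_params, DosingScheme(route="gut", events=((0.0, 70.0),)), 24.0
    )


class TestTissueTimepoints:
    def test_predose_zero(self, profile):
        assert pbpk.tissue_timepoints(profile, "brain", [0.0])[0] == 0.0

    def test_grid_node_exact_and_midpoint_mean(self, profile):
        c = profile.concentrations["brain"].to_numpy()
        at_node = pbpk.tissue_timepoints(profile, "brain", [profile.times[50]])[0]
        assert at_node == c[50]
        mid = pbpk.tissue_timepoints(
            profile, "brain", [(profile.times[50] + profile.times[51]) / 2]
        )[0]
        assert mid == pytest.approx((c[50] + c[51]) / 2)

    def test_unknown_compartment_raises(self, profile):
        with pytest.raises(KeyError):
            pbpk.tissue_timepoints(profile, "gills", [1.0])


class TestFitting:
    def test_noiseless_recovery_within_one_percent(self, base_params):
        p1 = one_compartment(base_params)
        v = base_params.volumes["blood"]
        obs = fx.synth_pk_observations(k_a=1.2, cl=0.3, volume=v, f=0.9, dose=70.0)
        scheme = DosingScheme(route="gut", events=((0.0, 70.0),))
        fit = pbpk.fit_absorption_clearance(p1, scheme, obs)
        assert fit.k_a == pytest.approx(1.2, rel=0.01)
        assert fit.clearance_scale == pytest.approx(1.0, rel=0.01)
        assert fit.blood_volume_adjustment == pytest.approx(1.0, rel=0.01)
        assert fit.r_squared > 0.999

    def test_noisy_recovery_median_error_below_ten_percent(self, base_params):
        p1 = one_compartment(base_params)
        v = base_params.volumes["blood"]
        scheme = DosingScheme(route="gut", events=((0.0, 70.0),))
        errors = []
        for seed in range(20):
            obs = fx.synth_pk_observations(
                k_a=1.2, cl=0.3, volume=v, f=0.9, dose=70.0, noise=0.05, seed=seed
            )
            fit = pbpk.fit_absorption_clearance(p1, scheme, obs)
            errors.append(abs(fit.k_a - 1.2) / 1.2)
            errors.append(abs(fit.clearance_scale - 1.0))
        assert np.median(errors) < 0.10

    def test_all_zero_observations_rejected(self, base_params):
        obs = pbpk.PKObservations(times=(1.0, 2.0, 3.0, 4.0),
                                  concentrations=(0.0, 0.0, 0.0, 0.0))
        scheme = DosingScheme(route="gut", events=((0.0, 70.0),))
        with pytest.raises(pbpk.FitError):
            pbpk.fit_absorption_clearance(base_params, scheme, obs)

    def test_too_few_points_rejected(self, base_params):
        obs = pbpk.PKObservations(times=(1.0, 2.0), concentrations=(0.5, 0.4))
        scheme = DosingScheme(route="gut", events=((0.0, 70.0),))
        with pytest.raises(pbpk.FitError):
            pbpk.fit_absorption_clearance(base_params, scheme, obs)


def test_bateman_peak_time_closed_form():
    k_a, cl, v = 1.2, 0.3, 5.0
    t = np.linspace(0.01, 24, 20000)
    c = fx.bateman(t, k_a, cl, v, 0.9, 70.0)
    assert t[np.argmax(c)] == pytest.approx(fx.bateman_tmax(k_a, cl, v), abs=2e-3)
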