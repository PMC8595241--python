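"""Virtual population generation: MVND construction, annealing acceptance,
Metropolis-Hastings pediatric sampling, z-test validation, arm allocation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isct import fixtures as fx
from isct import vpop
from isct.vpop import (
    ArmSpec,
    DemographicReference,
    GrowthReferenceTable,
    MHConfig,
    StandardDistributionTable,
    UnresolvableVariableError,
    VariableSummary,
    VirtualPatient,
)


def make_reference(sex_f=0.5, **moments):
    variables = {k: VariableSummary(k, m, s) for k, (m, s) in moments.items()}
    return DemographicReference(variables=variables, sex_female_fraction=sex_f)


def flat_growth_table(height=(150.0, 10.0), bmi=(19.0, 3.0)):
    """Growth grid whose cells are identical across age and sex."""
    rows = []
    w_mean = bmi[0] * (height[0] / 100.0) ** 2
    for sex in ("F", "M"):
        for age in range(6, 18):
            rows += [
                {"age": age, "sex": sex, "variable": "height", "mean": height[0], "sd": height[1]},
                {"age": age, "sex": sex, "variable": "bmi", "mean": bmi[0], "sd": bmi[1]},
                {"age": age, "sex": sex, "variable": "weight", "mean": w_mean, "sd": 10.0},
            ]
    return GrowthReferenceTable(pd.DataFrame(rows))


class TestBuildMvnd:
    def test_reference_moments_become_marginals(self, adult_reference):
        spec = vpop.build_mvnd(adult_reference)
        assert spec.variables == ("age", "height", "weight")
        np.testing.assert_allclose(spec.mean, [36.58, 171.7, 78.75])
        np.testing.assert_allclose(np.sqrt(np.diag(spec.cov)), [10.10, 9.4, 17.20])
        assert spec.filled == ()

    def test_covariance_symmetric_psd_with_height_weight_corr(self, adult_reference):
        spec = vpop.build_mvnd(adult_reference, height_weight_corr=0.5)
        np.testing.assert_allclose(spec.cov, spec.cov.T)
        assert np.linalg.eigvalsh(spec.cov).min() >= -1e-9
        rho = spec.cov[1, 2] / (9.4 * 17.20)
        assert rho == pytest.approx(0.5)

    def test_missing_variable_filled_and_flagged(self):
        ref = make_reference(age=(40.0, 5.0), height=(170.0, 8.0))
        fill = StandardDistributionTable({"weight": (75.0, 15.0)})
        spec = vpop.build_mvnd(ref, fill)
        assert "weight" in spec.filled
        assert spec.mean[2] == 75.0

    def test_unresolvable_variable_raises(self):
        ref = make_reference(age=(40.0, 5.0))
        with pytest.raises(UnresolvableVariableError):
            vpop.build_mvnd(ref, StandardDistributionTable({"height": (170, 8)}))

    def test_zero_variance_reference_yields_degenerate_draws(self):
        ref = make_reference(age=(40.0, 0.0), height=(170.0, 0.0), weight=(70.0, 0.0))
        pop = vpop.generate_adult_vpop(ref, n=5, seed=0)
        assert np.allclose(pop.values("age"), 40.0)
        assert np.allclose(pop.values("height"), 170.0)
        assert np.allclose(pop.values("weight"), 70.0)


class TestValidatePopulation:
    def test_exact_match_gives_z_zero_p_one(self):
        ref = make_reference(age=(36.58, 10.10))
        res = vpop.validate_population({"age": np.full(100, 36.58)}, ref)
        assert res["variables"]["age"]["z"] == pytest.approx(0.0)
        assert res["variables"]["age"]["p"] == pytest.approx(1.0)
        assert res["pass"]

    def test_hand_computed_z_and_p(self):
        # x_bar 37.5 vs mu 36.58, sigma 10.10, n 500 -> z ~ 2.037, p ~ 0.0417
        ref = make_reference(age=(36.58, 10.10))
        x = np.full(500, 37.5)
        res = vpop.validate_population({"age": x}, ref)
        z = (37.5 - 36.58) / (10.10 / math.sqrt(500))
        assert res["variables"]["age"]["z"] == pytest.approx(z)
        assert res["variables"]["age"]["p"] == pytest.approx(2 * stats.norm.sf(abs(z)))
        assert res["variables"]["age"]["p"] == pytest.approx(0.0417, abs=5e-4)
        assert not res["variables"]["age"]["pass"]

    def test_empty_population_rejected(self):
        ref = make_reference(age=(36.58, 10.10))
        with pytest.raises(ValueError):
            vpop.validate_population({"age": np.array([])}, ref)


class TestAdultGenerator:
    def test_accepted_population_passes_its_own_z_tests(self, adult_population_500):
        check = adult_population_500.provenance["validation"]
        assert check["pass"]
        assert all(v["p"] > 0.05 for v in check["variables"].values())

    def test_sample_moments_near_reference(self, adult_population_500, adult_reference):
        for name in ("age", "height", "weight"):
            s = adult_reference.summary(name)
            se = s.sd / math.sqrt(500)
            assert abs(adult_population_500.values(name).mean() - s.mean) < 3 * se

    def test_sex_quota_round_half_up(self, adult_population_500):
        # 0.416 * 500 = 208 females exactly
        assert sum(p.sex == "F" for p in adult_population_500.patients) == 208

    def test_bmi_identity_every_patient(self, adult_population_500):
        for p in adult_population_500.patients:
            assert p.bmi == pytest.approx(p.weight / (p.height / 100) ** 2, rel=1e-6)

    def test_seed_determinism(self, adult_reference):
        a = vpop.generate_adult_vpop(adult_reference, n=50, seed=5)
        b = vpop.generate_adult_vpop(adult_reference, n=50, seed=5)
        assert vpop.population_to_frame(a).equals(vpop.population_to_frame(b))

    def test_single_patient_zero_variance_equals_means(self):
        ref = make_reference(age=(40.0, 0.0), height=(175.0, 0.0), weight=(80.0, 0.0))
        pop = vpop.generate_adult_vpop(ref, n=1, seed=0)
        p = pop.patients[0]
        assert (p.age, p.height, p.weight) == (40.0, 175.0, 80.0)

    def test_monte_carlo_acceptance_loop(self):
        # synthetic reference age 40 +/- 5, n=200: sample mean within
        # 3 * (5/sqrt(200)) of 40 in at least 99% of 100 seeded runs
        ref = make_reference(age=(40.0, 5.0), height=(170.0, 8.0), weight=(75.0, 12.0))
        tol = 3 * 5 / math.sqrt(200)
        hits = sum(
            abs(vpop.generate_adult_vpop(ref, n=200, seed=s).values("age").mean() - 40.0) < tol
            for s in range(100)
        )
        assert hits >= 99


class TestPediatricGenerator:
    def test_ages_within_bounds_and_validation_passes(self, pediatric_reference_and_growth):
        ref, growth = pediatric_reference_and_growth
        pop = vpop.generate_pediatric_vpop(ref, growth, n=300, seed=2)
        ages = pop.values("age")
        assert ages.min() >= 6.0 and ages.max() < 18.0
        assert pop.provenance["validation"]["pass"]

    def test_growth_consistency_within_four_sd(self, pediatric_reference_and_growth):
        ref, growth = pediatric_reference_and_growth
        pop = vpop.generate_pediatric_vpop(ref, growth, n=200, seed=3)
        for p in pop.patients:
            for var, value in (("height", p.height), ("weight", p.weight)):
                m, sd = growth.cell(p.age, p.sex, var)
                assert abs(value - m) <= 4 * sd + 1e-9

    def test_single_cell_target_reproduces_cell_moments(self):
        # all age cells identical -> output height marginal must match the cell
        ref = make_reference(sex_f=0.5, age=(11.0, 1.5))
        growth = flat_growth_table(height=(150.0, 8.0), bmi=(19.0, 2.0))
        pop = vpop.generate_pediatric_vpop(ref, growth, n=400, seed=4)
        assert pop.values("height").mean() == pytest.approx(150.0, abs=3 * 8 / 20)

    def test_long_chain_matches_target_age_distribution(self):
        # truncation negligible for age 11 +/- 1.5; Kolmogorov distance <= 0.08
        ref = make_reference(sex_f=0.5, age=(11.0, 1.5))
        growth = flat_growth_table()
        pop = vpop.generate_pediatric_vpop(ref, growth, n=2000, seed=5)
        d, _ = stats.kstest(pop.values("age"), stats.norm(11.0, 1.5).cdf)
        assert d < 0.08

    def test_seed_determinism(self, pediatric_reference_and_growth):
        ref, growth = pediatric_reference_and_growth
        a = vpop.generate_pediatric_vpop(ref, growth, n=60, seed=9)
        b = vpop.generate_pediatric_vpop(ref, growth, n=60, seed=9)
        assert vpop.population_to_frame(a).equals(vpop.population_to_frame(b))

    def test_growth_table_gap_raises(self, pediatric_reference_and_growth):
        ref, growth = pediatric_reference_and_growth
        broken = growth.frame[~((growth.frame.age == 12) & (growth.frame.sex == "M"))]
        with pytest.raises(KeyError):
            vpop.generate_pediatric_vpop(ref, GrowthReferenceTable(broken), n=10, seed=0)


class TestAssignArms:
    def test_partition_exact_sizes_and_tags(self, adult_population_500):
        arms = [ArmSpec("a", frozenset(), 300), ArmSpec("b", frozenset({"dep"}), 200)]
        pop = vpop.assign_arms(adult_population_500, arms, seed=1)
        counts = pd.Series([p.arm_id for p in pop.patients]).value_counts()
        assert counts["a"] == 300 and counts["b"] == 200
        for p in pop.patients:
            assert p.comorbidity_tags == (frozenset({"dep"}) if p.arm_id == "b" else frozenset())

    def test_size_mismatch_raises(self, adult_population_500):
        with pytest.raises(vpop.AllocationError):
            vpop.assign_arms(adult_population_500, [ArmSpec("a", frozenset(), 100)], seed=0)

    def test_different_seeds_same_histogram_different_partition(self, adult_population_500):
        arms = [ArmSpec("a", frozenset(), 250), ArmSpec("b", frozenset(), 250)]
        p1 = vpop.assign_arms(adult_population_500, arms, seed=1)
        p2 = vpop.assign_arms(adult_population_500, arms, seed=2)
        h1 = sorted(pd.Series([p.arm_id for p in p1.patients]).value_counts())
        h2 = sorted(pd.Series([p.arm_id for p in p2.patients]).value_counts())
        assert h1 == h2
        assert [p.arm_id for p in p1.patients] != [p.arm_id for p in p2.patients]

    def test_single_arm_identity(self, adult_population_500):
        pop = vpop.assign_arms(
            adult_population_500, [ArmSpec("only", frozenset(), 500)], seed=0
        )
        assert all(p.arm_id == "only" for p in pop.patients)


class TestPatientInvariants:
    @pytest.mark.parametrize("height,weight", [(180.0, 80.0), (120.0, 25.0)])
    def test_bmi_identity_enforced(self, height, weight):
        bmi = weight / (height / 100) ** 2
        VirtualPatient(id="x", sex="M", age=30, height=height, weight=weight, bmi=bmi)
        with pytest.raises(ValueError):
            VirtualPatient(id="x", sex="M", age=30, height=height, weight=weight, bmi=bmi + 1)

    def test_population_kind_age_bounds(self):
        child = VirtualPatient(id="c", sex="F", age=10, height=140, weight=35,
                               bmi=35 / 1.4**2)
        with pytest.raises(ValueError):
            vpop.VirtualPopulation([child], population_kind="adult", seed=0)


def test_roundtrip_write_read(tmp_path, adult_population_500):
    path = tmp_path / "pop.tsv"
    vpop.write_population(adult_population_500, path)
    frame = pd.read_csv(path, sep="\t")
    assert len(frame) == 500
    assert path.with_suffix(".tsv.provenance.json").exists()
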