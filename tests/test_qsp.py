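"""QSP surrogate: Emax target modulation, damped signed propagation,
training-set accuracy, ensemble constraints, and tSignal algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isct import qsp
from isct.qsp import (
    ActivityVector,
    DiseaseDefinition,
    DrugTargetProfile,
    ProteinNetwork,
    QSPConfig,
    TrainingEntry,
    TrainingSet,
)


@pytest.fixture
def chain_network():
    # A -> B (+1), B -> C (-1)
    return ProteinNetwork(
        ["A", "B", "C"], [("A", "B", 1, 1.0), ("B", "C", -1, 1.0)]
    )


class TestTargetModulation:
    def test_zero_concentration_gives_zero(self):
        profile = DrugTargetProfile("d", (("T", -1),))
        mod = qsp.target_modulation([0.0, 0.0], profile, {"T": 1.0})
        assert mod["T"] == 0.0

    def test_half_maximal_at_ec50_with_inhibition_sign(self):
        profile = DrugTargetProfile("d", (("T", -1),))
        mod = qsp.target_modulation([2.0, 2.0], profile, {"T": 2.0})
        assert mod["T"] == pytest.approx(-0.5)

    def test_mean_over_timepoints(self):
        # {EC50, 3 EC50} -> (0.5 + 0.75)/2 = 0.625
        profile = DrugTargetProfile("d", (("T", 1),))
        mod = qsp.target_modulation([1.0, 3.0], profile, {"T": 1.0})
        assert mod["T"] == pytest.approx(0.625)

    def test_missing_ec50_raises(self):
        profile = DrugTargetProfile("d", (("T", 1),))
        with pytest.raises(KeyError):
            qsp.target_modulation([1.0], profile, {})


class TestPropagation:
    def test_zero_stimulus_zero_noise_stays_zero(self, chain_network):
        sol = qsp.propagate_activity(chain_network, np.zeros(3))
        assert all(v == 0.0 for v in sol.values.values())
        assert sol.converged

    def test_downstream_sign_follows_edge_signs(self, chain_network):
        sol = qsp.propagate_activity(chain_network, {"A": 0.8})
        assert sol.values["A"] > 0
        assert np.sign(sol.values["B"]) == np.sign(sol.values["A"])
        assert np.sign(sol.values["C"]) == -np.sign(sol.values["B"])

    def test_negative_edge_flips_downstream_activity(self):
        pos = ProteinNetwork(["A", "B"], [("A", "B", 1, 1.0)])
        neg = ProteinNetwork(["A", "B"], [("A", "B", -1, 1.0)])
        sp = qsp.propagate_activity(pos, {"A": 0.8})
        sn = qsp.propagate_activity(neg, {"A": 0.8})
        assert sp.values["B"] == pytest.approx(-sn.values["B"])
        assert sp.values["B"] > 0

    def test_outputs_strictly_inside_unit_interval(self, molecular_fixture):
        net, _, d1, _, _ = molecular_fixture
        sol = qsp.propagate_activity(net, {p: 5.0 * e for p, e in d1.targets})
        values = np.array(list(sol.values.values()))
        assert np.all(np.abs(values) < 1.0)

    def test_contraction_converges_below_spectral_bound(self, molecular_fixture):
        net, *_ = molecular_fixture
        config = QSPConfig(damping=0.9 / net.spectral_bound())
        sol = qsp.propagate_activity(net, np.zeros(len(net)),
                                     config, np.full(len(net), 0.3))
        assert sol.converged

    def test_clamped_protein_held_fixed(self, chain_network):
        sol = qsp.propagate_activity(chain_network, {"A": 0.8}, clamp={"B": -0.5})
        assert sol.values["B"] == -0.5


class TestTSignal:
    def test_fully_expressed_signature_scores_minus_one(self):
        definition = DiseaseDefinition("d", (("A", 1), ("B", -1)))
        values = {"A": 1.0 - 1e-15, "B": -1.0 + 1e-15}
        assert qsp.compute_tsignal(values, definition) == pytest.approx(-1.0)

    def test_zero_activity_scores_zero(self):
        definition = DiseaseDefinition("d", (("A", 1), ("B", -1)))
        assert qsp.compute_tsignal({"A": 0.0, "B": 0.0}, definition) == 0.0

    def test_hand_computed_mixed_case(self):
        # v=(+1,-1,+1), y=(0.5,0.5,-1.0): sum v*y = -1.0 -> -(1/3)(-1.0) = 1/3
        definition = DiseaseDefinition("d", (("A", 1), ("B", -1), ("C", 1)))
        values = {"A": 0.5, "B": 0.5, "C": -1.0}
        assert qsp.compute_tsignal(values, definition) == pytest.approx(1 / 3, abs=1e-12)

    def test_missing_protein_contributes_zero(self):
        definition = DiseaseDefinition("d", (("A", 1), ("ZZ", 1)))
        assert qsp.compute_tsignal({"A": 0.5}, definition) == pytest.approx(-0.25)

    @settings(derandomize=True, max_examples=50)
    @given(
        y=st.lists(st.floats(-0.999, 0.999), min_size=1, max_size=8),
        signs=st.lists(st.sampled_from([1, -1]), min_size=8, max_size=8),
        alpha=st.floats(0.0, 1.0),
    )
    def test_bounds_and_linearity(self, y, signs, alpha):
        proteins = tuple((f"P{i}", signs[i]) for i in range(len(y)))
        definition = DiseaseDefinition("d", proteins)
        values = {f"P{i}": y[i] for i in range(len(y))}
        ts = qsp.compute_tsignal(values, definition)
        assert -1.0 <= ts <= 1.0
        scaled = {k: alpha * v for k, v in values.items()}
        assert qsp.compute_tsignal(scaled, definition) == pytest.approx(alpha * ts, abs=1e-12)

    def test_full_reversion_scores_plus_one(self):
        definition = DiseaseDefinition("d", (("A", 1), ("B", -1)))
        values = {"A": -1.0 + 1e-15, "B": 1.0 - 1e-15}
        assert qsp.compute_tsignal(values, definition) == pytest.approx(1.0)


class TestAccuracy:
    def test_satisfiable_fixture_scores_100_noiseless(self, molecular_fixture):
        net, definition, d1, _, training = molecular_fixture
        sol = qsp.propagate_activity(net, {p: float(e) for p, e in d1.targets})
        assert qsp.solution_accuracy(sol, training, net) == 100.0

    def test_counting_of_satisfied_relationships(self, chain_network):
        # build 2 entries, one satisfied and one with impossible direction
        drug = DrugTargetProfile("d", (("A", 1),))
        cond = DiseaseDefinition("c", (("B", -1),))  # drug activates B -> tSignal rises
        good = TrainingEntry(drug, cond, expected_direction=1)
        bad = TrainingEntry(drug, cond, expected_direction=-1)
        sol = qsp.propagate_activity(chain_network, {"A": 0.8})
        acc = qsp.solution_accuracy(sol, TrainingSet((good, bad)), chain_network)
        assert acc == 50.0


class TestEnsemble:
    def test_meets_size_and_accuracy_constraints(self, molecular_fixture):
        net, definition, d1, _, training = molecular_fixture
        modulation = {p: 0.8 * e for p, e in d1.targets}
        ens = qsp.sample_ensemble("pat", "drugA", net, training, modulation, seed=3)
        assert len(ens.solutions) >= 50
        assert min(ens.accuracies) >= 85.0

    def test_noiseless_config_gives_identical_solutions(self, molecular_fixture):
        net, definition, d1, _, training = molecular_fixture
        config = QSPConfig(noise_scale=0.0, ensemble_min=5, attempt_budget=10)
        modulation = {p: 0.8 * e for p, e in d1.targets}
        ens = qsp.sample_ensemble("pat", "drugA", net, training, modulation,
                                  config=config, seed=0)
        first = np.array(list(ens.solutions[0].values.values()))
        for sol in ens.solutions[1:]:
            assert np.allclose(first, np.array(list(sol.values.values())))
        assert all(a == 100.0 for a in ens.accuracies)

    def test_impossible_floor_is_infeasible(self, molecular_fixture):
        net, definition, d1, _, training = molecular_fixture
        config = QSPConfig(accuracy_floor=101.0)
        with pytest.raises(qsp.EnsembleInfeasibleError):
            qsp.sample_ensemble("pat", "drugA", net, training,
                                {p: 0.5 * e for p, e in d1.targets},
                                config=config, seed=0)

    def test_mean_tsignal_seed_stable_within_monte_carlo_error(self, molecular_fixture):
        net, definition, d1, _, training = molecular_fixture
        modulation = {p: 0.8 * e for p, e in d1.targets}
        means, ses = [], []
        for seed in (1, 2):
            ens = qsp.sample_ensemble("pat", "drugA", net, training, modulation, seed=seed)
            ts = [qsp.compute_tsignal(s, definition) for s in ens.solutions]
            means.append(np.mean(ts))
            ses.append(np.std(ts, ddof=1) / np.sqrt(len(ts)))
        assert abs(means[0] - means[1]) < 4 * max(ses)


def test_opposite_target_signs_give_opposite_tsignals(molecular_fixture):
    net, definition, d1, d2, _ = molecular_fixture
    s1 = qsp.propagate_activity(net, {p: float(e) for p, e in d1.targets})
    s2 = qsp.propagate_activity(net, {p: float(e) for p, e in d2.targets})
    t1 = qsp.compute_tsignal(s1, definition)
    t2 = qsp.compute_tsignal(s2, definition)
    assert t1 > 0 > t2
    assert t1 == pytest.approx(-t2, rel=1e-6)


def test_activity_vector_rejects_out_of_range():
    with pytest.raises(ValueError):
        ActivityVector(values={"A": 1.0})
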