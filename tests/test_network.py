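import json
from itertools import product

import numpy as np
import pandas as pd
import pytest

from framingnet.fixtures import random_cpts, random_structure
from framingnet.network import (
    CategoricalDataset,
    ContradictoryEvidenceError,
    CPTSet,
    NetworkStructure,
    VariableSpec,
    estimate_cpts,
    joint_probability,
    posterior_target,
    predict_target,
)

from helpers import brute_posterior, full_joint
from conftest import make_dataset


class TestStructureConstraints:
    def _vars(self):
        return [
            VariableSpec("a", "T1", ("x", "y")),
            VariableSpec("m", "MESSAGE", ("gain", "nonloss", "nongain", "loss")),
            VariableSpec("s", "T2", ("x", "y")),
            VariableSpec("z", "OUTCOME", ("x", "y")),
        ]

    def test_valid_structure(self):
        s = NetworkStructure(self._vars(), [("a", "z"), ("m", "s"), ("s", "z")])
        assert s.outcome == "z" and s.message == "m"
        assert s.parents("z") == ("a", "s")

    def test_arc_into_message_rejected(self):
        with pytest.raises(ValueError, match="parentless"):
            NetworkStructure(self._vars(), [("a", "m")])

    def test_outcome_must_be_childless(self):
        # an outgoing outcome arc always also runs against time order, so
        # either guard may fire first
        with pytest.raises(ValueError, match="no children|time orientation"):
            NetworkStructure(self._vars(), [("z", "s")])

    def test_time_orientation_enforced(self):
        with pytest.raises(ValueError, match="time orientation"):
            NetworkStructure(self._vars(), [("s", "a")])

    def test_cycle_rejected(self):
        variables = [
            VariableSpec("p", "T1", ("x", "y")),
            VariableSpec("q", "T1", ("x", "y")),
            VariableSpec("z", "OUTCOME", ("x", "y")),
        ]
        with pytest.raises(ValueError, match="cycle"):
            NetworkStructure(variables, [("p", "q"), ("q", "p")])

    def test_message_needs_four_categories(self):
        with pytest.raises(ValueError, match="4 categories"):
            VariableSpec("m", "MESSAGE", ("a", "b", "c"))

    def test_exactly_one_outcome(self):
        with pytest.raises(ValueError, match="OUTCOME"):
            NetworkStructure([VariableSpec("a", "T1", ("x", "y"))], [])


class TestEstimateCPTs:
    def test_laplace_smoothing_arithmetic(self):
        variables = [
            VariableSpec("x", "T1", ("a", "b", "c")),
            VariableSpec("z", "OUTCOME", ("u", "v")),
        ]
        structure = NetworkStructure(variables, [])
        frame = pd.DataFrame({"x": ["a", "a"], "z": ["u", "v"]})
        cpts = estimate_cpts(structure, CategoricalDataset(structure, frame), alpha=1.0)
        # counts (2, 0, 0) with alpha=1 -> (3/5, 1/5, 1/5)
        np.testing.assert_allclose(cpts.tables["x"][0], [3 / 5, 1 / 5, 1 / 5])

    def test_deterministic_relation_unsmoothed_gives_indicators(self):
        variables = [
            VariableSpec("x", "T1", ("a", "b")),
            VariableSpec("z", "OUTCOME", ("u", "v")),
        ]
        structure = NetworkStructure(variables, [("x", "z")])
        frame = pd.DataFrame({"x": ["a", "b", "a", "b"], "z": ["u", "v", "u", "v"]})
        cpts = estimate_cpts(structure, CategoricalDataset(structure, frame), alpha=0.0)
        np.testing.assert_allclose(cpts.tables["z"], [[1, 0], [0, 1]])

    def test_zero_support_row_rejected_without_smoothing(self):
        variables = [
            VariableSpec("x", "T1", ("a", "b")),
            VariableSpec("z", "OUTCOME", ("u", "v")),
        ]
        structure = NetworkStructure(variables, [("x", "z")])
        frame = pd.DataFrame({"x": ["a", "a"], "z": ["u", "v"]})
        with pytest.raises(ValueError, match="support"):
            estimate_cpts(structure, CategoricalDataset(structure, frame), alpha=0.0)

    def test_parameter_recovery_from_known_tables(self, recovery_net):
        structure, cpts = recovery_net
        data = make_dataset(structure, cpts, 10_000, seed=11)
        est = estimate_cpts(structure, data, alpha=1.0)
        worst = max(
            np.abs(est.tables[n] - cpts.tables[n]).max() for n in structure.names
        )
        assert worst <= 0.05

    def test_alpha_limits(self, chain_ab):
        structure, cpts = chain_ab
        data = make_dataset(structure, cpts, 500, seed=3)
        near_uniform = estimate_cpts(structure, data, alpha=1e9)
        np.testing.assert_allclose(near_uniform.tables["B"], 0.5, atol=1e-5)
        raw = estimate_cpts(structure, data, alpha=0.0)
        freq_a = np.mean(data.codes("A") == 0)
        np.testing.assert_allclose(raw.tables["A"][0, 0], freq_a)


class TestJointProbability:
    def test_chain_product(self, chain_ab):
        structure, cpts = chain_ab
        assert joint_probability(structure, cpts, {"A": "a0", "B": "b0"}) == pytest.approx(0.2)

    def test_edgeless_network_is_product_of_marginals(self):
        variables = [
            VariableSpec("p", "T1", ("x", "y")),
            VariableSpec("z", "OUTCOME", ("u", "v")),
        ]
        structure = NetworkStructure(variables, [])
        cpts = CPTSet(structure, {"p": np.array([[0.3, 0.7]]), "z": np.array([[0.9, 0.1]])})
        assert joint_probability(structure, cpts, {"p": "y", "z": "u"}) == pytest.approx(0.63)

    def test_incomplete_assignment_rejected(self, chain_ab):
        structure, cpts = chain_ab
        with pytest.raises(ValueError, match="incomplete"):
            joint_probability(structure, cpts, {"A": "a0"})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_joint_and_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        structure = random_structure(rng, n_nodes=5)
        cpts = random_cpts(structure, rng)
        joint = full_joint(structure, cpts)
        assert sum(joint.values()) == pytest.approx(1.0)
        names = structure.names
        for combo, expected in list(joint.items())[::7]:
            got = joint_probability(structure, cpts, dict(zip(names, combo)))
            assert got == pytest.approx(expected, abs=1e-12)


class TestPosterior:
    def test_prior_marginal_without_evidence(self):
        variables = [
            VariableSpec("p", "T1", ("x", "y")),
            VariableSpec("z", "OUTCOME", ("u", "v", "w")),
        ]
        structure = NetworkStructure(variables, [])
        cpts = CPTSet(
            structure,
            {"p": np.array([[0.3, 0.7]]), "z": np.array([[0.5, 0.2, 0.3]])},
        )
        np.testing.assert_allclose(posterior_target(structure, cpts, {}), [0.5, 0.2, 0.3])

    def test_full_parent_evidence_returns_cpt_row(self, chain_ab):
        structure, cpts = chain_ab
        np.testing.assert_allclose(
            posterior_target(structure, cpts, {"A": "a1"}), [0.1, 0.9]
        )

    def test_partial_evidence_matches_brute_force(self, six_node):
        structure, cpts = six_node
        evidence = {"u": "medium", "v": "high", "msg": "loss"}
        got = posterior_target(structure, cpts, {"u": "medium", "v": "high"}, message="loss")
        expected = brute_posterior(structure, cpts, "z", evidence)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_observing_outcome_rejected(self, chain_ab):
        structure, cpts = chain_ab
        with pytest.raises(ValueError, match="outcome"):
            posterior_target(structure, cpts, {"B": "b0"})

    def test_contradictory_evidence_is_distinct_condition(self):
        variables = [
            VariableSpec("p", "T1", ("x", "y")),
            VariableSpec("z", "OUTCOME", ("u", "v")),
        ]
        structure = NetworkStructure(variables, [("p", "z")])
        cpts = CPTSet(
            structure,
            {"p": np.array([[1.0, 0.0]]), "z": np.array([[0.5, 0.5], [0.2, 0.8]])},
        )
        with pytest.raises(ContradictoryEvidenceError):
            posterior_target(structure, cpts, {"p": "y"})

    def test_posterior_invariant_to_declaration_order(self, six_node):
        structure, cpts = six_node
        perm = [structure.variables[i] for i in (4, 0, 2, 1, 3, 5)]
        permuted = NetworkStructure(perm, structure.arcs)
        cpts2 = CPTSet(permuted, cpts.tables)
        obs = {"v": "low"}
        np.testing.assert_allclose(
            posterior_target(structure, cpts, obs, message="gain"),
            posterior_target(permuted, cpts2, obs, message="gain"),
            atol=1e-12,
        )

    def test_predict_breaks_ties_toward_earlier_category(self):
        variables = [
            VariableSpec("p", "T1", ("x", "y")),
            VariableSpec("z", "OUTCOME", ("neg", "zero", "pos")),
        ]
        structure = NetworkStructure(variables, [])
        cpts = CPTSet(
            structure,
            {"p": np.array([[0.5, 0.5]]), "z": np.array([[0.2, 0.4, 0.4]])},
        )
        assert predict_target(structure, cpts, {}) == "zero"


class TestSerialization:
    def test_round_trip_equality(self, six_node, tmp_path):
        from framingnet.fixtures import load_structure
        from framingnet.network import save_network

        structure, cpts = six_node
        path = tmp_path / "net.json"
        save_network(path, structure, cpts)
        loaded, loaded_cpts = load_structure(path)
        assert loaded == structure
        for n in structure.names:
            np.testing.assert_allclose(loaded_cpts.tables[n], cpts.tables[n])

    def test_parent_config_keys_join_labels(self, chain_ab):
        structure, cpts = chain_ab
        doc = cpts.to_json_dict()
        assert set(doc["cpts"]["B"]) == {"a0", "a1"}

    def test_invalid_cpt_rows_rejected(self, chain_ab):
        structure, _ = chain_ab
        bad = {"A": np.array([[0.4, 0.6]]), "B": np.array([[0.7, 0.5], [0.1, 0.9]])}
        with pytest.raises(ValueError, match="sum to 1"):
            CPTSet(structure, bad)
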