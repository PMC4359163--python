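"""Minimal-intervention-set enumeration: validity, minimality, oracle equivalence."""

import itertools

import numpy as np
import pytest

from temnet.boolnet import parse_network
from temnet.mis import (
    CATEGORY_INFLAMMATORY,
    CATEGORY_RTK,
    CATEGORY_TIE2_LIGAND,
    CATEGORY_VEGFR1_LIGAND,
    Intervention,
    InterventionSet,
    MISQuery,
    NetworkValidationError,
    classify_mis,
    is_valid_intervention,
    mis_bruteforce,
    mis_unroll,
    propagate_polarities,
    unroll_network,
)
from temnet.synthetic import generate_random_network


def random_query(seed, n_nodes=8, k_max=3):
    network = generate_random_network(n_nodes, max_indegree=3, seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    n_roots = int(rng.integers(1, 3))
    roots = [network.nodes[i] for i in rng.choice(network.n_nodes, n_roots, replace=False)]
    constraint = {r: int(rng.integers(0, 2)) for r in roots}
    return MISQuery(network=network, constraint=constraint, k_max=k_max)


class TestValidity:
    def test_upstream_over_expression_forces_the_target(self):
        network = parse_network("B, A\nA, A\n")
        query = MISQuery(network=network, constraint={"B": 1})
        assert is_valid_intervention(query, [Intervention("A", 1)])
        assert not is_valid_intervention(query, [Intervention("A", 0)])

    def test_incompatible_set_rejected(self):
        with pytest.raises(NetworkValidationError):
            InterventionSet([Intervention("A", 0), Intervention("A", 1)])

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_explicit_fixed_point_scan(self, seed):
        query = random_query(seed)
        rng = np.random.default_rng(seed)
        nodes = list(query.network.nodes)
        picked = [nodes[i] for i in rng.choice(len(nodes), 2, replace=False)]
        candidate = InterventionSet(
            Intervention(n, int(rng.integers(0, 2))) for n in picked
        )
        clamped = query.network.clamp(candidate.as_clamps())
        fps = clamped.fixed_points()
        expected = bool(fps) and all(
            all(s[n] == v for n, v in query.constraint.items()) for s in fps
        )
        assert is_valid_intervention(query, candidate) == expected


class TestBruteForce:
    def test_and_gate_enumeration_by_hand(self):
        network = parse_network("C, A & B\nA, A\nB, B\n")
        query = MISQuery(network=network, constraint={"C": 1})
        result = mis_bruteforce(query)
        expected = [
            InterventionSet([Intervention("C", 1)]),
            InterventionSet([Intervention("A", 1), Intervention("B", 1)]),
        ]
        assert sorted(result, key=InterventionSet.sort_key) == sorted(
            expected, key=InterventionSet.sort_key
        )
        # the size-3 superset is excluded as non-minimal
        assert InterventionSet(
            [Intervention("A", 1), Intervention("B", 1), Intervention("C", 1)]
        ) not in result

    def test_already_satisfied_constraint_yields_the_empty_set(self):
        network = parse_network("A, 1\nB, A\n")
        query = MISQuery(network=network, constraint={"B": 1})
        assert mis_bruteforce(query) == [InterventionSet()]

    @pytest.mark.parametrize("seed", range(15))
    def test_reported_sets_are_valid_and_minimal(self, seed):
        query = random_query(seed + 500)
        for mis in mis_bruteforce(query):
            assert is_valid_intervention(query, mis)
            for size in range(len(mis)):
                for subset in itertools.combinations(mis, size):
                    assert not is_valid_intervention(query, InterventionSet(subset))


class TestUnroll:
    def test_tree_terminates_at_duplicates(self):
        network = parse_network("A, B\nB, !A\n")
        (tree,) = unroll_network(network, ["A"])
        assert tree.node == "A"
        assert tree.children[0].node == "B"
        assert tree.children[0].children[0].terminated  # A repeats on the path

    def test_propagation_proposes_the_and_gate_vectors(self):
        network = parse_network("C, A & B\nA, A\nB, B\n")
        (tree,) = unroll_network(network, ["C"])
        vectors = propagate_polarities(network, tree, 1, k_max=3)
        assert frozenset({("C", 1)}) in vectors
        assert frozenset({("A", 1), ("B", 1)}) in vectors

    def test_matches_bruteforce_on_the_and_gate(self):
        network = parse_network("C, A & B\nA, A\nB, B\n")
        query = MISQuery(network=network, constraint={"C": 1})
        assert mis_unroll(query) == mis_bruteforce(query)

    def test_off_path_oscillator_requires_a_stabilizing_clamp(self):
        # B oscillates regardless of A, so no fixed point exists until B is
        # clamped; every MIS must therefore include a clamp on B even
        # though B is outside the constraint's regulator cone.
        network = parse_network("A, A\nB, !B\n")
        query = MISQuery(network=network, constraint={"A": 1}, k_max=2)
        result = mis_unroll(query)
        assert result == mis_bruteforce(query)
        assert result
        assert all(any(iv.node == "B" for iv in mis) for mis in result)

    @pytest.mark.parametrize("seed", range(30))
    def test_set_equality_with_bruteforce_on_random_networks(self, seed):
        query = random_query(seed, n_nodes=8)
        assert mis_unroll(query) == mis_bruteforce(query)

    def test_antitone_in_k_max(self):
        for seed in range(5):
            query2 = random_query(seed, k_max=2)
            query3 = MISQuery(
                network=query2.network, constraint=query2.constraint, k_max=3
            )
            assert set(mis_bruteforce(query2)) <= set(mis_bruteforce(query3))

    def test_polarity_restrictions_are_respected(self):
        network = parse_network("B, A\nA, A\n")
        query = MISQuery(
            network=network,
            constraint={"B": 1},
            allowed_polarities={"A": (0,), "B": (0, 1)},
        )
        result = mis_unroll(query)
        assert result == [InterventionSet([Intervention("B", 1)])]


class TestClassification:
    categories = {
        "TIE2": CATEGORY_RTK,
        "VEGFR1": CATEGORY_RTK,
        "TGFB": CATEGORY_INFLAMMATORY,
        "TNFA": CATEGORY_INFLAMMATORY,
        "VEGF": CATEGORY_VEGFR1_LIGAND,
        "PLGF": CATEGORY_VEGFR1_LIGAND,
        "ANG1": CATEGORY_TIE2_LIGAND,
        "ANG2": CATEGORY_TIE2_LIGAND,
    }
    names = {"TGFB": "TGF-β", "TNFA": "TNF-α", "PLGF": "PlGF", "ANG2": "ANG-2", "TIE2": "TIE-2"}

    def test_dampening_row_layout(self):
        mis = InterventionSet(
            [Intervention("TIE2", 0), Intervention("TGFB", 1), Intervention("VEGF", 1)]
        )
        (row,) = classify_mis([mis], self.categories, self.names)
        assert row["rtk_inhibited"] == "TIE-2"
        assert row["inflammatory_up"] == "TGF-β"
        assert row["vegfr1_ligand_up"] == "VEGF"
        assert row["tie2_ligand_up"] == "-"

    def test_promoting_row_layout(self):
        mis = InterventionSet(
            [Intervention("TNFA", 1), Intervention("ANG2", 1), Intervention("PLGF", 1)]
        )
        (row,) = classify_mis([mis], self.categories, self.names)
        assert row["rtk_inhibited"] == "-"
        assert row["inflammatory_up"] == "TNF-α"
        assert row["vegfr1_ligand_up"] == "PlGF"
        assert row["tie2_ligand_up"] == "ANG-2"

    def test_empty_list_gives_empty_report(self):
        assert classify_mis([], self.categories) == []

    def test_uncategorized_node_lands_in_other(self):
        mis = InterventionSet([Intervention("MYSTERY", 1)])
        (row,) = classify_mis([mis], self.categories)
        assert row["other"] != "-"
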