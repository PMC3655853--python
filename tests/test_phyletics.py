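"""Tests for phyletic set queries, paralog statistics and gain/loss parsimony."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sagkit import (
    AnnotatedTree,
    EvolutionSpec,
    PhyleticMatrix,
    cluster_paralogs,
    core_families,
    dollo_ancestral_states,
    gain_loss_recovery,
    mp_place_and_count,
    paralog_density,
    shared_exclusive_families,
    signature_families,
    simulate_gene_content_evolution,
)
from sagkit.trees import TreeError


class TestCoreFamilies:
    def test_all_ones_matrix(self):
        matrix = PhyleticMatrix(["A", "B"], ["g1", "g2"], np.ones((2, 2), dtype=int))
        assert core_families(matrix, ["g1", "g2"]) == {"A", "B"}

    def test_toy_patterns(self, toy_matrix):
        assert core_families(toy_matrix, ["g1", "g2", "g3"]) == {"A"}
        assert core_families(toy_matrix, ["g1", "g2"]) == {"A", "B"}

    def test_empty_taxa_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            core_families(toy_matrix, [])

    def test_unknown_genome_rejected(self, toy_matrix):
        with pytest.raises(KeyError):
            core_families(toy_matrix, ["nope"])

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_adding_a_genome_never_enlarges_the_core(self, data):
        n_fam = data.draw(st.integers(1, 8))
        n_gen = data.draw(st.integers(2, 6))
        bits = data.draw(
            st.lists(
                st.lists(st.integers(0, 1), min_size=n_gen, max_size=n_gen),
                min_size=n_fam,
                max_size=n_fam,
            )
        )
        genomes = [f"g{i}" for i in range(n_gen)]
        matrix = PhyleticMatrix([f"f{i}" for i in range(n_fam)], genomes, bits)
        k = data.draw(st.integers(1, n_gen - 1))
        assert core_families(matrix, genomes[: k + 1]) <= core_families(matrix, genomes[:k])


class TestSignatureAndShared:
    def test_clade_exclusive_family(self):
        matrix = PhyleticMatrix(
            ["X", "Y"],
            ["c1", "c2", "b1"],
            [[1, 1, 0], [1, 1, 1]],
        )
        assert signature_families(matrix, ["c1", "c2"], ["b1"]) == {"X"}

    def test_background_presence_excludes(self):
        matrix = PhyleticMatrix(["X"], ["c1", "c2", "b1"], [[1, 1, 1]])
        assert signature_families(matrix, ["c1", "c2"], ["b1"]) == set()

    def test_partial_clade_presence_with_relaxed_fraction(self):
        matrix = PhyleticMatrix(["X"], ["c1", "c2", "b1"], [[1, 0, 0]])
        assert signature_families(matrix, ["c1", "c2"], ["b1"], min_clade_fraction=0.5) == {"X"}
        assert signature_families(matrix, ["c1", "c2"], ["b1"], min_clade_fraction=1.0) == set()

    def test_overlapping_sets_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            signature_families(toy_matrix, ["g1"], ["g1", "g2"])

    def test_shared_exclusive_toy(self):
        # families shared by n1+n2, absent from c1+c2, majority of e1..e3
        genomes = ["n1", "n2", "c1", "c2", "e1", "e2", "e3"]
        counts = [
            [1, 1, 0, 0, 1, 1, 0],  # S1: qualifies
            [1, 1, 0, 0, 1, 1, 1],  # S2: qualifies
            [1, 1, 1, 0, 1, 1, 1],  # present in c1
            [1, 0, 0, 0, 1, 1, 1],  # missing in n2
            [1, 1, 0, 0, 1, 0, 0],  # only 1/3 of majority_in
        ]
        matrix = PhyleticMatrix([f"S{i+1}" for i in range(5)], genomes, counts)
        result = shared_exclusive_families(
            matrix, in_all=["n1", "n2"], absent_in=["c1", "c2"], majority_in=["e1", "e2", "e3"]
        )
        assert result == {"S1", "S2"}

    def test_majority_threshold_one_reduces_to_core(self):
        genomes = ["n1", "c1", "e1", "e2"]
        counts = [[1, 0, 1, 1], [1, 0, 1, 0]]
        matrix = PhyleticMatrix(["A", "B"], genomes, counts)
        strict = shared_exclusive_families(
            matrix, ["n1"], ["c1"], ["e1", "e2"], majority_threshold=1.0 - 1e-12
        )
        assert strict == {"A"}  # B present in only half of majority_in


class TestParalogs:
    @pytest.mark.parametrize(
        "counts, expected",
        [([1, 1, 2, 0], 4 / 3), ([1, 1, 1], 1.0), ([3, 3], 3.0)],
    )
    def test_density(self, counts, expected):
        matrix = PhyleticMatrix(
            [f"f{i}" for i in range(len(counts))], ["g"], np.array(counts)[:, None]
        )
        assert paralog_density(matrix, "g") == pytest.approx(expected)

    def test_density_at_least_one(self, rng):
        for _ in range(30):
            counts = rng.integers(0, 5, size=(10, 1))
            if not (counts >= 1).any():
                continue
            matrix = PhyleticMatrix([f"f{i}" for i in range(10)], ["g"], counts)
            density = paralog_density(matrix, "g")
            assert density >= 1.0
            if (counts[counts >= 1] == 1).all():
                assert density == 1.0

    def test_empty_genome_rejected(self):
        matrix = PhyleticMatrix(["f1"], ["g"], [[0]])
        with pytest.raises(ValueError):
            paralog_density(matrix, "g")

    def test_single_linkage_basics(self):
        clusters = cluster_paralogs([("a", "b", 90.0)], ["a", "b", "c"], threshold=80)
        assert clusters == [frozenset({"a", "b"}), frozenset({"c"})]

    def test_chain_transitivity(self):
        clusters = cluster_paralogs(
            [("a", "b", 85.0), ("b", "c", 85.0)], ["a", "b", "c"], threshold=80
        )
        assert clusters == [frozenset({"a", "b", "c"})]

    def test_threshold_above_all_edges_gives_singletons(self):
        clusters = cluster_paralogs([("a", "b", 99.9)], ["a", "b"], threshold=100)
        assert clusters == [frozenset({"a"}), frozenset({"b"})]

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            cluster_paralogs([("a", "z", 90.0)], ["a", "b"], threshold=50)

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_higher_threshold_refines_lower(self, data):
        n = data.draw(st.integers(2, 10))
        genes = [f"g{i}" for i in range(n)]
        n_edges = data.draw(st.integers(0, 15))
        edges = [
            (
                genes[data.draw(st.integers(0, n - 1))],
                genes[data.draw(st.integers(0, n - 1))],
                data.draw(st.floats(0, 100, allow_nan=False)),
            )
            for _ in range(n_edges)
        ]
        t1 = data.draw(st.floats(0, 100))
        t2 = data.draw(st.floats(0, 100))
        t1, t2 = min(t1, t2), max(t1, t2)
        coarse = cluster_paralogs(edges, genes, threshold=t1)
        fine = cluster_paralogs(edges, genes, threshold=t2)
        for cluster in fine:
            assert any(cluster <= c for c in coarse)


class TestGainLoss:
    def _annotated(self, tree, node_states, universe=None):
        return tree.with_states(node_states, family_universe=universe)

    def test_identical_sets_no_events(self, balanced_tree):
        tree = self._annotated(balanced_tree, {"n1": {"A", "B"}})
        result = mp_place_and_count(tree, "n1", {"A", "B"})
        assert (result.n_gained, result.n_lost) == (0, 0)

    def test_hand_example(self, balanced_tree):
        tree = self._annotated(
            balanced_tree, {"n1": {"A", "B", "C"}}, universe={"A", "B", "C", "D"}
        )
        result = mp_place_and_count(tree, "n1", {"A", "D"})
        assert result.gained == {"D"}
        assert result.lost == {"B", "C"}

    def test_empty_genome_all_losses(self, balanced_tree):
        tree = self._annotated(balanced_tree, {"n1": {"A"}})
        result = mp_place_and_count(tree, "n1", set())
        assert (result.n_gained, result.n_lost) == (0, 1)

    def test_missing_ancestral_state_names_family(self, balanced_tree):
        tree = self._annotated(balanced_tree, {"n1": {"A"}}, universe={"A"})
        with pytest.raises(TreeError, match="'Z'"):
            mp_place_and_count(tree, "n1", {"A", "Z"})

    def test_set_identity_on_simulations(self, balanced_tree):
        for seed in range(5):
            sim = simulate_gene_content_evolution(
                EvolutionSpec(
                    tree=balanced_tree, root_family_count=40, gain_rate=2.0,
                    loss_rate=0.5, seed=seed,
                )
            )
            for leaf in sim.tree.leaf_names():
                parent = sim.tree.parent(leaf)
                result = mp_place_and_count(sim.tree, parent, sim.tree.presence(leaf))
                assert len(sim.tree.presence(leaf)) == (
                    len(sim.tree.presence(parent)) + result.n_gained - result.n_lost
                )

    def test_recovery_exact_without_gains(self, balanced_tree):
        spec = EvolutionSpec(
            tree=balanced_tree, root_family_count=100, gain_rate=0.0, loss_rate=0.4, seed=7
        )
        stats = gain_loss_recovery(spec, reps=20)
        assert stats.exact_match_fraction == 1.0
        assert stats.mean_abs_error_losses == 0.0

    def test_recovery_no_events(self, balanced_tree):
        spec = EvolutionSpec(tree=balanced_tree, root_family_count=50, seed=8)
        stats = gain_loss_recovery(spec, reps=10)
        assert stats.exact_match_fraction == 1.0
        assert stats.mean_abs_error_gains == 0.0


class TestDollo:
    def test_family_in_all_leaves_present_everywhere(self, balanced_tree):
        matrix = PhyleticMatrix(["A"], ["a", "b", "c", "d"], [[1, 1, 1, 1]])
        annotated = dollo_ancestral_states(balanced_tree, matrix)
        for node in annotated.node_ids():
            assert "A" in annotated.presence(node)

    def test_singleton_family_gained_on_leaf_branch(self, balanced_tree):
        matrix = PhyleticMatrix(["A"], ["a", "b", "c", "d"], [[1, 0, 0, 0]])
        annotated = dollo_ancestral_states(balanced_tree, matrix)
        assert "A" in annotated.presence("a")
        for node in ("b", "c", "d", "n1", "n2", "root"):
            assert "A" not in annotated.presence(node)

    def test_sister_pair_family_present_at_parent_only(self, balanced_tree):
        matrix = PhyleticMatrix(["A"], ["a", "b", "c", "d"], [[1, 1, 0, 0]])
        annotated = dollo_ancestral_states(balanced_tree, matrix)
        for node in ("a", "b", "n1"):
            assert "A" in annotated.presence(node)
        for node in ("root", "n2", "c", "d"):
            assert "A" not in annotated.presence(node)

    def test_presence_sets_are_connected_subtrees(self, balanced_tree, rng):
        for _ in range(20):
            counts = rng.integers(0, 2, size=(12, 4))
            matrix = PhyleticMatrix(
                [f"f{i}" for i in range(12)], ["a", "b", "c", "d"], counts
            )
            annotated = dollo_ancestral_states(balanced_tree, matrix)
            for i, family in enumerate(matrix.families):
                nodes_with = {
                    node for node in annotated.node_ids()
                    if family in annotated.presence(node)
                }
                roots = [
                    node for node in nodes_with
                    if annotated.parent(node) not in nodes_with
                ]
                if nodes_with:
                    assert len(roots) == 1  # single origination => connected
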