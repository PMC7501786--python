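import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad

from mc3.phylo import (
    Alignment,
    NNIProposal,
    NodeHeightProposal,
    PhyloState,
    PhyloTarget,
    PopSizeScaleProposal,
    Tree,
    TreeScaleProposal,
    coalescent_log_density,
    jc69_log_likelihood,
    simulate_coalescent_tree,
    simulate_jc69_alignment,
)


def two_taxon_tree(height: float) -> Tree:
    return Tree(
        taxa=["A", "B"],
        parent=[2, 2, -1],
        children=[[-1, -1], [-1, -1], [0, 1]],
        heights=[0.0, 0.0, height],
        root=2,
    )


def _p_matrix(t: float, rate: float) -> np.ndarray:
    e = math.exp(-4.0 * rate * t / 3.0)
    ps, pd = 0.25 + 0.75 * e, 0.25 - 0.25 * e
    return np.full((4, 4), pd) + np.eye(4) * (ps - pd)


def brute_force_jc69(tree: Tree, alignment: Alignment, rate: float = 1.0) -> float:
    """Direct sum over all internal-node state assignments, per site."""
    internals = [v for v in range(tree.n_taxa, tree.n_nodes)]
    row_of = {t: i for i, t in enumerate(alignment.taxa)}
    total = 0.0
    for site in range(alignment.n_sites):
        site_sum = 0.0
        for assignment in itertools.product(range(4), repeat=len(internals)):
            states = {v: s for v, s in zip(internals, assignment)}
            for tip in range(tree.n_taxa):
                states[tip] = alignment.codes[row_of[tree.taxa[tip]], site]
            prob = 0.25  # uniform root frequency
            for node in range(tree.n_nodes):
                parent = tree.parent[node]
                if parent < 0:
                    continue
                t = tree.heights[parent] - tree.heights[node]
                prob *= _p_matrix(t, rate)[states[parent], states[node]]
            site_sum += prob
        total += math.log(site_sum)
    return total


class TestJC69Likelihood:
    def test_zero_length_identical_pair(self):
        tree = two_taxon_tree(0.0)
        # zero path length: tips must match the (uniform) root state
        aln = Alignment.from_sequences(["A", "B"], ["A", "A"])
        # height 0 makes the internal node coincide with the tips
        assert jc69_log_likelihood(tree, aln) == pytest.approx(math.log(0.25), abs=1e-12)

    def test_two_taxon_closed_form(self):
        # total tip-to-tip path 0.3 => p_same = 0.25 + 0.75 e^{-0.4}
        tree = two_taxon_tree(0.15)
        aln = Alignment.from_sequences(["A", "B"], ["C", "C"])
        expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-0.4)))
        assert jc69_log_likelihood(tree, aln, rate=1.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("newick,seqs", [
        ("((A:0.2,B:0.2):0.3,C:0.5);", ["AC", "GT", "AA"]),
        ("((A:0.1,B:0.1):0.4,(C:0.3,D:0.3):0.2);", ["ACG", "ACT", "GGA", "TAC"]),
        ("(((A:0.1,B:0.1):0.1,C:0.2):0.2,D:0.4);", ["AAA", "CCC", "GGG", "TTT"]),
    ])
    def test_matches_enumeration_oracle(self, newick, seqs):
        tree = Tree.from_newick(newick)
        aln = Alignment.from_sequences(list(tree.taxa), seqs)
        assert jc69_log_likelihood(tree, aln) == pytest.approx(
            brute_force_jc69(tree, aln), abs=1e-10
        )

    def test_pattern_compression_is_transparent(self):
        rng = np.random.default_rng(5)
        tree = simulate_coalescent_tree(5, 1.0, rng)
        aln = simulate_jc69_alignment(tree, 40, 1.0, rng)
        repeated = Alignment.from_sequences(
            list(aln.taxa), [aln.sequence(t) * 3 for t in aln.taxa]
        )
        assert jc69_log_likelihood(tree, repeated) == pytest.approx(
            3 * jc69_log_likelihood(tree, aln), rel=1e-12
        )

    def test_mismatched_taxa_rejected(self):
        tree = two_taxon_tree(0.1)
        aln = Alignment.from_sequences(["A", "X"], ["AA", "AA"])
        with pytest.raises(ValueError):
            jc69_log_likelihood(tree, aln)


class TestCoalescentDensity:
    def test_two_taxon_unit_popsize(self):
        assert coalescent_log_density(two_taxon_tree(0.7), 1.0) == pytest.approx(-0.7)

    def test_two_taxon_popsize_two(self):
        expected = -math.log(2) - 0.35
        assert coalescent_log_density(two_taxon_tree(0.7), 2.0) == pytest.approx(expected)

    def test_density_integrates_to_one(self):
        value, _ = quad(
            lambda t: math.exp(coalescent_log_density(two_taxon_tree(t), 1.3)), 0, 200
        )
        assert value == pytest.approx(1.0, abs=1e-6)

    def test_scaling_change_of_variables(self):
        """Scaling heights and Ne by c shifts log density by -(n-1) log c."""
        rng = np.random.default_rng(11)
        tree = simulate_coalescent_tree(7, 1.0, rng)
        c = 3.7
        scaled = tree.copy()
        scaled.heights *= c
        base = coalescent_log_density(tree, 2.0)
        assert coalescent_log_density(scaled, 2.0 * c) == pytest.approx(
            base - (7 - 1) * math.log(c), rel=1e-12
        )

    def test_non_ultrametric_rejected(self):
        tree = two_taxon_tree(0.5)
        tree.heights[0] = 0.1
        with pytest.raises(ValueError):
            coalescent_log_density(tree, 1.0)


class TestSimulators:
    def test_two_taxon_tmrca_mean(self):
        rng = np.random.default_rng(1)
        tm = [simulate_coalescent_tree(2, 1.0, rng).heights[2] for _ in range(10_000)]
        assert np.mean(tm) == pytest.approx(1.0, abs=0.05)

    def test_ten_taxon_tmrca_mean(self):
        rng = np.random.default_rng(2)
        tm = [
            max(simulate_coalescent_tree(10, 1.0, rng).heights)
            for _ in range(10_000)
        ]
        # E[TMRCA] = sum_k 2/(k(k-1)) = 2 (1 - 1/n)
        assert np.mean(tm) == pytest.approx(1.8, abs=0.1)

    def test_simulated_trees_satisfy_invariants(self):
        rng = np.random.default_rng(3)
        for n in (2, 3, 5, 12):
            simulate_coalescent_tree(n, 0.5, rng).validate()

    def test_zero_rate_alignment_is_constant(self):
        rng = np.random.default_rng(4)
        tree = simulate_coalescent_tree(6, 1.0, rng)
        aln = simulate_jc69_alignment(tree, 30, 0.0, rng)
        seqs = {aln.sequence(t) for t in aln.taxa}
        assert len(seqs) == 1

    def test_pairwise_difference_fraction(self):
        """At total distance 0.5 the JC69 mismatch fraction is
        0.75 (1 - e^{-4*0.5/3}) ~ 0.365."""
        rng = np.random.default_rng(6)
        tree = two_taxon_tree(0.25)
        aln = simulate_jc69_alignment(tree, 10_000, 1.0, rng)
        diff = np.mean(aln.codes[0] != aln.codes[1])
        assert diff == pytest.approx(0.75 * (1 - math.exp(-2 / 3)), abs=0.02)


class TestProposals:
    def _state(self, n=6, seed=7):
        rng = np.random.default_rng(seed)
        return PhyloState(simulate_coalescent_tree(n, 1.0, rng), 1.0), rng

    def test_nni_is_an_involution_on_topology(self):
        state, rng = self._state()
        before = state.tree.clades()
        prop = NNIProposal()
        # replay the same node/child choice by reusing a fixed-seed stream
        new, lh = prop.propose(state, np.random.default_rng(42))
        assert lh == 0.0
        if new is None:
            pytest.skip("geometrically invalid draw")
        again, _ = prop.propose(new, np.random.default_rng(42))
        assert again is not None
        assert again.tree.clades() == before
        assert new.tree.clades() != before

    def test_nni_produces_valid_trees(self):
        state, rng = self._state(8)
        prop = NNIProposal()
        produced = 0
        for _ in range(200):
            new, _ = prop.propose(state, rng)
            if new is not None:
                new.tree.validate()
                produced += 1
                state = new
        assert produced > 50

    def test_tree_scale_multiplier_one_is_identity(self):
        state, _ = self._state()

        class FixedRng:
            def random(self):
                return 0.5  # multiplier exp(0) = 1

        new, lh = TreeScaleProposal().propose(state, FixedRng(), 0.5)
        assert lh == 0.0
        np.testing.assert_array_equal(new.tree.heights, state.tree.heights)

    def test_tree_scale_hastings_exponent(self):
        state, _ = self._state(5)

        class FixedRng:
            def random(self):
                return 1.0

        new, lh = TreeScaleProposal().propose(state, FixedRng(), 0.8)
        m = math.exp(0.8 * 0.5)
        assert lh == pytest.approx((5 - 1) * math.log(m))
        np.testing.assert_allclose(new.tree.heights[5:], state.tree.heights[5:] * m)
        new.tree.validate()

    def test_node_height_move_respects_bracket(self):
        state, rng = self._state(7)
        prop = NodeHeightProposal()
        for _ in range(100):
            new, lh = prop.propose(state, rng)
            assert lh == 0.0
            if new is not None:
                new.tree.validate()
                state = new

    def test_popsize_scale_hastings(self):
        state, _ = self._state()

        class FixedRng:
            def random(self):
                return 1.0

        new, lh = PopSizeScaleProposal().propose(state, FixedRng(), 0.7)
        m = math.exp(0.35)
        assert new.pop_size == pytest.approx(state.pop_size * m)
        assert lh == pytest.approx(math.log(m))


class TestTreeStructure:
    def test_clades_of_balanced_quartet(self):
        tree = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        clades = tree.clades()
        assert frozenset("AB") in clades
        assert frozenset("CD") in clades
        assert frozenset("ABCD") in clades

    def test_newick_round_trip(self):
        rng = np.random.default_rng(9)
        tree = simulate_coalescent_tree(5, 1.0, rng)
        back = Tree.from_newick(tree.newick(), taxa=tree.taxa)
        assert back.clades() == tree.clades()
        for clade_tree in (tree, back):
            clade_tree.validate()
        np.testing.assert_allclose(
            np.sort(back.heights), np.sort(tree.heights), atol=1e-12
        )

    def test_serialization_round_trip_is_exact(self):
        rng = np.random.default_rng(10)
        tree = simulate_coalescent_tree(6, 2.0, rng)
        clone = Tree.from_data(tree.to_data())
        np.testing.assert_array_equal(clone.heights, tree.heights)
        assert clone.clades() == tree.clades()

    def test_validate_rejects_broken_trees(self):
        tree = two_taxon_tree(1.0)
        tree.heights[2] = -0.5
        with pytest.raises(ValueError):
            tree.validate()


class TestPhyloTarget:
    def test_prior_only_target_has_zero_likelihood(self):
        target = PhyloTarget(taxa=["A", "B", "C", "D"])
        state = target.initial_state(np.random.default_rng(0))
        assert target.log_likelihood(state) == 0.0
        assert math.isfinite(target.log_prior(state))

    def test_state_round_trip(self):
        target = PhyloTarget(taxa=list("ABCDE"))
        state = target.initial_state(np.random.default_rng(1))
        clone = target.state_from_data(target.state_to_data(state))
        assert clone.pop_size == state.pop_size
        np.testing.assert_array_equal(clone.tree.heights, state.tree.heights)

    def test_likelihood_prior_decomposition(self):
        rng = np.random.default_rng(2)
        tree = simulate_coalescent_tree(4, 1.0, rng)
        aln = simulate_jc69_alignment(tree, 50, 1.0, rng)
        target = PhyloTarget(aln)
        state = PhyloState(tree, 1.5)
        assert target.log_likelihood(state) == pytest.approx(
            jc69_log_likelihood(tree, aln), rel=1e-12
        )
        lp = target.log_prior(state)
        z = math.log(1.5)
        lognorm = -0.5 * z * z - math.log(1.5 * math.sqrt(2 * math.pi))
        assert lp == pytest.approx(coalescent_log_density(tree, 1.5) + lognorm, rel=1e-12)
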