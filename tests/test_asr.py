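"""Pruning likelihood and marginal ancestral reconstruction."""

import numpy as np
import pytest

from ancestlib.family import AlignedFamily
from ancestlib.asr import marginal_asr, pruning_loglik, rank_ancestral_nodes
from ancestlib.models import AA_INDEX, AMINO_ACIDS
from ancestlib.phylo import PhyloTree
from ancestlib.simulate import FamilySimSpec, simulate_family
from oracles import quartet_loglik, star3_loglik, star3_root_posterior


def fam(ids_seqs, ref=None):
    ids = [i for i, _ in ids_seqs]
    return AlignedFamily(ids, [s for _, s in ids_seqs], ref or ids[0])


class TestTransitionMatrices:
    @pytest.mark.parametrize("t", [0.0, 0.1, 1.0, 10.0])
    def test_rows_sum_to_one(self, wag, poisson, t):
        for model in (wag, poisson):
            p = model.transition_matrix(t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_time_is_identity(self, wag):
        assert np.allclose(wag.transition_matrix(0.0), np.eye(20), atol=1e-12)

    def test_long_time_reaches_equilibrium(self, wag):
        p = wag.transition_matrix(100.0)
        assert np.allclose(p, np.tile(wag.frequencies, (20, 1)), atol=1e-6)

    def test_detailed_balance(self, wag):
        q = wag.rate_matrix
        pi = wag.frequencies
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)


class TestPruningLikelihood:
    def test_two_identical_leaves_zero_branches(self, poisson):
        family = fam([("A1", "A"), ("B1", "A")])
        tree = PhyloTree.from_newick("(A1:0.0,B1:0.0);")
        ll = pruning_loglik(family, tree, poisson)
        assert ll == pytest.approx(np.log(poisson.frequencies[AA_INDEX["A"]]))

    def test_three_leaf_enumeration_oracle(self, wag):
        family = fam([("a", "AC"), ("b", "AD"), ("c", "WC")])
        tree = PhyloTree.from_newick("(a:0.1,b:0.25,c:0.4);")
        ll = pruning_loglik(family, tree, wag)
        expected = sum(
            star3_loglik(wag, [0.1, 0.25, 0.4],
                         [AA_INDEX[family.row(x)[col]] for x in "abc"])
            for col in range(2))
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_quartet_enumeration_oracle(self, wag):
        family = fam([("a", "K"), ("b", "R"), ("c", "K"), ("d", "E")])
        tree = PhyloTree.from_newick(
            "((a:0.15,b:0.3):0.2,(c:0.1,d:0.45):0.05);")
        ll = pruning_loglik(family, tree, wag)
        expected = quartet_loglik(wag, 0.2, 0.05, (0.15, 0.3, 0.1, 0.45),
                                  [AA_INDEX[x] for x in "KRKE"])
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_gaps_are_missing_data(self, wag):
        family = fam([("a", "K"), ("b", "-"), ("c", "K")])
        tree = PhyloTree.from_newick("(a:0.1,b:0.2,c:0.3);")
        ll = pruning_loglik(family, tree, wag)
        expected = star3_loglik(wag, [0.1, 0.2, 0.3],
                                [AA_INDEX["K"], None, AA_INDEX["K"]])
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_rerooting_invariance(self, wag):
        family, tree, _ = simulate_family(FamilySimSpec(n_taxa=6, length=20,
                                                        seed=4))
        ll0 = pruning_loglik(family, tree, wag)
        internals = [nd for nd in tree.tree.preorder_node_iter()
                     if not nd.is_leaf()][1:4]
        for node in internals:
            tree.tree.reroot_at_node(node, update_bipartitions=False)
            assert pruning_loglik(family, tree, wag) == pytest.approx(
                ll0, abs=1e-8)

    def test_leaf_order_invariance(self, wag):
        family, tree, _ = simulate_family(FamilySimSpec(n_taxa=5, length=15,
                                                        seed=7))
        ll0 = pruning_loglik(family, tree, wag)
        perm = list(reversed(range(len(family.ids))))
        shuffled = AlignedFamily([family.ids[i] for i in perm],
                                 [family.sequences[i] for i in perm],
                                 family.ids[perm[0]])
        assert pruning_loglik(shuffled, tree, wag) == pytest.approx(ll0)

    def test_loglik_nonpositive(self, wag, demo_family):
        family, tree, _ = demo_family
        assert pruning_loglik(family, tree, wag) < 0

    def test_mismatched_leaves_listed(self, wag):
        family = fam([("a", "K"), ("b", "R"), ("zz", "E")])
        tree = PhyloTree.from_newick("(a:0.1,b:0.2,c:0.3);")
        with pytest.raises(ValueError, match="zz"):
            pruning_loglik(family, tree, wag)


class TestMarginalASR:
    def test_conserved_column_near_zero_branches(self, wag):
        family = fam([("a", "K"), ("b", "K"), ("c", "K")])
        tree = PhyloTree.from_newick("(a:1e-8,b:1e-8,c:1e-8);")
        post = marginal_asr(family, tree, wag)
        for label in post.node_labels:
            assert post.probabilities[label][0, AA_INDEX["K"]] > 0.999
            assert post.map_sequences[label] == "K"

    def test_three_leaf_posterior_equals_bayes_oracle(self, wag):
        family = fam([("a", "AC"), ("b", "AD"), ("c", "WC")])
        tree = PhyloTree.from_newick("(a:0.1,b:0.25,c:0.4);")
        post = marginal_asr(family, tree, wag)
        # the midpoint-rooted tree's deepest node corresponds to the star
        # center only when the root sits at the center; compare instead on
        # an explicitly rooted star (root = center, zero-length root edge).
        tree2 = PhyloTree.from_newick("(a:0.1,b:0.25,c:0.4)root;")
        post2 = marginal_asr(family, tree2, wag)
        for col in range(2):
            states = [AA_INDEX[family.row(x)[col]] for x in "abc"]
            oracle = star3_root_posterior(wag, [0.1, 0.25, 0.4], states)
            found = False
            for p in (post, post2):
                for label in p.node_labels:
                    if np.allclose(p.probabilities[label][col], oracle,
                                   atol=1e-9):
                        found = True
            assert found

    def test_posteriors_normalized_and_map_consistent(self, wag, demo_family):
        family, tree, _ = demo_family
        post = marginal_asr(family, tree, wag)
        for label in post.node_labels:
            p = post.probabilities[label]
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
            best = p.max(axis=1)
            assert np.all(best >= 1 / 20 - 1e-12)
            for col, aa in enumerate(post.map_sequences[label]):
                if aa != "-":
                    assert p[col, AA_INDEX[aa]] == pytest.approx(best[col])

    def test_recovery_at_shallow_depth(self, wag, demo_family):
        """MAP ancestral sequences recover >= 90% of true states on the
        bundled fixture (depth 0.25 <= 0.3 substitutions/site)."""
        family, tree, truth = demo_family
        post = marginal_asr(family, tree, wag)
        correct = total = 0
        for label in post.node_labels:
            t = truth[label]
            s = post.map_sequences[label]
            correct += sum(1 for a, b in zip(s, t) if a == b)
            total += len(t)
        assert correct / total >= 0.90

    def test_accuracy_monotone_in_depth(self, wag):
        accs = []
        for depth in (0.1, 0.5, 1.5):
            vals = []
            for seed in (0, 1, 2):
                family, tree, truth = simulate_family(
                    FamilySimSpec(n_taxa=10, length=80, depth=depth,
                                  seed=seed))
                post = marginal_asr(family, tree, wag)
                c = t = 0
                for label in post.node_labels:
                    c += sum(1 for a, b in zip(post.map_sequences[label],
                                               truth[label]) if a == b)
                    t += len(truth[label])
                vals.append(c / t)
            accs.append(np.mean(vals))
        assert accs[0] >= accs[1] >= accs[2]

    def test_gap_presence_by_parsimony(self, wag):
        family = fam([("a", "K-"), ("b", "K-"), ("c", "KC"), ("d", "KC")])
        tree = PhyloTree.from_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        post = marginal_asr(family, tree, wag)
        # the (a,b) ancestor lacks column 2; the (c,d) ancestor has it
        by_desc = {}
        for nd in tree.tree.preorder_node_iter():
            if not nd.is_leaf():
                leaves = frozenset(l.taxon.label for l in nd.leaf_iter())
                by_desc[leaves] = nd.label
        assert post.map_sequences[by_desc[frozenset("ab")]][1] == "-"
        assert post.map_sequences[by_desc[frozenset("cd")]][1] == "C"


class TestNodeRanking:
    def test_node_equal_to_target_scores_one(self, wag):
        family = fam([("t", "KKKK"), ("a", "KKKK"), ("b", "KKKK")], ref="t")
        tree = PhyloTree.from_newick("(t:0.01,a:0.01,b:0.01);")
        post = marginal_asr(family, tree, wag)
        ranking = rank_ancestral_nodes(post, family, "t",
                                       active_site_columns=[1, 2])
        assert (ranking["identity"] == 1.0).all()
        assert (ranking["active_site_conservation"] == 1.0).all()

    def test_constructed_half_divergent_root(self, poisson):
        """Target differs from the true root at 30 of 60 positions; with two
        near-identical witnesses of the root, root identity ~= 0.5."""
        root_seq = (AMINO_ACIDS * 3)[:60]
        shifted = "".join(AMINO_ACIDS[(AMINO_ACIDS.index(c) + 1) % 20]
                          for c in root_seq[:30])
        target = shifted + root_seq[30:]
        assert sum(a != b for a, b in zip(root_seq, target)) == 30
        family = fam([("t", target), ("a", root_seq), ("b", root_seq)],
                     ref="t")
        tree = PhyloTree.from_newick("(t:0.8,a:0.001,b:0.001);")
        post = marginal_asr(family, tree, poisson)
        ranking = rank_ancestral_nodes(post, family, "t", [1],
                                       sort_by="identity")
        assert ranking["identity"].iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_ranking_is_complete_permutation(self, wag, demo_family):
        family, tree, _ = demo_family
        post = marginal_asr(family, tree, wag)
        ranking = rank_ancestral_nodes(post, family, family.reference_id, [1])
        assert sorted(ranking["node"]) == sorted(post.node_labels)

    def test_empty_active_site_warns_conservation_one(self, wag, demo_family):
        family, tree, _ = demo_family
        post = marginal_asr(family, tree, wag)
        with pytest.warns(UserWarning, match="active-site"):
            ranking = rank_ancestral_nodes(post, family, family.reference_id,
                                           [])
        assert (ranking["active_site_conservation"] == 1.0).all()
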