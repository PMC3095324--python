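"""Tree building: NJ exactness, bootstrap supports, ML branch lengths,
Newick round-trips and clade sampling."""

import math

import dendropy
import numpy as np
import pytest

from ratecmp.alignio import CodonAlignment
from ratecmp.distances import DistanceMatrix, k2p_distance
from ratecmp.phylo import (
    bootstrap_support,
    k80_pmatrix,
    ml_branch_lengths,
    nj_tree,
    read_newick,
    sample_clades,
    tip_path_length,
    write_newick,
)

from conftest import make_aln


def additive_matrix_from_tree(tree: dendropy.Tree) -> DistanceMatrix:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ti = tree.taxon_namespace.get_taxon(labels[i])
            tj = tree.taxon_namespace.get_taxon(labels[j])
            vals[i, j] = vals[j, i] = pdm.distance(ti, tj)
    return DistanceMatrix(labels, vals, np.zeros((n, n), dtype=bool))


def random_tree(rng, n_taxa: int) -> dendropy.Tree:
    """Random topology with strictly positive branch lengths."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    newick_parts = list(taxa)
    rng.shuffle(newick_parts)
    while len(newick_parts) > 1:
        a = newick_parts.pop()
        b = newick_parts.pop()
        newick_parts.insert(0, f"({a},{b})")
    tree = read_newick(newick_parts[0] + ";")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.05, 1.0))
    return tree


class TestNJ:
    def test_four_taxon_exact_recovery(self):
        tree = read_newick("((A:1,B:2):1,(C:3,D:4));")
        dm = additive_matrix_from_tree(tree)
        nj = nj_tree(dm)
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1 :]:
                assert tip_path_length(nj, a, b) == pytest.approx(
                    dm.get(a, b), abs=1e-9
                )
        # terminal branch lengths recovered exactly
        tips = {lf.taxon.label: lf.edge.length for lf in nj.leaf_node_iter()}
        assert tips == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxon_closed_form(self):
        vals = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        dm = DistanceMatrix(["A", "B", "C"], vals, np.zeros((3, 3), bool))
        nj = nj_tree(dm)
        tips = {lf.taxon.label: lf.edge.length for lf in nj.leaf_node_iter()}
        assert tips["A"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert tips["B"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert tips["C"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_random_additive_trees_recovered(self, rng):
        """NJ is exact on additive matrices (up to 8 taxa)."""
        for n_taxa in (4, 5, 6, 7, 8):
            for _ in range(3):
                tree = random_tree(rng, n_taxa)
                dm = additive_matrix_from_tree(tree)
                nj = nj_tree(dm)
                for i, a in enumerate(dm.labels):
                    for b in dm.labels[i + 1 :]:
                        assert tip_path_length(nj, a, b) == pytest.approx(
                            dm.get(a, b), abs=1e-9
                        )

    def test_tie_breaks_to_lowest_index_pair(self):
        # fully symmetric 4-taxon matrix: every Q equal; (0,1) must join
        vals = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(["a", "b", "c", "d"], vals, np.zeros((4, 4), bool))
        nj = nj_tree(dm)
        cherries = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in nj.preorder_internal_node_iter()
            if nd is not nj.seed_node
        }
        assert frozenset({"a", "b"}) in cherries

    def test_undefined_entries_rejected(self):
        vals = np.array([[0, np.nan, 1.0], [np.nan, 0, 1.0], [1.0, 1.0, 0]])
        sat = np.zeros((3, 3), bool)
        sat[0, 1] = sat[1, 0] = True
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(["a", "b", "c"], vals, sat))

    def test_agrees_with_skbio_on_random_matrix(self, rng):
        """Independent cross-check against scikit-bio's NJ implementation."""
        skbio = pytest.importorskip("skbio")
        n = 6
        # noisy (non-additive) but tie-free matrix
        base = additive_matrix_from_tree(random_tree(rng, n))
        noise = rng.uniform(0, 0.02, size=(n, n))
        vals = base.values + noise + noise.T
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(base.labels, vals, np.zeros((n, n), bool))
        ours = nj_tree(dm)
        theirs = skbio.tree.nj(
            skbio.DistanceMatrix(vals, ids=base.labels)
        )
        ours_bips = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in ours.preorder_internal_node_iter()
        }
        theirs_bips = {
            frozenset(t.name for t in nd.tips())
            for nd in theirs.non_tips(include_self=False)
        }
        norm = lambda bips: {
            min(b, frozenset(base.labels) - b, key=lambda s: (len(s), sorted(s)))
            for b in bips
            if 1 < len(b) < n - 1
        }
        assert norm(ours_bips) == norm(theirs_bips)


class TestBootstrap:
    @pytest.fixture()
    def clustered_aln(self, rng):
        """Two clearly separated clusters of tips."""
        L = 600
        anc = rng.choice(list("ACGT"), L)

        def mutate(seq, p):
            out = seq.copy()
            mask = rng.random(L) < p
            out[mask] = rng.choice(list("ACGT"), int(mask.sum()))
            return out

        left = mutate(anc, 0.3)
        right = mutate(anc, 0.3)
        seqs = {}
        for i in range(2):
            seqs[f"L{i}"] = "".join(mutate(left, 0.02))
        for i in range(3):
            seqs[f"R{i}"] = "".join(mutate(right, 0.02))
        return make_aln(seqs)

    def test_separating_bipartition_strongly_supported(self, clustered_aln):
        tree = bootstrap_support(clustered_aln, n_reps=100, seed=4)
        supports = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter()): nd.support
            for nd in tree.preorder_internal_node_iter()
            if hasattr(nd, "support")
        }
        key = frozenset({"L0", "L1"})
        sep = [s for k, s in supports.items() if k in (key, frozenset({"R0", "R1", "R2"}))]
        assert sep and min(sep) >= 95.0

    def test_single_replicate_supports_binary(self, clustered_aln):
        tree = bootstrap_support(clustered_aln, n_reps=1, seed=9)
        for nd in tree.preorder_internal_node_iter():
            if hasattr(nd, "support"):
                assert nd.support in (0.0, 100.0)

    def test_deterministic_given_seed(self, clustered_aln):
        t1 = bootstrap_support(clustered_aln, n_reps=30, seed=42)
        t2 = bootstrap_support(clustered_aln, n_reps=30, seed=42)
        s1 = sorted(nd.support for nd in t1.preorder_internal_node_iter() if hasattr(nd, "support"))
        s2 = sorted(nd.support for nd in t2.preorder_internal_node_iter() if hasattr(nd, "support"))
        assert s1 == s2

    def test_zero_reps_rejected(self, clustered_aln):
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap_support(clustered_aln, n_reps=0, seed=1)


class TestMLBranchLengths:
    def simulate_k80(self, rng, tree, kappa, L):
        seqs = {}

        def down(node, seq):
            for ch in node.child_nodes():
                M = k80_pmatrix(ch.edge.length, kappa)
                cum = np.cumsum(M, axis=1)
                new = (rng.random(L)[:, None] > cum[seq]).sum(axis=1)
                if ch.is_leaf():
                    seqs[ch.taxon.label] = new
                else:
                    down(ch, new)

        down(tree.seed_node, rng.integers(0, 4, L))
        return make_aln(
            {k: "".join("ACGT"[i] for i in v) for k, v in seqs.items()}
        )

    def test_two_taxon_equals_k2p_closed_form(self, rng):
        tree = read_newick("(A:0.1,B:0.1);")
        aln = self.simulate_k80(rng, tree, 2.0, 6000)
        fit = ml_branch_lengths(aln, tree, kappa="estimate")
        total = sum(lf.edge.length for lf in fit.leaf_node_iter())
        seqs = {rid: s for rid, _, s in aln.records}
        expected = k2p_distance(seqs["A"], seqs["B"]).d
        assert total == pytest.approx(expected, abs=1e-6)

    def test_identical_sequences_zero_lengths(self):
        aln = make_aln({"A": "ACGT" * 30, "B": "ACGT" * 30, "C": "ACGT" * 30})
        tree = read_newick("(A:0.1,(B:0.1,C:0.1):0.1);")
        fit = ml_branch_lengths(aln, tree, kappa=2.0)
        for edge in fit.preorder_edge_iter():
            if edge.head_node is not fit.seed_node:
                assert edge.length == pytest.approx(0.0, abs=1e-6)

    def test_five_taxon_recovery_within_5pct(self, rng):
        newick = "(Os:0.25,(At:0.22,(Mt:0.16,(Vv:0.07,Pt:0.07):0.04):0.04):0.10);"
        tree = read_newick(newick)
        aln = self.simulate_k80(rng, tree, 2.0, 30000)
        fit = ml_branch_lengths(aln, tree, kappa=2.0)
        assert fit.converged
        # after collapsing the basal bifurcation the outgroup edge absorbs
        # the stem: Os = 0.25 + 0.10
        truth = {"Os": 0.35, "At": 0.22, "Mt": 0.16, "Vv": 0.07, "Pt": 0.07}
        for lf in fit.leaf_node_iter():
            assert lf.edge.length == pytest.approx(
                truth[lf.taxon.label], rel=0.05, abs=0.005
            )

    def test_loglik_improves_over_start(self, rng):
        tree = read_newick("((A:0.3,B:0.3):0.1,(C:0.3,D:0.3):0.1);")
        aln = self.simulate_k80(rng, tree, 3.0, 2000)
        # start from deliberately wrong lengths
        start = read_newick("((A:1.5,B:0.001):1.0,(C:0.9,D:0.0001));")
        fit = ml_branch_lengths(aln, start, kappa=3.0)
        assert fit.converged
        ref = ml_branch_lengths(aln, tree, kappa=3.0)
        assert fit.log_likelihood == pytest.approx(ref.log_likelihood, abs=1e-3)


class TestNewickIO:
    def test_roundtrip_preserves_everything(self, tmp_path):
        s = "((A:0.1,B:0.2)95:0.05,(C:0.3,D:0.4)87:0.06,E:0.5);"
        tree = read_newick(s)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert {lf.taxon.label for lf in back.leaf_node_iter()} == set("ABCDE")
        labels = sorted(
            nd.label for nd in back.preorder_internal_node_iter() if nd.label
        )
        assert labels == ["87", "95"]
        assert tip_path_length(back, "A", "B") == pytest.approx(0.3)


class TestCladeSampling:
    REQUIRED = {"At", "Mt", "Vv", "Pt"}

    def test_qualifying_clade_with_sister_outgroup(self):
        s = "((g1|At:1,(g2|Mt:1,(g3|Vv:1,g4|Pt:1)99:1)90:1)87:1,(g5|Os:1,g6|Os:1):1);"
        tree = read_newick(s)
        clades = sample_clades(tree, self.REQUIRED, support_min=50)
        assert len(clades) == 1
        c = clades[0]
        assert c.species_coverage >= self.REQUIRED
        assert c.support == 87.0
        assert set(c.outgroup_tips) == {"g5|Os", "g6|Os"}

    def test_boundary_support_is_strict(self):
        s = "((g1|At:1,(g2|Mt:1,(g3|Vv:1,g4|Pt:1)99:1)90:1)50:1,g5|Os:1);"
        tree = read_newick(s)
        assert sample_clades(tree, self.REQUIRED, support_min=50) == []

    def test_nested_qualifying_clades_yield_maximal_only(self):
        # 12 tips; an inner 4-dicot clade (support 80) nested in an outer
        # qualifying clade (support 91): only the outer one is returned
        inner = "(a1|At:1,(m1|Mt:1,(v1|Vv:1,p1|Pt:1)88:1)85:1)80:1"
        outer = f"({inner},(a2|At:1,(m2|Mt:1,(v2|Vv:1,p2|Pt:1)70:1)65:1)60:1)91:1"
        s = f"(({outer},(o1|Os:1,o2|Os:1)44:1)30:1,(o3|Os:1,o4|Os:1):1);"
        tree = read_newick(s)
        clades = sample_clades(tree, self.REQUIRED, support_min=50)
        supports = sorted(c.support for c in clades)
        assert supports == [91.0]
        assert len(clades[0].member_tips) == 8

    def test_unlabeled_tips_rejected(self):
        tree = dendropy.Tree()
        a = dendropy.Node()
        tree.seed_node.add_child(a)
        with pytest.raises(ValueError, match="unlabeled"):
            sample_clades(tree, {"At"})
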