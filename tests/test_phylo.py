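"""F84 distances, neighbor joining, bootstrap supports, and ortholog selection."""

import math

import dendropy
import numpy as np
import pytest

from sinopan.cluster import ClusterTable
from sinopan.io import SequenceRecord
from sinopan.phylo import (
    Alignment,
    DistanceMatrix,
    SaturationError,
    annotate_supports,
    bidirectional_best_hits,
    bootstrap_supports,
    build_tree,
    collapse_low_support,
    distance_matrix,
    f84_distance,
    neighbor_joining,
    path_length_matrix,
    select_single_copy_families,
    tree_splits,
)
from sinopan.simulate import F84Params, random_binary_tree, simulate_f84_alignment

from conftest import make_protein, mutate_protein, record


class TestF84Distance:
    def test_identical_sequences(self):
        assert f84_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_equal_frequency_reduction_to_k2p(self):
        # P=0.1, Q=0.05 at equal frequencies: the F84 formula collapses to
        # the Kimura two-parameter closed form.
        L = 200
        a = ("ACGT" * (L // 4))
        b = list(a)
        # 20 transitions (A<->G at A positions), 10 transversions (C->A)
        for i in range(20):
            b[4 * i] = "G"
        for i in range(10):
            b[4 * i + 1] = "A"
        d = f84_distance("".join(a), "".join(b), frequencies=(0.25,) * 4)
        expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert d == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1701811651, abs=1e-9)

    def test_symmetry(self):
        a, b = "ACGTTGCAACGT", "ACGTTGCATCGA"
        assert f84_distance(a, b) == f84_distance(b, a)

    def test_monotone_in_transitions(self):
        freqs = (0.25,) * 4
        base = "ACGT" * 100

        def with_changes(ts):
            b = list(base)
            for i in range(ts):
                b[4 * i] = "G"
            return "".join(b)

        dists = [
            f84_distance(base, with_changes(ts), frequencies=freqs)
            for ts in (5, 10, 20, 40)
        ]
        assert all(x < y for x, y in zip(dists, dists[1:]))

    def test_ambiguous_sites_skipped(self):
        # N-columns are invisible: same P, Q over fewer sites
        assert f84_distance("ACGTN", "ACGTA") == 0.0
        with pytest.raises(ValueError, match="comparable"):
            f84_distance("NNN", "ACG")

    def test_saturation_raises_with_pair_names(self):
        with pytest.raises(SaturationError, match="x.*y"):
            f84_distance("A" * 50, "G" * 50, frequencies=(0.25,) * 4, names=("x", "y"))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            f84_distance("ACGT", "ACG")


class TestDistanceMatrix:
    def test_identity_alignment_gives_zero_matrix(self):
        aln = Alignment.from_sequences({"a": "ACGTACGT", "b": "ACGTACGT"})
        dm = distance_matrix(aln)
        assert np.allclose(dm.d, 0.0)

    def test_symmetry_and_pairwise_oracle(self):
        rng = np.random.default_rng(30)
        tree = random_binary_tree(["a", "b", "c", "d"], seed=31)
        aln = simulate_f84_alignment(tree, F84Params(), 2000, seed=32)
        dm = distance_matrix(aln)
        assert np.allclose(dm.d, dm.d.T)
        # brute-force per-pair recomputation with the pooled frequencies
        mat = aln.matrix
        counts = np.array([(mat == b).sum() for b in range(4)], dtype=float)
        freqs = tuple(counts / counts.sum())
        for i in range(aln.n_taxa):
            for j in range(i + 1, aln.n_taxa):
                d = f84_distance(
                    aln.sequence(aln.taxa[i]), aln.sequence(aln.taxa[j]), frequencies=freqs
                )
                assert dm.d[i, j] == pytest.approx(d, abs=1e-12)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]])))
        plm = path_length_matrix(tree)
        assert plm.value("A", "B") == pytest.approx(0.4)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        taxa = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(taxa, D))
        assert np.abs(path_length_matrix(tree).d - D).max() < 1e-12
        assert set(tree_splits(tree)) == {frozenset({"C", "D"})}

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_inverts_random_additive_matrices(self, n_taxa):
        for seed in range(3):
            true = random_binary_tree(
                [f"t{i}" for i in range(n_taxa)], seed=100 * n_taxa + seed
            )
            dm = path_length_matrix(true)
            tree = neighbor_joining(DistanceMatrix(dm.taxa, dm.d))
            back = path_length_matrix(tree)
            assert back.taxa == dm.taxa
            assert np.abs(back.d - dm.d).max() < 1e-9
            assert set(tree_splits(tree)) == set(tree_splits(true))

    def test_agrees_with_skbio_topology(self):
        """Independent implementation cross-check on an additive matrix."""
        skbio = pytest.importorskip("skbio")
        true = random_binary_tree([f"t{i}" for i in range(7)], seed=77)
        dm = path_length_matrix(true)
        ours = neighbor_joining(DistanceMatrix(dm.taxa, dm.d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.taxa))
        import io as _io

        buf = _io.StringIO()
        theirs.write(buf, format="newick")
        ns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=buf.getvalue(), schema="newick", taxon_namespace=ns)
        t1_splits = {
            frozenset(
                lf.taxon.label for lf in nd.leaf_iter()
            )
            for nd in t1.preorder_node_iter()
            if not nd.is_leaf() and nd is not t1.seed_node
        }
        ref = min(dm.taxa)
        all_leaves = set(dm.taxa)
        canon = {
            frozenset(all_leaves - s) if ref in s else s
            for s in t1_splits
        }
        canon = {s for s in canon if 2 <= len(s) <= len(all_leaves) - 2}
        assert canon == set(tree_splits(ours))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]])))
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]])))

    def test_negative_branch_estimates_clamped(self):
        # a non-additive matrix known to produce a negative NJ estimate
        D = np.array(
            [
                [0.0, 0.1, 0.4, 0.41],
                [0.1, 0.0, 0.4, 0.41],
                [0.4, 0.4, 0.0, 0.01],
                [0.41, 0.41, 0.01, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c", "d"], D))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0


class TestBootstrapAndCollapse:
    def _alignment(self, seed=40, n_sites=3000):
        tree = random_binary_tree([f"t{i}" for i in range(6)], seed=seed)
        return tree, simulate_f84_alignment(tree, F84Params(), n_sites, seed=seed + 1)

    def test_same_seed_same_supports(self):
        _, aln = self._alignment()
        s1, k1 = bootstrap_supports(aln, n_reps=50, seed=5)
        s2, k2 = bootstrap_supports(aln, n_reps=50, seed=5)
        assert s1 == s2 and k1 == k2

    def test_congruent_divergent_signal_all_supports_high(self):
        true, aln = self._alignment(seed=41, n_sites=5000)
        supports, skipped = bootstrap_supports(aln, n_reps=100, seed=6)
        assert skipped == 0
        for split in tree_splits(true):
            assert supports[split] == pytest.approx(100.0)

    def test_support_reproducibility_across_seeds(self):
        _, aln = self._alignment(seed=42, n_sites=1500)
        s1, _ = bootstrap_supports(aln, n_reps=1000, seed=7)
        s2, _ = bootstrap_supports(aln, n_reps=1000, seed=8)
        common = set(s1) & set(s2)
        assert common
        for split in common:
            if max(s1[split], s2[split]) > 20:  # ignore rare noise splits
                assert abs(s1[split] - s2[split]) <= 4.0

    def _tree_with_support(self, support):
        ns = dendropy.TaxonNamespace(["A", "B", "C", "D"])
        tree = dendropy.Tree(taxon_namespace=ns)

        def leaf(lab):
            n = dendropy.Node(taxon=ns.get_taxon(lab))
            n.edge.length = 1.0
            return n

        inner = dendropy.Node()
        inner.add_child(leaf("A"))
        inner.add_child(leaf("B"))
        inner.edge.length = 1.0
        tree.seed_node.add_child(inner)
        tree.seed_node.add_child(leaf("C"))
        tree.seed_node.add_child(leaf("D"))
        annotate_supports(tree, {frozenset({"C", "D"}): support})
        # the A,B-side split is canonically keyed by the C,D side (ref taxon A)
        return tree

    def test_collapse_is_strictly_below_threshold(self):
        kept = self._tree_with_support(60.0)
        collapse_low_support(kept, 60)
        assert len(tree_splits(kept)) == 1

        gone = self._tree_with_support(59.0)
        collapse_low_support(gone, 60)
        assert len(tree_splits(gone)) == 0
        assert sum(1 for _ in gone.leaf_node_iter()) == 4

    def test_build_tree_roots_at_outgroup(self):
        _, aln = self._alignment(seed=43, n_sites=2000)
        tree, supports, skipped = build_tree(aln, outgroup="t0", n_reps=50, seed=9)
        children = tree.seed_node.child_nodes()
        assert any(
            c.is_leaf() and c.taxon.label == "t0" for c in children
        )


class TestSingleCopySelection:
    def _table(self, membership):
        table = ClusterTable()
        for fam, members in enumerate(membership):
            ids = [f"{s}|g{fam}_{i}" for i, s in enumerate(members)]
            table.clusters.append((fam, ids[0], ids))
            for gid, s in zip(ids, members):
                table.family_of[gid] = fam
                table.strain_of[gid] = s
        return table

    def test_exactly_one_copy_everywhere(self):
        table = self._table([["s0", "s1"], ["s0", "s0", "s1"], ["s0"]])
        assert select_single_copy_families(table, ["s0", "s1"]) == {0}

    def test_duplicated_copy_excluded(self):
        table = self._table([["s0", "s0", "s1"]])
        assert select_single_copy_families(table, ["s0", "s1"]) == set()

    def test_missing_strain_gives_empty_result(self):
        table = self._table([["s0"], ["s0"]])
        assert select_single_copy_families(table, ["s0", "s1"]) == set()


class TestBidirectionalBestHits:
    def test_identical_proteomes_pair_everything(self):
        rng = np.random.default_rng(50)
        prots = [record(f"a|p{i}", make_protein(rng, 80)) for i in range(5)]
        other = [record(f"b|p{i}", p.residues) for i, p in enumerate(prots)]
        pairs = bidirectional_best_hits(prots, other)
        assert pairs == [(f"a|p{i}", f"b|p{i}") for i in range(5)]

    def test_identity_below_threshold_rejected(self):
        rng = np.random.default_rng(51)
        a = make_protein(rng, 100)
        at_69 = mutate_protein(rng, a, 31)  # identity 0.69 < 0.70
        at_71 = mutate_protein(rng, a, 29)  # identity 0.71 >= 0.70
        assert bidirectional_best_hits([record("x|p", a)], [record("y|p", at_69)]) == []
        assert bidirectional_best_hits([record("x|p", a)], [record("y|p", at_71)]) == [
            ("x|p", "y|p")
        ]

    def test_low_coverage_rejected(self):
        rng = np.random.default_rng(52)
        core = make_protein(rng, 100)
        long = core + make_protein(rng, 40)  # span 100/140 = 0.71 < 0.80
        assert bidirectional_best_hits([record("x|p", core)], [record("y|p", long)]) == []

    def test_asymmetric_best_hits_excluded(self):
        rng = np.random.default_rng(53)
        a = make_protein(rng, 120)
        b = mutate_protein(rng, a, 12)  # 0.90 to a
        c = mutate_protein(rng, b, 6)  # 0.95 to b, ~0.85-0.90 to a
        # a's best is b; b's best is c: no reciprocal pair for (a, b)
        pairs = bidirectional_best_hits(
            [record("x|a", a)], [record("y|b", b), record("y|c", c)]
        )
        rev = bidirectional_best_hits(
            [record("y|b", b), record("y|c", c)], [record("x|a", a)]
        )
        assert [p for p in pairs if p[1] == "y|b"] == pairs  # a pairs with b
        # build the true 3-way scenario: src = {b}, dst = {a, c}
        pairs2 = bidirectional_best_hits(
            [record("x|a", a), record("x|c2", c)], [record("y|b", b)]
        )
        # y|b's unique best among {a, c2} is c2 (0.95 > 0.90), so (x|a, y|b)
        # must NOT be reported even though y|b is x|a's best hit.
        assert ("x|a", "y|b") not in pairs2

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            bidirectional_best_hits([], [record("y|p", "MKVWY")])
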