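"""p-distance, neighbor joining and Newick serialisation."""

import io
import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from rhizoquant.phylo import (
    DistanceMatrix,
    neighbor_joining,
    p_distance,
    tree_path_distances,
    write_newick,
)


def aln(pairs):
    return list(pairs.items())


class TestPDistance:
    def test_identical_sequences_zero(self):
        dm = p_distance(aln({"a": "ACDE", "b": "ACDE"}))
        assert dm.d[0, 1] == 0.0

    def test_single_mismatch_fraction(self):
        dm = p_distance(aln({"a": "ACDE", "b": "ACDF"}))
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gapped_columns_excluded_pairwise(self):
        dm = p_distance(aln({"a": "A-CD", "b": "AXCD"}))
        assert dm.d[0, 1] == 0.0  # 3 compared columns, all equal

    def test_zero_overlap_pair_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance(aln({"a": "A--", "b": "--A"}))

    def test_ragged_alignment_is_error(self):
        with pytest.raises(ValueError, match="ragged"):
            p_distance(aln({"a": "ACDE", "b": "ACD"}))


def star3(d12, d13, d23):
    d = np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0]], float)
    return DistanceMatrix(("A", "B", "C"), d)


def additive4(labels=("A", "B", "C", "D"), limbs=(1.0, 2.0, 3.0, 4.0), internal=5.0):
    """Distance matrix of the tree (A,B)--internal--(C,D) by path sums."""
    a, b, c, d = limbs
    m = np.array(
        [
            [0, a + b, a + internal + c, a + internal + d],
            [a + b, 0, b + internal + c, b + internal + d],
            [a + internal + c, b + internal + c, 0, c + d],
            [a + internal + d, b + internal + d, c + d, 0],
        ],
        float,
    )
    return DistanceMatrix(tuple(labels), m)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        tree = neighbor_joining(star3(3, 4, 5))
        assert write_newick(tree) == "(A:1,B:2,C:3);"

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0.0]])))

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B", "C"), m)

    @pytest.mark.parametrize("perm", list(itertools.permutations(range(4))))
    def test_additive_four_taxon_recovered_under_all_label_orders(self, perm):
        base = additive4()
        labels = tuple(base.labels[i] for i in perm)
        d = base.d[np.ix_(perm, perm)]
        tree = neighbor_joining(DistanceMatrix(labels, d))
        paths = tree_path_distances(tree)
        for i, j in itertools.combinations(range(4), 2):
            key = tuple(sorted((labels[i], labels[j])))
            assert paths[key] == pytest.approx(d[i, j], abs=1e-9)
        # topology: A,B on one side of the internal edge
        nwk = write_newick(tree)
        assert "(A:1,B:2)" in nwk

    def test_negative_limbs_clamped_to_zero(self):
        tree = neighbor_joining(star3(1, 1, 3))  # violates triangle inequality
        lengths = sorted(round(c.branch_length, 9) for c in tree.children)
        assert lengths[0] == 0.0 and all(l >= 0 for l in lengths)

    def test_ultrametric_six_taxon_topology_recovered(self):
        # balanced ultrametric tree: ((a,b),(c,d)),(e,f) with heights 1,2,3
        labels = ("a", "b", "c", "d", "e", "f")
        groups = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 2, "f": 2}
        m = np.zeros((6, 6))
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i == j:
                    continue
                if groups[li] == groups[lj]:
                    m[i, j] = 2.0
                elif {groups[li], groups[lj]} == {0, 1}:
                    m[i, j] = 4.0
                else:
                    m[i, j] = 6.0
        tree = neighbor_joining(DistanceMatrix(labels, m))
        nwk = write_newick(tree)
        truth = "((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);"
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(
            data=nwk, schema="newick", taxon_namespace=tns, rooting="force-unrooted"
        )
        t2 = dendropy.Tree.get(
            data=truth, schema="newick", taxon_namespace=tns, rooting="force-unrooted"
        )
        assert treecompare.symmetric_difference(t1, t2) == 0
        # cherry limb lengths of the generating ultrametric tree
        assert "(a:1,b:1)" in nwk and "(e:1,f:1)" in nwk

    def test_matches_skbio_topology_on_random_matrices(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            m = rng.uniform(0.1, 1.0, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = tuple(f"t{i}" for i in range(n))
            mine = write_newick(neighbor_joining(DistanceMatrix(labels, m)))
            buf = io.StringIO()
            nj(SkDM(m, labels)).write(buf)
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(
                data=mine, schema="newick", taxon_namespace=tns, rooting="force-unrooted"
            )
            t2 = dendropy.Tree.get(
                data=buf.getvalue(), schema="newick", taxon_namespace=tns,
                rooting="force-unrooted",
            )
            assert treecompare.symmetric_difference(t1, t2) == 0

    def test_output_invariant_to_label_permutation(self):
        base = additive4()
        nwk_base = write_newick(neighbor_joining(base))
        perm = (2, 0, 3, 1)
        labels = tuple(base.labels[i] for i in perm)
        d = base.d[np.ix_(perm, perm)]
        assert write_newick(neighbor_joining(DistanceMatrix(labels, d))) == nwk_base


class TestWriteNewick:
    def test_three_leaf_star(self):
        assert write_newick(neighbor_joining(star3(3, 4, 5))) == "(A:1,B:2,C:3);"

    def test_reparse_reproduces_path_distances(self):
        tree = neighbor_joining(additive4())
        nwk = write_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        expected = tree_path_distances(tree)
        for (a, b), dist in expected.items():
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                dist, abs=1e-6
            )

    def test_label_requiring_quotes_is_quoted(self):
        dm = DistanceMatrix(
            ("NCR 1", "B", "C"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        )
        nwk = write_newick(neighbor_joining(dm))
        assert "'NCR 1'" in nwk

    def test_deterministic_and_terminated(self):
        nwk1 = write_newick(neighbor_joining(additive4()))
        nwk2 = write_newick(neighbor_joining(additive4()))
        assert nwk1 == nwk2 and nwk1.endswith(";")
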