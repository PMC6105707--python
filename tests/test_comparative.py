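"""k-mer distances, neighbour joining and dot-plot segment extraction."""

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagechar._dna import random_dna, revcomp
from phagechar.comparative import (
    DistanceMatrix,
    canonical_kmers,
    distance_matrix,
    dotplot_segments,
    kmer_distance,
    nj_tree,
)


def _rand(seed, n=500):
    return random_dna(np.random.default_rng(seed), n, 0.4)


class TestKmerDistance:
    def test_identical_zero(self):
        s = _rand(1)
        assert kmer_distance(s, s) == 0.0

    def test_disjoint_capped_at_one(self):
        assert kmer_distance("A" * 60, "C" * 60, k=15) == 1.0

    def test_formula_matches_set_enumeration_oracle(self):
        a, b = _rand(2, 60), _rand(3, 60)
        k = 7
        sa = {min(a[i:i + k], revcomp(a[i:i + k])) for i in range(len(a) - k + 1)}
        sb = {min(b[i:i + k], revcomp(b[i:i + k])) for i in range(len(b) - k + 1)}
        j = len(sa & sb) / len(sa | sb)
        expected = 1.0 if j == 0 else min(1.0, -math.log(2 * j / (1 + j)) / k)
        assert kmer_distance(a, b, k=k) == pytest.approx(expected)

    def test_strand_neutrality(self):
        a, b = _rand(4), _rand(5)
        assert kmer_distance(a, b) == pytest.approx(kmer_distance(a, revcomp(b)))

    def test_zero_iff_equal_kmer_sets(self):
        a = _rand(6)
        rotated = a[100:] + a[:100]  # near-equal sets but not identical
        d = kmer_distance(a, rotated, k=15)
        same = canonical_kmers(a, 15) == canonical_kmers(rotated, 15)
        assert (d == 0.0) == same

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            kmer_distance("ACGT", "ACGTACGT", k=15)


def _parse_newick_leaf_sets(newick):
    """Bipartitions induced by internal edges, via dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    out = []
    for b in tree.bipartition_encoding:
        out.append(frozenset(t.label for t in tree.taxon_namespace
                             if b.leafset_bitmask & tree.taxon_namespace.taxon_bitmask(t)))
    return out


def _tree_path_lengths(newick):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    return {(a.label, b.label): pdm.distance(a, b) for a in taxa for b in taxa if a != b}


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        newick = nj_tree(DistanceMatrix(ids, d))
        paths = _tree_path_lengths(newick)
        # closed form: v_a = (d_ab + d_ac - d_bc)/2 etc.; path lengths are exact
        assert paths[("a", "b")] == pytest.approx(5)
        assert paths[("a", "c")] == pytest.approx(9)
        assert paths[("b", "c")] == pytest.approx(10)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((a:2,b:3):1,(c:4,d:5)); additive distances
        ids = ["a", "b", "c", "d"]
        d = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 0, 0],
        ], dtype=float)
        d[2, 3] = d[3, 2] = 9
        newick = nj_tree(DistanceMatrix(ids, d))
        paths = _tree_path_lengths(newick)
        for (x, y), v in {("a", "b"): 5, ("a", "c"): 7, ("a", "d"): 8,
                          ("b", "c"): 8, ("b", "d"): 9, ("c", "d"): 9}.items():
            assert paths[(x, y)] == pytest.approx(v)
        splits = _parse_newick_leaf_sets(newick)
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6), st.integers(5, 7))
    def test_additive_matrices_inverted_exactly(self, seed, n_taxa):
        """NJ on distances from a random tree reproduces its path lengths."""
        rng = np.random.default_rng(seed)
        # build a random binary tree by sequential joining; store path lengths
        ids = [f"t{i}" for i in range(n_taxa)]
        import dendropy

        taxa = dendropy.TaxonNamespace(ids)
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
            taxon_namespace=taxa, rng=__import__("random").Random(seed))
        for e in tree.edges():
            e.length = float(rng.uniform(0.5, 3.0))
        pdm = tree.phylogenetic_distance_matrix()
        taxa_sorted = sorted(tree.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa_sorted]
        d = np.array([[0.0 if a is b else pdm.distance(a, b) for b in taxa_sorted]
                      for a in taxa_sorted])
        newick = nj_tree(DistanceMatrix(labels, d))
        paths = _tree_path_lengths(newick)
        for i, x in enumerate(labels):
            for y in labels[i + 1:]:
                assert paths[(x, y)] == pytest.approx(d[labels.index(x), labels.index(y)],
                                                      rel=1e-6)

    def test_matches_skbio_topology(self):
        """Independent oracle: scikit-bio's NJ on the same matrix yields the
        same set of bipartitions."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(12)
        n = 6
        coords = rng.uniform(0, 10, size=(n, 3))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        ids = [f"g{i}" for i in range(n)]
        ours = set(map(frozenset, (
            s for s in _parse_newick_leaf_sets(nj_tree(DistanceMatrix(ids, d)))
            if 1 < len(s) < n - 1)))
        theirs_tree = skbio_nj(SkbioDM(d, ids))
        theirs = set()
        for node in theirs_tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < n - 1:
                theirs.add(tips)
        norm = lambda splits: {min(s, frozenset(ids) - s, key=sorted) for s in splits}
        assert norm(ours) == norm(theirs)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], d)


class TestDotPlots:
    def test_self_match_full_diagonal(self):
        s = _rand(31, 800)
        segs = dotplot_segments(s, s, w=20)
        assert any(g.x_start == 0 and g.y_start == 0 and g.length == 800
                   and g.orientation == "forward" for g in segs)

    def test_reverse_complement_full_reverse_segment(self):
        s = _rand(32, 600)
        segs = dotplot_segments(s, revcomp(s), w=20)
        assert any(g.length == 600 and g.orientation == "reverse" for g in segs)

    def test_single_snv_splits_diagonal(self):
        s = _rand(33, 1000)
        p = 473
        other = s[:p] + ("A" if s[p] != "A" else "C") + s[p + 1:]
        segs = [g for g in dotplot_segments(s, other, w=20)
                if g.orientation == "forward" and g.x_start == g.y_start]
        main = sorted((g for g in segs if g.length > 100), key=lambda g: g.x_start)
        assert [(g.x_start, g.length) for g in main] == [(0, p), (p + 1, 1000 - p - 1)]

    def test_segments_re_extract_identically(self):
        a, b = _rand(34, 700), _rand(34, 700)[:650] + _rand(35, 50)
        for g in dotplot_segments(a, b, w=15):
            x = a[g.x_start:g.x_start + g.length]
            y = b[g.y_start:g.y_start + g.length]
            assert x == (y if g.orientation == "forward" else revcomp(y))

    def test_coverage_of_identical_genomes_complete(self):
        s = _rand(36, 400)
        segs = dotplot_segments(s, s, w=20)
        covered = np.zeros(400, dtype=bool)
        for g in segs:
            if g.orientation == "forward":
                covered[g.x_start:g.x_start + g.length] = True
        assert covered.all()


class TestDistanceMatrixHelper:
    def test_matrix_symmetric_zero_diagonal(self, default_genome):
        from phagechar.seq_io import PhageGenome
        a = default_genome
        b = PhageGenome("rot", a.seq[3000:] + a.seq[:3000])
        c = PhageGenome("rand", _rand(40, len(a)))
        dm = distance_matrix([a, b, c])
        assert dm.d[0, 1] == dm.d[1, 0]
        assert dm.d[0, 1] < 0.01 < dm.d[0, 2]
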