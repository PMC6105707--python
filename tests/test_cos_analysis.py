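"""cos site detection and mapping of its flanking packaging-signal elements."""

import re

import numpy as np
import pytest

from phagechar._dna import hamming, random_dna, revcomp
from phagechar.cos_analysis import (
    DEFAULT_COS_MOTIF,
    CosRegion,
    find_cos_site,
    find_direct_repeats,
    find_inverted_repeats,
    map_terminase_sites,
)
from phagechar.errors import ConfigError
from phagechar.seq_io import PhageGenome
from phagechar.synthetic_data import SYNTH_TERMINASE_MOTIFS


def _random_genome(seed, n=2000, scrub=None):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, n, 0.35)
    while scrub and scrub in seq:
        i = seq.find(scrub)
        repl = "G" if seq[i] != "G" else "T"
        seq = seq[:i] + repl + seq[i + 1:]
    return seq


class TestFindCos:
    def test_default_genome_single_11nt_hit(self, default_genome, default_truth):
        hits = find_cos_site(default_genome)
        assert len(hits) == 1
        assert hits[0].cos_end - hits[0].cos_start == 11
        assert hits[0].cos_start == default_truth["cos_start"]
        assert hits[0].cos_seq == DEFAULT_COS_MOTIF

    def test_absent_motif_gives_empty(self):
        seq = _random_genome(3, scrub=DEFAULT_COS_MOTIF)
        assert find_cos_site(PhageGenome("r", seq)) == []

    def test_motif_spanning_linear_ends_found_in_circular_view(self):
        motif = DEFAULT_COS_MOTIF
        core = _random_genome(5, n=1000, scrub=motif)
        seq = motif[6:] + core + motif[:6]   # 5 nt at start, 6 nt at end
        g = PhageGenome("wrap", seq)
        hits = find_cos_site(g)
        # oracle: scan of seq+seq concatenation
        doubled = [m.start() for m in re.finditer(f"(?={motif})", seq + seq)]
        expected = sorted({p for p in doubled if p < len(seq)})
        assert [h.cos_start for h in hits] == expected
        assert any(h.cos_start == len(seq) - 6 for h in hits)

    def test_strand_consistency(self, default_genome, default_truth):
        """Scanning the reverse complement finds the rc motif at mirrored coordinates."""
        rc = PhageGenome("rc", revcomp(default_genome.seq))
        hits = find_cos_site(rc, motif=revcomp(DEFAULT_COS_MOTIF))
        starts = [len(default_genome) - h.cos_end for h in hits]
        assert default_truth["cos_start"] in starts


class TestInvertedRepeats:
    def _toy(self, seed=11):
        rng = np.random.default_rng(seed)
        arm = "ACGTTGCAAC"
        left = random_dna(rng, 40, 0.35)
        right = random_dna(rng, 40, 0.35)
        motif = DEFAULT_COS_MOTIF
        seq = left + arm + "GGT" + motif + "TTG" + revcomp(arm) + right
        cos_start = len(left) + 13
        g = PhageGenome("toy", seq)
        cos = CosRegion(cos_start, cos_start + 11, motif)
        return g, cos, len(left), len(left) + 13 + 11 + 3

    def test_planted_pair_found_exactly(self):
        g, cos, larm, rarm = self._toy()
        pairs = find_inverted_repeats(g, cos, window=60)
        match = [p for p in pairs if p.left_start == larm and p.right_start == rarm]
        assert match and match[0].mismatches == 0 and match[0].arm_len == 10

    def test_no_complementary_arms_empty(self):
        seq = "A" * 50 + DEFAULT_COS_MOTIF + "C" * 50
        g = PhageGenome("flat", seq)
        cos = CosRegion(50, 61, DEFAULT_COS_MOTIF)
        # poly-A left arms revcomp to poly-T, right window is poly-C
        assert find_inverted_repeats(g, cos, window=40, max_mismatch=0) == []

    def test_against_exhaustive_oracle(self):
        g, cos, _, _ = self._toy(seed=23)
        got = find_inverted_repeats(g, cos, window=50, max_mismatch=1)
        # brute-force all arm pairs, then check every reported pair is valid
        # and that the best planted-quality pair survives pruning
        all_pairs = []
        for ls in range(max(0, cos.cos_start - 50), cos.cos_start - 10 + 1):
            for rs in range(cos.cos_end, min(len(g), cos.cos_end + 50) - 10 + 1):
                mm = hamming(revcomp(g.seq[ls:ls + 10]), g.seq[rs:rs + 10])
                if mm <= 1:
                    all_pairs.append((ls, rs, mm))
        assert {(p.left_start, p.right_start, p.mismatches) for p in got} <= set(all_pairs)
        best_mm = min(mm for *_, mm in all_pairs)
        assert any(p.mismatches == best_mm for p in got)

    def test_reported_pairs_self_consistent(self, default_genome):
        cos = find_cos_site(default_genome)[0]
        for p in find_inverted_repeats(default_genome, cos):
            left = default_genome.seq[p.left_start:p.left_end]
            right = default_genome.seq[p.right_start:p.right_end]
            assert hamming(revcomp(left), right) == p.mismatches

    def test_symmetry_under_reverse_complement(self):
        g, cos, larm, rarm = self._toy(seed=31)
        n = len(g)
        rc = PhageGenome("rc", revcomp(g.seq))
        cos_rc = CosRegion(n - cos.cos_end, n - cos.cos_start, revcomp(cos.cos_seq))
        mirrored = find_inverted_repeats(rc, cos_rc, window=60)
        assert any(p.left_start == n - (rarm + 10) and p.right_start == n - (larm + 10)
                   for p in mirrored)


class TestDirectRepeats:
    def test_generator_default_six_labelled(self, default_genome):
        cos = find_cos_site(default_genome)[0]
        drs = find_direct_repeats(default_genome, cos)
        assert [d.label for d in drs] == [f"D{i}" for i in range(1, 7)]
        for d in drs:
            assert default_genome.seq[d.start:d.end] == "AATCT"

    def test_no_occurrence_empty(self):
        seq = "G" * 100 + DEFAULT_COS_MOTIF + "G" * 100
        g = PhageGenome("g", seq)
        assert find_direct_repeats(g, CosRegion(100, 111, DEFAULT_COS_MOTIF)) == []

    def test_counts_match_regex_oracle(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            seq = random_dna(rng, 500, 0.35)
            g = PhageGenome("r", seq)
            cos = CosRegion(250, 261, seq[250:261])
            got = find_direct_repeats(g, cos, window=100)
            lo, hi = 150, 361
            expected = len(re.findall("(?=AATCT)", seq[lo:hi]))
            assert len(got) == expected


class TestTerminaseSites:
    def test_planted_sites_mapped(self, default_genome):
        cos = find_cos_site(default_genome)[0]
        sites = {t.label: t for t in
                 map_terminase_sites(default_genome, cos, SYNTH_TERMINASE_MOTIFS)}
        assert sites["R1"].complete and sites["R3"].complete
        assert not sites["R2"].complete
        assert "D6" in sites["R2"].overlapping_drs

    def test_absent_motifs_incomplete(self):
        seq = "G" * 100 + DEFAULT_COS_MOTIF + "G" * 100
        g = PhageGenome("g", seq)
        cos = CosRegion(100, 111, DEFAULT_COS_MOTIF)
        sites = map_terminase_sites(g, cos, {"R1": "AATTCCAATTCC"})
        assert not sites[0].complete
        assert sites[0].matched_fraction < 1.0

    def test_best_match_equals_hamming_scan_oracle(self):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 400, 0.35)
        g = PhageGenome("r", seq)
        cos = CosRegion(200, 211, seq[200:211])
        motif = "GGTTCACGTAAGGTAC"
        site = map_terminase_sites(g, cos, {"X": motif}, window=150)[0]
        lo, hi = 50, 361
        dists = [(hamming(seq[p:p + len(motif)], motif), p)
                 for p in range(lo, hi - len(motif) + 1)]
        assert (min(dists)[1]) == site.start

    def test_empty_motifs_config_error(self, default_genome):
        cos = find_cos_site(default_genome)[0]
        with pytest.raises(ConfigError):
            map_terminase_sites(default_genome, cos, {})
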