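"""ORF calling, genome statistics, transcription-region partition and holin TMD classification.

The gene caller is a deterministic six-frame scanner: every stop-bounded
frame segment is reported as an ORF anchored at its most upstream in-segment
start codon, provided the resulting ORF reaches ``min_orf_len``.  This is
intentionally simple (no ribosome-binding-site or coding-potential model)
but exact, which is what the planted-truth tests require.

936-type phage genomes carry three same-strand transcription regions (late,
early, middle in genome order from the cos cut).  :func:`partition_regions`
recovers them from sequence alone by splitting the coding-strand ORF chain
at its two largest intergenic gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import DEFAULT_START_CODONS, STOP_CODONS, revcomp, translate
from .errors import PartitionError
from .seq_io import Feature, PhageGenome, REGION_LABELS

__all__ = [
    "OrfCall",
    "RegionBlock",
    "RegionPartition",
    "gc_content",
    "at_content",
    "call_orfs",
    "partition_regions",
    "count_tmds",
    "classify_holin",
]


@dataclass(frozen=True)
class OrfCall:
    """A called open reading frame; coordinates are top-strand 0-based half-open
    and include the stop codon."""

    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class RegionBlock:
    label: str
    orfs: list[OrfCall]

    @property
    def start(self) -> int:
        return self.orfs[0].start

    @property
    def end(self) -> int:
        return self.orfs[-1].end


@dataclass
class RegionPartition:
    """Late/early/middle blocks of the coding-strand ORF chain, in genome order
    from the cos anchor, plus the two boundary gap sizes (bp)."""

    blocks: list[RegionBlock]
    boundary_gaps: tuple[int, int]
    strand: str

    def label_of(self, orf: OrfCall) -> str:
        for block in self.blocks:
            if orf in block.orfs:
                return block.label
        raise KeyError(f"ORF [{orf.start},{orf.end}) not in partition")


def gc_content(seq: str) -> float:
    """GC percentage of a non-empty ACGT string, to 1 decimal."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    gc = seq.count("G") + seq.count("C")
    return round(100.0 * gc / len(seq), 1)


def at_content(seq: str) -> float:
    if not seq:
        raise ValueError("at_content of empty sequence")
    at = seq.count("A") + seq.count("T")
    return round(100.0 * at / len(seq), 1)


def _scan_strand(seq: str, min_orf_len: int, start_codons: tuple[str, ...]) -> list[tuple[int, int, int]]:
    """All (start, end, frame) ORFs on the given (forward-oriented) sequence."""
    out = []
    n = len(seq)
    starts = set(start_codons)
    for frame in range(3):
        first_start = None  # most upstream start codon in the open segment
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if first_start is not None and pos + 3 - first_start >= min_orf_len:
                    out.append((first_start, pos + 3, frame))
                first_start = None
            elif first_start is None and codon in starts:
                first_start = pos
        # an open segment at the sequence end has no terminator: not an ORF
    return out


def call_orfs(
    genome: PhageGenome | str,
    min_orf_len: int = 90,
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS,
    both_strands: bool = True,
) -> list[OrfCall]:
    """Six-frame (or top-strand-only) ORF calling.

    Case-insensitive in the sequence; deterministic ordering by
    ``(start, strand)``.  ``length_nt`` counts start through stop codon
    inclusive; the reported protein excludes the stop.
    """
    seq = (genome.seq if isinstance(genome, PhageGenome) else genome).upper()
    calls: list[OrfCall] = []
    for s, e, frame in _scan_strand(seq, min_orf_len, start_codons):
        calls.append(OrfCall(s, e, "+", frame, translate(seq[s:e - 3])))
    if both_strands:
        rc = revcomp(seq)
        n = len(seq)
        for s, e, frame in _scan_strand(rc, min_orf_len, start_codons):
            calls.append(OrfCall(n - e, n - s, "-", frame, translate(rc[s:e - 3])))
    calls.sort(key=lambda o: (o.start, o.strand, o.end))
    return calls


def partition_regions(genome: PhageGenome, orfs: list[OrfCall]) -> RegionPartition:
    """Split the coding-strand ORF chain at its two largest intergenic gaps.

    The coding strand is the strand carrying the larger summed ORF length.
    Blocks are labelled late, early, middle in genome order from position 0
    (the cos cut sits between the middle and late regions on the circular
    map).  Gap ties break toward the earliest gap position.
    """
    if genome.topology != "linear_cos":
        raise PartitionError("region partition requires a cos-anchored linear genome")
    by_strand = {"+": [o for o in orfs if o.strand == "+"],
                 "-": [o for o in orfs if o.strand == "-"]}
    strand = max("+-", key=lambda s: sum(o.length_nt for o in by_strand[s]))
    chain = sorted(by_strand[strand], key=lambda o: (o.start, o.end))
    if len(chain) < 3:
        raise PartitionError(f"need >= 3 coding-strand ORFs, got {len(chain)}")
    # intergenic gap relative to the running coverage end, so ORFs nested in
    # (or overlapping) earlier ones cannot fabricate gaps
    gaps = []
    cover = chain[0].end
    for i in range(len(chain) - 1):
        gaps.append(chain[i + 1].start - cover)
        cover = max(cover, chain[i + 1].end)
    order = sorted(range(len(gaps)), key=lambda i: (-gaps[i], i))
    cut1, cut2 = sorted(order[:2])
    blocks = [
        RegionBlock(REGION_LABELS[0], chain[: cut1 + 1]),
        RegionBlock(REGION_LABELS[1], chain[cut1 + 1: cut2 + 1]),
        RegionBlock(REGION_LABELS[2], chain[cut2 + 1:]),
    ]
    return RegionPartition(blocks=blocks, boundary_gaps=(gaps[cut1], gaps[cut2]),
                           strand=strand)


# Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def count_tmds(protein: str, window: int = 19, threshold: float = 1.6) -> int:
    """Number of predicted transmembrane domains by sliding-window Kyte-Doolittle
    hydropathy: maximal runs of windows with mean >= ``threshold`` each count once."""
    protein = protein.upper().rstrip("*")
    if len(protein) < window:
        raise ValueError(f"protein shorter than the {window}-residue window")
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    above = means >= threshold
    # count maximal runs of consecutive qualifying windows
    return int(np.count_nonzero(above[1:] & ~above[:-1]) + (1 if above.size and above[0] else 0))


_HOLIN_CLASSES = {3: "I", 2: "II", 1: "III"}


def classify_holin(protein: str, window: int = 19, threshold: float = 1.6) -> str:
    """Holin class from TMD count (class I = 3 TMDs, II = 2, III = 1)."""
    n = count_tmds(protein, window=window, threshold=threshold)
    return _HOLIN_CLASSES.get(n, f"unclassified({n} TMDs)")
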