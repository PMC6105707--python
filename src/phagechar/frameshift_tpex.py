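"""Detection and simulation of the +1 'shifty stop' frameshift fusing MTP and TpeX.

Several 936-type phages end their major tail protein (mtp) gene in the
sequence CCC.UAG.  At this signal a fraction of ribosomes incorporate the
proline, slip one nucleotide forward instead of terminating, and continue in
the +1 frame into the downstream tail-protein-extension (tpeX) coding
region, producing an elongated MTP-TpeX fusion.

Shift mechanics used here: after the Pro at CCC the ribosome resumes one
nucleotide past the CCC/TAG junction, i.e. the first post-shift codon starts
at the A of the TAG.  This register is isolated in :func:`_post_shift_start`
so the alternative (+1 from the U) is a one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._dna import STOP_CODONS, translate
from .genome_annotation import OrfCall
from .seq_io import PhageGenome


@dataclass(frozen=True)
class FrameshiftCandidate:
    """An ORF ending in CCC.TAG with an in-frame stop available after the +1 shift."""

    upstream_orf: OrfCall
    shifty_codon_pos: int     # coordinate of the CCC codon
    stop_pos: int             # coordinate of the TAG terminator
    downstream_stop_pos: int  # next +1-frame stop after the shift


@dataclass(frozen=True)
class FrameshiftFusion:
    candidate: FrameshiftCandidate
    fused_protein: str

    @property
    def fused_len(self) -> int:
        return len(self.fused_protein)


def _post_shift_start(stop_pos: int) -> int:
    """First post-shift codon position: one nucleotide into the former TAG."""
    return stop_pos + 1


def _next_inframe_stop(seq: str, start: int, limit: int) -> int | None:
    """Position of the first stop codon in the frame anchored at ``start``,
    scanning at most ``limit`` nt; None when absent."""
    end = min(len(seq) - 2, start + limit)
    for pos in range(start, end, 3):
        if seq[pos:pos + 3] in STOP_CODONS:
            return pos
    return None


def find_shifty_stops(
    genome: PhageGenome,
    orfs: list[OrfCall],
    scan_limit: int = 3000,
) -> list[FrameshiftCandidate]:
    """Coding-strand ORFs whose last sense codon is CCC and terminator is TAG.

    An ORF qualifies only when a +1-frame stop exists within ``scan_limit``
    nt downstream of the shift (otherwise no fusion product can form).
    Deterministic order by ORF start.
    """
    seq = genome.seq
    out: list[FrameshiftCandidate] = []
    for orf in sorted(orfs, key=lambda o: (o.start, o.end)):
        if orf.strand != "+" or orf.length_nt < 6:
            continue
        stop_pos = orf.end - 3
        if seq[stop_pos:stop_pos + 3] != "TAG":
            continue
        if seq[stop_pos - 3:stop_pos] != "CCC":
            continue
        shift_start = _post_shift_start(stop_pos)
        down = _next_inframe_stop(seq, shift_start, scan_limit)
        if down is None:
            continue
        out.append(FrameshiftCandidate(orf, stop_pos - 3, stop_pos, down))
    return out


def simulate_frameshift(genome: PhageGenome, candidate: FrameshiftCandidate) -> FrameshiftFusion:
    """Translate the fused MTP-TpeX product for a detected candidate.

    The upstream ORF is translated through its CCC (Pro included), the frame
    advances by +1, and translation continues to the next in-frame stop
    (exclusive).
    """
    seq = genome.seq
    orf = candidate.upstream_orf
    if seq[candidate.stop_pos:candidate.stop_pos + 3] != "TAG":
        raise ValueError("candidate terminator is not TAG")
    upstream = translate(seq[orf.start:candidate.stop_pos])
    shift_start = _post_shift_start(candidate.stop_pos)
    downstream = translate(seq[shift_start:candidate.downstream_stop_pos])
    fused = upstream + downstream
    if "*" in fused:
        raise ValueError("internal stop in fused product; candidate is inconsistent")
    return FrameshiftFusion(candidate, fused)
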