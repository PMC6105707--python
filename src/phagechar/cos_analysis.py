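"""Locate the cos site and map its flanking packaging-signal elements.

936-type phage chromosomes carry an 11-nt cohesive-end (cos) sequence with a
characteristic neighbourhood: a 10-bp inverted repeat on each side, a tract
of short AATCT direct repeats (D1..Dn) and putative terminase binding sites
(R1-R3), one of which (R2) survives only as a truncation coinciding with the
last direct repeat.  All detectors here are exact-word or Hamming scanners
over a window around the cos site; every reported coordinate re-extracts to
the claimed sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from ._dna import find_all, hamming, revcomp
from .errors import ConfigError
from .seq_io import PhageGenome

logger = logging.getLogger("phagechar")

DEFAULT_COS_MOTIF = "CACAAAGGACT"


@dataclass(frozen=True)
class IRPair:
    """A left/right inverted-repeat arm pair around cos; the right arm matches
    the reverse complement of the left arm up to ``mismatches``."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    mismatches: int

    @property
    def arm_len(self) -> int:
        return self.left_end - self.left_start

    @property
    def span(self) -> int:
        return self.right_end - self.left_start


@dataclass(frozen=True)
class DirectRepeat:
    label: str
    start: int
    end: int


@dataclass(frozen=True)
class TerminaseSite:
    label: str
    start: int
    end: int
    matched_fraction: float
    complete: bool
    overlapping_drs: tuple[str, ...] = ()


@dataclass
class CosRegion:
    """The cos 11-mer plus whatever flanking elements have been mapped so far."""

    cos_start: int
    cos_end: int          # may exceed len(genome) when the motif spans the join
    cos_seq: str
    irs: list[IRPair] = field(default_factory=list)
    drs: list[DirectRepeat] = field(default_factory=list)
    terminase_sites: list[TerminaseSite] = field(default_factory=list)


def _circular_view(genome: PhageGenome, overhang: int) -> str:
    if genome.topology == "linear_cos" and overhang > 0:
        return genome.seq + genome.seq[: min(overhang, len(genome.seq))]
    return genome.seq


def find_cos_site(
    genome: PhageGenome,
    motif: str = DEFAULT_COS_MOTIF,
    max_mismatch: int = 0,
) -> list[CosRegion]:
    """All top-strand occurrences of the cos motif, circular view included.

    For ``linear_cos`` genomes the scan wraps across the join so an 11-mer
    split between the two chromosome ends is still found.  Returns an empty
    list when absent; warns when more than one occurrence exists.
    """
    view = _circular_view(genome, len(motif) - 1)
    hits: list[CosRegion] = []
    if max_mismatch == 0:
        positions = list(find_all(view, motif))
    else:
        positions = [
            i for i in range(len(view) - len(motif) + 1)
            if hamming(view[i:i + len(motif)], motif) <= max_mismatch
        ]
    for p in positions:
        if p < len(genome.seq):
            hits.append(CosRegion(p, p + len(motif), view[p:p + len(motif)]))
    if len(hits) > 1:
        warnings.warn(f"{genome.id}: {len(hits)} cos motif occurrences found")
    return hits


def find_inverted_repeats(
    genome: PhageGenome,
    cos: CosRegion,
    arm_len: int = 10,
    window: int = 200,
    max_mismatch: int = 1,
) -> list[IRPair]:
    """Inverted-repeat arm pairs flanking cos.

    Every left arm ending at or before ``cos_start`` is paired with every
    right arm starting at or after ``cos_end`` within ``window`` bp; pairs
    whose right arm matches the reverse complement of the left arm with at
    most ``max_mismatch`` mismatches are kept.  Overlapping redundant pairs
    are pruned to the best-scoring one (fewest mismatches, then smallest
    span, then leftmost), and the survivors are sorted by total distance to
    the cos site.
    """
    seq = genome.seq
    left_lo = max(0, cos.cos_start - window)
    if left_lo == 0 and cos.cos_start - window < 0:
        warnings.warn("inverted-repeat window clipped at the genome start")
    right_hi = min(len(seq), cos.cos_end + window)
    if right_hi == len(seq) and cos.cos_end + window > len(seq):
        warnings.warn("inverted-repeat window clipped at the genome end")
    candidates: list[IRPair] = []
    for ls in range(left_lo, cos.cos_start - arm_len + 1):
        left = seq[ls:ls + arm_len]
        target = revcomp(left)
        for rs in range(cos.cos_end, right_hi - arm_len + 1):
            mm = hamming(target, seq[rs:rs + arm_len])
            if mm <= max_mismatch:
                candidates.append(IRPair(ls, ls + arm_len, rs, rs + arm_len, mm))
    # prune overlapping pairs: deterministic best-first greedy
    candidates.sort(key=lambda p: (p.mismatches, p.span, p.left_start, p.right_start))
    kept: list[IRPair] = []
    for cand in candidates:
        clash = any(
            (cand.left_start < k.left_end and k.left_start < cand.left_end)
            or (cand.right_start < k.right_end and k.right_start < cand.right_end)
            for k in kept
        )
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda p: ((cos.cos_start - p.left_end) + (p.right_start - cos.cos_end),
                             p.left_start))
    return kept


def find_direct_repeats(
    genome: PhageGenome,
    cos: CosRegion,
    motif: str = "AATCT",
    window: int = 200,
) -> list[DirectRepeat]:
    """Exact occurrences of the direct-repeat motif within ``window`` bp of cos,
    labelled D1..Dn in positional order."""
    lo = max(0, cos.cos_start - window)
    hi = min(len(genome.seq), cos.cos_end + window)
    hits = [p + lo for p in find_all(genome.seq[lo:hi], motif)]
    return [DirectRepeat(f"D{i + 1}", p, p + len(motif)) for i, p in enumerate(hits)]


def map_terminase_sites(
    genome: PhageGenome,
    cos: CosRegion,
    site_motifs: dict[str, str],
    min_complete_fraction: float = 1.0,
    window: int = 200,
    drs: list[DirectRepeat] | None = None,
) -> list[TerminaseSite]:
    """Best match of each terminase-site motif in the cos window.

    ``site_motifs`` must be supplied (the R1-R3 sequences are a configuration
    input, not a constant of the method).  A site is ``complete`` when its
    matched fraction reaches ``min_complete_fraction``.  Direct repeats whose
    coordinates fall inside a partial match are recorded as truncations of
    that site (the D6/R2 relationship).
    """
    if not site_motifs:
        raise ConfigError("map_terminase_sites requires at least one site motif")
    if drs is None:
        drs = find_direct_repeats(genome, cos, window=window)
    seq = genome.seq
    lo = max(0, cos.cos_start - window)
    hi = min(len(seq), cos.cos_end + window)
    out: list[TerminaseSite] = []
    for label, motif in site_motifs.items():
        best_pos, best_mm = None, len(motif) + 1
        for p in range(lo, hi - len(motif) + 1):
            mm = hamming(seq[p:p + len(motif)], motif)
            if mm < best_mm:
                best_pos, best_mm = p, mm
        if best_pos is None:
            continue
        frac = 1.0 - best_mm / len(motif)
        complete = frac >= min_complete_fraction
        overlapping = ()
        if not complete:
            overlapping = tuple(
                d.label for d in drs if d.start >= best_pos and d.end <= best_pos + len(motif)
            )
            if overlapping:
                logger.info("%s: %s fall inside a partial %s match (truncated site)",
                            genome.id, overlapping, label)
        out.append(TerminaseSite(label, best_pos, best_pos + len(motif), frac,
                                 complete, overlapping))
    return out


def analyze_cos_region(
    genome: PhageGenome,
    motif: str = DEFAULT_COS_MOTIF,
    site_motifs: dict[str, str] | None = None,
    window: int = 200,
) -> CosRegion | None:
    """Convenience wrapper: locate cos and populate IRs, DRs and terminase sites."""
    hits = find_cos_site(genome, motif=motif)
    if not hits:
        return None
    cos = hits[0]
    cos.irs = find_inverted_repeats(genome, cos, window=window)
    cos.drs = find_direct_repeats(genome, cos, window=window)
    if site_motifs:
        cos.terminase_sites = map_terminase_sites(genome, cos, site_motifs,
                                                  window=window, drs=cos.drs)
    return cos
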