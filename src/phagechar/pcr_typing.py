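"""In-silico multiplex PCR typing with 936- and c2-specific primer pairs.

A primer binds where its 3'-terminal clamp matches the template exactly and
the remaining bases carry at most ``max_mismatch`` mismatches (polymerase
extension requires a matched 3' end).  Product length is the standard
amplicon size: 5' end of the forward primer site through the far end of the
reverse primer site, both footprints included.  ``linear_cos`` templates are
treated as circular, so products spanning the cos join are found.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._dna import revcomp
from .seq_io import DEFAULT_PRIMERS, PhageGenome, PrimerPair


@dataclass(frozen=True)
class AmpliconResult:
    pair: str
    fwd_pos: int          # 5' end of the forward primer site, top strand
    rev_pos: int          # leftmost base of the reverse primer site, top strand
    length: int
    fwd_mismatches: int
    rev_mismatches: int


def _site_mismatches(window: str, site: str, clamp_lo: int, clamp_hi: int,
                     max_mismatch: int) -> int | None:
    """Mismatch count if the site binds (exact over [clamp_lo, clamp_hi), at
    most ``max_mismatch`` elsewhere); None otherwise."""
    mm = 0
    for i, (a, b) in enumerate(zip(window, site)):
        if a != b:
            if clamp_lo <= i < clamp_hi:
                return None
            mm += 1
            if mm > max_mismatch:
                return None
    return mm


def in_silico_pcr(
    genome: PhageGenome,
    pair: PrimerPair,
    max_mismatch: int = 2,
    clamp_len: int = 5,
    max_product: int = 5000,
) -> list[AmpliconResult]:
    """All convergent forward/reverse binding-site pairs yielding a product of
    at most ``max_product`` bp."""
    if clamp_len > min(len(pair.fwd), len(pair.rev)):
        raise ValueError("primer shorter than the 3' clamp length")
    n = len(genome)
    circular = genome.topology in ("linear_cos", "circular")
    template = genome.seq + (genome.seq[: min(max_product, n)] if circular else "")
    out: list[AmpliconResult] = []
    # PCR is strand-symmetric: either primer may play the top-strand role
    for fwd, rev, swapped in ((pair.fwd, pair.rev, False), (pair.rev, pair.fwd, True)):
        out.extend(_scan_orientation(template, n, pair.name, fwd, rev, swapped,
                                     max_mismatch, clamp_len, max_product))
    out.sort(key=lambda a: (a.fwd_pos, a.length))
    return out


def _scan_orientation(template: str, n: int, pair_name: str, fwd: str, rev: str,
                      swapped: bool, max_mismatch: int, clamp_len: int,
                      max_product: int) -> list[AmpliconResult]:
    rev_site = revcomp(rev)  # reverse-role primer footprint on the top strand
    lf, lr = len(fwd), len(rev_site)

    # anchor the scan on exact occurrences of the 3' clamp: a binding site
    # must contain them, so only clamp hits need the full mismatch check
    fwd_hits: list[tuple[int, int]] = []
    clamp_f = fwd[lf - clamp_len:]
    i = template.find(clamp_f)
    while i != -1:
        p = i - (lf - clamp_len)
        if 0 <= p < n and p + lf <= len(template):
            mm = _site_mismatches(template[p:p + lf], fwd, lf - clamp_len, lf, max_mismatch)
            if mm is not None:
                fwd_hits.append((p, mm))
        i = template.find(clamp_f, i + 1)
    rev_hits: list[tuple[int, int]] = []
    clamp_r = rev_site[:clamp_len]  # the reverse primer's 3' clamp, top strand
    q = template.find(clamp_r)
    while q != -1:
        if q + lr <= len(template):
            mm = _site_mismatches(template[q:q + lr], rev_site, 0, clamp_len, max_mismatch)
            if mm is not None:
                rev_hits.append((q, mm))
        q = template.find(clamp_r, q + 1)

    out: list[AmpliconResult] = []
    for p, fmm in fwd_hits:
        for q, rmm in rev_hits:
            length = q + lr - p
            # a circular template cannot yield a product longer than itself
            if q >= p + lf and length <= max_product and length <= n:
                if swapped:
                    # report mismatches/coordinates under the pair's own naming
                    out.append(AmpliconResult(pair_name, q % n, p % n, length, rmm, fmm))
                else:
                    out.append(AmpliconResult(pair_name, p % n, q % n, length, fmm, rmm))
    return out


def classify_phage_type(
    genome: PhageGenome,
    pairs: dict[str, PrimerPair] | None = None,
    **pcr_kwargs: object,
) -> str:
    """Type call from multiplex amplicon presence.

    One pair amplifying -> that pair's expected type; several -> ``"mixed"``;
    none -> ``"untyped"``.  Multiplexing is simulated as independent
    single-pair reactions (no competition model).
    """
    if pairs is None:
        pairs = DEFAULT_PRIMERS
    if not pairs:
        raise ValueError("classify_phage_type requires at least one primer pair")
    positive = [
        pair.expected_type
        for pair in pairs.values()
        if in_silico_pcr(genome, pair, **pcr_kwargs)
    ]
    if not positive:
        return "untyped"
    if len(set(positive)) > 1:
        return "mixed"
    return positive[0]
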