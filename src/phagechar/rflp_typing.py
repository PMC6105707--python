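"""In-silico restriction digestion, gel-aware band patterns and restriction grouping.

Phage chromosomes with cohesive ends run differently on a gel depending on
whether the annealed cos termini were dissociated (formamide/heat) before
electrophoresis.  ``end_mode="dissociated"`` digests the linear molecule (the
two terminal fragments run separately); ``end_mode="cohesive"`` digests the
circularized molecule, joining the terminal fragments into one band.  Band
patterns are compared with a greedy size-matching Dice distance and grouped
by single linkage into restriction types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._dna import find_all
from .seq_io import EnzymeDef, PhageGenome

END_MODES = ("dissociated", "cohesive")


@dataclass
class RestrictionPattern:
    """Fragment multiset for one genome x enzyme x end-mode, plus the visible bands."""

    genome_id: str
    enzyme: str
    end_mode: str
    fragments: tuple[int, ...]                 # sorted ascending; sums to genome length
    bands: list[float] = field(default_factory=list)  # descending, after gel filtering


def digest(genome: PhageGenome, enzyme: EnzymeDef, end_mode: str = "dissociated",
           min_size: int = 200, rel_tol: float = 0.05) -> RestrictionPattern:
    """Digest a genome and compute its band pattern.

    Cut positions are ``site start + cut_offset`` on the top strand (type II
    palindromic enzymes: the double-strand cut collapses to a single
    coordinate).  With no site the molecule stays intact in either mode.
    """
    if end_mode not in END_MODES:
        raise ValueError(f"end_mode must be one of {END_MODES}")
    n = len(genome)
    if n == 0:
        raise ValueError("cannot digest a zero-length genome")
    cuts = sorted(p + enzyme.cut_offset for p in find_all(genome.seq, enzyme.site))
    if not cuts:
        fragments = (n,)
    elif end_mode == "dissociated":
        bounds = [0] + cuts + [n]
        fragments = tuple(sorted(b - a for a, b in zip(bounds, bounds[1:]) if b > a))
    else:  # cohesive: the two terminal fragments ligate into one
        inner = [b - a for a, b in zip(cuts, cuts[1:])]
        joined = (n - cuts[-1]) + cuts[0]
        fragments = tuple(sorted(inner + [joined])) if joined > 0 else tuple(sorted(inner))
    pattern = RestrictionPattern(genome.id, enzyme.name, end_mode, fragments)
    pattern.bands = to_bands(pattern, min_size=min_size, rel_tol=rel_tol)
    return pattern


def to_bands(pattern: RestrictionPattern, min_size: int = 200,
             rel_tol: float = 0.05) -> list[float]:
    """Visible band sizes: drop fragments below ``min_size`` (they run off a
    0.7% gel), merge co-migrating fragments (|ln(s1/s2)| <= ln(1+rel_tol))
    into one band at their mean, return descending."""
    sizes = sorted((s for s in pattern.fragments if s >= min_size), reverse=True)
    bands: list[float] = []
    cluster: list[int] = []
    log_tol = math.log1p(rel_tol)
    for s in sizes:
        if cluster and abs(math.log(cluster[-1] / s)) <= log_tol:
            cluster.append(s)
        else:
            if cluster:
                bands.append(sum(cluster) / len(cluster))
            cluster = [s]
    if cluster:
        bands.append(sum(cluster) / len(cluster))
    return bands


def pattern_distance(p1: RestrictionPattern, p2: RestrictionPattern,
                     rel_tol: float = 0.05) -> float:
    """Dice-style band-pattern distance in [0, 1].

    Bands are matched greedily largest-first under the ratio test; the
    distance is ``1 - 2m/(|b1|+|b2|)`` for ``m`` matched band pairs.
    Symmetric and zero on identical patterns; the triangle inequality is not
    guaranteed (greedy matching), so this is a semimetric.
    """
    if (p1.enzyme, p1.end_mode) != (p2.enzyme, p2.end_mode):
        raise ValueError("patterns from different enzymes/end modes are not comparable")
    b1, b2 = p1.bands, p2.bands
    if not b1 and not b2:
        return 0.0
    log_tol = math.log1p(rel_tol)
    i = j = m = 0
    while i < len(b1) and j < len(b2):
        if abs(math.log(b1[i] / b2[j])) <= log_tol:
            m += 1
            i += 1
            j += 1
        elif b1[i] > b2[j]:
            i += 1
        else:
            j += 1
    return 1.0 - 2.0 * m / (len(b1) + len(b2))


def group_patterns(patterns: list[RestrictionPattern], threshold: float = 0.1,
                   rel_tol: float = 0.05) -> list[int]:
    """Single-linkage restriction grouping.

    Groups are the connected components of the graph joining patterns at
    distance <= ``threshold``; labels are integers (1, 2, ...) assigned in
    order of each group's first member, so the result is deterministic for a
    given input order.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    n = len(patterns)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if pattern_distance(patterns[i], patterns[j], rel_tol=rel_tol) <= threshold:
                parent[find(i)] = find(j)
    labels: list[int] = []
    seen: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in seen:
            seen[root] = len(seen) + 1
        labels.append(seen[root])
    return labels
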