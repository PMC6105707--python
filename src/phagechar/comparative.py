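"""Alignment-free genome comparison: k-mer distances, neighbour joining, dot plots.

Pairwise distances use canonical k-mer sets (lexicographic minimum of each
k-mer and its reverse complement, so distances are strand-neutral) and the
Mash formulation d = -(1/k) ln(2J/(1+J)) on the Jaccard index J, capped at
1.0.  Trees are built with classic neighbour joining with deterministic
tie-breaking; dot plots report maximal exact-match segments in both
orientations via shared-word anchoring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._dna import revcomp
from .seq_io import PhageGenome


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Set of canonical k-mers (min of k-mer and its reverse complement)."""
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    rc = revcomp(seq)
    n = len(seq)
    return {min(seq[i:i + k], rc[n - k - i:n - i]) for i in range(n - k + 1)}


def kmer_distance(g1: PhageGenome | str, g2: PhageGenome | str, k: int = 15) -> float:
    """Mash-style distance between two genomes' canonical k-mer sets.

    0 when the sets are equal; capped at 1.0, the sentinel for disjoint sets.
    """
    s1 = g1.seq if isinstance(g1, PhageGenome) else g1
    s2 = g2.seq if isinstance(g2, PhageGenome) else g2
    a, b = canonical_kmers(s1, k), canonical_kmers(s2, k)
    inter = len(a & b)
    if inter == 0:
        return 1.0
    j = inter / len(a | b)
    if j == 1.0:
        return 0.0
    return min(1.0, -math.log(2 * j / (1 + j)) / k)


def distance_matrix(genomes: list[PhageGenome], k: int = 15) -> DistanceMatrix:
    """All pairwise k-mer distances (k-mer sets computed once per genome)."""
    sets = [canonical_kmers(g.seq, k) for g in genomes]
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if inter == 0:
                dij = 1.0
            else:
                jac = inter / len(sets[i] | sets[j])
                dij = 0.0 if jac == 1.0 else min(1.0, -math.log(2 * jac / (1 + jac)) / k)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix([g.id for g in genomes], d)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbour joining with deterministic (lowest index pair) tie-breaking.

    Returns a Newick string with branch lengths; negative branch lengths are
    clamped to 0 with a warning.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[str] = []  # newick subtrees
    for name in dm.ids:
        nodes.append(name)
    active = list(range(n))

    def branch(x: float) -> float:
        if x < -1e-9:
            warnings.warn(f"negative NJ branch length {x:.4g} clamped to 0")
        return max(x, 0.0)

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - row_sums[a] - row_sums[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        dab = sub[a, b]
        va = 0.5 * dab + (row_sums[a] - row_sums[b]) / (2 * (m - 2))
        vb = dab - va
        va, vb = branch(va), branch(vb)
        new_label = f"({nodes[ia]}:{va:.12g},{nodes[ib]}:{vb:.12g})"
        # distances from the new node to every other active node
        new_d = np.zeros(d.shape[0] + 1)
        for c in range(m):
            ic = active[c]
            if ic in (ia, ib):
                continue
            new_d[ic] = 0.5 * (d[ia, ic] + d[ib, ic] - dab)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d[:-1]
        d[:-1, -1] = new_d[:-1]
        nodes.append(new_label)
        active = [i for i in active if i not in (ia, ib)] + [d.shape[0] - 1]
    ia, ib = active
    v = branch(d[ia, ib])
    return f"({nodes[ia]}:{v:.12g},{nodes[ib]}:0);"


# ---------------------------------------------------------------------------
# Dot plots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DotPlotSegment:
    """A maximal exact-match segment; for ``reverse`` orientation g1[x:x+len]
    equals the reverse complement of g2[y:y+len]."""

    x_start: int
    y_start: int
    length: int
    orientation: str  # "forward" | "reverse"


def _anchor_segments(s1: str, s2: str, w: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches of length >= w as (x, y, length) via merging of
    consecutive shared-word anchors along each diagonal."""
    index: dict[str, list[int]] = {}
    for y in range(len(s2) - w + 1):
        index.setdefault(s2[y:y + w], []).append(y)
    anchors: dict[int, list[int]] = {}  # diagonal -> x positions
    for x in range(len(s1) - w + 1):
        for y in index.get(s1[x:x + w], ()):
            anchors.setdefault(x - y, []).append(x)
    segments = []
    for diag, xs in anchors.items():
        xs.sort()
        run_start = prev = xs[0]
        for x in xs[1:]:
            if x == prev + 1:
                prev = x
            else:
                segments.append((run_start, run_start - diag, prev - run_start + w))
                run_start = prev = x
        segments.append((run_start, run_start - diag, prev - run_start + w))
    return segments


def dotplot_segments(g1: PhageGenome | str, g2: PhageGenome | str, w: int = 20) -> list[DotPlotSegment]:
    """Maximal exact-match segments (forward and reverse-complement) of length
    >= ``w`` between two genomes, sorted by ``x_start``."""
    s1 = g1.seq if isinstance(g1, PhageGenome) else g1
    s2 = g2.seq if isinstance(g2, PhageGenome) else g2
    if min(len(s1), len(s2)) < w:
        raise ValueError(f"sequences must be at least w={w} long")
    out = [DotPlotSegment(x, y, ln, "forward") for x, y, ln in _anchor_segments(s1, s2, w)]
    rc2 = revcomp(s2)
    for x, y_rc, ln in _anchor_segments(s1, rc2, w):
        out.append(DotPlotSegment(x, len(s2) - y_rc - ln, ln, "reverse"))
    out.sort(key=lambda s: (s.x_start, s.y_start, s.orientation))
    return out
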