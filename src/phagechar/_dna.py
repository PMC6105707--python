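"""Low-level DNA string utilities used across the package.

Sequences are plain upper-case ``str`` over the strict {A,C,G,T} alphabet;
coordinates are 0-based half-open throughout the library.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from Bio.Seq import Seq

from .errors import AlphabetError

DNA_ALPHABET = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate with the bacterial code (table 11); trailing partial codon ignored."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate(table=11))


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Upper-case ``seq`` and reject anything outside ACGT (no ambiguity codes)."""
    up = seq.upper()
    if not up:
        raise AlphabetError(f"{name}: empty sequence")
    bad = set(up) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{name}: non-ACGT characters {sorted(bad)}; ambiguity codes are rejected"
        )
    return up


def find_all(seq: str, word: str) -> Iterator[int]:
    """Yield every (possibly overlapping) start position of ``word`` in ``seq``."""
    i = seq.find(word)
    while i != -1:
        yield i
        i = seq.find(word, i + 1)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    """i.i.d. random DNA with the requested expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=n, p=p)
    return arr.tobytes().decode("ascii")
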