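"""Sequence and feature I/O, enzyme/primer registries and run configuration.

Domain model
------------
A :class:`PhageGenome` is a linear dsDNA sequence with optional
:class:`Feature` annotations.  For ``topology="linear_cos"`` position 0 is,
by convention, the first base 3' of the cos cut on the top strand, so the
genome may be viewed circularly by joining its two cohesive ends.

Coordinates are 0-based half-open internally.  Emitted feature tables use
1-based inclusive coordinates (GenBank convention); the conversion is
bijective and exposed via :func:`to_one_based` / :func:`from_one_based`.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import validate_dna
from .errors import ConfigError, FastaParseError

logger = logging.getLogger("phagechar")

FEATURE_KINDS = (
    "orf",
    "cos",
    "inverted_repeat",
    "direct_repeat",
    "terminase_site",
    "primer_site",
    "restriction_site",
    "region",
)

REGION_LABELS = ("late", "early", "middle")


@dataclass
class Feature:
    """A located genome element; ``start``/``end`` are 0-based half-open top-strand coordinates."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature coordinates [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind in ("orf", "primer_site") and self.strand == ".":
            raise ValueError(f"{self.kind} features require a defined strand")
        if self.kind == "region":
            label = self.qualifiers.get("label")
            if label not in REGION_LABELS:
                raise ValueError(f"region feature needs qualifier label in {REGION_LABELS}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PhageGenome:
    """A phage genome sequence plus annotations.

    ``topology`` is ``"linear_cos"`` (a linear chromosome with cohesive ends,
    circularizable at the cos cut) or ``"circular"``.
    """

    id: str
    seq: str
    topology: str = "linear_cos"
    features: list[Feature] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.seq = validate_dna(self.seq, name=f"genome {self.id!r}")
        if self.topology not in ("linear_cos", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(
                    f"feature [{f.start},{f.end}) exceeds genome length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class EnzymeDef:
    """A type II restriction enzyme: exact recognition site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", validate_dna(self.site, name=f"enzyme {self.name}"))
        if not (0 <= self.cut_offset <= len(self.site)):
            raise ValueError("cut_offset must lie within the recognition site")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse PCR primer pair and the phage type it diagnoses."""

    name: str
    fwd: str
    rev: str
    expected_type: str

    def __post_init__(self) -> None:
        for attr in ("fwd", "rev"):
            seq = validate_dna(getattr(self, attr), name=f"primer {self.name}.{attr}")
            object.__setattr__(self, attr, seq)
            if len(seq) < 15:
                raise ValueError(f"primer {self.name}.{attr} shorter than 15 nt")


#: Enzymes used for RFLP typing of lactococcal phage DNA (6-bp, low-GC sites).
DEFAULT_ENZYMES: dict[str, EnzymeDef] = {
    "EcoRI": EnzymeDef("EcoRI", "GAATTC", 1),
    "EcoRV": EnzymeDef("EcoRV", "GATATC", 3),
    "HindIII": EnzymeDef("HindIII", "AAGCTT", 1),
}

#: Multiplex typing primers for the 936 and c2 lactococcal phage groups.
DEFAULT_PRIMERS: dict[str, PrimerPair] = {
    "936": PrimerPair("936", "TCAATGGAAGACCAAGCGGA", "GTAGGAGACCAACCCAAGCC", "936"),
    "c2": PrimerPair("c2", "CAGGTGTAAAAGTTCGAGAACT", "CAGATAATGCACCTGAATCA", "c2"),
}


def get_enzyme(name: str) -> EnzymeDef:
    try:
        return DEFAULT_ENZYMES[name]
    except KeyError:
        raise ConfigError(
            f"unknown enzyme {name!r}; registered: {sorted(DEFAULT_ENZYMES)}"
        ) from None


def get_primer_pair(name: str) -> PrimerPair:
    try:
        return DEFAULT_PRIMERS[name]
    except KeyError:
        raise ConfigError(
            f"unknown primer pair {name!r}; registered: {sorted(DEFAULT_PRIMERS)}"
        ) from None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, topology: str = "linear_cos") -> list[PhageGenome]:
    """Read a FASTA file into :class:`PhageGenome` records.

    Sequences are upper-cased; any non-ACGT character raises
    :class:`~phagechar.errors.AlphabetError` naming the record.  A file whose
    first non-blank line is not a header raises :class:`FastaParseError`
    naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header starting with '>'"
                    )
                break
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes.append(PhageGenome(id=rec.id, seq=str(rec.seq), topology=topology,
                                   provenance=f"read from {path}"))
    return genomes


def write_fasta(genomes: Iterable[PhageGenome], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def fetch_genbank_fasta(accession: str, timeout: float = 30.0) -> PhageGenome:
    """Optional convenience: download one nucleotide record from NCBI as FASTA.

    Requires network access; nothing in the package or its tests depends on
    this helper.  Useful for pulling reference phage genomes (e.g. sk1,
    NC_001835.1) to run the typing pipeline on deposited sequences.
    """
    import io
    import urllib.request

    url = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
           f"?db=nuccore&id={accession}&rettype=fasta&retmode=text")
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    rec = next(SeqIO.parse(io.StringIO(text), "fasta"))
    return PhageGenome(id=accession, seq=str(rec.seq), topology="linear_cos",
                       provenance=f"fetched from NCBI nuccore {accession}")


# ---------------------------------------------------------------------------
# Feature tables (tab-delimited, 1-based inclusive)
# ---------------------------------------------------------------------------

def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return first - 1, last


_TABLE_HEADER = ["start", "end", "strand", "kind", "qualifiers"]


def _format_qualifiers(q: dict[str, str]) -> str:
    for k, v in q.items():
        if any(c in f"{k}{v}" for c in "\t;="):
            raise ValueError(f"qualifier {k}={v} contains a reserved character")
    return ";".join(f"{k}={v}" for k, v in q.items()) or "."


def _parse_qualifiers(text: str) -> dict[str, str]:
    if text == ".":
        return {}
    out = {}
    for item in text.split(";"):
        k, _, v = item.partition("=")
        out[k] = v
    return out


def write_feature_table(genome: PhageGenome, path: str | Path) -> None:
    """Write the genome's features as a tab-delimited 1-based inclusive table."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_HEADER) + "\n")
        for f in genome.features:
            first, last = to_one_based(f.start, f.end)
            fh.write(
                f"{first}\t{last}\t{f.strand}\t{f.kind}\t{_format_qualifiers(f.qualifiers)}\n"
            )


def read_feature_table(path: str | Path) -> list[Feature]:
    """Inverse of :func:`write_feature_table`; lossless round trip."""
    features = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TABLE_HEADER:
            raise ValueError(f"{path}: unexpected feature table header {header}")
        for line in fh:
            if not line.strip():
                continue
            first, last, strand, kind, quals = line.rstrip("\n").split("\t")
            start, end = from_one_based(int(first), int(last))
            features.append(Feature(kind=kind, start=start, end=end, strand=strand,
                                    qualifiers=_parse_qualifiers(quals)))
    return features


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Documented defaults for every run-configuration key.
DEFAULT_CONFIG: dict[str, object] = {
    "enzyme": "EcoRV",          # RFLP enzyme giving the most differential patterns
    "primers": "936,c2",        # multiplex typing pairs
    "min_size": 200,            # smallest band visible on a 0.7% agarose gel, bp
    "rel_tol": 0.05,            # band co-migration / matching ratio tolerance
    "group_threshold": 0.1,     # single-linkage distance cutoff for restriction groups
    "min_orf_len": 90,          # minimum reported ORF length, nt
    "kmer_k": 15,               # k for alignment-free genome distances
    "word_size": 20,            # dot-plot exact-match word size
    "cos_motif": "CACAAAGGACT",  # 936-type cohesive-end 11-mer
    "seed": 1,
}


def load_config(path: str | Path | None = None, **overrides: object) -> dict[str, object]:
    """Load a flat ``key=value`` config file, filling missing keys with defaults.

    Unknown keys raise :class:`ConfigError` listing the valid keys and, when
    close, suggesting the nearest one.  The effective configuration is logged.
    """
    cfg = dict(DEFAULT_CONFIG)
    items: list[tuple[str, str]] = []
    if path is not None:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}: line {lineno}: expected key=value")
                k, v = (s.strip() for s in line.split("=", 1))
                items.append((k, v))
    items.extend((k, v) for k, v in overrides.items())
    for key, value in items:
        if key not in cfg:
            hint = difflib.get_close_matches(key, cfg, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(
                f"unknown config key {key!r}{suggestion} valid keys: {sorted(cfg)}"
            )
        default = DEFAULT_CONFIG[key]
        if isinstance(default, bool):
            cfg[key] = str(value).lower() in ("1", "true", "yes")
        elif isinstance(default, int) and not isinstance(value, bool):
            cfg[key] = int(value)
        elif isinstance(default, float):
            cfg[key] = float(value)
        else:
            cfg[key] = str(value)
    logger.info("effective config: %s", cfg)
    return cfg
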