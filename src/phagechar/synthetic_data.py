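"""Synthetic 936-like genomes, RFLP cohorts and one-step growth curves with recorded truth.

The generator emulates the genome architecture of 936-type dairy phages:
~29.3-30.2 kb linear dsDNA at ~34.7% GC, one cos 11-mer flanked by 10-bp
inverted repeats, a tract of AATCT direct repeats and terminase-binding
motifs (R1/R3 intact, R2 surviving only as a truncation coinciding with the
last direct repeat), three same-strand transcription regions (late, early,
middle in genome order from the cos cut) separated by large intergenic gaps,
an mtp ORF ending in the CCC.TAG shifty stop followed by a +1-frame tpeX
coding region, planted multiplex-PCR primer sites and planted restriction
sites.  Every planted element is recorded in a :class:`TruthSet` with exact
coordinates.

Background sequence is i.i.d. with base probabilities tuned to the target
GC.  To keep the planted truth *exact* the builder then scrubs accidental
signal from the background: duplicate cos motifs, unplanned restriction
sites, stray AATCT words near cos, coding-strand ORFs outside planted
footprints and accidental CCC.TAG shifty stops are all mutated away (inside
planted ORFs only via changes that keep every governing reading frame
sense).  A final verification pass re-detects every planted element with
the package's own analysis modules and regenerates from a fresh derived
seed on any failure, so generation is deterministic in the spec seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._dna import STOP_CODONS, random_dna, revcomp
from .cos_analysis import find_cos_site, find_direct_repeats, find_inverted_repeats, map_terminase_sites
from .errors import GenerationError, SpecError
from .genome_annotation import _scan_strand, call_orfs, partition_regions
from .growth_kinetics import GrowthCurve, GrowthParams
from .frameshift_tpex import find_shifty_stops, simulate_frameshift
from .pcr_typing import in_silico_pcr
from .rflp_typing import digest, pattern_distance
from .seq_io import (
    DEFAULT_ENZYMES,
    DEFAULT_PRIMERS,
    Feature,
    PhageGenome,
    get_primer_pair,
)

__all__ = [
    "GenomeSpec",
    "TruthSet",
    "SYNTH_TERMINASE_MOTIFS",
    "generate_genome",
    "generate_cohort",
    "simulate_growth_curve",
]

#: Synthetic stand-ins for the R1-R3 terminase binding motifs (the real
#: sequences are a configuration input, not published constants).  R2 starts
#: with the direct-repeat word: the generator plants only its 8-nt prefix, so
#: the last direct repeat is a truncated R2, as in real 936-type cos regions.
SYNTH_TERMINASE_MOTIFS: dict[str, str] = {
    "R1": "GGTTCACGTAAGGTAC",
    "R2": "AATCTGTGCGGT",
    "R3": "CCATGTGACGTTGGAC",
}

_R2_TRUNC_LEN = 10
_POST_SHIFT_CODONS = 340   # fused MTP-TpeX = 180 + 340 = 520 aa
_MTP_LEN = 543             # ATG + 178 sense codons + CCC + TAG
_COS_WINDOW = 200
_MAX_ATTEMPTS = 30


@dataclass
class GenomeSpec:
    """Generator parameters; defaults are the 936-type study conditions."""

    length: int | None = None            # None: drawn uniformly in [29300, 30200]
    gc: float = 0.347
    cos_motif: str = "CACAAAGGACT"
    ir_len: int = 10
    n_direct_repeats: int = 6            # includes the truncated-R2 repeat
    dr_motif: str = "AATCT"
    region_plan: tuple[int, int, int] = (22, 28, 4)   # late, early, middle ORF counts
    shifty_stop: bool = True
    primer_sites: tuple[tuple[str, int], ...] = (("936", 179),)  # (pair name, amplicon bp)
    enzyme_sites: dict[str, list[int]] | None = None  # None: random layout per enzyme
    seed: int = 1


@dataclass
class TruthSet:
    """Ground truth for generated data: planted features and scalar truths per genome."""

    features: dict[str, list[Feature]] = field(default_factory=dict)
    scalars: dict[str, dict[str, object]] = field(default_factory=dict)


class _Retry(Exception):
    """Internal: restart genome construction from a fresh derived seed."""


def _validate_spec(spec: GenomeSpec) -> None:
    if not (0.25 <= spec.gc <= 0.6):
        raise SpecError(f"requested GC {spec.gc} outside [0.25, 0.6]")
    if spec.length is not None and spec.length < 8000:
        raise SpecError("genome length below 8 kb cannot hold the planted layout")
    if spec.n_direct_repeats < 1:
        raise SpecError("need at least one direct repeat")
    if any(c < 1 for c in spec.region_plan) or spec.region_plan[0] < 2:
        raise SpecError("region plan needs >= 1 ORF per region and >= 2 late ORFs")
    for name, amp in spec.primer_sites:
        pair = get_primer_pair(name)
        if amp < len(pair.fwd) + len(pair.rev):
            raise SpecError(f"amplicon {amp} bp shorter than the {name} primer footprints")


def _forbidden_words(spec: GenomeSpec) -> list[str]:
    words = [spec.cos_motif, spec.dr_motif]
    words += [e.site for e in DEFAULT_ENZYMES.values()]
    return words


class _Builder:
    def __init__(self, spec: GenomeSpec, seed: int, genome_id: str):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self.gid = genome_id
        self.buf = bytearray()
        self.features: list[Feature] = []
        self.protected: list[tuple[int, int]] = []
        self.L = int(spec.length) if spec.length is not None else int(self.rng.integers(29300, 30201))

    # -- assembly helpers ---------------------------------------------------

    def cur(self) -> int:
        return len(self.buf)

    def add(self, s: str) -> None:
        self.buf += s.encode("ascii")

    def add_protected(self, s: str) -> None:
        self.protected.append((self.cur(), self.cur() + len(s)))
        self.add(s)

    def bg(self, n: int) -> str:
        return random_dna(self.rng, n, self.spec.gc)

    def sense_codons(self, n: int) -> str:
        arr = bytearray(self.bg(3 * n).encode("ascii"))
        for i in range(0, 3 * n, 3):
            while bytes(arr[i:i + 3]).decode() in STOP_CODONS:
                arr[i:i + 3] = self.bg(3).encode("ascii")
        return arr.decode("ascii")

    def feat(self, kind: str, start: int, end: int, strand: str = "+", **quals: str) -> Feature:
        f = Feature(kind=kind, start=start, end=end, strand=strand,
                    qualifiers={k: str(v) for k, v in quals.items()})
        self.features.append(f)
        return f

    # -- planted elements ---------------------------------------------------

    def draw_ir_arm(self) -> str:
        forb = _forbidden_words(self.spec)
        for _ in range(300):
            arm = self.bg(self.spec.ir_len)
            left_ctx = arm + "A"
            right_ctx = "A" + revcomp(arm)
            if any(w in left_ctx or w in right_ctx for w in forb):
                continue
            return arm
        raise _Retry("could not draw a clean inverted-repeat arm")

    def build_cos_block(self) -> None:
        spec = self.spec
        self.add(self.bg(40))
        arm = self.draw_ir_arm()
        self.feat("inverted_repeat", self.cur(), self.cur() + len(arm), ".",
                  pair="IR1", arm="left")
        self.add(arm)
        self.add_protected("A")             # guard against frame-shifted IR ghosts
        self.add(self.bg(3))
        self.cos_pos = self.cur()
        self.feat("cos", self.cur(), self.cur() + len(spec.cos_motif), ".")
        self.add(spec.cos_motif)
        self.add(self.bg(6))
        r1 = SYNTH_TERMINASE_MOTIFS["R1"]
        self.feat("terminase_site", self.cur(), self.cur() + len(r1), ".",
                  label="R1", complete="true")
        self.add(r1)
        self.add(self.bg(6))
        self.dr_starts: list[int] = []
        # fixed spacer with zero identity to the R2 suffix (GTGCGGT), so only
        # the last repeat -- the planted R2 truncation -- resembles R2
        dr_spacer = "CACTAAC"
        for i in range(spec.n_direct_repeats - 1):
            self.dr_starts.append(self.cur())
            self.feat("direct_repeat", self.cur(), self.cur() + len(spec.dr_motif), ".",
                      label=f"D{i + 1}")
            self.add(spec.dr_motif)
            self.add_protected(dr_spacer)
        # last direct repeat doubles as the prefix of a truncated R2 site
        r2_trunc = SYNTH_TERMINASE_MOTIFS["R2"][:_R2_TRUNC_LEN]
        self.dr_starts.append(self.cur())
        self.feat("direct_repeat", self.cur(), self.cur() + len(spec.dr_motif), ".",
                  label=f"D{spec.n_direct_repeats}")
        self.feat("terminase_site", self.cur(), self.cur() + len(r2_trunc), ".",
                  label="R2", complete="false")
        self.add(r2_trunc)
        # fixed bases mismatching the R2 tail keep the site unambiguously truncated
        self.add_protected("CA")
        self.add(self.bg(4))
        r3 = SYNTH_TERMINASE_MOTIFS["R3"]
        self.feat("terminase_site", self.cur(), self.cur() + len(r3), ".",
                  label="R3", complete="true")
        self.add(r3)
        self.add(self.bg(2))
        self.add_protected("A")
        self.feat("inverted_repeat", self.cur(), self.cur() + len(arm), ".",
                  pair="IR1", arm="right")
        self.add(revcomp(arm))
        self.ir_left_arm = arm

    def add_orf(self, length: int, region: str, name: str) -> Feature:
        """Normal ORF: ATG + sense codons + TAA/TGA terminator."""
        assert length % 3 == 0 and length >= 9
        start = self.cur()
        term = "TAA" if self.rng.integers(2) == 0 else "TGA"
        self.add("ATG" + self.sense_codons(length // 3 - 2) + term)
        return self.feat("orf", start, self.cur(), "+", name=name, region=region)

    def add_mtp_tpex(self, region: str) -> None:
        """The mtp ORF ending CCC.TAG plus the +1-frame tpeX coding region."""
        start = self.cur()
        self.add("ATG" + self.sense_codons(_MTP_LEN // 3 - 3))
        self.add_protected("CCCTAG")
        mtp_end = self.cur()
        self.feat("orf", start, mtp_end, "+", name="mtp", region=region)
        self.mtp_coords = (start, mtp_end)
        # +1 frame anchors one nucleotide into the TAG; first fused codon is AG?
        tpex_start = mtp_end - 2
        self.add(self.bg(1))                       # completes the AG? codon
        # remaining post-shift sense codons, in the shifted frame
        self.add(self._shifted_sense(_POST_SHIFT_CODONS - 1))
        self.add_protected("TAA")
        self.feat("orf", tpex_start, self.cur(), "+", name="tpeX",
                  region=region, frameshift="+1")
        self.tpex_span = (tpex_start, self.cur())

    def _shifted_sense(self, n: int) -> str:
        out = []
        for _ in range(n):
            codon = self.bg(3)
            while codon in STOP_CODONS:
                codon = self.bg(3)
            out.append(codon)
        return "".join(out)

    def gap(self, total: int) -> None:
        """Intergenic background ending in a protected in-frame stop for the next ORF."""
        assert total >= 3
        self.add(self.bg(total - 3))
        self.add_protected("TAA")

    # -- main assembly ------------------------------------------------------

    def assemble(self) -> None:
        spec = self.spec
        rng = self.rng
        self.build_cos_block()
        n_late, n_early, n_mid = spec.region_plan
        mtp_idx = min(7, n_late - 1) if spec.shifty_stop else None

        mid_lens = [int(rng.integers(50, 101)) * 3 for _ in range(n_mid)]
        if n_mid >= 3:
            mid_lens[2] = 483          # the conserved Holliday-junction-resolvase mid-orf
        else:
            mid_lens[-1] = 483
        n_var = n_late + n_early - (1 if spec.shifty_stop else 0)
        gap_lens = [int(g) for g in rng.integers(30, 81, size=n_late + n_early + n_mid)]
        boundary = (400, 350)
        constructs = sum(amp for _, amp in spec.primer_sites) + 30 * len(spec.primer_sites)
        overhead = (self.cur() + sum(gap_lens) + sum(boundary) + sum(mid_lens)
                    + (_MTP_LEN + _POST_SHIFT_CODONS * 3 + 1 if spec.shifty_stop else 0)
                    + 80 + constructs + 60)
        budget = self.L - overhead
        if budget < n_var * 150:
            raise SpecError(
                f"genome length {self.L} cannot hold {sum(spec.region_plan)} ORFs "
                f"with the planted layout (need >= {overhead + n_var * 150} bp)"
            )
        raw = rng.integers(50, 281, size=n_var) * 3
        lens = np.clip((raw * (budget / raw.sum()) // 3).astype(int) * 3, 150, 1800)
        var_lens = [int(x) for x in lens]

        gi = iter(gap_lens)
        vi = iter(var_lens)
        region_bounds: dict[str, tuple[int, int]] = {}
        for label, count, bgap in (("late", n_late, None),
                                   ("early", n_early, boundary[0]),
                                   ("middle", n_mid, boundary[1])):
            first = None
            for k in range(count):
                if k == 0 and bgap is not None:
                    self.gap(bgap)
                else:
                    self.gap(next(gi))
                if first is None:
                    first = self.cur()
                if label == "late" and mtp_idx is not None and k == mtp_idx:
                    self.add_mtp_tpex(label)
                elif label == "middle":
                    self.add_orf(mid_lens[k], label, f"mid_orf{k + 1}")
                else:
                    self.add_orf(next(vi), label, f"{label}_orf{k + 1}")
            region_bounds[label] = (first, self.cur())
        self.region_bounds = region_bounds

        # tail: primer constructs then background fill to the target length
        self.add(self.bg(80))
        self.planted_amplicons: list[tuple[str, int, int]] = []
        for pname, amp in spec.primer_sites:
            pair = get_primer_pair(pname)
            p0 = self.cur()
            self.feat("primer_site", p0, p0 + len(pair.fwd), "+", pair=pname, role="fwd")
            self.add(pair.fwd)
            self.add(self.bg(amp - len(pair.fwd) - len(pair.rev)))
            self.feat("primer_site", self.cur(), self.cur() + len(pair.rev), "-",
                      pair=pname, role="rev")
            self.add(revcomp(pair.rev))
            self.planted_amplicons.append((pname, p0, amp))
            self.add(self.bg(30))
        fill = self.L - self.cur()
        if fill < 0:
            raise _Retry("layout overshot the genome length")
        self.add(self.bg(fill))
        for label, (s, e) in region_bounds.items():
            self.feat("region", s, e, ".", label=label)

    # -- masks and planting of restriction sites ----------------------------

    def _rebuild_masks(self) -> None:
        m = np.zeros(self.L, dtype=bool)
        for f in self.features:
            if f.kind != "region":
                m[f.start:f.end] = True
        for s, e in self.protected:
            m[s:e] = True
        self.immutable = m
        self.free = ~m

    def plant_enzyme_sites(self) -> None:
        spec = self.spec
        plan: dict[str, list[int]] = {}
        if spec.enzyme_sites is not None:
            for name, positions in spec.enzyme_sites.items():
                enz = DEFAULT_ENZYMES[name] if name in DEFAULT_ENZYMES else None
                if enz is None:
                    raise SpecError(f"enzyme_sites references unregistered enzyme {name!r}")
                plan[name] = sorted(int(p) for p in positions)
        else:
            for name in DEFAULT_ENZYMES:
                plan[name] = []
        self._rebuild_masks()
        taken = np.zeros(self.L, dtype=bool)
        self.enzyme_plan: dict[str, list[int]] = {}
        for name in plan:
            enz = DEFAULT_ENZYMES[name]
            w = len(enz.site)
            if spec.enzyme_sites is not None:
                positions = plan[name]
                for p in positions:
                    if p < 0 or p + w > self.L or taken[p:p + w].any() \
                            or any(self.immutable_hard(q) for q in range(p, p + w)):
                        raise SpecError(f"planted {name} site at {p} overlaps another element")
                    taken[p:p + w] = True
                    self._write_site(p, enz.site)
            else:
                n_sites = int(self.rng.integers(6, 13))
                ok = self.free & ~taken
                # positions where a full site fits in free, untaken background
                fit = np.flatnonzero(np.convolve(ok.astype(int), np.ones(w, dtype=int),
                                                 mode="valid") == w)
                positions = []
                for _ in range(n_sites):
                    fit = fit[(~taken[fit]).nonzero()]
                    cand = [p for p in fit if not taken[p:p + w].any()]
                    if not cand:
                        raise _Retry("no room left for restriction sites")
                    p = int(self.rng.choice(cand))
                    positions.append(p)
                    taken[max(0, p - w + 1):p + w] = True
                positions.sort()
            if spec.enzyme_sites is None:
                for p in positions:
                    self.buf[p:p + w] = enz.site.encode("ascii")
            for p in positions:
                self.feat("restriction_site", p, p + w, ".", enzyme=name)
            self.enzyme_plan[name] = positions
        self._rebuild_masks()

    def _write_site(self, p: int, site: str) -> None:
        """Overwrite a recognition site at p; explicit layouts may fall inside
        ORF interiors, so junction codons that become stops are repaired by
        changing a neighbouring base outside the site."""
        w = len(site)
        self.buf[p:p + w] = site.encode("ascii")
        for q in range(max(0, p - 2), min(self.L, p + w + 2)):
            if self._frames_ok(q):
                continue
            fixed = False
            for anchor, _lo, _hi in self._orf_frames_at(q):
                cstart = anchor + ((q - anchor) // 3) * 3
                if bytes(self.buf[cstart:cstart + 3]).decode() not in STOP_CODONS:
                    continue
                for r in range(cstart, cstart + 3):
                    if p <= r < p + w or self.immutable_hard(r):
                        continue
                    old = self.buf[r]
                    for bb in b"ACGT":
                        if bb == old:
                            continue
                        self.buf[r] = bb
                        if self._frames_ok(r) and self._frames_ok(q):
                            fixed = True
                            break
                    if fixed:
                        break
                    self.buf[r] = old
                if fixed:
                    break
            if not fixed:
                raise SpecError(
                    f"explicit restriction site at {p} cannot be planted without "
                    "breaking a planted reading frame"
                )

    # -- scrubbing ----------------------------------------------------------

    def _orf_frames_at(self, pos: int) -> list[tuple[int, int, int]]:
        """(anchor, sense_start, sense_end) of every planted coding frame covering pos."""
        out = []
        for f in self.features:
            if f.kind != "orf":
                continue
            if f.qualifiers.get("frameshift"):
                anchor, lo, hi = f.start, f.start, f.end - 3
            else:
                anchor, lo, hi = f.start, f.start, f.end - 3
            if lo <= pos < hi:
                out.append((anchor, lo, hi))
        return out

    def _mutate_in(self, lo: int, hi: int) -> bool:
        """Change one base in [lo, hi) to break a word, preferring free positions
        and otherwise keeping every governing reading frame sense."""
        positions = [p for p in range(max(0, lo), min(self.L, hi))]
        free_pos = [p for p in positions if self.free[p]]
        order = free_pos + [p for p in positions if not self.free[p] and not self.immutable_hard(p)]
        for p in order:
            old = self.buf[p]
            bases = [b for b in b"ACGT" if b != old]
            self.rng.shuffle(bases)
            for b in bases:
                self.buf[p] = b
                if self._frames_ok(p):
                    return True
            self.buf[p] = old
        return False

    def immutable_hard(self, p: int) -> bool:
        """True for positions that may never change: planted non-ORF elements and guards."""
        for s, e in self.protected:
            if s <= p < e:
                return True
        for f in self.features:
            if f.kind in ("cos", "inverted_repeat", "direct_repeat", "terminase_site",
                          "primer_site", "restriction_site") and f.start <= p < f.end:
                return True
            # an ORF's start and stop codons define its called coordinates
            if f.kind == "orf" and (f.start <= p < f.start + 3 or f.end - 3 <= p < f.end):
                return True
        return False

    def _frames_ok(self, p: int) -> bool:
        for anchor, lo, hi in self._orf_frames_at(p):
            cstart = anchor + ((p - anchor) // 3) * 3
            codon = bytes(self.buf[cstart:cstart + 3]).decode()
            if codon in STOP_CODONS:
                return False
        return True

    def _scrub_once(self) -> bool:
        changed = False
        s = self.buf.decode("ascii")
        spec = self.spec
        # 1. duplicate cos motifs (circular view)
        view = s + s[: len(spec.cos_motif) - 1]
        i = view.find(spec.cos_motif)
        while i != -1:
            if i < self.L and i != self.cos_pos:
                if not self._mutate_in(i, i + len(spec.cos_motif)):
                    raise _Retry("cannot remove duplicate cos motif")
                changed = True
                s = self.buf.decode("ascii")
                view = s + s[: len(spec.cos_motif) - 1]
                i = view.find(spec.cos_motif)
                continue
            i = view.find(spec.cos_motif, i + 1)
        # 2. unplanned restriction sites
        for name, planted in self.enzyme_plan.items():
            site = DEFAULT_ENZYMES[name].site
            pset = set(planted)
            i = s.find(site)
            while i != -1:
                if i not in pset:
                    if not self._mutate_in(i, i + len(site)):
                        raise _Retry(f"cannot remove stray {name} site")
                    changed = True
                    s = self.buf.decode("ascii")
                    i = s.find(site)
                    continue
                i = s.find(site, i + 1)
        # 3. stray direct-repeat words near cos
        lo = max(0, self.cos_pos - _COS_WINDOW)
        hi = min(self.L, self.cos_pos + len(spec.cos_motif) + _COS_WINDOW)
        drset = set(self.dr_starts)
        i = s.find(spec.dr_motif, lo)
        while i != -1 and i < hi:
            if i not in drset:
                if not self._mutate_in(i, i + len(spec.dr_motif)):
                    raise _Retry("cannot remove stray direct-repeat word near cos")
                changed = True
                s = self.buf.decode("ascii")
                i = s.find(spec.dr_motif, lo)
                continue
            i = s.find(spec.dr_motif, i + 1)
        # 4. coding-strand ORFs outside planted footprints
        planted_orfs = {(f.start, f.end) for f in self.features
                        if f.kind == "orf" and not f.qualifiers.get("frameshift")}
        for (cs, ce, _frame) in _scan_strand(s, 90, ("ATG", "GTG", "TTG")):
            if (cs, ce) in planted_orfs:
                continue
            slots = [p for p in range(cs, ce - 3, 3) if self.free[p:p + 3].all()]
            if not slots:
                continue  # fully buried in planted footprints; harmless
            p = slots[0]
            self.buf[p:p + 3] = b"TAA"
            # protect the stuffed stop so later fixes cannot undo it
            # (overlapping ORFs in other frames would otherwise oscillate)
            self.protected.append((p, p + 3))
            self._rebuild_masks()
            changed = True
            s = self.buf.decode("ascii")
        # 5. accidental shifty stops on called ORFs other than mtp
        mtp = getattr(self, "mtp_coords", None)
        for (cs, ce, _frame) in _scan_strand(s, 90, ("ATG", "GTG", "TTG")):
            if mtp is not None and (cs, ce) == mtp:
                continue
            if s[ce - 6:ce - 3] == "CCC" and s[ce - 3:ce] == "TAG":
                if self._mutate_in(ce - 6, ce - 3):
                    changed = True
                    s = self.buf.decode("ascii")
                elif self._mutate_in(ce - 3, ce):
                    changed = True
                    s = self.buf.decode("ascii")
                # else: buried and immutable; verification will decide
        return changed

    def scrub(self) -> None:
        for _ in range(20):
            if not self._scrub_once():
                return
        raise _Retry("scrubbing did not converge")

    def adjust_gc(self) -> None:
        target = self.spec.gc
        arr = np.frombuffer(bytes(self.buf), dtype=np.uint8)
        count = int(np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).sum())
        need = int(round(target * self.L)) - count
        if need == 0:
            return
        free_idx = np.flatnonzero(self.free)
        self.rng.shuffle(free_idx)
        gcb, atb = b"GC", b"AT"
        for p in free_idx:
            if need == 0:
                break
            b = self.buf[p]
            if need > 0 and b in atb:
                self.buf[p] = gcb[int(self.rng.integers(2))]
                need -= 1
            elif need < 0 and b in gcb:
                self.buf[p] = atb[int(self.rng.integers(2))]
                need += 1

    # -- verification -------------------------------------------------------

    def verify(self) -> PhageGenome:
        spec = self.spec
        s = self.buf.decode("ascii")
        genome = PhageGenome(self.gid, s, "linear_cos",
                             features=list(self.features),
                             provenance=f"synthetic 936-like genome, seed material {spec.seed}")
        gc_obs = (s.count("G") + s.count("C")) / len(s)
        if abs(gc_obs - spec.gc) > 0.0045:
            raise _Retry(f"realized GC {gc_obs:.4f} off target {spec.gc}")
        hits = find_cos_site(genome, motif=spec.cos_motif)
        if len(hits) != 1 or hits[0].cos_start != self.cos_pos:
            raise _Retry("cos site not unique at the planted position")
        cos = hits[0]
        ir_feats = [f for f in self.features if f.kind == "inverted_repeat"]
        left, right = ir_feats[0], ir_feats[1]
        import warnings as _warnings
        with _warnings.catch_warnings():
            # cos sits near position 0 by construction, so window clipping
            # at the genome start is expected here
            _warnings.filterwarnings("ignore", message=".*window clipped.*")
            pairs = find_inverted_repeats(genome, cos, arm_len=spec.ir_len)
        if not any(p.left_start == left.start and p.right_start == right.start
                   and p.mismatches == 0 for p in pairs):
            raise _Retry("planted inverted-repeat pair not recovered exactly")
        drs = find_direct_repeats(genome, cos, motif=spec.dr_motif)
        if [d.start for d in drs] != self.dr_starts:
            raise _Retry("direct repeats not recovered exactly")
        sites = {t.label: t for t in map_terminase_sites(
            genome, cos, SYNTH_TERMINASE_MOTIFS, drs=drs)}
        r_feats = {f.qualifiers["label"]: f for f in self.features
                   if f.kind == "terminase_site"}
        if not (sites["R1"].complete and sites["R1"].start == r_feats["R1"].start
                and sites["R3"].complete and sites["R3"].start == r_feats["R3"].start):
            raise _Retry("R1/R3 terminase sites not recovered")
        if sites["R2"].complete or f"D{spec.n_direct_repeats}" not in sites["R2"].overlapping_drs:
            raise _Retry("truncated R2/D-overlap relationship not reproduced")
        orfs = call_orfs(genome)
        called_plus = {(o.start, o.end) for o in orfs if o.strand == "+"}
        planted = [f for f in self.features
                   if f.kind == "orf" and not f.qualifiers.get("frameshift")]
        for f in planted:
            if (f.start, f.end) not in called_plus:
                raise _Retry(f"planted ORF [{f.start},{f.end}) not recovered")
        part = partition_regions(genome, orfs)
        by_coords = {(o.start, o.end): o for o in orfs if o.strand == "+"}
        for f in planted:
            if part.label_of(by_coords[(f.start, f.end)]) != f.qualifiers["region"]:
                raise _Retry("region partition disagrees with the plan")
        cands = find_shifty_stops(genome, orfs)
        if spec.shifty_stop:
            if len(cands) != 1 or (cands[0].upstream_orf.start,
                                   cands[0].upstream_orf.end) != self.mtp_coords:
                raise _Retry("shifty stop not unique at the planted mtp")
            fusion = simulate_frameshift(genome, cands[0])
            if fusion.fused_len != (_MTP_LEN - 3) // 3 + _POST_SHIFT_CODONS:
                raise _Retry("fused MTP-TpeX length off plan")
        elif cands:
            raise _Retry("unexpected shifty-stop candidate without a planted one")
        for pname, pair in DEFAULT_PRIMERS.items():
            amps = in_silico_pcr(genome, pair)
            expect = [(p0, amp) for nm, p0, amp in self.planted_amplicons if nm == pname]
            if sorted((a.fwd_pos, a.length) for a in amps) != sorted(expect):
                raise _Retry(f"PCR products for pair {pname} differ from the plan")
        for name, positions in self.enzyme_plan.items():
            site = DEFAULT_ENZYMES[name].site
            found = []
            i = s.find(site)
            while i != -1:
                found.append(i)
                i = s.find(site, i + 1)
            if found != positions:
                raise _Retry(f"{name} sites differ from the plan")
        return genome

    def truth(self, genome: PhageGenome) -> dict[str, object]:
        s = genome.seq
        return {
            "length": self.L,
            "gc_percent": round(100 * (s.count("G") + s.count("C")) / len(s), 1),
            "cos_start": self.cos_pos,
            "region_bounds": dict(self.region_bounds),
            "mtp": getattr(self, "mtp_coords", None),
            "fused_len": ((_MTP_LEN - 3) // 3 + _POST_SHIFT_CODONS
                          if self.spec.shifty_stop else None),
            "enzyme_sites": {k: list(v) for k, v in self.enzyme_plan.items()},
            "amplicons": list(self.planted_amplicons),
            "n_planted_orfs": sum(1 for f in self.features if f.kind == "orf"
                                  and not f.qualifiers.get("frameshift")),
        }


def _build(spec: GenomeSpec, seed: int, genome_id: str) -> tuple[PhageGenome, dict[str, object]]:
    b = _Builder(spec, seed, genome_id)
    b.assemble()
    b.plant_enzyme_sites()
    b.adjust_gc()
    for _round in range(4):
        b.scrub()
        arr = bytes(b.buf)
        gc_obs = (arr.count(b"G") + arr.count(b"C")) / len(arr)
        if abs(gc_obs - spec.gc) <= 0.0005:
            break
        b.adjust_gc()
    genome = b.verify()
    return genome, b.truth(genome)


def generate_genome(spec: GenomeSpec | None = None,
                    genome_id: str | None = None) -> tuple[PhageGenome, TruthSet]:
    """Generate one 936-like genome and its ground truth.

    Deterministic in ``spec.seed``: the same spec yields byte-identical
    output.  Raises :class:`~phagechar.errors.GenerationError` when the
    planted layout cannot be realized.
    """
    spec = spec or GenomeSpec()
    _validate_spec(spec)
    gid = genome_id or f"synth_s{spec.seed}"
    master = np.random.default_rng(spec.seed)
    last = None
    for _attempt in range(_MAX_ATTEMPTS):
        sub = int(master.integers(0, 2 ** 31))
        try:
            genome, scalars = _build(spec, sub, gid)
        except _Retry as err:
            last = err
            continue
        truth = TruthSet(features={gid: list(genome.features)}, scalars={gid: scalars})
        return genome, truth
    raise GenerationError(f"genome generation failed after {_MAX_ATTEMPTS} attempts: {last}")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _mutate_copy(seq: str, rng: np.random.Generator, n_mut: int,
                 allowed: np.ndarray, avoid_words: list[str]) -> tuple[str, list[int]]:
    """Apply n_mut SNVs at allowed positions, rejecting changes that create a
    new occurrence of any word in ``avoid_words``."""
    buf = bytearray(seq.encode("ascii"))
    idx = np.flatnonzero(allowed)
    if idx.size == 0 or n_mut == 0:
        return seq, []
    chosen = rng.choice(idx, size=min(n_mut, idx.size), replace=False)
    snvs = []
    for p in sorted(int(x) for x in chosen):
        old = buf[p]
        bases = [b for b in b"ACGT" if b != old]
        rng.shuffle(bases)
        placed = False
        for b in bases:
            buf[p] = b
            lo = max(0, p - 11)
            window = bytes(buf[lo:p + 12]).decode()
            before = seq[lo:p + 12]
            if any(window.count(w) > before.count(w) for w in avoid_words):
                continue
            placed = True
            break
        if not placed:
            buf[p] = old
            continue
        snvs.append(p)
    return buf.decode("ascii"), snvs


def generate_cohort(
    n: int,
    n_archetypes: int,
    snv_rate: float,
    seed: int,
    base_spec: GenomeSpec | None = None,
    footprint_masking: bool = True,
    group_threshold: float = 0.1,
) -> tuple[list[PhageGenome], TruthSet]:
    """A cohort of ``n`` genomes descending from ``n_archetypes`` archetypes.

    Archetypes are independently generated genomes whose EcoRV
    dissociated-mode band patterns are verified to be pairwise more distant
    than ``group_threshold`` (regenerating up to 100 attempts otherwise), so
    the restriction-archetype structure is reliable under a fixed seed.
    Each cohort genome is a copy of its archetype carrying SNVs that, by
    default, avoid planted feature footprints; the archetype label and SNV
    positions are recorded as truth.
    """
    if not (n >= n_archetypes >= 1):
        raise SpecError("need n >= n_archetypes >= 1")
    master = np.random.default_rng(seed)
    spec0 = base_spec or GenomeSpec()
    ecorv = DEFAULT_ENZYMES["EcoRV"]
    archetypes: list[PhageGenome] = []
    arch_patterns = []
    attempts = 0
    while len(archetypes) < n_archetypes:
        attempts += 1
        if attempts > 100:
            raise GenerationError("could not realize pairwise-distinct archetypes in 100 attempts")
        aseed = int(master.integers(0, 2 ** 31))
        spec = dataclasses.replace(spec0, seed=aseed, enzyme_sites=None)
        g, _ = generate_genome(spec, genome_id=f"arch{len(archetypes) + 1}")
        pat = digest(g, ecorv, "dissociated")
        if all(pattern_distance(pat, p) > group_threshold for p in arch_patterns):
            archetypes.append(g)
            arch_patterns.append(pat)
    labels = list(range(n_archetypes))
    labels += [int(master.integers(0, n_archetypes)) for _ in range(n - n_archetypes)]
    avoid = [spec0.cos_motif] + [e.site for e in DEFAULT_ENZYMES.values()]
    masks = []
    for g in archetypes:
        m = np.ones(len(g), dtype=bool)
        if footprint_masking:
            for f in g.features:
                if f.kind != "region":
                    m[f.start:f.end] = False
        masks.append(m)
    genomes: list[PhageGenome] = []
    truth = TruthSet()
    for i, a in enumerate(labels):
        arch = archetypes[a]
        n_mut = int(master.binomial(len(arch), snv_rate))
        seq, snvs = _mutate_copy(arch.seq, master, n_mut, masks[a], avoid)
        gid = f"phage_{i + 1:03d}"
        genomes.append(PhageGenome(gid, seq, "linear_cos",
                                   features=[dataclasses.replace(f, qualifiers=dict(f.qualifiers))
                                             for f in arch.features],
                                   provenance=f"cohort member of archetype A{a + 1}"))
        truth.features[gid] = genomes[-1].features
        truth.scalars[gid] = {"archetype": f"A{a + 1}", "snv_positions": snvs}
    return genomes, truth


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    params: GrowthParams,
    n0: float = 1e5,
    dt: float = 3.0,
    t_max: float = 45.0,
    noise_sd: float = 0.05,
    seed: int = 1,
) -> GrowthCurve:
    """One-step growth PFU(t) series for the given generating parameters.

    Titer stays at ``n0`` before the latent period, rises log-linearly to
    ``n0 * burst_size`` between latent period and burst time, and plateaus
    afterwards; multiplicative lognormal noise (natural-log sd ``noise_sd``)
    is applied pointwise.  Samples are taken every ``dt`` minutes from 0,
    matching the assay's 3-min sampling.
    """
    if n0 <= 0:
        raise ValueError("initial infected-cell count must be positive")
    if not (params.latent_min < params.burst_time_min <= t_max):
        raise ValueError("require latent < burst_time <= t_max")
    times = np.arange(0.0, t_max + dt / 2, dt)
    frac = np.clip((times - params.latent_min)
                   / (params.burst_time_min - params.latent_min), 0.0, 1.0)
    titers = n0 * params.burst_size ** frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        titers = titers * rng.lognormal(0.0, noise_sd, size=times.size)
    return GrowthCurve(times=times, titers=titers, n0=n0)
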