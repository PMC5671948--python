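"""Circular genome model: coordinates, restriction digestion, amplicons, FASTA/BED I/O.

Coordinate convention used throughout the package
-------------------------------------------------
Positions are **1-based**; intervals are **end-exclusive**, so an interval
``(start, end)`` has length ``end - start``.  This is the convention under
which every targeted-amplicon design table row satisfies
``amplicon size == end - start`` (e.g. a D-loop amplicon at 6-298 is 292 bp).
On circular genomes ``end`` may exceed the genome length, meaning the
interval wraps across the sequence origin.

BED input (0-based, half-open) is converted on read:
``start_1based = bed_start + 1``, ``end_1based_exclusive = bed_end + 1``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "CircularGenome",
    "GenomicInterval",
    "RestrictionEnzyme",
    "DigestProduct",
    "BAMHI",
    "BGLII",
    "reverse_complement",
    "circular_subseq",
    "find_sites",
    "digest",
    "extract_amplicon",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

HEAVY = "+"   # heavy strand, reported as '+'
LIGHT = "-"   # light strand, reported as '-'


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """A reference sequence with explicit topology.

    Parameters
    ----------
    name
        Sequence identifier (FASTA header word).
    sequence
        Uppercase DNA over ``{A, C, G, T, N}``.
    is_circular
        Whether coordinate accessors may wrap across the origin.
    """

    name: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        seq = self.sequence.upper()
        if set(seq) - _VALID_BASES:
            bad = sorted(set(seq) - _VALID_BASES)
            raise ValueError(f"invalid bases in genome sequence: {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at 1-based ``position``; wraps when circular."""
        L = len(self.sequence)
        if self.is_circular:
            return self.sequence[(position - 1) % L]
        if not 1 <= position <= L:
            raise IndexError(f"position {position} outside linear genome of length {L}")
        return self.sequence[position - 1]

    def rotated(self, offset: int) -> "CircularGenome":
        """Genome with the sequence origin shifted by ``offset`` bases (circular only)."""
        if not self.is_circular:
            raise ValueError("cannot rotate a linear genome")
        L = len(self.sequence)
        k = offset % L
        return CircularGenome(self.name, self.sequence[k:] + self.sequence[:k], True)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, end-exclusive interval; length == end - start.

    ``end`` may exceed the genome length on circular genomes (wrap-around).
    Strand ``'+'`` is the heavy/top strand, ``'-'`` the light/bottom strand.
    """

    start: int
    end: int
    strand: str = HEAVY
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval {self.start}-{self.end}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.strand not in (HEAVY, LIGHT):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def positions(self, genome_length: int) -> list[int]:
        """1-based genome positions covered, reduced modulo the genome length."""
        return [((p - 1) % genome_length) + 1 for p in range(self.start, self.end)]

    def contains(self, position: int, genome_length: int) -> bool:
        """Whether 1-based ``position`` falls in the (possibly wrapped) interval."""
        p = (position - 1) % genome_length
        s = (self.start - 1) % genome_length
        e = s + self.length
        return s <= p < e or s <= p + genome_length < e


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease with a non-degenerate recognition site.

    ``cut_offset`` is the 0-based offset of the cut within the recognition
    sequence on the forward strand (G^GATCC -> offset 1).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if len(rec) < 4:
            raise ValueError("recognition sequence must be >= 4 bp")
        if set(rec) - set("ACGT"):
            raise ValueError(
                f"degenerate or invalid recognition bases not supported: {rec}"
            )
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError("cut_offset outside recognition site")
        object.__setattr__(self, "recognition", rec)


#: The enzyme used to linearize human mtDNA (single GGATCC site).
BAMHI = RestrictionEnzyme("BamHI", "GGATCC", 1)
#: Its murine counterpart (AGATCT).
BGLII = RestrictionEnzyme("BglII", "AGATCT", 1)


@dataclass(frozen=True)
class DigestProduct:
    """Result of an in-silico complete digest."""

    fragments: tuple[str, ...]
    site_positions: tuple[int, ...]
    was_linearized: bool

    @property
    def total_length(self) -> int:
        return sum(len(f) for f in self.fragments)


def find_sites(genome: CircularGenome, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based start positions of every recognition-site occurrence.

    Scanning is on the forward strand only (the sites of interest here are
    palindromic).  On circular genomes the scan crosses the origin: a site
    whose start lies in ``[1, L]`` but whose body wraps is reported at its
    start.  ``N`` never matches.  Positions are sorted ascending and each
    site is reported once.
    """
    rec = enzyme.recognition
    seq = genome.sequence
    L = len(seq)
    haystack = seq + seq[: len(rec) - 1] if genome.is_circular else seq
    sites = []
    start = haystack.find(rec)
    while start != -1:
        if start < L:
            sites.append(start + 1)
        start = haystack.find(rec, start + 1)
    return sites


def digest(genome: CircularGenome, enzyme: RestrictionEnzyme) -> DigestProduct:
    """Complete digestion; fragment boundaries at site start + cut_offset.

    A circular genome with ``k >= 1`` sites yields exactly ``k`` linear
    fragments (one full-length fragment when ``k == 1``); zero sites leave
    the molecule unchanged.  A linear genome with ``k`` internal cuts yields
    ``k + 1`` fragments.  Fragment lengths always sum to the genome length.
    """
    sites = find_sites(genome, enzyme)
    seq = genome.sequence
    L = len(seq)
    if not sites:
        return DigestProduct((seq,), (), False)
    # 0-based cut coordinates
    cuts = sorted(((s - 1 + enzyme.cut_offset) % L) for s in sites)
    frags: list[str] = []
    if genome.is_circular:
        doubled = seq + seq
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            end = nxt if nxt > c else nxt + L
            frags.append(doubled[c:end])
    else:
        bounds = [0] + cuts + [L]
        frags = [seq[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    return DigestProduct(tuple(frags), tuple(sites), True)


def circular_subseq(
    genome: CircularGenome, start: int, length: int, strand: str = HEAVY
) -> str:
    """Subsequence of ``length`` bases from 1-based ``start``.

    Wraps across the origin when the genome is circular; raises for
    out-of-range requests on linear genomes and for ``length`` exceeding the
    genome length.  Light-strand requests return the reverse complement.
    """
    L = len(genome.sequence)
    if length > L:
        raise ValueError(f"requested {length} bp from a {L} bp genome")
    if length < 1:
        raise ValueError("length must be >= 1")
    s0 = start - 1
    if genome.is_circular:
        s0 %= L
        out = (genome.sequence + genome.sequence)[s0 : s0 + length]
    else:
        if s0 < 0 or s0 + length > L:
            raise IndexError(
                f"interval {start}-{start + length} outside linear genome of length {L}"
            )
        out = genome.sequence[s0 : s0 + length]
    return reverse_complement(out) if strand == LIGHT else out


def extract_amplicon(genome: CircularGenome, interval: GenomicInterval) -> str:
    """Sequence of an amplicon interval; light-strand designs are reverse-complemented."""
    L = len(genome.sequence)
    if interval.start > L:
        raise IndexError(f"start {interval.start} beyond genome length {L}")
    if interval.end > L + 1 and not genome.is_circular:
        raise IndexError("interval wraps but genome is linear")
    return circular_subseq(genome, interval.start, interval.length, interval.strand)


# ---------------------------------------------------------------------------
# FASTA / BED I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, is_circular: bool = True) -> list[CircularGenome]:
    """Read a (multi-)FASTA into :class:`CircularGenome` records.

    Input may be wrapped and lower-case; sequences are canonicalised to
    uppercase.  The topology flag is supplied by the caller because FASTA
    carries no topology information.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(CircularGenome(rec.id, str(rec.seq).upper(), is_circular))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(genomes: Sequence[CircularGenome] | CircularGenome, path: str | Path,
                width: int = 70) -> None:
    if isinstance(genomes, CircularGenome):
        genomes = [genomes]
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into the package's 1-based end-exclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            start0, end0 = int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else HEAVY
            out.append(GenomicInterval(start0 + 1, end0 + 1, strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              chrom: str = "chrM") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{chrom}\t{iv.start - 1}\t{iv.end - 1}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )
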