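"""Desk-scale bisulfite read processing: trimming, three-letter alignment,
deduplication, and per-cytosine methylation calling.

The aligner is a deliberately small re-implementation of the standard
three-letter strategy used by production bisulfite mappers: the read and
reference are compared after collapsing C->T (for reads deriving from the
original top strand or its PCR complement) or G->A (original bottom strand
and complement), so that bisulfite conversion never counts as a mismatch.
Candidate loci are found by exact seeding with collapsed k-mers and verified
by full Hamming comparison; a read is reported only when its best locus
beats the runner-up by at least one mismatch (unique best hit).  It is
restricted to small references (<= ~1 Mb total) — mitochondrial genomes and
nuclear decoys — and directs users to external mappers beyond that.

Methylation calling follows the per-cytosine report convention: one row per
reference cytosine on each strand (including uncovered ones), with
methylated (C) and unmethylated (T) call counts, context (CpG/CHG/CHH) and
the reference trinucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bisulfite import ReadPair
from .genome import HEAVY, LIGHT, CircularGenome, reverse_complement

__all__ = [
    "Alignment",
    "AlignedPair",
    "CytosineRecord",
    "BisulfiteAligner",
    "align_bisulfite",
    "trim_heads",
    "deduplicate",
    "call_methylation",
    "classify_context",
    "records_to_dataframe",
    "write_cytosine_report",
    "read_cytosine_report",
    "write_sam",
]

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")

MIN_READ_LEN_AFTER_TRIM = 20
MAX_REFERENCE_LENGTH = 1_000_000


@dataclass(frozen=True)
class Alignment:
    """A verified unique-best placement of one read."""

    reference: str
    start: int            # 1-based
    end: int              # exclusive; may exceed reference length (wrap)
    mapped_strand: str    # '+' read matches collapsed reference forward
    bisulfite_strand: str  # OT / OB / CTOT / CTOB space of the match
    mismatches: int
    unique: bool
    read_name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("alignment end must exceed start")


@dataclass(frozen=True)
class AlignedPair:
    """A concordant read pair with its fragment-level coordinates."""

    aln1: Alignment
    aln2: Alignment
    read1: str
    read2: str
    name: str
    fragment_start: int
    fragment_end: int

    @property
    def reference(self) -> str:
        return self.aln1.reference

    @property
    def bisulfite_strand(self) -> str:
        return self.aln1.bisulfite_strand

    @property
    def mismatches(self) -> int:
        return self.aln1.mismatches + self.aln2.mismatches


@dataclass
class CytosineRecord:
    """Per-cytosine methylation call (the CX cytosine-report row)."""

    reference: str
    position: int   # 1-based
    strand: str     # '+' top-strand C, '-' bottom-strand C (a G on top)
    count_methylated: int
    count_unmethylated: int
    context: str        # CpG / CHG / CHH
    trinucleotide: str

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def methylation_percent(self) -> float:
        """100 * C / (C + T); NaN when uncovered."""
        cov = self.coverage
        if cov == 0:
            return float("nan")
        return 100.0 * self.count_methylated / cov


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim_heads(pairs: Sequence[ReadPair], n_head: int) -> list[ReadPair]:
    """Remove the first ``n_head`` bases (and qualities) from each mate.

    Head-trimming removes the primer/fill-in positional bias at read starts.
    A pair is dropped when either trimmed mate falls below the 20 bp floor
    (i.e. the original mate was shorter than ``n_head + 20``).
    """
    if n_head < 0:
        raise ValueError("n_head must be >= 0")
    if n_head == 0:
        return list(pairs)
    out = []
    for p in pairs:
        r1, r2 = p.read1[n_head:], p.read2[n_head:]
        if len(r1) < MIN_READ_LEN_AFTER_TRIM or len(r2) < MIN_READ_LEN_AFTER_TRIM:
            continue
        out.append(
            ReadPair(
                p.name, r1, r2, p.qual1[n_head:], p.qual2[n_head:],
                p.bisulfite_strand, p.truth_start, p.truth_end, p.truth_topology,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Mini three-letter aligner
# ---------------------------------------------------------------------------

class _Reference:
    def __init__(self, genome: CircularGenome, extension: int):
        self.name = genome.name
        self.length = len(genome)
        self.is_circular = genome.is_circular
        ext = min(extension, self.length - 1) if genome.is_circular else 0
        seq_ext = genome.sequence + genome.sequence[:ext]
        self.ct = np.frombuffer(seq_ext.translate(_CT).encode(), dtype="S1")
        self.ga = np.frombuffer(seq_ext.translate(_GA).encode(), dtype="S1")
        self.ext_length = len(seq_ext)


# mate space expected for read2 given read1's space
_MATE_SPACE = {"OT": "CTOT", "CTOT": "OT", "OB": "CTOB", "CTOB": "OB"}
# spaces in which the read string itself matches the collapsed forward reference
_FORWARD_SPACES = ("OT", "CTOB")


class BisulfiteAligner:
    """Seed-and-verify three-letter aligner for small references.

    Parameters
    ----------
    references
        Genomes to index (total length <= 1 Mb).
    max_mismatches
        Maximum Hamming mismatches in collapsed space (default 5).
    seed_k
        Exact-seed k-mer length (default 20).  Up to five seeds are spread
        along each read, so loci are found whenever any seed-sized stretch
        is error-free (guaranteed for <= 4 mismatches with reads >= 100 bp).
    max_insert
        Maximum fragment span for a concordant pair.
    """

    def __init__(
        self,
        references: Sequence[CircularGenome] | CircularGenome,
        max_mismatches: int = 5,
        seed_k: int = 20,
        max_insert: int = 1200,
        extension: int = 600,
    ):
        if isinstance(references, CircularGenome):
            references = [references]
        total = sum(len(g) for g in references)
        if total > MAX_REFERENCE_LENGTH:
            raise ValueError(
                f"total reference length {total} exceeds the mini-aligner limit "
                f"({MAX_REFERENCE_LENGTH} bp); use a production bisulfite mapper "
                "for large genomes"
            )
        self.max_mismatches = max_mismatches
        self.seed_k = seed_k
        self.max_insert = max_insert
        self.refs = [_Reference(g, extension) for g in references]
        self._index_ct: dict[bytes, list[tuple[int, int]]] = {}
        self._index_ga: dict[bytes, list[tuple[int, int]]] = {}
        for ri, ref in enumerate(self.refs):
            ct = ref.ct.tobytes()
            ga = ref.ga.tobytes()
            n_starts = ref.length if ref.is_circular else ref.length - seed_k + 1
            for p in range(max(0, n_starts)):
                self._index_ct.setdefault(ct[p : p + seed_k], []).append((ri, p))
                self._index_ga.setdefault(ga[p : p + seed_k], []).append((ri, p))

    # -- candidate generation ------------------------------------------------

    def _spaces(self, read: str) -> list[tuple[str, str, str]]:
        rc = reverse_complement(read)
        return [
            ("OT", read.translate(_CT), "ct"),
            ("CTOT", rc.translate(_CT), "ct"),
            ("OB", rc.translate(_GA), "ga"),
            ("CTOB", read.translate(_GA), "ga"),
        ]

    def _candidates(self, query: bytes, index: dict) -> set[tuple[int, int]]:
        k = self.seed_k
        m = len(query)
        n_seeds = min(5, max(1, m // k))
        offsets = sorted({round(i * (m - k) / max(1, n_seeds - 1)) for i in range(n_seeds)})
        cands: set[tuple[int, int]] = set()
        for off in offsets:
            for ri, p in index.get(query[off : off + k], ()):
                start = p - off
                ref = self.refs[ri]
                if ref.is_circular:
                    cands.add((ri, start % ref.length))
                elif 0 <= start <= ref.length - m:
                    cands.add((ri, start))
        return cands

    def _verify(self, query: np.ndarray, ri: int, start: int, which: str) -> int | None:
        ref = self.refs[ri]
        m = len(query)
        if start + m > ref.ext_length:
            return None  # wrap beyond indexed extension (read longer than extension)
        arr = ref.ct if which == "ct" else ref.ga
        return int(np.count_nonzero(arr[start : start + m] != query))

    # -- public API ----------------------------------------------------------

    def align_read(self, read: str, name: str = "") -> Alignment | None:
        """Best unique placement of a single read, or ``None`` if unmapped.

        All four bisulfite spaces are searched; the best hit must beat every
        other candidate (across spaces and loci) by at least one mismatch.
        """
        if len(read) < self.seed_k:
            return None
        hits: list[tuple[int, int, int, str]] = []  # (mm, ri, start, space)
        seen: set[tuple[str, int, int]] = set()
        for space, collapsed, which in self._spaces(read):
            q = collapsed.encode()
            qarr = np.frombuffer(q, dtype="S1")
            for ri, start in self._candidates(q, self._index_ct if which == "ct" else self._index_ga):
                key = (space, ri, start)
                if key in seen:
                    continue
                seen.add(key)
                mm = self._verify(qarr, ri, start, which)
                if mm is not None and mm <= self.max_mismatches:
                    hits.append((mm, ri, start, space))
        if not hits:
            return None
        hits.sort(key=lambda h: h[0])
        best = hits[0]
        if len(hits) > 1 and hits[1][0] <= best[0]:
            return None  # ambiguous: no unique best hit with margin >= 1
        mm, ri, start, space = best
        ref = self.refs[ri]
        return Alignment(
            reference=ref.name,
            start=start + 1,
            end=start + 1 + len(read),
            mapped_strand=HEAVY if space in _FORWARD_SPACES else LIGHT,
            bisulfite_strand=space,
            mismatches=mm,
            unique=True,
            read_name=name,
        )

    def align_pair(self, pair: ReadPair) -> AlignedPair | None:
        """Concordant unique alignment of a read pair, or ``None``.

        Mates must map uniquely to the same reference in complementary
        bisulfite spaces (OT<->CTOT, OB<->CTOB) within the insert limit.
        """
        a1 = self.align_read(pair.read1, pair.name)
        if a1 is None:
            return None
        a2 = self.align_read(pair.read2, pair.name)
        if a2 is None:
            return None
        if a1.reference != a2.reference:
            return None
        if a2.bisulfite_strand != _MATE_SPACE[a1.bisulfite_strand]:
            return None
        ref = next(r for r in self.refs if r.name == a1.reference)
        s1, s2 = a1.start, a2.start
        best_shift = 0
        if ref.is_circular:
            # choose the representation of mate2 minimising the fragment span
            spans = []
            for shift in (-ref.length, 0, ref.length):
                lo = min(s1, s2 + shift)
                hi = max(a1.end, a2.end + shift)
                spans.append((hi - lo, shift))
            span, best_shift = min(spans)
        s2 += best_shift
        frag_start = min(s1, s2)
        frag_end = max(a1.end, a2.end + best_shift)
        if frag_end - frag_start > self.max_insert:
            return None
        if best_shift:
            a2 = Alignment(
                a2.reference, s2, s2 + (a2.end - a2.start), a2.mapped_strand,
                a2.bisulfite_strand, a2.mismatches, a2.unique, a2.read_name,
            )
        return AlignedPair(
            a1, a2, pair.read1, pair.read2, pair.name, frag_start, frag_end
        )

    def align_pairs(self, pairs: Iterable[ReadPair]) -> list[AlignedPair]:
        out = []
        for p in pairs:
            ap = self.align_pair(p)
            if ap is not None:
                out.append(ap)
        return out


def align_bisulfite(
    read_pair: ReadPair,
    references: Sequence[CircularGenome] | CircularGenome,
    max_mismatches: int = 5,
) -> AlignedPair | None:
    """One-shot convenience wrapper around :class:`BisulfiteAligner`."""
    return BisulfiteAligner(references, max_mismatches).align_pair(read_pair)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def deduplicate(pairs: Sequence[AlignedPair]) -> list[AlignedPair]:
    """Keep one representative per (reference, fragment start/end, mapped
    strand, bisulfite strand) key — the presumed-PCR-duplicate rule.

    Applied to shotgun (whole-genome) libraries only; amplicon libraries are
    expected to stack reads and are never deduplicated.  Idempotent.
    """
    seen = set()
    out = []
    for p in pairs:
        key = (
            p.reference, p.fragment_start, p.fragment_end,
            p.aln1.mapped_strand, p.bisulfite_strand,
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Context classification
# ---------------------------------------------------------------------------

def classify_context(
    genome: CircularGenome, position: int, strand: str
) -> tuple[str, str]:
    """(context, trinucleotide) of the cytosine at 1-based ``position``.

    The two bases immediately downstream *on the cytosine's strand* decide
    the class: CG. -> CpG, C-H-G -> CHG, otherwise CHH (H = A/C/T).  On
    circular genomes the lookup wraps; at linear ends missing bases are
    recorded as N in the trinucleotide and classified as CHH.
    """
    L = len(genome)
    seq = genome.sequence

    def base_at(i: int) -> str:  # 0-based with topology handling
        if genome.is_circular:
            return seq[i % L]
        return seq[i] if 0 <= i < L else "N"

    i = position - 1
    if strand == HEAVY:
        if base_at(i) != "C":
            raise ValueError(f"position {position}+ is not a cytosine")
        b1, b2 = base_at(i + 1), base_at(i + 2)
    elif strand == LIGHT:
        if base_at(i) != "G":
            raise ValueError(f"position {position}- is not a cytosine")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        b1, b2 = comp[base_at(i - 1)], comp[base_at(i - 2)]
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if b1 == "G":
        ctx = "CpG"
    elif b2 == "G":
        ctx = "CHG"
    else:
        ctx = "CHH"
    return ctx, "C" + b1 + b2


# ---------------------------------------------------------------------------
# Methylation calling
# ---------------------------------------------------------------------------

def call_methylation(
    pairs: Sequence[AlignedPair], genome: CircularGenome
) -> list[CytosineRecord]:
    """Per-cytosine C/T call counts over every reference cytosine.

    Reads whose bisulfite space derives from the original top strand
    (OT/CTOT) interrogate top-strand cytosines; OB/CTOB reads interrogate
    bottom-strand cytosines (reference G positions).  At a cytosine column,
    a read base matching C is a methylated call and T an unmethylated call;
    any other base (sequencing error) is ignored.  Where the two mates of a
    pair overlap, only read 1 is counted.  Records are emitted for all
    cytosines, covered or not.
    """
    L = len(genome)
    ref_arr = np.frombuffer(genome.sequence.encode(), dtype="S1")
    meth = np.zeros((2, L), dtype=np.int64)
    unmeth = np.zeros((2, L), dtype=np.int64)

    for p in pairs:
        if p.reference != genome.name:
            continue
        r1_start0 = p.aln1.start - 1
        r1_len = p.aln1.end - p.aln1.start
        for mate_idx, (aln, read) in enumerate(((p.aln1, p.read1), (p.aln2, p.read2))):
            oriented = (
                read if aln.bisulfite_strand in _FORWARD_SPACES
                else reverse_complement(read)
            )
            m = len(oriented)
            pos0 = (aln.start - 1 + np.arange(m)) % L
            bases = np.frombuffer(oriented.encode(), dtype="S1")
            keep = np.ones(m, dtype=bool)
            if mate_idx == 1:
                keep = ((pos0 - r1_start0) % L) >= r1_len  # skip mate overlap
            row = 0 if aln.bisulfite_strand in ("OT", "CTOT") else 1
            if row == 0:
                at_c = (ref_arr[pos0] == b"C") & keep
                np.add.at(meth[0], pos0[at_c & (bases == b"C")], 1)
                np.add.at(unmeth[0], pos0[at_c & (bases == b"T")], 1)
            else:
                at_c = (ref_arr[pos0] == b"G") & keep
                np.add.at(meth[1], pos0[at_c & (bases == b"G")], 1)
                np.add.at(unmeth[1], pos0[at_c & (bases == b"A")], 1)

    records: list[CytosineRecord] = []
    for row, strand, base in ((0, HEAVY, b"C"), (1, LIGHT, b"G")):
        for i in np.flatnonzero(ref_arr == base):
            ctx, tri = classify_context(genome, int(i) + 1, strand)
            records.append(
                CytosineRecord(
                    genome.name, int(i) + 1, strand,
                    int(meth[row, i]), int(unmeth[row, i]), ctx, tri,
                )
            )
    records.sort(key=lambda r: (r.position, r.strand))
    return records


# ---------------------------------------------------------------------------
# Cytosine report and SAM I/O
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "chrom", "position", "strand", "count_methylated", "count_unmethylated",
    "context", "trinucleotide",
]


def records_to_dataframe(records: Sequence[CytosineRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (r.reference, r.position, r.strand, r.count_methylated,
             r.count_unmethylated, r.context, r.trinucleotide)
            for r in records
        ],
        columns=_REPORT_COLUMNS,
    )
    cov = df["count_methylated"] + df["count_unmethylated"]
    df["coverage"] = cov
    df["methylation_percent"] = np.where(
        cov > 0, 100.0 * df["count_methylated"] / cov.replace(0, 1), np.nan
    )
    return df


def write_cytosine_report(
    records: Sequence[CytosineRecord], path: str | Path
) -> None:
    """Write the tab-separated CX cytosine report (no header, Bismark column order)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.reference}\t{r.position}\t{r.strand}\t{r.count_methylated}"
                f"\t{r.count_unmethylated}\t{r.context}\t{r.trinucleotide}\n"
            )


def read_cytosine_report(path: str | Path) -> list[CytosineRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, strand, cm, cu, ctx, tri = line.rstrip("\n").split("\t")
            out.append(
                CytosineRecord(chrom, int(pos), strand, int(cm), int(cu), ctx, tri)
            )
    return out


def write_sam(
    pairs: Sequence[AlignedPair],
    genome: CircularGenome,
    path: str | Path,
) -> None:
    """Minimal SAM export of aligned pairs (mapped records only).

    Wrapped (origin-spanning) alignments are reported at their modular start
    with a soft-clip-free CIGAR; this export exists for interoperability and
    inspection, not as the primary output.
    """
    L = len(genome)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{genome.name}\tLN:{L}\n")
        fh.write("@PG\tID:mtartifact\tPN:mtartifact\n")
        for p in pairs:
            for mate_idx, (aln, read, qualflag) in enumerate(
                ((p.aln1, p.read1, 0x40), (p.aln2, p.read2, 0x80))
            ):
                flag = 0x1 | 0x2 | qualflag
                if aln.mapped_strand == LIGHT:
                    flag |= 0x10
                mate = p.aln2 if mate_idx == 0 else p.aln1
                if mate.mapped_strand == LIGHT:
                    flag |= 0x20
                pos = (aln.start - 1) % L + 1
                mpos = (mate.start - 1) % L + 1
                tlen = p.fragment_end - p.fragment_start
                if mate_idx == 1:
                    tlen = -tlen
                seq = read if aln.mapped_strand == HEAVY else reverse_complement(read)
                fh.write(
                    f"{p.name}\t{flag}\t{genome.name}\t{pos}\t42\t{len(read)}M\t=\t"
                    f"{mpos}\t{tlen}\t{seq}\t{'F' * len(read)}\t"
                    f"NM:i:{aln.mismatches}\tXB:Z:{aln.bisulfite_strand}\n"
                )
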