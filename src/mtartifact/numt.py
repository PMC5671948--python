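"""NUMT contamination screening and in-silico PCR primer specificity.

NUMTs — nuclear insertions of mitochondrial sequence — are the standard
alternative explanation for apparent mtDNA methylation: nuclear DNA is
methylated, contaminates mitochondrial preps, and (if its reads mapped to
the mitochondrial reference) would masquerade as mtDNA methylation.  The
screen bounds this risk exhaustively: every possible fixed-length read from
every NUMT copy, in both fully-methylated (unconverted) and unmethylated
(fully converted) states and from both strands, is aligned against the
combined mitochondrial + nuclear reference with the pipeline's
unique-best-hit rule.  The pass condition is that *zero* such reads are
uniquely assigned to the mitochondrial genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .align import BisulfiteAligner
from .genome import CircularGenome, circular_subseq, reverse_complement
from .simulate import NUMTRecord

__all__ = [
    "ScreenReport",
    "enumerate_numt_reads",
    "screen",
    "insilico_pcr",
    "write_screen_report",
]

_CT = str.maketrans("C", "T")


@dataclass
class ScreenReport:
    """Outcome of the exhaustive NUMT read-enumeration screen."""

    total_reads: int
    aligned_to_mt: int
    aligned_to_nuclear: int
    unmapped_or_ambiguous: int
    per_numt: pd.DataFrame

    @property
    def passed(self) -> bool:
        """True when no enumerated NUMT read was assigned to the mt genome."""
        return self.aligned_to_mt == 0

    def __post_init__(self) -> None:
        total = self.aligned_to_mt + self.aligned_to_nuclear + self.unmapped_or_ambiguous
        if total != self.total_reads:
            raise ValueError("screen category counts do not sum to total")


def enumerate_numt_reads(
    numt_sequence: str,
    read_len: int = 300,
    states: Sequence[str] = ("methylated", "unmethylated"),
    strands: Sequence[str] = ("top", "bottom"),
) -> list[tuple[str, str]]:
    """All possible fixed-length reads from a NUMT copy.

    One read per start offset (step 1) per strand per state:
    ``max(0, L - read_len + 1) * len(strands) * len(states)`` reads in
    total.  The *methylated* state leaves the sequence intact (every
    cytosine resisted conversion — the worst case for confusability with
    unconverted mtDNA); the *unmethylated* state applies complete bisulfite
    conversion (every C of the read's strand becomes T).

    Returns (label, sequence) tuples; labels encode offset/strand/state.
    """
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    L = len(numt_sequence)
    out: list[tuple[str, str]] = []
    templates = {}
    if "top" in strands:
        templates["top"] = numt_sequence
    if "bottom" in strands:
        templates["bottom"] = reverse_complement(numt_sequence)
    for strand, template in templates.items():
        for state in states:
            src = template.translate(_CT) if state == "unmethylated" else template
            for off in range(max(0, L - read_len + 1)):
                out.append((f"{off}:{strand}:{state}", src[off : off + read_len]))
    return out


def screen(
    numts: Sequence[NUMTRecord],
    mt_genome: CircularGenome,
    nuclear_genome: CircularGenome,
    read_len: int = 300,
    max_mismatches: int = 5,
) -> ScreenReport:
    """Exhaustively realign all possible NUMT reads against mt + nuclear.

    Each NUMT's sequence is taken from its position on the nuclear decoy,
    enumerated into reads (both strands, both methylation states), and
    aligned single-end against the concatenated reference set.  Reads are
    tallied as uniquely mt-assigned, uniquely nuclear-assigned, or
    unmapped/ambiguous (multi-hit reads fail the unique-best-hit rule and
    are never assigned).  Deterministic: no randomness anywhere.
    """
    aligner = BisulfiteAligner([mt_genome, nuclear_genome], max_mismatches)
    rows = []
    tot = mt_hits = nuc_hits = other = 0
    for numt in numts:
        seq = circular_subseq(
            nuclear_genome, numt.nuclear_position.start,
            numt.nuclear_position.length,
        )
        reads = enumerate_numt_reads(seq, read_len)
        n_mt = n_nuc = n_other = 0
        for label, read in reads:
            aln = aligner.align_read(read, f"{numt.name}:{label}")
            if aln is None:
                n_other += 1
            elif aln.reference == mt_genome.name:
                n_mt += 1
            else:
                n_nuc += 1
        rows.append(
            {
                "numt": numt.name,
                "length": numt.length,
                "divergence": numt.divergence,
                "alignment_score": numt.alignment_score,
                "reads": len(reads),
                "aligned_to_mt": n_mt,
                "aligned_to_nuclear": n_nuc,
                "unmapped_or_ambiguous": n_other,
            }
        )
        tot += len(reads)
        mt_hits += n_mt
        nuc_hits += n_nuc
        other += n_other
    per_numt = pd.DataFrame(rows)
    return ScreenReport(tot, mt_hits, nuc_hits, other, per_numt)


def write_screen_report(report: ScreenReport, path: str | Path) -> None:
    report.per_numt.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _hamming_hits(template: str, probe: str, max_mm: int) -> list[int]:
    """0-based start offsets where probe matches template with <= max_mm mismatches."""
    out = []
    m = len(probe)
    if max_mm == 0:
        start = template.find(probe)
        while start != -1:
            out.append(start)
            start = template.find(probe, start + 1)
        return out
    for start in range(len(template) - m + 1):
        mm = 0
        window = template[start : start + m]
        for a, b in zip(window, probe):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            out.append(start)
    return out


def insilico_pcr(
    primer_fwd: str,
    primer_rev: str,
    genome: CircularGenome,
    converted: bool = True,
    max_mismatches: int = 0,
    max_product_length: int = 2000,
) -> list[tuple[str, int, int]]:
    """Predict PCR products of a primer pair on a (bisulfite-converted) genome.

    When ``converted`` is set, the template set is the four first-round PCR
    strands of the fully converted genome (original top/bottom and their
    complements) — the sequences a bisulfite primer can actually anneal to.
    Unconverted mode uses the plain top and bottom strands.  A product is
    reported wherever the forward primer and the reverse complement of the
    reverse primer hybridise convergently on one template within
    ``max_product_length``.

    Returns ``(template_label, genome_start_1based, product_length)``
    tuples, where the genome start refers to the top-strand coordinate of
    the product's lowest base.
    """
    for primer in (primer_fwd, primer_rev):
        if len(primer) < 15:
            raise ValueError("primers must be >= 15 nt")
    seq = genome.sequence
    L = len(seq)
    if converted:
        ot = seq.translate(_CT)
        ob = reverse_complement(seq).translate(_CT)
        templates = {
            "OT": ot,
            "OB": ob,
            "CTOT": reverse_complement(ot),
            "CTOB": reverse_complement(ob),
        }
        # string index -> genome 0-based position of that base
        forward_coords = {"OT": True, "CTOB": True, "OB": False, "CTOT": False}
    else:
        templates = {"top": seq, "bottom": reverse_complement(seq)}
        forward_coords = {"top": True, "bottom": False}

    rev_rc = reverse_complement(primer_rev)
    products = []
    for label, template in templates.items():
        ext = min(max_product_length, L - 1) if genome.is_circular else 0
        t = template + template[:ext]
        fwd_hits = [h for h in _hamming_hits(t, primer_fwd, max_mismatches) if h < L]
        rev_hits = _hamming_hits(t, rev_rc, max_mismatches)
        for f in fwd_hits:
            for r in rev_hits:
                end = r + len(rev_rc)
                if end <= f:
                    continue
                length = end - f
                if length > max_product_length:
                    continue
                if forward_coords[label]:
                    gstart = f % L
                else:
                    gstart = (L - end) % L if end <= L else (2 * L - end) % L
                products.append((label, gstart + 1, length))
    return sorted(set(products))
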