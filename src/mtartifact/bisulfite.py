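"""Fragmentation, in-silico bisulfite conversion, and paired-end read generation.

The physics being emulated
--------------------------
Sonication fragments each genome copy; a fragment that overlaps a protected
window of a *supercoiled* parent is recovered only with probability ``rho``
(shear protection).  Bisulfite then deaminates unmethylated cytosines to
uracil (sequenced as T) on each strand independently; a cytosine inside an
active protected window escapes conversion with elevated probability
``epsilon_prot`` instead of the baseline ``epsilon_0`` (structural blocking
of the reagent).  Both couplings — release and conversion — can be switched
off independently to study either mechanism in isolation.

Reads carry their ground truth (source interval, bisulfite strand, parent
topology) in a colon-separated name tag so that downstream mapping can be
scored; the aligner never looks at the tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import HEAVY, CircularGenome, GenomicInterval, reverse_complement
from .simulate import MethylomeTruth, MoleculeInstance

__all__ = [
    "ConversionModel",
    "Fragment",
    "ReadPair",
    "fragment_population",
    "bisulfite_convert",
    "generate_reads",
    "write_fastq_pairs",
    "read_fastq",
    "parse_truth_tag",
]

BS_STRANDS = ("OT", "OB", "CTOT", "CTOB")

DEFAULT_QUALITY_CHAR = "F"  # constant Phred 37


@dataclass(frozen=True)
class ConversionModel:
    """Bisulfite conversion error model.

    epsilon_0
        Probability an unmethylated, unprotected cytosine escapes conversion
        (read as C: the background false-methylation rate).
    epsilon_prot
        The same for a cytosine inside an active protected window; must be
        >= epsilon_0.
    delta
        Over-conversion: probability a truly methylated cytosine is
        nevertheless read as T.
    """

    epsilon_0: float = 0.005
    epsilon_prot: float = 0.30
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon_0 <= self.epsilon_prot <= 1.0:
            raise ValueError("need 0 <= epsilon_0 <= epsilon_prot <= 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0,1]")


@dataclass(frozen=True)
class Fragment:
    """A double-stranded sonication fragment.

    ``start`` is 1-based on the genome; ``end`` is exclusive and may exceed
    the genome length (origin-spanning fragment from a circular parent).
    """

    start: int
    end: int
    molecule_index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadPair:
    name: str
    read1: str
    read2: str
    qual1: str
    qual2: str
    bisulfite_strand: str
    truth_start: int
    truth_end: int
    truth_topology: str


def fragment_population(
    molecules: Sequence[MoleculeInstance],
    genome: CircularGenome,
    mean_len: float,
    sd_len: float,
    rho: float,
    target_fragment_count: int,
    seed: int | None = None,
    min_len: int = 50,
    read_len_hint: int | None = None,
    release_coupling: bool = True,
) -> list[Fragment]:
    """Sonicate a molecule population into fragments.

    Candidate fragments are drawn with a uniformly random start on a
    uniformly chosen parent molecule and a normal length truncated at
    ``min_len`` (50 bp).  A candidate overlapping any active protected
    window of its parent is retained with probability ``rho`` (only when
    ``release_coupling`` is on).  Drawing continues until
    ``target_fragment_count`` fragments are retained.  Circular parents may
    produce origin-spanning fragments; linear (digested) parents never span
    their cut point.
    """
    if target_fragment_count <= 0:
        raise ValueError("target_fragment_count must be positive")
    if read_len_hint is not None and mean_len < 2 * read_len_hint:
        warnings.warn(
            f"mean fragment length {mean_len} < 2x read length {read_len_hint}; "
            "mates will overlap heavily",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    L = len(genome)
    n_mol = len(molecules)
    out: list[Fragment] = []
    max_draws = 100 * target_fragment_count
    draws = 0
    batch = max(1024, target_fragment_count)
    while len(out) < target_fragment_count and draws < max_draws:
        idx = rng.integers(n_mol, size=batch)
        lens = np.clip(
            np.rint(rng.normal(mean_len, sd_len, size=batch)).astype(int), min_len, L
        )
        u = rng.random(batch)
        keep_u = rng.random(batch)
        for i in range(batch):
            draws += 1
            mol = molecules[idx[i]]
            flen = int(lens[i])
            if mol.digested or mol.topology == "linear":
                # offset within the linearised molecule, mapped to genome coords
                off = int(u[i] * (L - flen + 1))
                start = (mol.linear_origin - 1 + off) % L + 1
            else:
                start = int(u[i] * L) + 1
            frag = Fragment(start, start + flen, int(idx[i]))
            if release_coupling and rho < 1.0 and _overlaps_protected(frag, mol, L):
                if keep_u[i] >= rho:
                    continue
            out.append(frag)
            if len(out) >= target_fragment_count:
                break
    return out


def _overlaps_protected(frag: Fragment, mol: MoleculeInstance, L: int) -> bool:
    if not mol.active_protected_windows:
        return False
    for iv in mol.active_protected_windows:
        s = (iv.start - 1) % L
        e = s + iv.length
        f = (frag.start - 1) % L
        g = f + frag.length
        # compare on the circle: shift fragment by 0 and ±L
        for shift in (-L, 0, L):
            if f + shift < e and g + shift > s:
                return True
    return False


def _protection_flags(
    frag: Fragment, mol: MoleculeInstance, L: int
) -> np.ndarray:
    """Boolean per-base vector: position under an active protected window."""
    flags = np.zeros(frag.length, dtype=bool)
    if not mol.active_protected_windows:
        return flags
    pos0 = (np.arange(frag.start - 1, frag.end - 1)) % L  # 0-based genome pos
    for iv in mol.active_protected_windows:
        s = (iv.start - 1) % L
        e = s + iv.length
        if e <= L:
            flags |= (pos0 >= s) & (pos0 < e)
        else:  # window wraps
            flags |= (pos0 >= s) | (pos0 < e - L)
    return flags


def bisulfite_convert(
    sequence: str,
    meth_top: np.ndarray,
    meth_bottom: np.ndarray,
    protected: np.ndarray,
    model: ConversionModel,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, str]:
    """Convert one double-stranded fragment.

    Parameters
    ----------
    sequence
        Top-strand fragment sequence (5'->3').
    meth_top, meth_bottom
        Per-base true methylation probabilities for the cytosines of the top
        strand (``C`` positions of ``sequence``) and of the bottom strand
        (``G`` positions of ``sequence``); entries at other positions are
        ignored.
    protected
        Per-base flags marking positions under an active protected window.

    Returns
    -------
    (top, bottom)
        The converted top strand (5'->3', genome orientation) and the
        converted bottom strand (5'->3', i.e. reverse-complement
        orientation).  Only C (top) and G-complement C (bottom) positions
        can change; A/T and sequence length are untouched.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n = len(sequence)
    if not (len(meth_top) == len(meth_bottom) == len(protected) == n):
        raise ValueError("state/flag vectors must match sequence length")
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    eps = np.where(protected, model.epsilon_prot, model.epsilon_0)

    top = arr.copy()
    c_idx = np.flatnonzero(arr == b"C")
    if c_idx.size:
        methylated = rng.random(c_idx.size) < np.asarray(meth_top)[c_idx]
        stays_c = np.where(
            methylated,
            rng.random(c_idx.size) >= model.delta,
            rng.random(c_idx.size) < eps[c_idx],
        )
        top[c_idx[~stays_c]] = b"T"

    # bottom strand: its cytosines sit opposite top-strand Gs
    g_idx = np.flatnonzero(arr == b"G")
    bottom = np.frombuffer(
        reverse_complement(sequence).encode(), dtype="S1"
    ).copy()
    if g_idx.size:
        methylated = rng.random(g_idx.size) < np.asarray(meth_bottom)[g_idx]
        stays_c = np.where(
            methylated,
            rng.random(g_idx.size) >= model.delta,
            rng.random(g_idx.size) < eps[g_idx],
        )
        converted = g_idx[~stays_c]
        bottom[n - 1 - converted] = b"T"
    return top.tobytes().decode(), bottom.tobytes().decode()


def _methylome_slices(
    methylome: MethylomeTruth, frag: Fragment, L: int
) -> tuple[np.ndarray, np.ndarray]:
    pos0 = np.arange(frag.start - 1, frag.end - 1) % L
    return methylome.levels[0, pos0], methylome.levels[1, pos0]


def generate_reads(
    fragments: Sequence[Fragment],
    molecules: Sequence[MoleculeInstance],
    genome: CircularGenome,
    methylome: MethylomeTruth,
    model: ConversionModel,
    read_len: int = 150,
    directional: bool = True,
    seed: int | None = None,
    conversion_coupling: bool = True,
    error_rate: float = 0.0,
    duplicate_fraction: float = 0.0,
    quality_char: str = DEFAULT_QUALITY_CHAR,
    forced_bs_strand: str | None = None,
) -> list[ReadPair]:
    """Convert fragments and sequence them as paired-end reads.

    Directional libraries sequence the two original bisulfite strands
    (OT/OB, 50:50); non-directional (post-bisulfite random-primed) libraries
    additionally emit their PCR complements (CTOT/CTOB) at 25% each.  Read 1
    is the 5' end of the selected strand, read 2 the reverse complement of
    its 3' end; fragments shorter than ``read_len`` yield truncated reads.

    ``conversion_coupling=False`` ignores protection during conversion
    (every cytosine sees the baseline failure rate).  ``error_rate`` adds
    uniform substitution sequencing error; ``duplicate_fraction`` appends
    exact copies of already-emitted pairs (for deduplication testing).
    """
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    if forced_bs_strand is not None and forced_bs_strand not in BS_STRANDS:
        raise ValueError(f"forced_bs_strand must be one of {BS_STRANDS}")
    rng = np.random.default_rng(seed)
    L = len(genome)
    strand_choices = BS_STRANDS if not directional else BS_STRANDS[:2]
    pairs: list[ReadPair] = []
    for i, frag in enumerate(fragments):
        mol = molecules[frag.molecule_index]
        seq = (genome.sequence * 2)[frag.start - 1 : frag.end - 1] if frag.end - 1 > L \
            else genome.sequence[frag.start - 1 : frag.end - 1]
        m_top, m_bot = _methylome_slices(methylome, frag, L)
        prot = (
            _protection_flags(frag, mol, L)
            if conversion_coupling
            else np.zeros(frag.length, dtype=bool)
        )
        top_c, bottom_c = bisulfite_convert(seq, m_top, m_bot, prot, model, rng)
        bs = forced_bs_strand or strand_choices[rng.integers(len(strand_choices))]
        if bs == "OT":
            strand_seq = top_c
        elif bs == "OB":
            strand_seq = bottom_c
        elif bs == "CTOT":
            strand_seq = reverse_complement(top_c)
        else:  # CTOB
            strand_seq = reverse_complement(bottom_c)
        n = min(read_len, frag.length)
        r1 = strand_seq[:n]
        r2 = reverse_complement(strand_seq)[:n]
        if error_rate > 0.0:
            r1 = _add_errors(r1, error_rate, rng)
            r2 = _add_errors(r2, error_rate, rng)
        name = f"frag{i}:{frag.start}:{frag.end}:{bs}:{mol.topology}"
        pairs.append(
            ReadPair(
                name, r1, r2, quality_char * len(r1), quality_char * len(r2),
                bs, frag.start, frag.end, mol.topology,
            )
        )
    if duplicate_fraction > 0.0 and pairs:
        n_dup = int(round(duplicate_fraction * len(pairs)))
        for j, k in enumerate(rng.integers(len(pairs), size=n_dup)):
            src = pairs[k]
            pairs.append(
                ReadPair(
                    src.name.replace("frag", f"dup{j}_frag", 1),
                    src.read1, src.read2, src.qual1, src.qual2,
                    src.bisulfite_strand, src.truth_start, src.truth_end,
                    src.truth_topology,
                )
            )
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    bases = np.array([b"A", b"C", b"G", b"T"])
    for h in hits:
        alts = bases[bases != arr[h]]
        arr[h] = alts[rng.integers(len(alts))]
    return arr.tobytes().decode()


def parse_truth_tag(name: str) -> dict:
    """Decode the colon-separated truth tag written into read names."""
    frag_id, start, end, bs, topo = name.split(":")
    return {
        "fragment": frag_id,
        "start": int(start),
        "end": int(end),
        "bisulfite_strand": bs,
        "topology": topo,
    }


# ---------------------------------------------------------------------------
# FASTQ I/O (plain 4-line, Phred+33)
# ---------------------------------------------------------------------------

def write_fastq_pairs(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.read1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.read2}\n+\n{p.qual2}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a FASTQ file into (name, sequence, quality) tuples."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            out.append((header[1:], seq, qual))
    return out
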