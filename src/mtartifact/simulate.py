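"""Synthetic inputs with known ground truth.

Everything the downstream analysis consumes can be generated here: an
mtDNA-like circular genome, a true methylome (all-zero by default, since the
working conclusion is that the mitochondrial genome carries essentially no
cytosine methylation), a population of genome copies with mixed topology,
and a nuclear decoy sequence carrying planted NUMTs (nuclear insertions of
mitochondrial sequence).

The topology model is the causal variable of the artifact under study: a
*supercoiled* genome copy carries "protected" windows in which cytosines
both resist bisulfite conversion and resist sonication release.  Linear and
open-circular copies behave identically (unprotected); only supercoiling
changes conversion and release behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genome import (
    HEAVY,
    LIGHT,
    CircularGenome,
    GenomicInterval,
    circular_subseq,
    reverse_complement,
)

__all__ = [
    "MethylomeTruth",
    "TopologyModel",
    "MoleculeInstance",
    "NUMTRecord",
    "generate_genome",
    "make_mtdna_like_genome",
    "generate_methylome",
    "make_population",
    "plant_numts",
    "write_methylome",
    "read_methylome",
    "write_numt_table",
    "read_numt_table",
    "write_population_table",
]

_BASES = np.array(list("ACGT"))

Topology = Literal["linear", "open_circular", "supercoiled"]


# ---------------------------------------------------------------------------
# Genome and methylome generation
# ---------------------------------------------------------------------------

def generate_genome(
    length: int, gc_fraction: float = 0.44, seed: int | None = None,
    name: str = "chrM", is_circular: bool = True,
) -> CircularGenome:
    """Random genome with the requested GC content in expectation.

    Reproducible under a fixed seed; base probabilities are
    (1-gc)/2, gc/2, gc/2, (1-gc)/2 over A, C, G, T.
    """
    if length < 100:
        raise ValueError("genome length must be >= 100")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0,1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    seq = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return CircularGenome(name, "".join(seq), is_circular)


def make_mtdna_like_genome(
    length: int = 16569,
    gc_fraction: float = 0.44,
    seed: int | None = None,
    site: str = "GGATCC",
    site_position: int = 14258,
    name: str = "chrM",
) -> CircularGenome:
    """Synthetic mtDNA-like genome carrying exactly one restriction site.

    This is a synthetic stand-in for the human mitochondrial reference: a
    random circular sequence in which every spurious occurrence of ``site``
    is broken and a single copy is planted at ``site_position`` (1-based),
    mimicking the unique BamHI site used to linearize human mtDNA.
    """
    g = generate_genome(length, gc_fraction, seed, name=name, is_circular=True)
    seq = list(g.sequence)
    # break spurious sites (scan doubled for wrap), then plant the real one
    doubled = "".join(seq) * 2
    k = len(site)
    pos = doubled.find(site)
    while pos != -1 and pos < length:
        seq[pos % length] = "A" if seq[pos % length] != "A" else "T"
        doubled = "".join(seq) * 2
        pos = doubled.find(site)
    for i, b in enumerate(site):
        seq[(site_position - 1 + i) % length] = b
    return CircularGenome(name, "".join(seq), True)


@dataclass
class MethylomeTruth:
    """Per-cytosine, per-strand true methylation probabilities.

    ``levels`` has shape (2, L): row 0 is the heavy/+ strand (C positions of
    the forward sequence), row 1 the light/- strand (G positions of the
    forward sequence).  Entries at non-cytosine positions are 0 and carry no
    meaning; ``defined`` masks true cytosine positions.
    """

    genome_name: str
    levels: np.ndarray
    defined: np.ndarray

    def prob(self, position: int, strand: str) -> float:
        """Methylation probability at 1-based ``position`` on ``strand``."""
        row = 0 if strand == HEAVY else 1
        if not self.defined[row, position - 1]:
            raise ValueError(f"position {position}{strand} is not a cytosine")
        return float(self.levels[row, position - 1])

    @property
    def n_cytosines(self) -> int:
        return int(self.defined.sum())


def _cytosine_mask(genome: CircularGenome) -> np.ndarray:
    arr = np.frombuffer(genome.sequence.encode(), dtype="S1")
    return np.stack([arr == b"C", arr == b"G"])


def generate_methylome(
    genome: CircularGenome,
    mode: str = "all_zero",
    p: float = 0.0,
    site_list: Sequence[tuple[int, str, float]] | None = None,
    seed: int | None = None,
) -> MethylomeTruth:
    """True methylome for a genome.

    Modes
    -----
    ``all_zero``
        Every cytosine has probability 0 (the default working truth: the
        mitochondrial genome is unmethylated, and any apparent signal is
        artifactual).
    ``uniform``
        Every cytosine has constant probability ``p``.
    ``site_list``
        Zero everywhere except the listed ``(position, strand, probability)``
        entries; listing a non-cytosine position is an error.
    """
    mask = _cytosine_mask(genome)
    levels = np.zeros_like(mask, dtype=float)
    if mode == "all_zero":
        pass
    elif mode == "uniform":
        if not 0.0 <= p <= 1.0:
            raise ValueError("uniform methylation probability must be in [0,1]")
        levels[mask] = p
    elif mode == "site_list":
        for pos, strand, prob in site_list or []:
            row = 0 if strand == HEAVY else 1
            if not mask[row, pos - 1]:
                raise ValueError(
                    f"site {pos}{strand} is not a cytosine on that strand"
                )
            if not 0.0 <= prob <= 1.0:
                raise ValueError("site probability must be in [0,1]")
            levels[row, pos - 1] = prob
    else:
        raise ValueError(f"unknown methylome mode {mode!r}")
    return MethylomeTruth(genome.name, levels, mask)


# ---------------------------------------------------------------------------
# Topology / molecule population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyModel:
    """Latent topology parameters of a genome-copy population.

    supercoiled_fraction
        Probability that a copy is supercoiled (vs unprotected).
    protected_windows
        Genome intervals that are inaccessible on supercoiled copies.  The
        default is a single window over the start of the genome, the analog
        of the structured control region (D-loop) where regulatory proteins
        bend the duplex.
    epsilon_prot
        Conversion-failure probability for cytosines inside an active
        protected window (must be >= the baseline failure of the conversion
        model in use).
    rho
        Release penalty: probability that a sonication fragment overlapping
        an active protected window is recovered at all (1 = no penalty).
    """

    supercoiled_fraction: float = 0.5
    protected_windows: tuple[GenomicInterval, ...] = (
        GenomicInterval(1, 701, HEAVY, "control_region"),
    )
    epsilon_prot: float = 0.30
    rho: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.supercoiled_fraction <= 1.0:
            raise ValueError("supercoiled_fraction must be in [0,1]")
        if not 0.0 <= self.epsilon_prot <= 1.0:
            raise ValueError("epsilon_prot must be in [0,1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0,1]")
        object.__setattr__(self, "protected_windows", tuple(self.protected_windows))


@dataclass(frozen=True)
class MoleculeInstance:
    """One genome copy: its topology and the windows it actually protects."""

    topology: Topology
    active_protected_windows: tuple[GenomicInterval, ...] = ()
    digested: bool = False
    # 1-based genome coordinate where a linear molecule starts (cut point)
    linear_origin: int = 1

    def __post_init__(self) -> None:
        if self.digested and (
            self.topology != "linear" or self.active_protected_windows
        ):
            raise ValueError("digested molecules are linear and unprotected")


def make_population(
    genome: CircularGenome,
    n_copies: int,
    topology_model: TopologyModel,
    digested: bool = False,
    seed: int | None = None,
    cut_position: int = 1,
) -> list[MoleculeInstance]:
    """Draw a population of genome copies.

    Undigested copies are supercoiled with probability
    ``supercoiled_fraction`` (carrying the model's protected windows) and
    open-circular otherwise.  ``digested=True`` forces every copy linear,
    opened at ``cut_position``, with all protection removed — the in-silico
    analog of complete restriction digestion before conversion.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if digested:
        return [
            MoleculeInstance("linear", (), True, cut_position)
            for _ in range(n_copies)
        ]
    rng = np.random.default_rng(seed)
    supercoiled = rng.random(n_copies) < topology_model.supercoiled_fraction
    return [
        MoleculeInstance("supercoiled", topology_model.protected_windows)
        if s
        else MoleculeInstance("open_circular")
        for s in supercoiled
    ]


# ---------------------------------------------------------------------------
# NUMT planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NUMTRecord:
    """A nuclear-mitochondrial segment planted in (or annotated on) a decoy genome."""

    name: str
    nuclear_position: GenomicInterval
    mt_origin: GenomicInterval
    length: int
    divergence: float
    n_substitutions: int
    alignment_score: int

    @property
    def identity(self) -> float:
        return 1.0 - self.n_substitutions / self.length


def plant_numts(
    mt_genome: CircularGenome,
    nuclear_length: int,
    numt_specs: Sequence[tuple[GenomicInterval, float]],
    seed: int | None = None,
    gc_fraction: float = 0.41,
    nuclear_name: str = "nuc_decoy",
) -> tuple[CircularGenome, list[NUMTRecord]]:
    """Build a nuclear decoy genome carrying diverged copies of mt segments.

    Each spec ``(mt_origin, divergence)`` copies the mt segment into the
    decoy with independent per-base substitutions at rate ``divergence``
    (substituted bases are always different from the original).  Placements
    are evenly spaced with flanking gaps; overlapping placements (segments
    that do not fit) raise.  The alignment score is the +1/-1
    match/mismatch score over the planted span: ``length - 2 * mismatches``.
    The mitochondrial genome itself is never modified.
    """
    rng = np.random.default_rng(seed)
    decoy = generate_genome(
        nuclear_length, gc_fraction, seed=rng.integers(2**31),
        name=nuclear_name, is_circular=False,
    )
    total = sum(iv.length for iv, _ in numt_specs)
    n = len(numt_specs)
    gap = (nuclear_length - total) // (n + 1) if n else 0
    if n and (total > nuclear_length or gap < 1):
        raise ValueError("NUMT specs overlap or do not fit in the nuclear decoy")
    seq = list(decoy.sequence)
    records: list[NUMTRecord] = []
    cursor = gap
    for i, (mt_iv, div) in enumerate(numt_specs):
        if not 0.0 <= div <= 1.0:
            raise ValueError("divergence must be in [0,1]")
        segment = circular_subseq(mt_genome, mt_iv.start, mt_iv.length, mt_iv.strand)
        mutated = list(segment)
        hits = np.flatnonzero(rng.random(len(segment)) < div)
        for j in hits:
            alts = [b for b in "ACGT" if b != mutated[j]]
            mutated[j] = alts[rng.integers(3)]
        nuc_iv = GenomicInterval(cursor + 1, cursor + 1 + mt_iv.length, HEAVY,
                                 f"numt{i}")
        seq[cursor : cursor + mt_iv.length] = mutated
        records.append(
            NUMTRecord(
                name=f"numt{i}",
                nuclear_position=nuc_iv,
                mt_origin=mt_iv,
                length=mt_iv.length,
                divergence=div,
                n_substitutions=int(len(hits)),
                alignment_score=mt_iv.length - 2 * int(len(hits)),
            )
        )
        cursor += mt_iv.length + gap
    nuclear = CircularGenome(nuclear_name, "".join(seq), False)
    return nuclear, records


# ---------------------------------------------------------------------------
# Tabular I/O (all round-trip tested)
# ---------------------------------------------------------------------------

def write_methylome(methylome: MethylomeTruth, path: str | Path) -> None:
    rows, cols = np.nonzero(methylome.defined)
    df = pd.DataFrame(
        {
            "chrom": methylome.genome_name,
            "position": cols + 1,
            "strand": np.where(rows == 0, HEAVY, LIGHT),
            "probability": methylome.levels[rows, cols],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_methylome(path: str | Path, genome: CircularGenome) -> MethylomeTruth:
    df = pd.read_csv(path, sep="\t")
    truth = generate_methylome(genome, "all_zero")
    rows = (df["strand"] == LIGHT).astype(int).to_numpy()
    truth.levels[rows, df["position"].to_numpy() - 1] = df["probability"].to_numpy()
    return truth


def write_numt_table(records: Iterable[NUMTRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "name": r.name,
                "nuclear_start": r.nuclear_position.start,
                "nuclear_end": r.nuclear_position.end,
                "mt_start": r.mt_origin.start,
                "mt_end": r.mt_origin.end,
                "mt_strand": r.mt_origin.strand,
                "length": r.length,
                "divergence": r.divergence,
                "n_substitutions": r.n_substitutions,
                "alignment_score": r.alignment_score,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_numt_table(path: str | Path) -> list[NUMTRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        NUMTRecord(
            name=str(r["name"]),
            nuclear_position=GenomicInterval(
                int(r["nuclear_start"]), int(r["nuclear_end"]), HEAVY, str(r["name"])
            ),
            mt_origin=GenomicInterval(
                int(r["mt_start"]), int(r["mt_end"]), str(r["mt_strand"])
            ),
            length=int(r["length"]),
            divergence=float(r["divergence"]),
            n_substitutions=int(r["n_substitutions"]),
            alignment_score=int(r["alignment_score"]),
        )
        for r in df.to_dict("records")
    ]


def write_population_table(
    molecules: Sequence[MoleculeInstance], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "molecule": i,
                "topology": m.topology,
                "digested": m.digested,
                "protected_windows": ";".join(
                    f"{iv.start}-{iv.end}" for iv in m.active_protected_windows
                ),
            }
            for i, m in enumerate(molecules)
        ]
    )
    df.to_csv(path, sep="\t", index=False)
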