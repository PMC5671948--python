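"""Orchestration of the two in-silico experiments.

* **Shotgun (WMGBS) experiment** — simulate a topology-mixed population of
  circular genome copies, sonicate, convert, sequence, head-trim 10 bp,
  align, deduplicate, call methylation, and compute the depth-methylation
  correlation.  The computational analog of discovering that apparent
  methylation concentrates where coverage dips.
* **Targeted digested-vs-undigested experiment** — amplicon bisulfite
  sequencing of designed regions in two arms (intact circular population vs
  completely digested, linearised population), head-trim 2 bp, align, call
  (no deduplication), then per-region min-max summaries and paired sign
  tests with Bonferroni correction over the region family.

Both runs are deterministic given a seed, write machine-readable manifests,
and log per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .align import (
    AlignedPair,
    BisulfiteAligner,
    CytosineRecord,
    call_methylation,
    deduplicate,
    trim_heads,
    write_cytosine_report,
)
from .bisulfite import (
    ConversionModel,
    Fragment,
    ReadPair,
    fragment_population,
    generate_reads,
    write_fastq_pairs,
)
from .diagnostics import (
    CorrelationResult,
    RegionSummary,
    SignTestResult,
    depth_methylation_correlation,
    region_summary,
    sign_test,
)
from .genome import (
    BAMHI,
    BGLII,
    HEAVY,
    LIGHT,
    CircularGenome,
    GenomicInterval,
    RestrictionEnzyme,
    digest,
    find_sites,
    write_fasta,
)
from .simulate import (
    MethylomeTruth,
    TopologyModel,
    generate_methylome,
    make_mtdna_like_genome,
    make_population,
)

logger = logging.getLogger("mtartifact")

__all__ = [
    "TABLE1_REGIONS",
    "TABLE1_PRIMERS",
    "ExperimentConfig",
    "WMGBSResult",
    "TargetedResult",
    "run_wmgbs",
    "run_targeted",
]

#: The six targeted amplicon designs (1-based start, end-exclusive, strand).
#: Heavy-strand assays cover the control region (two overlapping D-loop
#: amplicons), tRNA-F+12S and ND5; light-strand assays cover 16S and CYTB.
TABLE1_REGIONS: tuple[GenomicInterval, ...] = (
    GenomicInterval(6, 298, HEAVY, "D-Loop"),
    GenomicInterval(279, 458, HEAVY, "D-Loop-2"),
    GenomicInterval(577, 765, HEAVY, "tRNA-F+12S"),
    GenomicInterval(2763, 2873, LIGHT, "16S"),
    GenomicInterval(12687, 12856, HEAVY, "ND5"),
    GenomicInterval(15091, 15243, LIGHT, "CYTB"),
)

#: Published primer sequences for the designs above (forward, reverse).
TABLE1_PRIMERS: dict[str, tuple[str, str]] = {
    "D-Loop": ("AAATCTATCACCCTATTAAC", "GTGGAAATTTTTTGTTATGATGT"),
    "D-Loop-2": ("CATAACAAAAAATTTCCACCAAAC", "GGGAAAATAATGTGTTAGTT"),
    "tRNA-F+12S": ("TTTATATAACTTACCTCCTC", "GTGTTTGATGTTTGTTTTTTTTG"),
    "16S": ("AATAAATTTATAGGTTTTTAAATTATTAAAT", "TAACTAATAAAATCTTAACATATACTACTC"),
    "ND5": ("TTCAAATATCTACTCATCTTC", "ATAGGATTGTTTGAATGGTT"),
    "CYTB": ("GGTATTATTTTTTTGTTTGTAATTATAGTA", "CCTCAAATTCATTAAACTAAATCTATCC"),
}

_ENZYMES = {"BamHI": BAMHI, "BglII": BGLII}


@dataclass
class ExperimentConfig:
    """Everything a run needs; all fields serialisable to/from YAML.

    The defaults describe the desk-scale study conditions: a 16,569 bp
    mtDNA-like circular genome, an all-zero true methylome, half the copies
    supercoiled with the amplicon regions protected, conversion failure
    0.5% baseline / 30% protected, a release penalty of 0.2, and ~600x
    per-strand shotgun coverage (each read pair interrogates the cytosines
    of one strand only, so total depth is ~1200x).
    """

    # genome
    genome_length: int = 16569
    gc_fraction: float = 0.44
    enzyme: str = "BamHI"
    site_position: int = 14258
    # truth
    methylome_mode: str = "all_zero"
    methylome_p: float = 0.0
    # topology
    supercoiled_fraction: float = 0.5
    epsilon_prot: float = 0.30
    rho: float = 0.2
    protected_windows: list[tuple[int, int]] | None = None  # None -> region set
    # conversion
    epsilon_0: float = 0.005
    delta: float = 0.0
    conversion_coupling: bool = True
    release_coupling: bool = True
    # population / fragmentation / reads
    n_copies: int = 2000
    mean_fragment_length: float = 300.0
    sd_fragment_length: float = 60.0
    target_fragment_count: int = 71000
    read_length: int = 150
    directional: bool = True
    error_rate: float = 0.0
    # trimming
    trim_wmgbs: int = 10
    trim_targeted: int = 2
    # targeted experiment
    reads_per_region: int = 200
    regions: list[tuple[int, int, str, str]] | None = None  # None -> Table-1 layout
    # alignment
    max_mismatches: int = 5
    # reproducibility
    seed: int = 1

    def resolved_regions(self) -> tuple[GenomicInterval, ...]:
        if self.regions is None:
            return TABLE1_REGIONS
        return tuple(
            GenomicInterval(s, e, strand, name) for s, e, strand, name in self.regions
        )

    def topology_model(self) -> TopologyModel:
        if self.protected_windows is None:
            windows = tuple(
                GenomicInterval(iv.start, iv.end, HEAVY, iv.name)
                for iv in self.resolved_regions()
            )
        else:
            windows = tuple(
                GenomicInterval(s, e, HEAVY) for s, e in self.protected_windows
            )
        return TopologyModel(
            self.supercoiled_fraction, windows, self.epsilon_prot, self.rho
        )

    def conversion_model(self) -> ConversionModel:
        return ConversionModel(self.epsilon_0, self.epsilon_prot, self.delta)

    def restriction_enzyme(self) -> RestrictionEnzyme:
        try:
            return _ENZYMES[self.enzyme]
        except KeyError:
            raise ValueError(
                f"unknown enzyme {self.enzyme!r}; choose from {sorted(_ENZYMES)}"
            ) from None

    def validate(self) -> None:
        for prob_name in (
            "gc_fraction", "methylome_p", "supercoiled_fraction",
            "epsilon_prot", "rho", "epsilon_0", "delta", "error_rate",
        ):
            v = getattr(self, prob_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{prob_name} must be in [0,1], got {v}")
        if self.epsilon_prot < self.epsilon_0:
            raise ValueError("epsilon_prot must be >= epsilon_0")
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        self.restriction_enzyme()

    # -- serialisation -------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if data.get("regions") is not None:
            data["regions"] = [tuple(r) for r in data["regions"]]
        if data.get("protected_windows") is not None:
            data["protected_windows"] = [tuple(w) for w in data["protected_windows"]]
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _build_genome(cfg: ExperimentConfig, seed: int) -> CircularGenome:
    enz = cfg.restriction_enzyme()
    return make_mtdna_like_genome(
        cfg.genome_length, cfg.gc_fraction, seed,
        site=enz.recognition,
        site_position=min(cfg.site_position, cfg.genome_length),
    )


@dataclass
class WMGBSResult:
    genome: CircularGenome
    records: list[CytosineRecord]
    correlation: CorrelationResult
    stage_counts: dict[str, int]
    config: ExperimentConfig

    @property
    def mean_coverage(self) -> float:
        covs = [r.coverage for r in self.records]
        return float(np.mean(covs)) if covs else 0.0


def run_wmgbs(
    config: ExperimentConfig,
    outdir: str | Path | None = None,
    write_fastq: bool = False,
) -> WMGBSResult:
    """Shotgun experiment: population -> fragments -> conversion -> reads ->
    trim(10) -> align -> deduplicate -> call -> depth-methylation correlation."""
    config.validate()
    seeds = _spawn_seeds(config.seed, 5)
    genome = _build_genome(config, seeds[0])
    methylome = generate_methylome(
        genome, config.methylome_mode, config.methylome_p, seed=seeds[1]
    )
    topo = config.topology_model()
    molecules = make_population(genome, config.n_copies, topo, False, seeds[2])
    fragments = fragment_population(
        molecules, genome, config.mean_fragment_length, config.sd_fragment_length,
        config.rho, config.target_fragment_count, seeds[3],
        read_len_hint=config.read_length, release_coupling=config.release_coupling,
    )
    pairs = generate_reads(
        fragments, molecules, genome, methylome, config.conversion_model(),
        config.read_length, config.directional, seeds[4],
        conversion_coupling=config.conversion_coupling,
        error_rate=config.error_rate,
    )
    trimmed = trim_heads(pairs, config.trim_wmgbs)
    aligner = BisulfiteAligner(genome, config.max_mismatches)
    aligned = aligner.align_pairs(trimmed)
    deduped = deduplicate(aligned)
    records = call_methylation(deduped, genome)
    corr = depth_methylation_correlation(records)
    counts = {
        "molecules": len(molecules),
        "fragments": len(fragments),
        "read_pairs": len(pairs),
        "read_pairs_after_trim": len(trimmed),
        "aligned_pairs": len(aligned),
        "aligned_pairs_after_dedup": len(deduped),
        "cytosine_records": len(records),
    }
    _log_counts("wmgbs", counts)
    result = WMGBSResult(genome, records, corr, counts, config)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        if write_fastq:
            write_fastq_pairs(pairs, out / "reads_1.fastq", out / "reads_2.fastq")
        write_cytosine_report(records, out / "cytosine_report.CX.txt")
        _write_manifest(out / "manifest.json", config, counts, {
            "pearson_r": corr.r, "p_value": corr.p_value, "n": corr.n,
        })
    return result


@dataclass
class TargetedResult:
    genome: CircularGenome
    records_undigested: list[CytosineRecord]
    records_digested: list[CytosineRecord]
    summaries: dict[str, tuple[RegionSummary, RegionSummary]]
    context_summaries: dict[str, dict[str, list[RegionSummary]]]
    sign_tests: dict[str, SignTestResult]
    stage_counts: dict[str, int]
    config: ExperimentConfig


def _amplicon_pairs(
    cfg: ExperimentConfig,
    genome: CircularGenome,
    methylome: MethylomeTruth,
    molecules,
    regions: Sequence[GenomicInterval],
    seed: int,
) -> list[ReadPair]:
    """Amplicon sequencing: every fragment is a full design amplicon taken
    from a random molecule; the bisulfite strand follows the design strand
    (heavy-strand assays read the original top strand, light-strand assays
    the original bottom strand)."""
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    model = cfg.conversion_model()
    for region in regions:
        mol_idx = rng.integers(len(molecules), size=cfg.reads_per_region)
        frags = [Fragment(region.start, region.end, int(i)) for i in mol_idx]
        forced = "OT" if region.strand == HEAVY else "OB"
        pairs.extend(
            generate_reads(
                frags, molecules, genome, methylome, model,
                cfg.read_length, cfg.directional, int(rng.integers(2**31)),
                conversion_coupling=cfg.conversion_coupling,
                error_rate=cfg.error_rate,
                forced_bs_strand=forced,
            )
        )
    return pairs


def run_targeted(
    config: ExperimentConfig,
    outdir: str | Path | None = None,
) -> TargetedResult:
    """Digested-vs-undigested amplicon experiment with per-region sign tests.

    The undigested arm draws amplicons from the intact topology-mixed
    population; the digested arm first linearises every copy at the
    restriction site (removing all protection).  Calling skips
    deduplication (amplicon reads legitimately stack).  The Bonferroni
    family is the set of per-region sign tests in the run.
    """
    config.validate()
    seeds = _spawn_seeds(config.seed, 6)
    genome = _build_genome(config, seeds[0])
    enz = config.restriction_enzyme()
    sites = find_sites(genome, enz)
    if not sites:
        logger.warning("no %s site in genome; digested arm equals undigested",
                       enz.name)
        cut_position = 1
    else:
        cut_position = (sites[0] - 1 + enz.cut_offset) % len(genome) + 1
    methylome = generate_methylome(
        genome, config.methylome_mode, config.methylome_p, seed=seeds[1]
    )
    topo = config.topology_model()
    regions = config.resolved_regions()
    aligner = BisulfiteAligner(genome, config.max_mismatches)

    arm_records: dict[str, list[CytosineRecord]] = {}
    counts: dict[str, int] = {}
    for arm, digested, mol_seed, read_seed in (
        ("undigested", False, seeds[2], seeds[3]),
        ("digested", True, seeds[4], seeds[5]),
    ):
        molecules = make_population(
            genome, config.n_copies, topo, digested, mol_seed,
            cut_position=cut_position,
        )
        pairs = _amplicon_pairs(config, genome, methylome, molecules, regions,
                                read_seed)
        trimmed = trim_heads(pairs, config.trim_targeted)
        aligned = aligner.align_pairs(trimmed)   # no deduplication in amplicon mode
        arm_records[arm] = call_methylation(aligned, genome)
        counts[f"{arm}_read_pairs"] = len(pairs)
        counts[f"{arm}_after_trim"] = len(trimmed)
        counts[f"{arm}_aligned"] = len(aligned)
    _log_counts("targeted", counts)

    und, dig = arm_records["undigested"], arm_records["digested"]
    und_by_key = {(r.position, r.strand): r for r in und}
    dig_by_key = {(r.position, r.strand): r for r in dig}
    L = len(genome)
    summaries: dict[str, tuple[RegionSummary, RegionSummary]] = {}
    context_summaries: dict[str, dict[str, list[RegionSummary]]] = {}
    sign_tests: dict[str, SignTestResult] = {}
    m = len(regions)
    for region in regions:
        s_und = region_summary(und, region, L, name=region.name)[0]
        s_dig = region_summary(dig, region, L, name=region.name)[0]
        summaries[region.name] = (s_und, s_dig)
        context_summaries[region.name] = {
            "undigested": region_summary(und, region, L, True, region.name),
            "digested": region_summary(dig, region, L, True, region.name),
        }
        paired_a, paired_b = [], []
        for key, r_u in und_by_key.items():
            if not region.contains(key[0], L):
                continue
            r_d = dig_by_key.get(key)
            if r_d is None or r_u.coverage == 0 or r_d.coverage == 0:
                continue
            paired_a.append(r_u.methylation_percent)
            paired_b.append(r_d.methylation_percent)
        sign_tests[region.name] = sign_test(paired_a, paired_b, m_tests=m)

    result = TargetedResult(
        genome, und, dig, summaries, context_summaries, sign_tests, counts, config
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        write_cytosine_report(und, out / "undigested.CX.txt")
        write_cytosine_report(dig, out / "digested.CX.txt")
        _write_targeted_tables(out, result)
        _write_manifest(out / "manifest.json", config, counts, {
            region: {
                "undigested_min": summaries[region][0].minimum,
                "undigested_max": summaries[region][0].maximum,
                "digested_min": summaries[region][1].minimum,
                "digested_max": summaries[region][1].maximum,
                "sign_test_p_adjusted": sign_tests[region].p_adjusted,
            }
            for region in sign_tests
        })
    return result


def _write_targeted_tables(out: Path, result: TargetedResult) -> None:
    import pandas as pd

    rows = []
    for region, (s_und, s_dig) in result.summaries.items():
        st = result.sign_tests[region]
        rows.append(
            {
                "region": region,
                "undigested_min": s_und.minimum,
                "undigested_max": s_und.maximum,
                "digested_min": s_dig.minimum,
                "digested_max": s_dig.maximum,
                "n_pos": st.n_pos,
                "n_neg": st.n_neg,
                "n_ties": st.n_ties,
                "p_raw": st.p_raw,
                "p_adjusted": st.p_adjusted,
            }
        )
    pd.DataFrame(rows).to_csv(out / "region_results.tsv", sep="\t", index=False)


def _write_manifest(
    path: Path, config: ExperimentConfig, counts: dict, results: dict
) -> None:
    manifest = {
        "package_version": _pkg_version,
        "config": dataclasses.asdict(config),
        "stage_counts": counts,
        "results": results,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)


def _log_counts(stage: str, counts: dict[str, int]) -> None:
    for k, v in counts.items():
        logger.info("%s: %s = %d", stage, k, v)
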