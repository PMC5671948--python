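import numpy as np
import pysam
import pytest

from mtartifact import (
    BisulfiteAligner,
    CircularGenome,
    ConversionModel,
    TopologyModel,
    call_methylation,
    classify_context,
    deduplicate,
    fragment_population,
    generate_genome,
    generate_methylome,
    generate_reads,
    make_population,
    parse_truth_tag,
    read_cytosine_report,
    reverse_complement,
    trim_heads,
    write_cytosine_report,
    write_sam,
)
from mtartifact.align import Alignment, AlignedPair
from mtartifact.bisulfite import Fragment, ReadPair
from oracles import exhaustive_best_unique


def _mkpair(r1, r2, name="p"):
    return ReadPair(name, r1, r2, "F" * len(r1), "F" * len(r2), "?", 0, 0, "?")


@pytest.fixture(scope="module")
def sim():
    """Error-free directional simulation on a 5 kb genome (module-scoped)."""
    g = generate_genome(5000, 0.44, seed=31)
    pop = make_population(g, 100, TopologyModel(supercoiled_fraction=0.0), seed=1)
    truth = generate_methylome(g, "all_zero")
    frags = fragment_population(pop, g, 320, 50, 1.0, 400, seed=2)
    pairs = generate_reads(
        frags, pop, g, truth, ConversionModel(0.01, 0.01, 0.0),
        read_len=150, directional=False, seed=3,
    )
    return g, pairs


# ---------------------------------------------------------------------------
# trim_heads
# ---------------------------------------------------------------------------

def test_trim_removes_head_bases_and_qualities():
    p = _mkpair("A" * 150, "C" * 150)
    (out,) = trim_heads([p], 10)
    assert len(out.read1) == len(out.read2) == 140
    assert len(out.qual1) == 140


def test_trim_zero_is_identity():
    p = _mkpair("ACGT" * 30, "TGCA" * 30)
    assert trim_heads([p], 0) == [p]


def test_reads_below_floor_are_dropped():
    p = _mkpair("A" * 25, "A" * 150)  # mate1 would fall to 15 < 20
    assert trim_heads([p], 10) == []


# ---------------------------------------------------------------------------
# aligner vs exhaustive oracle
# ---------------------------------------------------------------------------

def test_aligner_matches_exhaustive_oracle_on_200_reads(sim):
    """Positions, mismatch counts and uniqueness all agree with a full
    Hamming scan over every locus in all four bisulfite strand spaces."""
    g, pairs = sim
    aligner = BisulfiteAligner(g, max_mismatches=5)
    refs = {g.name: (g.sequence, True)}
    reads = []
    for p in pairs:
        reads.extend([p.read1, p.read2])
    assert len(reads) >= 200
    checked = 0
    for read in reads[:200]:
        got = aligner.align_read(read)
        expect = exhaustive_best_unique(read, refs, 5)
        if expect is None:
            assert got is None
        else:
            mm, ref, start0, space = expect
            assert got is not None
            assert (got.mismatches, got.reference, got.start - 1,
                    got.bisulfite_strand) == (mm, ref, start0, space)
        checked += 1
    assert checked == 200


def test_identity_read_aligns_with_zero_mismatches():
    g = generate_genome(3000, 0.44, seed=41)
    aligner = BisulfiteAligner(g)
    read = g.sequence[500:650]
    aln = aligner.align_read(read)
    # an unconverted read legitimately matches OT and CTOB spaces at the
    # same locus only when it contains no informative C/G... here it has
    # both, so the best single space must win or the read is ambiguous;
    # verify against the oracle decision.
    expect = exhaustive_best_unique(read, {g.name: (g.sequence, True)}, 5)
    if expect is None:
        assert aln is None
    else:
        assert aln.start == expect[2] + 1


def test_fully_converted_read_aligns_at_origin_position():
    g = generate_genome(3000, 0.44, seed=43)
    read = g.sequence[1000:1150].replace("C", "T")
    aln = BisulfiteAligner(g).align_read(read)
    assert aln is not None
    assert aln.start == 1001
    assert aln.bisulfite_strand == "OT"
    assert aln.mismatches == 0


def test_duplicated_locus_is_ambiguous():
    core = generate_genome(1000, 0.5, seed=44).sequence
    dup = core[100:400]
    seq = core + "AT" * 50 + dup + "GC" * 50
    g = CircularGenome("dup", seq, is_circular=False)
    read = dup[50:200].replace("C", "T")
    assert BisulfiteAligner(g).align_read(read) is None
    assert exhaustive_best_unique(read, {"dup": (seq, False)}, 5) is None


def test_wrapping_read_aligns_across_origin(small_genome):
    L = len(small_genome)
    read = (small_genome.sequence * 2)[L - 60 : L + 60].replace("C", "T")
    aln = BisulfiteAligner(small_genome).align_read(read)
    assert aln is not None
    assert aln.start == L - 59
    assert aln.end == L + 61


def test_oversized_reference_rejected():
    g = CircularGenome("big", "ACGT" * 300_000, is_circular=False)
    with pytest.raises(ValueError, match="external|mapper|limit"):
        BisulfiteAligner(g)


def test_pair_alignment_concordance_and_truth(sim):
    g, pairs = sim
    aligner = BisulfiteAligner(g)
    aligned = aligner.align_pairs(pairs)
    assert len(aligned) / len(pairs) > 0.95
    correct = 0
    for ap in aligned:
        tag = parse_truth_tag(ap.name)
        L = len(g)
        if (ap.fragment_start - 1) % L == (tag["start"] - 1) % L:
            correct += 1
    assert correct / len(aligned) >= 0.99


# ---------------------------------------------------------------------------
# deduplicate
# ---------------------------------------------------------------------------

def _fake_pair(start, end, bs="OT", ref="chrM"):
    a1 = Alignment(ref, start, start + 50, "+", bs, 0, True)
    a2 = Alignment(ref, end - 50, end, "-", {"OT": "CTOT", "OB": "CTOB"}[bs], 0, True)
    return AlignedPair(a1, a2, "A" * 50, "A" * 50, f"r{start}-{end}-{bs}", start, end)


def test_identical_keys_collapse_to_one():
    pairs = [_fake_pair(10, 300) for _ in range(5)]
    assert len(deduplicate(pairs)) == 1


def test_distinct_keys_unchanged():
    pairs = [_fake_pair(10, 300), _fake_pair(11, 300), _fake_pair(10, 301)]
    assert len(deduplicate(pairs)) == 3


def test_same_coordinates_different_bisulfite_strand_both_kept():
    pairs = [_fake_pair(10, 300, "OT"), _fake_pair(10, 300, "OB")]
    assert len(deduplicate(pairs)) == 2


def test_deduplication_is_idempotent(sim):
    g, pairs = sim
    aligned = BisulfiteAligner(g).align_pairs(pairs)
    once = deduplicate(aligned)
    assert deduplicate(once) == once


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def test_context_rules_on_constructed_sequence():
    g = CircularGenome("ctx", "AACGTACAGTAACCAA", is_circular=False)
    assert classify_context(g, 3, "+") == ("CpG", "CGT")       # ..CGT..
    assert classify_context(g, 7, "+") == ("CHG", "CAG")       # ..CAG..
    assert classify_context(g, 13, "+") == ("CHH", "CCA")
    # bottom strand: G at position 4 pairs with a C whose downstream is
    # complement of positions 3,2 -> "GT" complement -> "CA"? (CGT on top)
    ctx, tri = classify_context(g, 4, "-")
    assert tri[0] == "C"


def test_context_wraps_on_circular_genome():
    # C at the final position, first base G -> CpG across the origin
    g = CircularGenome("wrapc", "G" + "A" * 98 + "C")
    assert classify_context(g, 100, "+") == ("CpG", "CGA")


def test_linear_end_pads_with_n_as_chh():
    g = CircularGenome("endc", "A" * 99 + "C", is_circular=False)
    assert classify_context(g, 100, "+") == ("CHH", "CNN")


def test_non_cytosine_position_rejected(small_genome):
    pos = small_genome.sequence.index("A") + 1
    with pytest.raises(ValueError):
        classify_context(small_genome, pos, "+")


def test_contexts_partition_all_cytosines(small_genome):
    """#CpG + #CHG + #CHH equals the total cytosine count on both strands."""
    counts = {"CpG": 0, "CHG": 0, "CHH": 0}
    seq = small_genome.sequence
    for i, b in enumerate(seq):
        if b == "C":
            counts[classify_context(small_genome, i + 1, "+")[0]] += 1
        if b == "G":
            counts[classify_context(small_genome, i + 1, "-")[0]] += 1
    assert sum(counts.values()) == seq.count("C") + seq.count("G")
    assert min(counts.values()) > 0


# ---------------------------------------------------------------------------
# call_methylation
# ---------------------------------------------------------------------------

def test_constructed_pileup_gives_thirty_percent():
    """3 methylated (C) + 7 unmethylated (T) calls at one position -> 30%."""
    g = CircularGenome("pile", "TTTTTTTTTTCGTTTTTTTTTTTTTTTTTTTATTTTTTTG" * 3,
                       is_circular=False)
    pos = 11  # the C of the first CG
    pairs = []
    for i in range(10):
        read = g.sequence[0:40]
        if i >= 3:
            read = read[:10] + "T" + read[11:]  # converted at the C
        a1 = Alignment("pile", 1, 41, "+", "OT", 0, True)
        a2 = Alignment("pile", 81, 121, "-", "CTOT", 0, True)
        pairs.append(AlignedPair(a1, a2, read, g.sequence[80:120], f"r{i}", 1, 121))
    records = call_methylation(pairs, g)
    rec = next(r for r in records if r.position == pos and r.strand == "+")
    assert (rec.count_methylated, rec.count_unmethylated) == (3, 7)
    assert rec.methylation_percent == pytest.approx(30.0)


def test_zero_coverage_cytosines_emitted(small_genome):
    records = call_methylation([], small_genome)
    assert len(records) == small_genome.sequence.count("C") + \
        small_genome.sequence.count("G")
    assert all(r.coverage == 0 for r in records)
    assert all(np.isnan(r.methylation_percent) for r in records)


def test_end_to_end_zero_methylome_perfect_conversion_is_all_zero(small_genome):
    """With an all-zero methylome and eps0=0 no pipeline stage can create a
    methylated call: every covered cytosine reads exactly 0%."""
    pop = make_population(
        small_genome, 50, TopologyModel(supercoiled_fraction=0.0), seed=1
    )
    truth = generate_methylome(small_genome, "all_zero")
    frags = fragment_population(pop, small_genome, 300, 50, 1.0, 600, seed=2)
    pairs = generate_reads(
        frags, pop, small_genome, truth, ConversionModel(0.0, 0.0, 0.0),
        read_len=150, seed=3,
    )
    aligned = BisulfiteAligner(small_genome).align_pairs(pairs)
    assert aligned
    records = call_methylation(aligned, small_genome)
    covered = [r for r in records if r.coverage > 0]
    assert covered
    assert all(r.count_methylated == 0 for r in covered)


def test_mate_overlap_not_double_counted():
    g = CircularGenome("ovl", "ATCGATTACA" * 10, is_circular=False)
    # fragment of 60 with two fully-overlapping 60 bp mates
    read1 = g.sequence[20:80]
    read2 = reverse_complement(read1)
    a1 = Alignment("ovl", 21, 81, "+", "OT", 0, True)
    a2 = Alignment("ovl", 21, 81, "-", "CTOT", 0, True)
    pair = AlignedPair(a1, a2, read1, read2, "r", 21, 81)
    records = call_methylation([pair], g)
    for r in records:
        if 21 <= r.position < 81 and r.strand == "+":
            assert r.coverage == 1  # not 2


# ---------------------------------------------------------------------------
# report / SAM I/O
# ---------------------------------------------------------------------------

def test_cytosine_report_round_trip(tmp_path, sim):
    g, pairs = sim
    aligned = BisulfiteAligner(g).align_pairs(pairs[:50])
    records = call_methylation(aligned, g)
    path = tmp_path / "cx.txt"
    write_cytosine_report(records, path)
    back = read_cytosine_report(path)
    assert back == records
    # dialect: 7 tab-separated columns, no header
    first = path.read_text().splitlines()[0].split("\t")
    assert len(first) == 7
    assert first[2] in "+-"


def test_sam_output_parses_with_htslib(tmp_path, sim):
    g, pairs = sim
    aligned = BisulfiteAligner(g).align_pairs(pairs[:20])
    path = tmp_path / "out.sam"
    write_sam(aligned, g, path)
    with pysam.AlignmentFile(str(path), "r") as sam:
        recs = list(sam)
    assert len(recs) == 2 * len(aligned)
    by_name = {}
    for r in recs:
        by_name.setdefault(r.query_name, []).append(r)
    for ap in aligned:
        r1, r2 = by_name[ap.name]
        assert {r1.reference_start + 1, r2.reference_start + 1} == {
            (ap.aln1.start - 1) % len(g) + 1, (ap.aln2.start - 1) % len(g) + 1
        }
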