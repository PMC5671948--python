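import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from mtartifact import (
    ConversionModel,
    GenomicInterval,
    TopologyModel,
    bisulfite_convert,
    fragment_population,
    generate_genome,
    generate_methylome,
    generate_reads,
    make_population,
    parse_truth_tag,
    read_fastq,
    reverse_complement,
    write_fastq_pairs,
)
from mtartifact.bisulfite import Fragment
from oracles import doubled_string_subseq


def _coverage(fragments, L):
    cov = np.zeros(L)
    for f in fragments:
        pos = np.arange(f.start - 1, f.end - 1) % L
        cov[pos] += 1
    return cov


# ---------------------------------------------------------------------------
# bisulfite_convert
# ---------------------------------------------------------------------------

def test_fully_methylated_fragment_is_untouched():
    seq = "ACGTTCGGAC" * 10
    n = len(seq)
    ones = np.ones(n)
    top, bottom = bisulfite_convert(
        seq, ones, ones, np.zeros(n, bool), ConversionModel(0.0, 0.0, 0.0), 1
    )
    assert top == seq
    assert bottom == reverse_complement(seq)


def test_complete_conversion_of_unmethylated_fragment():
    seq = "ACGTTCGGAC" * 10
    n = len(seq)
    zeros = np.zeros(n)
    top, bottom = bisulfite_convert(
        seq, zeros, zeros, np.zeros(n, bool), ConversionModel(0.0, 0.0, 0.0), 1
    )
    assert "C" not in top
    assert top == seq.replace("C", "T")
    assert "C" not in bottom
    assert bottom == reverse_complement(seq).replace("C", "T")


def test_conversion_preserves_length_and_non_cytosines():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    n = len(seq)
    top, bottom = bisulfite_convert(
        seq, np.zeros(n), np.zeros(n), np.zeros(n, bool),
        ConversionModel(0.3, 0.5, 0.2), 3,
    )
    assert len(top) == len(bottom) == n
    for orig, conv in zip(seq, top):
        if orig != "C":
            assert conv == orig
    for orig, conv in zip(reverse_complement(seq), bottom):
        if orig != "C":
            assert conv == orig


def test_unconverted_count_within_three_sigma_of_binomial():
    """10,000 unmethylated cytosines at a 1% failure rate."""
    seq = "CA" * 10_000
    n = len(seq)
    eps = 0.01
    top, _ = bisulfite_convert(
        seq, np.zeros(n), np.zeros(n), np.zeros(n, bool),
        ConversionModel(eps, eps, 0.0), 12345,
    )
    unconverted = top.count("C")
    sigma = math.sqrt(10_000 * eps * (1 - eps))
    assert abs(unconverted - 100) <= 3 * sigma


def test_protection_raises_failure_rate_only_in_windows():
    seq = "C" * 1000
    n = len(seq)
    protected = np.zeros(n, bool)
    protected[:500] = True
    top, _ = bisulfite_convert(
        seq, np.zeros(n), np.zeros(n), protected,
        ConversionModel(0.0, 1.0, 0.0), 5,
    )
    assert top[:500] == "C" * 500      # eps_prot = 1: every protected C escapes
    assert top[500:] == "T" * 500      # eps0 = 0: every unprotected C converts


def test_conversion_model_validates_ordering():
    with pytest.raises(ValueError):
        ConversionModel(epsilon_0=0.4, epsilon_prot=0.1)


# ---------------------------------------------------------------------------
# fragment_population
# ---------------------------------------------------------------------------

def test_uniform_coverage_without_protection(small_genome):
    """rho=1, no protection: fragment starts are uniform over the circle
    (chi-square GOF over 100 bins not rejected at alpha=0.001)."""
    pop = make_population(
        small_genome, 100, TopologyModel(supercoiled_fraction=0.0), seed=1
    )
    frags = fragment_population(pop, small_genome, 300, 60, 1.0, 50_000, seed=2)
    L = len(small_genome)
    starts = np.array([(f.start - 1) % L for f in frags])
    binned = np.bincount(starts * 100 // L, minlength=100)
    chi2, p = stats.chisquare(binned)
    assert p > 0.001
    # and mean per-base coverage matches fragments * mean length / L
    cov = _coverage(frags, L)
    assert cov.mean() == pytest.approx(50_000 * 300 / L, rel=0.05)


def test_release_penalty_thins_protected_window(small_genome):
    """Coverage ratio inside/outside a protected window approaches rho."""
    rho = 0.2
    window = GenomicInterval(1000, 2000)
    topo = TopologyModel(1.0, (window,), 0.3, rho)
    pop = make_population(small_genome, 100, topo, seed=3)
    frags = fragment_population(pop, small_genome, 300, 60, rho, 60_000, seed=4)
    cov = _coverage(frags, len(small_genome))
    # compare well inside the window vs well outside (clear of edge gradients)
    inside = cov[1250:1750].mean()
    outside = np.concatenate([cov[2500:3400], cov[100:700]]).mean()
    assert inside / outside == pytest.approx(rho, rel=0.15)


def test_origin_spanning_fragment_sequence_wraps(small_genome):
    L = len(small_genome)
    frag = Fragment(L - 49, L - 49 + 200, 0)
    expect = doubled_string_subseq(small_genome.sequence, L - 50, 200)
    pop = make_population(
        small_genome, 1, TopologyModel(supercoiled_fraction=0.0), seed=1
    )
    truth = generate_methylome(small_genome, "all_zero")
    (pair,) = generate_reads(
        [frag], pop, small_genome, truth,
        ConversionModel(0.0, 0.0, 0.0), read_len=200, seed=1,
        forced_bs_strand="OT",
    )
    # all-zero methylome + eps0=0: read is the fully converted wrap sequence
    assert pair.read1 == expect.replace("C", "T")


def test_digested_molecules_never_span_the_cut(small_genome):
    cut = 3500
    pop = make_population(
        small_genome, 50, TopologyModel(), digested=True, seed=5, cut_position=cut
    )
    frags = fragment_population(pop, small_genome, 300, 60, 1.0, 5_000, seed=6)
    L = len(small_genome)
    for f in frags:
        # offset of fragment start within the linearised molecule
        off = (f.start - cut) % L
        assert off + f.length <= L


def test_target_count_zero_rejected(small_genome):
    pop = make_population(small_genome, 10, TopologyModel(), seed=1)
    with pytest.raises(ValueError):
        fragment_population(pop, small_genome, 300, 60, 1.0, 0, seed=1)


# ---------------------------------------------------------------------------
# generate_reads
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def unconverted_setup():
    g = generate_genome(3000, 0.44, seed=21)
    pop = make_population(g, 50, TopologyModel(supercoiled_fraction=0.0), seed=1)
    truth = generate_methylome(g, "uniform", p=1.0)  # fully methylated: no conversion
    return g, pop, truth


def test_reads_tile_fragment_exactly_at_twice_read_length(unconverted_setup):
    g, pop, truth = unconverted_setup
    frag = Fragment(101, 101 + 160, 0)
    (pair,) = generate_reads(
        [frag], pop, g, truth, ConversionModel(0.0, 0.0, 0.0),
        read_len=80, seed=2, forced_bs_strand="OT",
    )
    assert pair.read1 + reverse_complement(pair.read2) == g.sequence[100:260]


def test_unconverted_reads_are_exact_genome_substrings(unconverted_setup):
    g, pop, truth = unconverted_setup
    frags = fragment_population(pop, g, 300, 60, 1.0, 200, seed=3)
    pairs = generate_reads(
        frags, pop, g, truth, ConversionModel(0.0, 0.0, 0.0),
        read_len=100, directional=False, seed=4,
    )
    doubled = g.sequence * 2
    doubled_rc = reverse_complement(g.sequence) * 2
    for p in pairs:
        for read in (p.read1, p.read2):
            assert read in doubled or read in doubled_rc


def test_non_directional_strand_tags_multinomial(unconverted_setup):
    g, pop, truth = unconverted_setup
    frags = fragment_population(pop, g, 300, 60, 1.0, 4_000, seed=5)
    pairs = generate_reads(
        frags, pop, g, truth, ConversionModel(), read_len=100,
        directional=False, seed=6,
    )
    counts = Counter(p.bisulfite_strand for p in pairs)
    n = len(pairs)
    sigma = math.sqrt(n * 0.25 * 0.75)
    for tag in ("OT", "OB", "CTOT", "CTOB"):
        assert abs(counts[tag] - n / 4) <= 3 * sigma


def test_directional_mode_emits_only_original_strands(unconverted_setup):
    g, pop, truth = unconverted_setup
    frags = fragment_population(pop, g, 300, 60, 1.0, 500, seed=7)
    pairs = generate_reads(
        frags, pop, g, truth, ConversionModel(), read_len=100, seed=8
    )
    assert set(p.bisulfite_strand for p in pairs) <= {"OT", "OB"}


def test_short_fragment_truncates_reads(unconverted_setup):
    g, pop, truth = unconverted_setup
    frag = Fragment(11, 11 + 60, 0)
    (pair,) = generate_reads(
        [frag], pop, g, truth, ConversionModel(), read_len=100, seed=9
    )
    assert len(pair.read1) == len(pair.read2) == 60


def test_apparent_methylation_converges_to_epsilon(unconverted_setup):
    """Law of large numbers: at >= 5,000 cytosine observations the pooled
    apparent methylation equals 100*eps0 within 3 binomial sigma."""
    g, pop, _ = unconverted_setup
    truth_zero = generate_methylome(g, "all_zero")
    eps = 0.01
    frags = fragment_population(pop, g, 300, 60, 1.0, 2_000, seed=10)
    pairs = generate_reads(
        frags, pop, g, truth_zero, ConversionModel(eps, eps, 0.0),
        read_len=150, seed=11,
    )
    c_calls = t_calls = 0
    for p in pairs:
        if p.bisulfite_strand != "OT":
            continue
        ref = doubled_string_subseq(g.sequence, p.truth_start - 1, len(p.read1))
        for rb, gb in zip(p.read1, ref):
            if gb == "C":
                c_calls += rb == "C"
                t_calls += rb == "T"
    n = c_calls + t_calls
    assert n >= 5_000
    sigma = math.sqrt(eps * (1 - eps) / n)
    assert abs(c_calls / n - eps) <= 3 * sigma


def test_truth_tag_round_trip(unconverted_setup):
    g, pop, truth = unconverted_setup
    frags = fragment_population(pop, g, 300, 60, 1.0, 5, seed=12)
    pairs = generate_reads(frags, pop, g, truth, ConversionModel(), seed=13)
    for p, f in zip(pairs, frags):
        tag = parse_truth_tag(p.name)
        assert (tag["start"], tag["end"]) == (f.start, f.end)
        assert tag["bisulfite_strand"] == p.bisulfite_strand


def test_fastq_round_trip(tmp_path, unconverted_setup):
    g, pop, truth = unconverted_setup
    frags = fragment_population(pop, g, 300, 60, 1.0, 20, seed=14)
    pairs = generate_reads(frags, pop, g, truth, ConversionModel(), seed=15)
    f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    write_fastq_pairs(pairs, f1, f2)
    back1, back2 = read_fastq(f1), read_fastq(f2)
    assert len(back1) == len(back2) == 20
    for p, (n1, s1, q1), (n2, s2, q2) in zip(pairs, back1, back2):
        assert n1 == p.name + "/1" and n2 == p.name + "/2"
        assert s1 == p.read1 and s2 == p.read2
        assert q1 == p.qual1 and q2 == p.qual2
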