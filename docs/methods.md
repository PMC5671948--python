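# Methods

This note documents the models, parameter choices, numerical conventions and
limitations behind `mtartifact`.

## Coordinate conventions

All coordinates are 1-based with end-exclusive intervals, so an interval
(start, end) has length `end − start`; every targeted amplicon design row
satisfies `size = end − start` exactly under this convention (e.g. the
D-loop design 6–298 is 292 bp).  On circular genomes `end` may exceed the
genome length (wrap across the origin); circular scans are implemented on
the doubled string with positions reduced modulo the length, and each site
is reported once.  BED input (0-based, half-open) is converted on read.
Restriction-cut boundaries are placed at recognition-site start +
`cut_offset` (BamHI G^GATCC → offset 1); only fragment lengths are
contract-bearing, and the reported site position is the recognition-site
start (whether published site coordinates refer to the recognition start or
the cut point is ambiguous; we state our choice here and use it
consistently).

## The generative model

**Genome.**  `make_mtdna_like_genome` draws a random circular sequence
(default 16,569 bp, GC 0.44, matching human mtDNA in length and
composition), breaks every spurious occurrence of the restriction site, and
plants exactly one copy at the configured position (default 14,258, the
coordinate of the single BamHI site in the human reference).  It is a
synthetic stand-in: no local sequence features of real mtDNA beyond length,
GC and the unique site are emulated.  Analyses of the real reference work by
supplying its FASTA.

**True methylome.**  Per-cytosine, per-strand methylation probabilities.
Default `all_zero` — the working truth is that mtDNA carries essentially no
cytosine methylation, so every apparent signal downstream is artifactual by
construction and fully attributable.  `uniform(p)` and `site_list` modes
support power/robustness studies.

**Topology.**  Each genome copy is supercoiled with probability
`supercoiled_fraction` (default 0.5) or open-circular otherwise; the
simulator deliberately collapses open-circular and linear copies into one
"unprotected" behaviour, because the artifact mechanism is attributed
specifically to supercoiling.  Supercoiled copies carry *protected
windows*.  The library-level default is a single window over the start of
the genome (the analog of the protein-bent control region); the pipeline
configs default to protecting all six amplicon design intervals, since the
digestion effect was observed at every assayed region.  Digestion
(`digested=True`) forces every copy linear at the cut coordinate with all
protection removed — complete digestion is assumed (a 4 h complete digest is
modelled as complete; no partial-digestion kinetics).

**Protection couples to two mechanisms**, each independently switchable:

1. *Release* (`release_coupling`, strength ρ, default 0.2): a candidate
   sonication fragment overlapping an active protected window of its parent
   is retained with probability ρ.  Fragment starts are uniform on the
   molecule (wrapping on circular parents, never crossing the cut on linear
   ones); lengths are normal (default mean 300, sd 60) truncated at 50 bp.
2. *Conversion* (`conversion_coupling`, ε_prot, default 0.30): an
   unmethylated cytosine under an active protected window escapes conversion
   with probability ε_prot instead of the baseline ε₀ (default 0.005, a
   typical bisulfite failure rate of half a percent).  A methylated cytosine
   is read as T with over-conversion probability δ (default 0).

The supercoiled fraction, ε_prot and ρ are latent quantities with no
published values; the defaults were chosen to produce a clearly visible
artifact at desk scale and are all exposed in the config.  How much of the
real depth dip is release bias versus conversion blocking is unknown; the
simulator exposes both as parameters rather than asserting a split.

**Reads.**  Directional libraries (default) sequence the two original
bisulfite strands (OT/OB, 50:50); the non-directional flag adds the PCR
complements (CTOT/CTOB) at 25% each, as in post-bisulfite random-primed
protocols.  Read 1 is the 5′ end of the selected strand, read 2 the reverse
complement of its 3′ end; default 150 bp paired-end.  Qualities are constant
Phred 37 (the analysis never uses them).  Sequencing error is off by default
(the subject is conversion artifacts, not sequencer noise); a uniform
substitution rate and an exact-copy duplication option (for deduplication
testing) exist.  Read names carry a colon-separated truth tag (source
interval, bisulfite strand, parent topology) that the aligner never reads.

## Read processing

Head trimming removes the first n bases of each mate (shotgun default 10,
targeted default 2 — adopted as configuration inputs, the way
position-bias trimming lengths are usually supplied); mates falling below a
20 bp floor drop the pair.

The aligner is a small three-letter mapper: read and reference are compared
after C→T collapse (OT/CTOT spaces) or G→A collapse (OB/CTOB spaces), so
conversion never counts as mismatch.  Candidate loci come from exact
20-mer seeds (up to five spread along the read, guaranteeing a clean seed
whenever the read has ≤ 4 scattered mismatches); candidates are verified by
full Hamming comparison in collapsed space, accepting ≤ 5 mismatches, and a
read is reported only if its best locus beats the runner-up by at least one
mismatch across all spaces and loci (unique best hit).  Mates must map
uniquely to the same reference in complementary spaces within the insert
limit (default 1,200 bp); circular references are handled by indexing a
600 bp origin extension and reducing positions modulo the length.  The
total reference is capped at 1 Mb — this is a desk-scale tool; larger
genomes belong to production mappers.  Note that a read in which *every*
cytosine escaped conversion is genuinely ambiguous between strand spaces
and is discarded by the uniqueness rule; at realistic ε this is vanishingly
rare.

Deduplication keeps one pair per (reference, fragment start, fragment end,
mapped strand, bisulfite strand) and is applied only in shotgun mode —
amplicon reads legitimately stack.  Calling counts C (methylated) and T
(unmethylated) read bases at reference cytosine columns of the strand the
read interrogates; other bases are ignored rather than counted as
unmethylated; where mates overlap only read 1 is counted.  Every reference
cytosine is emitted, covered or not, with CpG/CHG/CHH context from the two
downstream bases on its strand (wrapping on circular genomes; linear ends
pad with N and class as CHH).

## Diagnostics

**Depth–methylation correlation.**  Pearson r between log coverage and log
apparent methylation over cytosines with coverage ≥ 1 *and* apparent
methylation > 0.  The >0 filter mirrors how such correlations are computed
in practice; a consequence worth stating is that the statistic measures the
artifact among apparent-positive sites.  The natural logarithm is used;
Pearson r is invariant to the base (tested).  Pooling samples means
concatenating their filtered records.  Coverage is post-deduplication
coverage (whether to use pre- or post-dedup depth was an open choice; we
use the depth the caller actually saw).

**Sign test.**  Per region, cytosines covered in both arms are paired; ties
are excluded; p is the exact two-sided binomial tail
`min(1, 2·Σ_{i≤k} C(n,i)/2ⁿ)` with k the minority sign count, Bonferroni
multiplied by the family size m (default: the number of per-region tests in
the session, since no canonical family size exists).

**Region summaries.**  Min–max apparent methylation over covered cytosines,
optionally split CpG vs non-CpG; no covered cytosines → "ND".  Replicates
(emulated as extra seeds) are pooled before the min–max rather than shown
per replicate — a reporting choice, stated here.

**Background envelope.**  The expected apparent methylation at an
unprotected, unmethylated cytosine is 100·ε₀, with binomial noise
100·√(ε₀(1−ε₀)/n) at coverage n.  For a single site the envelope is the
3σ band.  A region's *maximum* over S covered sites systematically exceeds
a per-site 3σ band as S grows, so `background_envelope(ε₀, n, S)` widens the
band by a union bound: the smallest count threshold whose family tail
S·P(X > t) does not exceed the one-sided 3σ tail.  It reduces exactly to
the per-site band at S = 1.

**Profile smoothing.**  A centred circular sliding-window mean with window
= `window_fraction` × genome length (default 0.2) stands in for model-based
smoothers; it preserves constants and tends to the global mean as the
window grows.  Figure-level equivalence with any particular smoother is not
claimed.

**NUMT screen.**  Nuclear decoys carry planted mt segments with independent
per-base substitutions at a set divergence; the alignment score is the
+1/−1 match/mismatch score over the span (no indels; published NUMT-catalog
scoring schemes are not reproduced).  The screen enumerates every read of a
fixed length (default 300 bp, a read length at which no known human NUMT
retains perfect identity) from each NUMT copy — both strands, both a
fully-unconverted "methylated" state (the worst case for confusability) and
a fully-converted unmethylated state — and realigns them against the
combined references with the pipeline's uniqueness rule.  Identical copies
produce ambiguous, never mt-assigned, reads; the screen is fully
deterministic.  Full-genome screens (hg38-scale) require external mappers.

**In-silico PCR** matches the forward primer and the reverse complement of
the reverse primer convergently against the four first-round PCR strands of
the fully converted genome (or the two plain strands when unconverted),
with a Hamming mismatch allowance and a product-length cap.

## Problem sizes and statistical design

Default shotgun scale: 71,000 fragments on 16,569 bp, i.e. ~1200× total
depth and ~600× per strand (a read pair interrogates one strand's
cytosines).  This was chosen so that the expected number of
background-unconverted calls per cytosine is λ = 600·ε₀ ≈ 3.  The choice
matters for the *null*: apparent methylation is only defined for sites with
at least one unconverted call, and when λ ≪ 1 most positive sites carry
exactly one call, making apparent methylation ≈ 100/n and mechanically
anti-correlated with depth even without any artifact.  At λ ≈ 3 the
conditioning bias is negligible and the artifact-off configuration
(ε_prot = ε₀, ρ = 1) shows no significant negative correlation, while the
artifact-on defaults produce r around −0.5 over roughly 6–7 thousand
filtered cytosines.  The acceptance suite runs its five-seed artifact
reproduction on a half-length genome (8,285 bp) at the same per-strand
coverage — coverage, not genome length, is the operative condition — and
the targeted experiment uses 200 amplicon pairs per region per arm.

Reported real-data values on the order of r = −0.9 with astronomically
small sign-test p-values arise from much deeper data than these desk-scale
simulations; the package's claims are qualitative reproduction (sign,
significance, collapse to background after digestion), and nothing in the
tests asserts those real-data magnitudes.

## Known limitations

* No indel alignment, no quality-aware scoring, no mapping at mammalian
  genome scale, no adapter or PCR-bias modelling.
* No catenane-specific topology state; open-circular and linear copies are
  behaviourally identical by design.
* NUMTs are substitution-only; mouse-specific perfect-identity NUMT regions
  (which block mapping entirely on real data) are out of scope.
* The synthetic genome shares only length, GC and the unique restriction
  site with real mtDNA; conclusions from passing tests concern the
  mechanism and the statistics, not sequence-specific behaviour of any real
  genome.
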