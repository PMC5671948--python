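"""Diagnostic statistics that expose the false-positive methylation signal.

Three questions, three statistics:

* Is apparent methylation coupled to sequencing depth?  Pearson correlation
  between log coverage and log methylation over cytosines with any apparent
  methylation — a strong negative correlation is the signature of a
  structural artifact rather than true methylation.
* Does linearising the genome (restriction digestion before conversion)
  lower apparent methylation?  Paired sign test per region, Bonferroni
  corrected over the family of regions.
* Could nuclear copies of the mitochondrial genome (NUMTs) explain the
  signal?  Plain Pearson correlations of per-NUMT methylation against NUMT
  length and alignment score.

Plus min-max region summaries (optionally split by CpG / non-CpG context)
and a circular sliding-window profile smoother for coverage/methylation
tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .align import CytosineRecord
from .genome import GenomicInterval

__all__ = [
    "CorrelationResult",
    "SignTestResult",
    "RegionSummary",
    "depth_methylation_correlation",
    "sign_test",
    "region_summary",
    "numt_feature_correlation",
    "background_envelope",
    "smooth_profile",
    "plot_depth_methylation",
    "plot_profile",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its provenance."""

    r: float
    p_value: float
    n: int
    filter_description: str = ""
    defined: bool = True


@dataclass(frozen=True)
class SignTestResult:
    """Exact paired sign test with Bonferroni adjustment.

    ``p_raw`` is the two-sided exact binomial tail
    ``min(1, 2 * sum_{i<=k} C(n,i) / 2^n)`` with ``k = min(n_pos, n_neg)``
    over the ``n = n_pos + n_neg`` untied pairs; ties are excluded.
    """

    n_pos: int
    n_neg: int
    n_ties: int
    p_raw: float
    p_adjusted: float
    m_tests: int
    degenerate: bool = False

    @property
    def n_pairs(self) -> int:
        return self.n_pos + self.n_neg + self.n_ties


@dataclass(frozen=True)
class RegionSummary:
    """Min-max apparent methylation over the covered cytosines of a region."""

    name: str
    interval: GenomicInterval
    minimum: float
    maximum: float
    n_covered: int
    determined: bool
    context: str = "all"   # 'all', 'CpG' or 'non-CpG'

    def __str__(self) -> str:
        if not self.determined:
            return f"{self.name} [{self.context}]: ND"
        return (
            f"{self.name} [{self.context}]: "
            f"{self.minimum:.1f}-{self.maximum:.1f}% (n={self.n_covered})"
        )


def depth_methylation_correlation(
    records: Sequence[CytosineRecord],
    min_coverage: int = 1,
) -> CorrelationResult:
    """Pearson r between log coverage and log apparent methylation.

    Only cytosines with coverage >= ``min_coverage`` **and** apparent
    methylation strictly greater than 0 enter the statistic (sites with no
    unconverted calls carry no information about the artifact and their log
    is undefined).  Pooling several samples means concatenating their
    filtered records before calling this function.  The natural logarithm is
    used; Pearson r is invariant to the base.
    """
    cov = np.array([r.coverage for r in records], dtype=float)
    pct = np.array([r.methylation_percent for r in records], dtype=float)
    mask = (cov >= min_coverage) & (pct > 0)
    desc = f"coverage >= {min_coverage} and methylation_percent > 0"
    n = int(mask.sum())
    if n < 3:
        return CorrelationResult(math.nan, math.nan, n, desc, defined=False)
    x, y = np.log(cov[mask]), np.log(pct[mask])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, n, desc, defined=False)
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n, desc)


def sign_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    m_tests: int = 1,
) -> SignTestResult:
    """Exact two-sided sign test on paired values (a vs b), Bonferroni-adjusted.

    A pair contributes a positive sign when ``a > b`` (e.g. undigested
    apparent methylation exceeding the digested value at the same cytosine).
    All-tied input is degenerate and yields p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    d = a - b
    n_pos = int(np.sum(d > 0))
    n_neg = int(np.sum(d < 0))
    n_ties = int(np.sum(d == 0))
    n = n_pos + n_neg
    if n == 0:
        return SignTestResult(0, 0, n_ties, 1.0, 1.0, m_tests, degenerate=True)
    k = min(n_pos, n_neg)
    p_raw = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
    return SignTestResult(
        n_pos, n_neg, n_ties, p_raw, min(1.0, m_tests * p_raw), m_tests
    )


def region_summary(
    records: Sequence[CytosineRecord],
    region: GenomicInterval,
    genome_length: int | None = None,
    context_split: bool = False,
    name: str | None = None,
) -> list[RegionSummary]:
    """Min-max apparent methylation over covered cytosines in a region.

    Returns one summary, or two (CpG and non-CpG) when ``context_split`` is
    set.  A region with no covered cytosines is reported as not determined
    (the "ND" convention).  ``genome_length`` enables wrap-aware membership
    for origin-spanning regions on circular genomes.
    """
    gl = genome_length or max((r.position for r in records), default=0) or 1
    in_region = [
        r for r in records
        if region.contains(r.position, gl) and r.coverage > 0
    ]
    rname = name if name is not None else (region.name or f"{region.start}-{region.end}")

    def summarize(rs: list[CytosineRecord], ctx: str) -> RegionSummary:
        if not rs:
            return RegionSummary(rname, region, math.nan, math.nan, 0, False, ctx)
        pcts = [r.methylation_percent for r in rs]
        return RegionSummary(
            rname, region, float(min(pcts)), float(max(pcts)), len(rs), True, ctx
        )

    if not context_split:
        return [summarize(in_region, "all")]
    cpg = [r for r in in_region if r.context == "CpG"]
    non = [r for r in in_region if r.context != "CpG"]
    return [summarize(cpg, "CpG"), summarize(non, "non-CpG")]


def numt_feature_correlation(
    per_numt_methylation: Sequence[float],
    numt_lengths: Sequence[float],
    numt_scores: Sequence[float],
) -> tuple[CorrelationResult, CorrelationResult]:
    """Pearson correlations of per-NUMT methylation vs length and vs
    alignment score (no transform); a true-methylation-free signal should
    show neither."""
    meth = np.asarray(per_numt_methylation, dtype=float)

    def corr(x: Sequence[float], label: str) -> CorrelationResult:
        x = np.asarray(x, dtype=float)
        if x.shape != meth.shape:
            raise ValueError("feature vector length mismatch")
        if len(meth) < 3 or np.ptp(x) == 0 or np.ptp(meth) == 0:
            return CorrelationResult(math.nan, math.nan, len(meth), label, False)
        res = stats.pearsonr(meth, x)
        return CorrelationResult(float(res.statistic), float(res.pvalue), len(meth), label)

    return corr(numt_lengths, "methylation vs NUMT length"), corr(
        numt_scores, "methylation vs NUMT alignment score"
    )


def background_envelope(
    epsilon_0: float,
    coverage: int,
    n_sites: int = 1,
    z: float = 3.0,
) -> float:
    """Upper envelope (in percent) for apparent methylation that is pure
    conversion failure.

    For a single cytosine at the given coverage this is the classical
    ``100 * (epsilon_0 + z * sigma)`` binomial band.  When a *maximum* over
    ``n_sites`` cytosines is being compared (a region's min-max summary),
    the band must widen for multiplicity: the envelope is the smallest count
    threshold whose union-bound family tail ``n_sites * P(X > t)`` does not
    exceed the one-sided ``z``-sigma tail probability.  Reduces exactly to
    the single-site band at ``n_sites = 1``.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    tail = float(stats.norm.sf(z))
    if n_sites == 1:
        sigma = math.sqrt(epsilon_0 * (1 - epsilon_0) / coverage)
        return 100.0 * (epsilon_0 + z * sigma)
    # smallest t with n_sites * P(X > t) <= tail, X ~ Binomial(coverage, eps0)
    t = int(stats.binom.isf(tail / n_sites, coverage, epsilon_0))
    while n_sites * float(stats.binom.sf(t, coverage, epsilon_0)) > tail:
        t += 1
    return 100.0 * t / coverage


def smooth_profile(
    records: Sequence[CytosineRecord],
    genome_length: int,
    window_fraction: float = 0.2,
    circular: bool = True,
) -> pd.DataFrame:
    """Per-position sliding-window means of coverage and apparent methylation.

    A centred moving average with window ``window_fraction * genome_length``
    (circular wrap by default) stands in for a model-based smoother; it
    preserves constants and converges to the global mean as the window grows
    to the full genome.  Returns a position-indexed frame with raw and
    smoothed coverage and methylation tracks (both strands pooled per
    position).
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must be in (0, 1]")
    cov = np.zeros(genome_length)
    meth_pct = np.full(genome_length, np.nan)
    meth_counts = np.zeros(genome_length)
    total_counts = np.zeros(genome_length)
    for r in records:
        i = r.position - 1
        cov[i] += r.coverage
        meth_counts[i] += r.count_methylated
        total_counts[i] += r.coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        meth_pct = np.where(
            total_counts > 0, 100.0 * meth_counts / np.maximum(total_counts, 1), np.nan
        )
    window = max(1, int(round(window_fraction * genome_length)))
    mode = "wrap" if circular else "nearest"
    smooth_cov = ndimage.uniform_filter1d(cov, size=window, mode=mode)
    filled = np.where(np.isnan(meth_pct), 0.0, meth_pct)
    has = (~np.isnan(meth_pct)).astype(float)
    num = ndimage.uniform_filter1d(filled, size=window, mode=mode)
    den = ndimage.uniform_filter1d(has, size=window, mode=mode)
    with np.errstate(invalid="ignore", divide="ignore"):
        smooth_meth = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame(
        {
            "position": np.arange(1, genome_length + 1),
            "coverage": cov,
            "methylation_percent": meth_pct,
            "smoothed_coverage": smooth_cov,
            "smoothed_methylation_percent": smooth_meth,
        }
    )


# ---------------------------------------------------------------------------
# Plots (simple, non-interactive)
# ---------------------------------------------------------------------------

def plot_depth_methylation(
    records: Sequence[CytosineRecord], path: str | Path,
    result: CorrelationResult | None = None,
) -> None:
    """Log-log scatter of coverage vs apparent methylation for filtered cytosines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cov = np.array([r.coverage for r in records], dtype=float)
    pct = np.array([r.methylation_percent for r in records], dtype=float)
    mask = (cov >= 1) & (pct > 0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(cov[mask], pct[mask], s=6, alpha=0.4, edgecolors="none")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("Number of reads (coverage)")
    ax.set_ylabel("Apparent methylation (%)")
    title = "Depth vs apparent methylation"
    if result is not None and result.defined:
        title += f"  (r = {result.r:.3f}, p = {result.p_value:.2g}, n = {result.n})"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Coverage and apparent-methylation tracks along the genome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 4.5), sharex=True)
    axes[0].plot(profile["position"], profile["smoothed_coverage"], lw=1)
    axes[0].set_ylabel("Coverage")
    axes[1].plot(
        profile["position"], profile["smoothed_methylation_percent"],
        lw=1, color="firebrick",
    )
    axes[1].set_ylabel("Methylation (%)")
    axes[1].set_xlabel("Genome position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
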