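"""Independent brute-force oracles used to check the package implementation.

These deliberately avoid the code paths they verify: alignment is an
exhaustive Hamming scan over every position of every reference in all four
bisulfite strand spaces; the sign test is direct binomial enumeration;
Pearson is the closed-form sum formula.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")
_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def exhaustive_bisulfite_hits(
    read: str, references: dict[str, tuple[str, bool]], max_mm: int
) -> list[tuple[int, str, int, str]]:
    """All (mismatches, ref_name, start0, space) placements with mm <= max_mm.

    ``references`` maps name -> (sequence, is_circular).  Start positions
    are 0-based, canonical (mod L for circular references).
    """
    spaces = {
        "OT": (read.translate(_CT), "ct"),
        "CTOT": (rc(read).translate(_CT), "ct"),
        "OB": (rc(read).translate(_GA), "ga"),
        "CTOB": (read.translate(_GA), "ga"),
    }
    hits = []
    m = len(read)
    for name, (seq, circular) in references.items():
        L = len(seq)
        if m > L:
            continue
        ext = seq + seq[: m - 1] if circular else seq
        for which, collapse in (("ct", _CT), ("ga", _GA)):
            ref_arr = np.frombuffer(ext.translate(collapse).encode(), "S1")
            windows = np.lib.stride_tricks.sliding_window_view(ref_arr, m)
            for space, (q, w) in spaces.items():
                if w != which:
                    continue
                q_arr = np.frombuffer(q.encode(), "S1")
                mms = (windows != q_arr).sum(axis=1)
                for p in np.flatnonzero(mms <= max_mm):
                    hits.append((int(mms[p]), name, int(p) % L, space))
    # canonicalise duplicates (same placement reachable twice is impossible
    # here because starts are already reduced mod L and spaces distinct)
    return sorted(set(hits))


def exhaustive_best_unique(
    read: str, references: dict[str, tuple[str, bool]], max_mm: int
):
    """Unique-best-hit decision of the exhaustive scan: placement or None."""
    hits = exhaustive_bisulfite_hits(read, references, max_mm)
    if not hits:
        return None
    if len(hits) > 1 and hits[1][0] <= hits[0][0]:
        return None
    return hits[0]


def sign_test_enumeration(n_pos: int, n_neg: int) -> float:
    """Two-sided exact sign-test p by direct combinatorial enumeration."""
    n = n_pos + n_neg
    k = min(n_pos, n_neg)
    total = sum(math.comb(n, i) for i in range(k + 1))
    return min(1.0, 2.0 * total / 2**n)


def pearson_closed_form(x, y) -> float:
    """Pearson r via the raw-sum formula (no library calls)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def doubled_string_subseq(seq: str, start0: int, length: int) -> str:
    """Wrap-around subsequence oracle on the doubled string."""
    return (seq + seq)[start0 : start0 + length]


def doubled_string_find(seq: str, probe: str) -> list[int]:
    """0-based circular occurrences of probe, via the doubled string."""
    doubled = seq + seq[: len(probe) - 1]
    out = []
    p = doubled.find(probe)
    while p != -1:
        if p < len(seq):
            out.append(p)
        p = doubled.find(probe, p + 1)
    return out
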