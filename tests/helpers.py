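"""Independent oracles used across the test suite.

These deliberately reimplement the checked operations in the most naive way
possible (brute force, exact rational arithmetic, regex expansion) so they
stay independent of the library code paths they verify.
"""

from __future__ import annotations

import itertools
import re
from fractions import Fraction
from math import comb

import numpy as np

from cofbal.cistrome import IUPAC_CODES


def brute_force_clusters(pooled):
    """Greedy "<radius from index centre" partition, written as a plain loop.

    ``pooled`` is a list of (chrom, centre, score, label) tuples; returns the
    partition as a list of lists of pooled indices, radius fixed at 250.
    """
    order = sorted(range(len(pooled)),
                   key=lambda i: (pooled[i][0], pooled[i][1], -pooled[i][2], pooled[i][3]))
    partition = []
    index_of_current = None
    for i in order:
        chrom, centre = pooled[i][0], pooled[i][1]
        if index_of_current is not None:
            ic, icc = pooled[index_of_current][0], pooled[index_of_current][1]
            if chrom == ic and abs(centre - icc) < 250:
                partition[-1].append(i)
                continue
        partition.append([i])
        index_of_current = i
    return partition


def exact_hypergeom_tail(N: int, K: int, n: int, k: int, tail: str) -> Fraction:
    """Exact rational hypergeometric tail probability by direct summation."""
    denom = comb(N, n)
    if tail == "over":
        ks = range(k, min(n, K) + 1)
    else:
        ks = range(max(0, n - (N - K)), k + 1)
    return Fraction(sum(comb(K, j) * comb(N - K, n - j) for j in ks), denom)


def exact_fisher_greater(k: int, n: int, K: int, N: int) -> Fraction:
    """One-sided (enrichment) Fisher p for a 2x2 with margins n, K out of N."""
    return exact_hypergeom_tail(N, K, n, k, "over")


def pearson_chi2_by_hand(table: np.ndarray) -> float:
    """Textbook sum of (O - E)^2 / E for a 2x2 table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def km_by_hand(times, events):
    """Product-limit estimate from first principles (events-first at ties)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = []
    for t in sorted(set(times[events == 1])):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1 - d / at_risk
        out.append((t, at_risk, d, s))
    return out


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-squared from the O-E table."""
    times = np.concatenate([times_a, times_b]).astype(float)
    events = np.concatenate([events_a, events_b]).astype(int)
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 0)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (group == 0)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def iupac_regex(pattern: str) -> re.Pattern:
    """Regex expansion of an IUPAC consensus (character classes)."""
    return re.compile("".join(f"[{IUPAC_CODES[c]}]" for c in pattern.upper()))


def regex_motif_count(seq: str, pattern: str, both_strands: bool) -> int:
    """Overlapping-hit count of an IUPAC consensus via regex lookahead."""
    from cofbal.cistrome import reverse_complement

    def count(pat):
        return len(re.findall(f"(?=({pat.pattern}))", seq))

    total = count(iupac_regex(pattern))
    if both_strands:
        total += count(iupac_regex(reverse_complement(pattern)))
    return total
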