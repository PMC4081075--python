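"""Set-enrichment statistics: hypergeometric tests, BH FDR, bootstrap category
z-scores and 2x2 proportion comparison.

The hypergeometric test asks whether the overlap ``k`` between a query gene
set (size ``n``) and an annotation set (size ``K``) within a universe of
``N`` genes exceeds chance; the over-representation p-value is
``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``.  The bootstrap z-score draws
query-sized sets uniformly without replacement from the universe and scores
the observed per-category overlap against that empirical null — the companion
statistic used for differentiation-stage categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "SignatureCollection",
    "hypergeometric_test",
    "bh_fdr",
    "bootstrap_category_zscore",
    "signature_collection_enrichment",
    "proportion_chisq",
    "read_gmt",
    "write_gmt",
]


@dataclass
class EnrichmentResult:
    """k/n/K/N overlap counts with p (and optionally q, bootstrap z)."""

    k: int
    n: int
    K: int
    N: int
    p_value: float
    direction: str = "enriched"
    q_value: float | None = None
    z_score: float | None = None

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K) or max(self.n, self.K) > self.N:
            raise ValueError("inconsistent overlap counts")


def hypergeometric_test(query: Iterable, annotation: Iterable, universe: Iterable,
                        tail: str = "over") -> EnrichmentResult:
    """Exact hypergeometric enrichment (tail='over') or depletion (tail='under')."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    annotation = set(annotation)
    if not query <= universe or not annotation <= universe:
        raise ValueError("query and annotation must be subsets of the universe")
    n, K, N = len(query), len(annotation), len(universe)
    k = len(query & annotation)
    if n == 0:
        return EnrichmentResult(0, 0, K, N, 1.0, "enriched")
    if tail == "over":
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        direction = "enriched"
    elif tail == "under":
        p = float(stats.hypergeom.cdf(k, N, K, n))
        direction = "depleted"
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return EnrichmentResult(k, n, K, N, min(p, 1.0), direction)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_category_zscore(query: Iterable, category_map: Mapping,
                              universe: Iterable, n_iter: int = 10_000_000,
                              seed: int | None = None) -> dict[str, EnrichmentResult]:
    """Bootstrap enrichment z per category against random query-sized draws.

    The null draws ``n_iter`` sets of size ``|query|`` uniformly without
    replacement from the universe; the joint per-category overlap counts are
    realised directly as multivariate-hypergeometric samples over the category
    partition, which is distributionally identical to drawing the sets and
    counting.  z = (observed - null mean) / null sd; the empirical two-sided
    p uses the (r + 1)/(n_iter + 1) estimator so it is never exactly zero.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    for g in category_map:
        if g not in universe:
            raise ValueError(f"category gene {g!r} not in universe")
    cats = sorted(set(category_map.values()))
    N, n = len(universe), len(query)
    colors = [sum(1 for v in category_map.values() if v == c) for c in cats]
    colors.append(N - sum(colors))  # genes outside every category
    rng = np.random.default_rng(seed)
    # generate in chunks to bound memory at large n_iter (1e7 draws default)
    chunks = []
    remaining = int(n_iter)
    while remaining > 0:
        m = min(remaining, 1_000_000)
        chunks.append(
            rng.multivariate_hypergeometric(colors, n, size=m)[:, :len(cats)]
            .astype(np.int32)
        )
        remaining -= m
    draws = np.concatenate(chunks, axis=0)
    null_mean = draws.mean(axis=0)
    null_sd = draws.std(axis=0, ddof=1)

    out: dict[str, EnrichmentResult] = {}
    for j, cat in enumerate(cats):
        members = {g for g, v in category_map.items() if v == cat}
        o = len(query & members)
        if null_sd[j] == 0:
            warnings.warn(f"degenerate null for category {cat}: sd = 0")
            z = float("nan")
            p = 1.0
        else:
            z = (o - null_mean[j]) / null_sd[j]
            r = int(np.sum(np.abs(draws[:, j] - null_mean[j])
                           >= abs(o - null_mean[j])))
            p = (r + 1) / (n_iter + 1)
        out[cat] = EnrichmentResult(
            k=o, n=n, K=len(members), N=N, p_value=float(p),
            direction="enriched" if o >= null_mean[j] else "depleted",
            z_score=float(z),
        )
    return out


@dataclass
class SignatureCollection:
    """Named gene sets (e.g. read from GMT) with optional source labels."""

    sets: dict[str, frozenset[str]]
    sources: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def filtered(self, max_set_size: int) -> "SignatureCollection":
        """Keep signatures strictly smaller than ``max_set_size`` genes."""
        keep = {k: v for k, v in self.sets.items() if len(v) < max_set_size}
        return SignatureCollection(keep, {k: self.sources.get(k, "") for k in keep})


def read_gmt(path: str | Path) -> SignatureCollection:
    sets: dict[str, frozenset[str]] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, source, genes = fields[0], fields[1], fields[2:]
            sets[name] = frozenset(g for g in genes if g)
            sources[name] = source
    return SignatureCollection(sets, sources)


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.sources.get(name, '')}\t{genes}\n")


def signature_collection_enrichment(query: Iterable, collection: SignatureCollection,
                                    universe: Iterable,
                                    max_set_size: int = 1000) -> pd.DataFrame:
    """Hypergeometric enrichment of a query against every signature in a
    collection, with BH correction across the batch.

    Signatures of ``max_set_size`` genes or more are excluded before testing
    ("less than" is strict); signatures with no genes in the universe are
    skipped with a warning.  Returns a table sorted by q-value.
    """
    if not len(collection):
        raise ValueError("empty signature collection")
    universe = set(universe)
    query = set(query) & universe
    rows = []
    for name, genes in collection.filtered(max_set_size).sets.items():
        in_universe = genes & universe
        if not in_universe:
            warnings.warn(f"signature {name!r} has no genes in the universe; skipped")
            continue
        res = hypergeometric_test(query, in_universe, universe)
        rows.append((name, res.k, res.n, res.K, res.N, res.p_value))
    if not rows:
        return pd.DataFrame(columns=["signature", "k", "n", "K", "N", "p", "q"])
    df = pd.DataFrame(rows, columns=["signature", "k", "n", "K", "N", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values(["q", "p", "signature"], kind="stable").reset_index(drop=True)


def proportion_chisq(a_successes: int, a_total: int, b_successes: int,
                     b_total: int, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared (df=1) comparing two proportions.

    Continuity correction is off by default.  Warns when any expected cell
    count falls below 1, where an exact test is preferable.
    """
    if a_total <= 0 or b_total <= 0:
        raise ValueError("totals must be positive")
    table = np.array([
        [a_successes, a_total - a_successes],
        [b_successes, b_total - b_successes],
    ])
    if (table < 0).any():
        raise ValueError("successes exceed totals")
    res = stats.chi2_contingency(table, correction=correction)
    if (res.expected_freq < 1).any():
        warnings.warn("expected cell count < 1; consider Fisher's exact test")
    return float(res.statistic), float(res.pvalue)
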