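"""Binned genome-wide occupancy correlation and knockdown differential occupancy.

Two complementary views of how factor binding landscapes relate:

* genome-wide — each cistrome is reduced to a sparse 100 bp binned track and
  track pairs are compared by Pearson correlation, then ordered by
  hierarchical clustering on ``1 - r`` (the heat-map view of which factors
  share a genomic distribution);
* element-wise — read counts over merged regulatory elements in control
  versus knockdown chromatin give per-element log2 fold changes, summarised
  per occupancy signature, with a "stable subset" (fold change below a
  threshold, default 1.4) tested for enrichment of a focus signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .cistrome import Cistrome, OverlapCluster, signature_label
from .enrichment import EnrichmentResult, hypergeometric_test

__all__ = [
    "BinnedTrack",
    "ElementCountTable",
    "bin_occupancy",
    "occupancy_correlation_matrix",
    "hierarchical_order",
    "merge_tree_newick",
    "differential_occupancy",
    "stable_subset_enrichment",
]


@dataclass
class BinnedTrack:
    """Sparse fixed-width binned occupancy; only nonzero bins stored."""

    label: str
    bin_size: int
    values: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")


def bin_occupancy(cistrome: Cistrome, bin_size: int = 100,
                  mode: str = "presence") -> BinnedTrack:
    """Reduce a cistrome to a binned track.

    ``presence`` mode sets a bin to 1 when any peak interval overlaps it
    (the peak-call representation); ``signal`` mode sums peak scores into
    every overlapped bin.
    """
    if mode not in {"presence", "signal"}:
        raise ValueError(f"unknown mode {mode!r}")
    values: dict[tuple[str, int], float] = {}
    for p in cistrome.peaks:
        first = p.start // bin_size
        last = (p.end - 1) // bin_size
        for b in range(first, last + 1):
            key = (p.chrom, b)
            if mode == "presence":
                values[key] = 1.0
            else:
                values[key] = values.get(key, 0.0) + p.score
    return BinnedTrack(cistrome.label, bin_size, values)


def occupancy_correlation_matrix(tracks: Sequence[BinnedTrack],
                                 domain: str = "union_occupied",
                                 chrom_lengths: Mapping[str, int] | None = None,
                                 ) -> pd.DataFrame:
    """Pairwise Pearson correlation of binned tracks over a common bin domain.

    ``union_occupied`` correlates over the union of bins occupied by at least
    one track (the default: shared empty genome would otherwise inflate r);
    ``all_bins`` uses every bin of the genome and requires ``chrom_lengths``.
    A zero-variance track yields NaN entries with a warning rather than a
    silent 0.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    sizes = {t.bin_size for t in tracks}
    if len(sizes) != 1:
        raise ValueError(f"tracks disagree on bin_size: {sorted(sizes)}")
    if domain == "union_occupied":
        keys = sorted(set().union(*(t.values.keys() for t in tracks)))
    elif domain == "all_bins":
        if chrom_lengths is None:
            raise ValueError("all_bins domain requires chrom_lengths")
        bin_size = tracks[0].bin_size
        keys = [
            (c, b)
            for c in sorted(chrom_lengths)
            for b in range((chrom_lengths[c] + bin_size - 1) // bin_size)
        ]
    else:
        raise ValueError(f"unknown domain {domain!r}")
    mat = np.array([[t.values.get(k, 0.0) for k in keys] for t in tracks])
    labels = [t.label for t in tracks]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(mat)
    for i, row in enumerate(corr):
        if np.isnan(row).any():
            warnings.warn(f"track {labels[i]!r} has zero variance: correlation undefined (NaN)")
            break
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=labels, columns=labels)


def hierarchical_order(corr: pd.DataFrame, linkage: str = "average",
                       ) -> tuple[list[str], np.ndarray]:
    """Leaf order and merge tree from hierarchical clustering on ``1 - r``.

    Returns the ordered track labels and the scipy linkage matrix.  NaN
    correlations (zero-variance tracks) are rejected.
    """
    if linkage not in {"average", "complete"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = corr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("correlation matrix contains NaN entries")
    if not np.allclose(values, values.T):
        raise ValueError("correlation matrix must be symmetric")
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    order = hierarchy.leaves_list(Z)
    return [corr.index[i] for i in order], Z


def merge_tree_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage matrix as a Newick string with merge heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


@dataclass
class ElementCountTable:
    """Per-regulatory-element read counts for control vs knockdown chromatin."""

    element_ids: list[str]
    signatures: list[str]
    control_counts: np.ndarray
    kd_counts: np.ndarray
    library_sizes: tuple[float, float]  # (control, knockdown)

    def __post_init__(self) -> None:
        self.control_counts = np.asarray(self.control_counts, dtype=float)
        self.kd_counts = np.asarray(self.kd_counts, dtype=float)
        n = len(self.element_ids)
        if not (len(self.signatures) == len(self.control_counts)
                == len(self.kd_counts) == n):
            raise ValueError("field lengths disagree")
        if (self.control_counts < 0).any() or (self.kd_counts < 0).any():
            raise ValueError("counts must be non-negative")
        if min(self.library_sizes) <= 0:
            raise ValueError("library sizes must be positive")

    @classmethod
    def from_clusters(cls, clusters: Sequence[OverlapCluster],
                      control_counts, kd_counts,
                      library_sizes: tuple[float, float]) -> "ElementCountTable":
        return cls(
            element_ids=[f"e{cl.cluster_id}" for cl in clusters],
            signatures=[signature_label(cl.signature) for cl in clusters],
            control_counts=control_counts,
            kd_counts=kd_counts,
            library_sizes=library_sizes,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "element_id": self.element_ids,
            "signature": self.signatures,
            "control": self.control_counts,
            "kd": self.kd_counts,
        })


def element_log2fc(table: ElementCountTable, pseudocount: float = 1.0) -> np.ndarray:
    """Per-element log2 of depth-normalised (kd / control) with a pseudocount."""
    n_ctl, n_kd = table.library_sizes
    return np.log2(
        ((table.kd_counts + pseudocount) / n_kd)
        / ((table.control_counts + pseudocount) / n_ctl)
    )


def differential_occupancy(table: ElementCountTable, pseudocount: float = 1.0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Knockdown effect per occupancy class.

    Returns (per-element table with log2FC, per-class summary with
    median/IQR/n, pairwise class contrasts by two-sided Mann-Whitney U on the
    per-element log2FC).  Classes with no elements are dropped with a warning
    upstream (they cannot occur here since classes derive from the elements).
    """
    per_element = table.to_frame()
    per_element["log2fc"] = element_log2fc(table, pseudocount)

    groups = per_element.groupby("signature", sort=True)["log2fc"]
    summary = groups.agg(
        n="size", median="median",
        q25=lambda s: float(np.percentile(s, 25)),
        q75=lambda s: float(np.percentile(s, 75)),
    ).reset_index()

    sigs = sorted(per_element["signature"].unique())
    rows = []
    for i, a in enumerate(sigs):
        for b in sigs[i + 1:]:
            xa = per_element.loc[per_element["signature"] == a, "log2fc"]
            xb = per_element.loc[per_element["signature"] == b, "log2fc"]
            if len(xa) == 0 or len(xb) == 0:
                warnings.warn(f"empty class in contrast {a} vs {b}; skipped")
                continue
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append((a, b, float(res.statistic), float(res.pvalue)))
    contrasts = pd.DataFrame(rows, columns=["class_a", "class_b", "U", "p"])
    return per_element, summary, contrasts


def stable_subset_enrichment(table: ElementCountTable, focus_signature: str,
                             fc_threshold: float = 1.4,
                             pseudocount: float = 1.0) -> EnrichmentResult:
    """Enrichment of a focus signature among knockdown-stable elements.

    Stable = linear fold change within (1/threshold, threshold), i.e.
    |log2FC| < log2(threshold).  The stable subset is tested for
    over-representation of ``focus_signature`` against all elements by the
    hypergeometric test.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    log2fc = element_log2fc(table, pseudocount)
    stable = np.abs(log2fc) < np.log2(fc_threshold)
    universe = table.element_ids
    query = [e for e, s in zip(universe, stable) if s]
    annotation = [
        e for e, sig in zip(universe, table.signatures) if sig == focus_signature
    ]
    if not query:
        return EnrichmentResult(0, 0, len(annotation), len(universe), 1.0)
    return hypergeometric_test(query, annotation, universe)
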