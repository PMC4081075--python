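"""Expression-defined subgroups: quadrant assignment, per-cohort differential
expression, cross-cohort consensus meta-profiles, knockdown DE and marker
correlations.

ABC-class tumour samples are split into four quadrants by independent median
splits of two marker genes (default SPIB and BATF: top 50% = high, bottom
50% = low).  Differential expression between the two extreme quadrants
(SPIBhigh/BATFlow vs SPIBlow/BATFhigh) is computed per cohort at unadjusted
p < 0.05, and genes significant with a consistent sign in at least
``min_support`` cohorts (default 4) form the consensus *meta-profile* for
that direction — the cross-cohort replication requirement is the
multiplicity control at this step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

__all__ = [
    "ExpressionDataset",
    "MetaProfile",
    "read_expression_dataset",
    "write_expression_dataset",
    "assign_quadrants",
    "quadrant_labels",
    "differential_expression",
    "consensus_meta_profile",
    "knockdown_de",
    "summarize_expression_by_occupancy",
    "marker_correlations",
    "collapse_probes_max_mean",
]

ANNOTATION_COLUMNS = ["class", "os_time", "os_event", "myd88"]


@dataclass
class ExpressionDataset:
    """One cohort: genes x samples log2 expression plus sample annotations.

    ``annotations`` is indexed by sample with columns ``class`` (ABC/GCB/
    other), ``os_time`` (months), ``os_event`` (1 = death) and ``myd88``
    (wild_type / L265P / other / unknown).
    """

    dataset_id: str
    matrix: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate gene ids")
        if not self.matrix.columns.equals(self.annotations.index):
            raise ValueError(f"{self.dataset_id}: annotation rows must match matrix columns")

    def samples_of_class(self, cls: str) -> list[str]:
        return list(self.annotations.index[self.annotations["class"] == cls])


def read_expression_dataset(matrix_path: str | Path, annotation_path: str | Path,
                            dataset_id: str | None = None) -> ExpressionDataset:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return ExpressionDataset(dataset_id or Path(matrix_path).stem, matrix, ann)


def write_expression_dataset(ds: ExpressionDataset, matrix_path: str | Path,
                             annotation_path: str | Path) -> None:
    ds.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    ds.annotations.to_csv(annotation_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Quadrant assignment

def quadrant_labels(gene_a: str = "SPIB", gene_b: str = "BATF") -> list[str]:
    return [
        f"{gene_a}high_{gene_b}low",
        f"{gene_a}high_{gene_b}high",
        f"{gene_a}low_{gene_b}low",
        f"{gene_a}low_{gene_b}high",
    ]


def _median_split_high(values: pd.Series) -> pd.Series:
    """True for the top half of samples by a rank-based median split.

    Ties are broken by stable sample order; with odd n the middle sample goes
    to "low", so "high" is strictly the top floor(n/2).
    """
    order = np.argsort(values.to_numpy(), kind="stable")
    n = len(values)
    high = np.zeros(n, dtype=bool)
    high[order[n - n // 2:]] = True
    return pd.Series(high, index=values.index)


def assign_quadrants(dataset: ExpressionDataset, gene_a: str = "SPIB",
                     gene_b: str = "BATF", class_filter: str | None = "ABC",
                     ) -> pd.Series:
    """Label each (class-filtered) sample with its marker-expression quadrant.

    Returns a Series sample -> quadrant label (e.g. ``SPIBhigh_BATFlow``),
    an exhaustive and exclusive partition of the filtered samples.
    """
    for g in (gene_a, gene_b):
        if g not in dataset.matrix.index:
            raise KeyError(f"marker gene {g!r} absent from {dataset.dataset_id}")
    if class_filter is not None:
        samples = dataset.samples_of_class(class_filter)
    else:
        samples = list(dataset.matrix.columns)
    if len(samples) < 4:
        raise ValueError(
            f"{dataset.dataset_id}: need >= 4 samples after class filter, got {len(samples)}"
        )
    a_high = _median_split_high(dataset.matrix.loc[gene_a, samples])
    b_high = _median_split_high(dataset.matrix.loc[gene_b, samples])
    labels = [
        f"{gene_a}{'high' if a else 'low'}_{gene_b}{'high' if b else 'low'}"
        for a, b in zip(a_high, b_high)
    ]
    return pd.Series(labels, index=pd.Index(samples, name="sample"), name="quadrant")


# ---------------------------------------------------------------------------
# Differential expression

def differential_expression(dataset: ExpressionDataset, group_x: Sequence[str],
                            group_y: Sequence[str], test: str = "welch",
                            alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene two-sample comparison of group_x vs group_y.

    log2FC is mean(x) - mean(y) on the log2 scale (positive = higher in
    group_x).  ``test`` is "welch" (unequal-variance t) or "mannwhitney".
    Genes with zero variance in both groups get p = 1 when the means agree
    (degenerate flag set).
    """
    if len(group_x) < 3 or len(group_y) < 3:
        raise ValueError("each group needs at least 3 samples")
    X = dataset.matrix[list(group_x)].to_numpy()
    Y = dataset.matrix[list(group_y)].to_numpy()
    log2fc = X.mean(axis=1) - Y.mean(axis=1)
    degenerate = (X.var(axis=1) == 0) & (Y.var(axis=1) == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if test == "welch":
            p = stats.ttest_ind(X, Y, axis=1, equal_var=False).pvalue
        elif test == "mannwhitney":
            p = stats.mannwhitneyu(X, Y, axis=1, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    p = np.asarray(p, dtype=float)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "significant": p < alpha, "degenerate": degenerate},
        index=dataset.matrix.index,
    )
    return out


@dataclass
class MetaProfile:
    """Consensus gene list for one direction with per-gene support counts."""

    direction: str
    entries: pd.DataFrame  # index gene; columns: support, mean_log2fc
    min_support: int

    @property
    def genes(self) -> set[str]:
        return set(self.entries.index)

    def __len__(self) -> int:
        return len(self.entries)


def consensus_meta_profile(per_dataset_de: Sequence[pd.DataFrame],
                           min_support: int = 4,
                           directions: tuple[str, str] = (
                               "up_in_SPIBhigh_BATFlow", "up_in_SPIBlow_BATFhigh"),
                           ) -> tuple[MetaProfile, MetaProfile, list[str]]:
    """Build the pair of consensus meta-profiles from per-cohort DE tables.

    A gene enters a direction when significant with that sign in at least
    ``min_support`` cohorts.  The gene universe is the intersection of gene
    ids across cohorts (so support counts share a denominator); datasets with
    inconsistent universes are intersected with a warning.  Genes qualifying
    in both directions are excluded from both and returned as conflicts.
    """
    if len(per_dataset_de) < min_support:
        raise ValueError("fewer datasets than min_support")
    common = per_dataset_de[0].index
    for de in per_dataset_de[1:]:
        common = common.intersection(de.index)
    if any(len(common) != len(de.index) for de in per_dataset_de):
        warnings.warn("gene universes differ across datasets; using intersection")
    common = common.sort_values()

    sig_up = np.zeros(len(common), dtype=int)
    sig_down = np.zeros(len(common), dtype=int)
    fc_sum_up = np.zeros(len(common))
    fc_sum_down = np.zeros(len(common))
    for de in per_dataset_de:
        sub = de.loc[common]
        up = (sub["significant"] & (sub["log2fc"] > 0)).to_numpy()
        down = (sub["significant"] & (sub["log2fc"] < 0)).to_numpy()
        fc = sub["log2fc"].to_numpy()
        sig_up += up
        sig_down += down
        fc_sum_up += np.where(up, fc, 0.0)
        fc_sum_down += np.where(down, fc, 0.0)

    in_up = sig_up >= min_support
    in_down = sig_down >= min_support
    conflict = in_up & in_down
    conflicts = list(common[conflict])
    if conflicts:
        warnings.warn(f"{len(conflicts)} genes qualified in both directions; excluded")

    def build(mask, support, fc_sum, direction) -> MetaProfile:
        mask = mask & ~conflict
        entries = pd.DataFrame(
            {
                "support": support[mask],
                "mean_log2fc": fc_sum[mask] / np.maximum(support[mask], 1),
            },
            index=common[mask],
        )
        return MetaProfile(direction, entries, min_support)

    return (
        build(in_up, sig_up, fc_sum_up, directions[0]),
        build(in_down, sig_down, fc_sum_down, directions[1]),
        conflicts,
    )


def knockdown_de(control: pd.DataFrame, knockdown: pd.DataFrame,
                 fdr_alpha: float = 0.05, fc_threshold: float = 1.5,
                 ) -> tuple[pd.DataFrame, pd.Index, pd.Index]:
    """Two-stringency knockdown gene lists.

    ``control`` and ``knockdown`` are genes x replicates log2 matrices.
    Per-gene Welch t, BH-adjusted; list A = adjusted p < ``fdr_alpha``;
    list B = list A further restricted to linear |FC| >= ``fc_threshold``.
    log2FC is knockdown minus control, so downregulated genes are negative.
    """
    if control.shape[1] < 2 or knockdown.shape[1] < 2:
        raise ValueError("need >= 2 replicates per arm for a variance estimate")
    if not control.index.equals(knockdown.index):
        raise ValueError("gene indexes must match")
    log2fc = knockdown.mean(axis=1) - control.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(knockdown.to_numpy(), control.to_numpy(),
                            axis=1, equal_var=False).pvalue
    p = np.nan_to_num(np.asarray(p, dtype=float), nan=1.0)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=control.index,
    )
    list_a = table.index[table["q"] < fdr_alpha]
    list_b = table.index[
        (table["q"] < fdr_alpha) & (np.abs(table["log2fc"]) >= np.log2(fc_threshold))
    ]
    return table, list_a, list_b


def summarize_expression_by_occupancy(expression: pd.Series,
                                      occupancy_map: Mapping[str, str],
                                      ) -> pd.DataFrame:
    """Median and IQR of expression per occupancy group, with an all-genes
    baseline row labelled ``Total``."""
    if not occupancy_map:
        raise ValueError("empty occupancy map")
    rows = [("Total", expression)]
    groups: dict[str, list[str]] = {}
    for gene, grp in occupancy_map.items():
        groups.setdefault(grp, []).append(gene)
    for grp in sorted(groups):
        genes = [g for g in groups[grp] if g in expression.index]
        if not genes:
            warnings.warn(f"occupancy group {grp!r} has no genes with expression; omitted")
            continue
        rows.append((grp, expression.loc[genes]))
    return pd.DataFrame(
        {
            "group": [name for name, _ in rows],
            "n": [len(vals) for _, vals in rows],
            "median": [float(np.median(vals)) for _, vals in rows],
            "q25": [float(np.percentile(vals, 25)) for _, vals in rows],
            "q75": [float(np.percentile(vals, 75)) for _, vals in rows],
        }
    )


def marker_correlations(datasets: Sequence[ExpressionDataset],
                        genes: Sequence[str] = ("SPIB", "BATF", "IRF4"),
                        method: str = "spearman",
                        class_filter: str | None = "ABC",
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise marker-gene correlations per cohort and their cross-cohort
    unweighted mean +/- sd.

    Datasets where a marker is constant are skipped for the affected pair
    with a warning (rho undefined).
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
    rows = []
    for ds in datasets:
        samples = ds.samples_of_class(class_filter) if class_filter else list(ds.matrix.columns)
        if len(samples) < 4:
            raise ValueError(f"{ds.dataset_id}: fewer than 4 samples after filtering")
        for a, b in pairs:
            x = ds.matrix.loc[a, samples].to_numpy()
            y = ds.matrix.loc[b, samples].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"{ds.dataset_id}: constant marker in pair {a}-{b}; skipped"
                )
                continue
            rho = float(stats.spearmanr(x, y).statistic)
            rows.append((ds.dataset_id, f"{a}-{b}", rho))
    per_dataset = pd.DataFrame(rows, columns=["dataset", "pair", "rho"])
    summary = (
        per_dataset.groupby("pair")["rho"]
        .agg(mean="mean", sd=lambda s: float(np.std(s, ddof=1)) if len(s) > 1 else float("nan"),
             n_datasets="size")
        .reset_index()
    )
    return per_dataset, summary


def collapse_probes_max_mean(probe_matrix: pd.DataFrame,
                             probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes, keeping for each gene the
    probe with the highest mean expression (the standard max-mean rule)."""
    means = probe_matrix.mean(axis=1)
    best: dict[str, str] = {}
    for probe in probe_matrix.index:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    out = probe_matrix.loc[[best[g] for g in sorted(best)]]
    out.index = pd.Index(sorted(best), name="gene")
    return out
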