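"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator takes an explicit seed and is deterministic for a fixed
spec; there is no global random state.  The emulated structure:

* cistromes — latent regulatory elements placed with a guaranteed minimum
  spacing (default 4x the 250 bp clustering radius, so truth clusters are
  unambiguous); each element has a *base factor* that always binds, other
  factors bind with the pairwise sharing probability, and bound-factor peak
  centres are the element centre plus Gaussian summit jitter;
* element read counts — Poisson counts around lognormal element strengths,
  with knockdown means multiplied by a per-signature retained fraction;
* expression cohorts — Gaussian log2 noise around gene baselines, marker
  genes (SPIB/BATF) drawn independently per sample, quadrant-specific mean
  shifts for planted genes, exponential survival with a planted hazard
  ratio and Bernoulli mutation status with planted odds in one quadrant;
* motif sequences — i.i.d. background at a given GC with literal IUPAC
  instantiations embedded at known positions and strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cistrome import Cistrome, GeneModel, IUPAC_CODES, MotifPattern, Peak, reverse_complement
from .occupancy import ElementCountTable
from .subgroups import ExpressionDataset

__all__ = [
    "CistromeSimSpec",
    "CohortSimSpec",
    "gen_gene_models",
    "gen_cistromes",
    "gen_element_counts",
    "gen_expression_cohorts",
    "gen_motif_sequences",
    "write_fasta",
]

DEFAULT_CHROM_LENGTHS: Mapping[str, int] = {"chr1": 20_000_000, "chr2": 10_000_000}


@dataclass
class CistromeSimSpec:
    """Design of a multi-factor peak simulation with planted co-occupancy.

    ``sharing`` is a symmetric unit-diagonal matrix: ``sharing[i][j]`` is the
    probability that factor j binds an element whose base factor is i.
    """

    factors: tuple[str, ...] = ("A", "B", "C")
    n_elements_per_factor: int = 1000
    sharing: np.ndarray = field(default_factory=lambda: np.eye(3))
    centre_jitter_sd: float = 20.0
    peak_halfwidth: int = 150
    min_spacing: int = 1000
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    seed: int = 0

    def __post_init__(self) -> None:
        self.sharing = np.asarray(self.sharing, dtype=float)
        k = len(self.factors)
        if self.sharing.shape != (k, k):
            raise ValueError("sharing matrix shape must match factor count")
        if not np.allclose(self.sharing, self.sharing.T):
            raise ValueError("sharing matrix must be symmetric")
        if not np.allclose(np.diag(self.sharing), 1.0):
            raise ValueError("sharing matrix must have unit diagonal")
        if ((self.sharing < 0) | (self.sharing > 1)).any():
            raise ValueError("sharing probabilities must lie in [0, 1]")
        if self.centre_jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        if self.peak_halfwidth <= 0 or self.min_spacing <= 0:
            raise ValueError("halfwidth and spacing must be positive")
        if min(self.chrom_lengths.values()) <= 0:
            raise ValueError("chromosome lengths must be positive")


@dataclass
class CohortSimSpec:
    """Design of the multi-cohort expression simulation behind the quadrant
    analysis: planted quadrant-specific genes, survival and mutation effects."""

    n_datasets: int = 9
    n_samples: int = 50  # ABC-class samples per cohort
    n_genes: int = 10_000
    n_planted_per_direction: int = 50
    effect_size: float = 1.5  # log2 units
    noise_sd: float = 0.7  # log2 units
    hazard_ratio: float = 0.3  # applied to the SPIBhigh_BATFlow quadrant
    mutation_enrichment_odds: float = 6.0
    baseline_mutation_rate: float = 0.3
    baseline_median_survival: float = 30.0  # months
    censoring_time: float = 120.0  # months of follow-up
    on_small_quadrant: str = "regenerate"  # or "fail"
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.n_planted_per_direction > self.n_genes:
            raise ValueError("n_planted_per_direction must be <= n_genes / 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.baseline_mutation_rate <= 1:
            raise ValueError("baseline_mutation_rate must lie in [0, 1]")
        if self.on_small_quadrant not in {"regenerate", "fail"}:
            raise ValueError("on_small_quadrant must be 'regenerate' or 'fail'")


# ---------------------------------------------------------------------------
# Gene models

def gen_gene_models(n_genes: int, chrom_lengths: Mapping[str, int], seed: int,
                    body_length_range: tuple[int, int] = (2_000, 20_000),
                    min_gap: int = 1_000) -> list[GeneModel]:
    """Non-overlapping gene bodies on both strands, deterministic per seed.

    Genes are laid into disjoint slots of ``max body length + min_gap`` so
    bodies are pairwise disjoint by construction; raises when the genome
    cannot hold ``n_genes`` such slots.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    lo, hi = body_length_range
    slot = hi + min_gap
    chroms = sorted(chrom_lengths)
    slots = [(c, s) for c in chroms for s in range(chrom_lengths[c] // slot)]
    if len(slots) < n_genes:
        raise ValueError(
            f"genome too small: {len(slots)} slots of {slot} bp for {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(slots), size=n_genes, replace=False)
    chosen.sort()
    genes = []
    for i, idx in enumerate(chosen):
        chrom, s = slots[idx]
        length = int(rng.integers(lo, hi + 1))
        start = s * slot + int(rng.integers(0, hi - length + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end - 1
        genes.append(GeneModel(f"G{i:05d}", f"G{i:05d}", chrom, strand, tss, start, end))
    return genes


# ---------------------------------------------------------------------------
# Cistromes

def _place_elements(n: int, chrom_lengths: Mapping[str, int], min_spacing: int,
                    rng: np.random.Generator, margin: int) -> list[tuple[str, int]]:
    """Element centres on a min_spacing grid: guaranteed pairwise spacing."""
    chroms = sorted(chrom_lengths)
    slots = [
        (c, s) for c in chroms
        for s in range(margin // min_spacing + 1,
                       (chrom_lengths[c] - margin) // min_spacing)
    ]
    if len(slots) < n:
        raise ValueError(f"genome too small for {n} elements at spacing {min_spacing}")
    chosen = sorted(rng.choice(len(slots), size=n, replace=False))
    return [(slots[i][0], slots[i][1] * min_spacing) for i in chosen]


def gen_cistromes(spec: CistromeSimSpec) -> tuple[dict[str, Cistrome], pd.DataFrame]:
    """Simulated cistromes plus the element->factor membership truth table.

    Each latent element belongs to a base factor (always bound there); every
    other factor binds with probability ``sharing[base, other]``.  Bound
    peaks get centre = element centre + round(Normal(0, jitter sd)), clipped
    to keep the peak inside the chromosome.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.factors)
    n_total = k * spec.n_elements_per_factor
    margin = spec.peak_halfwidth + int(6 * spec.centre_jitter_sd) + 1
    positions = _place_elements(n_total, spec.chrom_lengths, spec.min_spacing, rng, margin)
    base = np.repeat(np.arange(k), spec.n_elements_per_factor)
    rng.shuffle(base)

    membership = np.zeros((n_total, k), dtype=bool)
    for e in range(n_total):
        for j in range(k):
            p = spec.sharing[base[e], j]
            membership[e, j] = (j == base[e]) or (rng.random() < p)

    peaks: dict[str, list[Peak]] = {f: [] for f in spec.factors}
    rows = []
    for e, (chrom, centre) in enumerate(positions):
        length = spec.chrom_lengths[chrom]
        for j, factor in enumerate(spec.factors):
            if not membership[e, j]:
                continue
            jitter = int(round(rng.normal(0.0, spec.centre_jitter_sd))) if spec.centre_jitter_sd else 0
            c = int(np.clip(centre + jitter, spec.peak_halfwidth, length - spec.peak_halfwidth - 1))
            peaks[factor].append(Peak(
                chrom, c - spec.peak_halfwidth, c + spec.peak_halfwidth + 1, c,
                score=float(np.round(rng.lognormal(3.0, 0.5), 3)),
                name=f"e{e}_{factor}",
            ))
        rows.append({
            "element_id": f"e{e}", "chrom": chrom, "centre": centre,
            "base_factor": spec.factors[base[e]],
            **{f: bool(membership[e, j]) for j, f in enumerate(spec.factors)},
        })
    truth = pd.DataFrame(rows).set_index("element_id")
    cistromes = {f: Cistrome(f, peaks[f]) for f in spec.factors}
    return cistromes, truth


def truth_signatures(truth: pd.DataFrame, factors: Sequence[str]) -> pd.Series:
    """Underscore-joined occupancy signature per element from a truth table."""
    return truth.apply(
        lambda row: "_".join(sorted(f for f in factors if row[f])), axis=1
    )


# ---------------------------------------------------------------------------
# Element counts

def gen_element_counts(truth: pd.DataFrame, factors: Sequence[str],
                       depletion_map: Mapping[str, float], library_size: float,
                       seed: int, strength_sigma: float = 0.5,
                       ) -> ElementCountTable:
    """Poisson control/knockdown counts per element with planted depletion.

    Element strengths are lognormal and scaled so control counts total about
    ``library_size``; knockdown means are the control means multiplied by the
    retained-signal fraction of the element's occupancy signature (default 1
    = unaffected).  Library sizes reported for normalisation are the nominal
    design depths for both arms, so log2 fold changes read out the retained
    fraction directly.
    """
    if truth.empty:
        raise ValueError("empty truth table")
    for sig, frac in depletion_map.items():
        if not 0 < frac <= 1:
            raise ValueError(f"retained fraction for {sig!r} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sigs = truth_signatures(truth, factors)
    strengths = rng.lognormal(0.0, strength_sigma, size=len(truth))
    strengths *= library_size / strengths.sum()
    retained = np.array([depletion_map.get(s, 1.0) for s in sigs])
    control = rng.poisson(strengths)
    kd = rng.poisson(strengths * retained)
    return ElementCountTable(
        element_ids=list(truth.index),
        signatures=list(sigs),
        control_counts=control.astype(float),
        kd_counts=kd.astype(float),
        library_sizes=(library_size, library_size),
    )


# ---------------------------------------------------------------------------
# Expression cohorts

def _quadrant_of(a_high: np.ndarray, b_high: np.ndarray) -> np.ndarray:
    labels = np.empty(len(a_high), dtype=object)
    labels[a_high & ~b_high] = "SPIBhigh_BATFlow"
    labels[a_high & b_high] = "SPIBhigh_BATFhigh"
    labels[~a_high & ~b_high] = "SPIBlow_BATFlow"
    labels[~a_high & b_high] = "SPIBlow_BATFhigh"
    return labels


def _rank_high(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    high = np.zeros(len(values), dtype=bool)
    high[order[len(values) - len(values) // 2:]] = True
    return high


def gen_expression_cohorts(spec: CohortSimSpec,
                           ) -> tuple[list[ExpressionDataset], dict[str, list[str]]]:
    """Simulated expression cohorts with planted quadrant structure.

    Returns the datasets and the truth lists of planted genes per direction
    (``up_in_SPIBhigh_BATFlow`` and ``up_in_SPIBlow_BATFhigh``).  Planted
    genes receive a +effect_size mean shift in their quadrant's samples only.
    Survival is exponential with the planted hazard ratio in the
    SPIBhigh/BATFlow quadrant and administrative censoring at the follow-up
    horizon; mutation status is Bernoulli with the planted odds multiplier in
    that quadrant.
    """
    n_up = spec.n_planted_per_direction
    gene_ids = ["SPIB", "BATF", "IRF4"] + [f"G{i:05d}" for i in range(spec.n_genes - 3)]
    planted_up = gene_ids[3:3 + n_up]
    planted_down = gene_ids[3 + n_up:3 + 2 * n_up]
    truth = {
        "up_in_SPIBhigh_BATFlow": planted_up,
        "up_in_SPIBlow_BATFhigh": planted_down,
    }
    master = np.random.default_rng(spec.seed)
    baseline = master.normal(7.0, 1.0, size=len(gene_ids))

    p0 = spec.baseline_mutation_rate
    odds1 = (p0 / (1 - p0)) * spec.mutation_enrichment_odds if p0 < 1 else np.inf
    p1 = odds1 / (1 + odds1) if np.isfinite(odds1) else 1.0
    lam0 = np.log(2) / spec.baseline_median_survival

    datasets: list[ExpressionDataset] = []
    for d in range(spec.n_datasets):
        for attempt in range(20):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, d, attempt]))
            n = spec.n_samples
            spib = rng.normal(0.0, 1.0, n)
            batf = rng.normal(0.0, 1.0, n)
            quadrant = _quadrant_of(_rank_high(spib), _rank_high(batf))
            counts = pd.Series(quadrant).value_counts()
            if counts.reindex([
                "SPIBhigh_BATFlow", "SPIBhigh_BATFhigh",
                "SPIBlow_BATFlow", "SPIBlow_BATFhigh",
            ]).fillna(0).min() >= 3:
                break
            if spec.on_small_quadrant == "fail":
                raise RuntimeError(
                    f"dataset {d}: a quadrant has fewer than 3 samples"
                )
        else:
            raise RuntimeError(f"dataset {d}: could not populate all quadrants")

        mat = baseline[:, None] + rng.normal(0.0, spec.noise_sd, (len(gene_ids), n))
        mat[0] = 8.0 + spib  # SPIB marker expression
        mat[1] = 8.0 + batf  # BATF marker expression
        in_q1 = quadrant == "SPIBhigh_BATFlow"
        in_q4 = quadrant == "SPIBlow_BATFhigh"
        mat[3:3 + n_up, in_q1] += spec.effect_size
        mat[3 + n_up:3 + 2 * n_up, in_q4] += spec.effect_size

        hazard = np.where(in_q1, lam0 * spec.hazard_ratio, lam0)
        t = rng.exponential(1.0 / hazard)
        event = (t <= spec.censoring_time).astype(int)
        os_time = np.minimum(t, spec.censoring_time)

        p_mut = np.where(in_q1, p1, p0)
        mutated = rng.random(n) < p_mut
        variant = np.where(rng.random(n) < 0.8, "L265P", "other")
        myd88 = np.where(mutated, variant, "wild_type")

        samples = [f"D{d}_S{i:03d}" for i in range(n)]
        matrix = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene"), columns=samples)
        ann = pd.DataFrame(
            {
                "class": "ABC",
                "os_time": np.round(os_time, 3),
                "os_event": event,
                "myd88": myd88,
            },
            index=pd.Index(samples, name="sample"),
        )
        datasets.append(ExpressionDataset(f"sim{d}", matrix.round(4), ann))
    return datasets, truth


# ---------------------------------------------------------------------------
# Motif sequences

def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC_CODES[c])) for c in pattern.upper())


def gen_motif_sequences(patterns: Sequence[MotifPattern], n_seq: int, seq_len: int,
                        embeddings: Sequence[tuple[int, str, int, str | None]],
                        gc: float = 0.4, seed: int = 0,
                        ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Random sequences with literal IUPAC instantiations embedded.

    ``embeddings`` is a list of (sequence index, pattern name, position,
    strand) tuples; strand ``None`` is randomised.  Returns named sequences
    and a truth table (seq, pattern, pos, strand, instance).
    """
    by_name = {p.name: p for p in patterns}
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = [
        "".join(rng.choice(list("ACGT"), size=seq_len, p=probs)) for _ in range(n_seq)
    ]
    rows = []
    for seq_idx, name, pos, strand in embeddings:
        pat = by_name[name]
        if len(pat.iupac) > seq_len:
            raise ValueError(f"pattern {name} longer than sequence length {seq_len}")
        if pos + len(pat.iupac) > seq_len:
            raise ValueError(f"embedding of {name} at {pos} exceeds sequence length")
        if strand is None:
            strand = "+" if rng.random() < 0.5 else "-"
        instance = _instantiate(pat.iupac, rng)
        planted = instance if strand == "+" else reverse_complement(instance)
        s = seqs[seq_idx]
        seqs[seq_idx] = s[:pos] + planted + s[pos + len(planted):]
        rows.append({"seq": f"seq{seq_idx}", "pattern": name, "pos": pos,
                     "strand": strand, "instance": instance})
    records = [(f"seq{i}", s) for i, s in enumerate(seqs)]
    truth = pd.DataFrame(rows, columns=["seq", "pattern", "pos", "strand", "instance"])
    return records, truth


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
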