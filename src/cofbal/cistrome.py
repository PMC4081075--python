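"""Peak I/O, multi-factor overlap clustering, occupancy signatures and motif counting.

A *cistrome* is the genome-wide set of binding sites (peaks) of one
transcription factor in one cell state.  The central operation here merges
the peaks of several cistromes into regulatory elements: pooled peaks are
scanned left to right and any peak whose centre lies strictly within the
clustering radius (default 250 bp) of the current cluster's *index peak*
centre joins that cluster; the first peak that does not founds the next
cluster and becomes its index.  Each merged element carries an *occupancy
signature* — the set of factors with a member peak — such as
``IRF4_SPIB_PU.1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "Peak",
    "Cistrome",
    "OverlapCluster",
    "GeneModel",
    "MotifPattern",
    "DEFAULT_MOTIFS",
    "read_peaks",
    "write_peaks",
    "cluster_peaks",
    "occupancy_signature_counts",
    "signature_label",
    "centre_distance_profile",
    "assign_peaks_to_genes",
    "promoter_fraction",
    "count_motif_matches",
    "iupac_match",
]

IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Peak:
    """A called binding event on BED conventions (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    centre: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if not (self.start <= self.centre < self.end):
            raise ValueError(
                f"centre {self.centre} outside [{self.start}, {self.end})"
            )


@dataclass
class Cistrome:
    """All peaks of one factor in one condition, sorted by (chrom, centre)."""

    factor: str
    peaks: list[Peak]
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.factor:
            raise ValueError("factor label must be nonempty")
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.centre))

    @property
    def label(self) -> str:
        return f"{self.factor}.{self.condition}" if self.condition else self.factor

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class OverlapCluster:
    """A merged regulatory element: member peaks within radius of the index centre."""

    cluster_id: int
    index_peak: Peak
    members: list[tuple[str, Peak]]

    @property
    def signature(self) -> frozenset[str]:
        return frozenset(label for label, _ in self.members)

    @property
    def chrom(self) -> str:
        return self.index_peak.chrom


def signature_label(signature: Iterable[str]) -> str:
    """Canonical underscore-joined label, e.g. ``IRF4_SPIB``."""
    return "_".join(sorted(signature))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.body_start < self.body_end:
            raise ValueError("body_start must be < body_end")
        expected = self.body_start if self.strand == "+" else self.body_end - 1
        if self.tss != expected:
            raise ValueError("TSS inconsistent with strand and gene body")


@dataclass(frozen=True)
class MotifPattern:
    """IUPAC consensus pattern, optionally scanned on both strands."""

    name: str
    iupac: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty pattern")
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC letters {sorted(bad)} in {self.name}")


#: Default consensus elements through which IRF4 binds with its ETS (SPIB/PU.1)
#: or AP1 (BATF) partners.  Editable config values, not fitted matrices.
DEFAULT_MOTIFS: tuple[MotifPattern, ...] = (
    MotifPattern("EICE", "GGAARTGAAAC"),
    MotifPattern("AICE1", "TTTCNNNNTGASTCA"),
    MotifPattern("AICE2", "GAAATGASTCA"),
    MotifPattern("AP1", "TGASTCA"),
    MotifPattern("ETS", "RGGAAR"),
)


# ---------------------------------------------------------------------------
# Peak I/O

def _bed_centre(start: int, end: int) -> int:
    return (start + end) // 2


def read_peaks(path: str | Path, dialect: str = "bed6",
               factor: str | None = None, condition: str = "") -> Cistrome:
    """Read a BED6 or ENCODE narrowPeak file into a :class:`Cistrome`.

    narrowPeak column 10 is the summit offset from ``start``; ``-1`` means no
    summit was called and the interval midpoint is used.  BED6 centres are the
    floored interval midpoint.
    """
    path = Path(path)
    if dialect not in {"bed6", "narrowPeak"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                if dialect == "narrowPeak":
                    if len(fields) < 10:
                        raise ValueError("narrowPeak needs 10 columns")
                    score = float(fields[6])  # signalValue
                    summit = int(fields[9])
                    centre = _bed_centre(start, end) if summit == -1 else start + summit
                else:
                    centre = _bed_centre(start, end)
                peaks.append(Peak(chrom, start, end, centre, score, name))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
    return Cistrome(factor or path.stem, peaks, condition)


def write_peaks(cistrome: Cistrome, path: str | Path, dialect: str = "bed6") -> None:
    """Write peaks back out; round-trips all Peak fields for both dialects."""
    with open(path, "w") as fh:
        for p in cistrome.peaks:
            if dialect == "bed6":
                # BED6 has no summit column: centre must be recomputable as midpoint
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\n")
            elif dialect == "narrowPeak":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t{p.score:g}"
                    f"\t-1\t-1\t{p.centre - p.start}\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Overlap clustering

def cluster_peaks(cistromes: Sequence[Cistrome], radius: int = 250) -> list[OverlapCluster]:
    """Greedy left-to-right merge of pooled peaks into overlap clusters.

    Pooled peaks are visited in (chrom, centre, -score, label) order.  A peak
    whose centre is strictly less than ``radius`` bp from the open cluster's
    index-peak centre joins it; otherwise it founds a new cluster and becomes
    the index.  The partition covers every input peak exactly once and is
    independent of the order the cistromes are supplied in.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pooled = [
        (p.chrom, p.centre, -p.score, c.label, p)
        for c in cistromes for p in c.peaks
    ]
    pooled.sort(key=lambda t: t[:4])
    clusters: list[OverlapCluster] = []
    for chrom, centre, _negscore, label, peak in pooled:
        if (
            clusters
            and clusters[-1].index_peak.chrom == chrom
            and abs(centre - clusters[-1].index_peak.centre) < radius
        ):
            clusters[-1].members.append((label, peak))
        else:
            clusters.append(OverlapCluster(len(clusters), peak, [(label, peak)]))
    return clusters


def occupancy_signature_counts(clusters: Sequence[OverlapCluster]) -> dict[str, int]:
    """Count clusters per exact factor-set signature (labels underscore-joined)."""
    counts: dict[str, int] = {}
    for cl in clusters:
        key = signature_label(cl.signature)
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Distance profiles

@dataclass
class DistanceProfile:
    """Signed reference-to-nearest-query centre distances within a window."""

    distances: np.ndarray
    window: int
    n_reference: int
    fraction_within_50: float

    def histogram(self, bin_width: int = 10) -> tuple[np.ndarray, np.ndarray]:
        edges = np.arange(-self.window, self.window + bin_width, bin_width)
        counts, edges = np.histogram(self.distances, bins=edges)
        return counts, edges


def centre_distance_profile(reference: Cistrome, query: Cistrome,
                            window: int = 500) -> DistanceProfile:
    """For each reference peak, the signed distance to the nearest query centre.

    Distances are query minus reference (positive = query downstream in
    genome coordinates) and only reported when |d| <= window.  Also reports
    the fraction of reference peaks with a query centre within 50 bp, the
    summary used to describe tightly co-occupied sites.
    """
    if not reference.peaks or not query.peaks:
        raise ValueError("both cistromes must be nonempty")
    by_chrom: dict[str, np.ndarray] = {}
    for p in query.peaks:
        by_chrom.setdefault(p.chrom, []).append(p.centre)  # type: ignore[arg-type]
    by_chrom = {c: np.asarray(v) for c, v in by_chrom.items()}

    dists = []
    n_within_50 = 0
    for p in reference.peaks:
        centres = by_chrom.get(p.chrom)
        if centres is None:
            continue
        i = np.searchsorted(centres, p.centre)
        cand = centres[max(0, i - 1):i + 1]
        d = cand[np.argmin(np.abs(cand - p.centre))] - p.centre
        if abs(d) <= 50:
            n_within_50 += 1
        if abs(d) <= window:
            dists.append(d)
    return DistanceProfile(
        distances=np.asarray(dists, dtype=int),
        window=window,
        n_reference=len(reference.peaks),
        fraction_within_50=n_within_50 / len(reference.peaks),
    )


# ---------------------------------------------------------------------------
# Gene assignment

def _gene_windows(gene: GeneModel, mode: str, flank: int) -> list[tuple[int, int]]:
    """Half-open coordinate windows in which a peak centre maps to the gene."""
    if mode == "upstream5kb_intragenic":
        body = (gene.body_start, gene.body_end)
        if gene.strand == "+":
            upstream = (gene.tss - 5000, gene.tss)
        else:
            # upstream of a '-' gene lies at coordinates greater than the TSS
            upstream = (gene.tss + 1, gene.tss + 5001)
        return [body, upstream]
    if mode == "tss_flank":
        return [(gene.tss - flank, gene.tss + flank + 1)]
    raise ValueError(f"unknown mode {mode!r}")


def assign_peaks_to_genes(cistrome: Cistrome, genes: Sequence[GeneModel],
                          mode: str = "upstream5kb_intragenic",
                          flank: int = 2000) -> dict[str, list[Peak]]:
    """Map genes to the peaks whose centre falls in their regulatory window.

    ``upstream5kb_intragenic``: centre within 5 kb upstream of the TSS
    (strand-aware) or anywhere in the gene body.  ``tss_flank``: centre within
    ``tss +/- flank``.  A peak may map to several genes.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for lo, hi in _gene_windows(g, mode, flank):
            lo = max(lo, 0)
            if lo < hi:
                tree.addi(lo, hi, g.gene_id)
    out: dict[str, list[Peak]] = {}
    for p in cistrome.peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in tree.at(p.centre):
            out.setdefault(iv.data, []).append(p)
    return out


def promoter_fraction(peaks: Cistrome | Sequence[OverlapCluster],
                      genes: Sequence[GeneModel],
                      promoter_flank: int = 2000) -> float:
    """Fraction of peaks (or cluster index peaks) centred within a promoter.

    A promoter is ``tss +/- promoter_flank`` of any gene.
    """
    if isinstance(peaks, Cistrome):
        items = peaks.peaks
    else:
        items = [cl.index_peak for cl in peaks]
    if not items:
        raise ValueError("empty peak set")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(g.tss - promoter_flank, 0)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, g.tss + promoter_flank + 1, g.gene_id)
    n_hit = sum(
        1 for p in items
        if p.chrom in trees and trees[p.chrom].overlaps_point(p.centre)
    )
    return n_hit / len(items)


# ---------------------------------------------------------------------------
# Consensus motif scanning

def iupac_match(seq: str, pattern: str) -> bool:
    """Exact IUPAC consensus match; any non-ACGT genome base is a mismatch."""
    if len(seq) != len(pattern):
        return False
    for base, code in zip(seq.upper(), pattern.upper()):
        if base not in IUPAC_CODES[code]:
            return False
    return True


def _scan_one(seq: str, pattern: MotifPattern) -> list[tuple[int, str]]:
    """All (offset, strand) hits of a consensus within ``seq``."""
    hits = []
    pats = [(pattern.iupac.upper(), "+")]
    if pattern.both_strands:
        pats.append((reverse_complement(pattern.iupac), "-"))
    L = len(pattern.iupac)
    for pat, strand in pats:
        for off in range(len(seq) - L + 1):
            if iupac_match(seq[off:off + L], pat):
                hits.append((off, strand))
    return hits


def open_genome(path: str | Path):
    """Open a FASTA file for random access (indexed via pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path))


def _get_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end]; accepts a dict or a pyfaidx.Fasta."""
    contig = genome[chrom]
    length = len(contig)
    if start < 0 or end > length:
        raise ValueError(
            f"region {chrom}:{start}-{end} outside contig bounds (len {length})"
        )
    return str(contig[start:end]).upper()


def count_motif_matches(regions, genome, patterns: Sequence[MotifPattern] = DEFAULT_MOTIFS,
                        window: int = 100,
                        suppress_within: Mapping[str, str] | None = None):
    """Count consensus motif hits within ``centre +/- window`` of each region.

    ``regions`` is a Cistrome or a sequence of Peaks/OverlapClusters; ``genome``
    a chrom->sequence mapping or an indexed FASTA (pyfaidx).  ``suppress_within``
    maps a pattern name to a container pattern name: hits of the former whose
    footprint overlaps a hit of the latter are not counted (e.g. an ETS match
    inside an EICE is not an independent ETS site).

    Returns a pandas DataFrame of hit counts, regions x patterns.
    """
    import pandas as pd

    if isinstance(genome, (str, Path)):
        genome = open_genome(genome)
    if isinstance(regions, Cistrome):
        items = regions.peaks
    else:
        items = [r.index_peak if isinstance(r, OverlapCluster) else r for r in regions]
    suppress_within = suppress_within or {}
    names = [p.name for p in patterns]
    for inner, outer in suppress_within.items():
        if inner not in names or outer not in names:
            raise ValueError(f"suppression pair ({inner}, {outer}) not among patterns")
    rows = np.zeros((len(items), len(patterns)), dtype=int)
    index = []
    for i, p in enumerate(items):
        index.append(f"{p.chrom}:{p.centre}")
        seq = _get_sequence(genome, p.chrom, p.centre - window, p.centre + window + 1)
        hits = {pat.name: _scan_one(seq, pat) for pat in patterns}
        for j, pat in enumerate(patterns):
            kept = hits[pat.name]
            container = suppress_within.get(pat.name)
            if container is not None:
                c_len = len(next(q for q in patterns if q.name == container).iupac)
                spans = [(off, off + c_len) for off, _ in hits[container]]
                p_len = len(pat.iupac)
                kept = [
                    (off, s) for off, s in kept
                    if not any(off < hi and off + p_len > lo for lo, hi in spans)
                ]
            rows[i, j] = len(kept)
    return pd.DataFrame(rows, index=index, columns=names)
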