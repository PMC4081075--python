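# Methods

This note documents the statistical procedures `cofbal` implements, the
parameters that matter, the synthetic data model used to exercise them, and
the design decisions taken where more than one reasonable convention exists.

## Overlap clustering and occupancy signatures

Peaks from all supplied cistromes are pooled and visited in
(chrom, centre, −score, label) order. A peak whose centre is strictly less
than the clustering radius (default **250 bp**) from the open cluster's
index-peak centre joins that cluster; otherwise it founds a new cluster and
becomes its index. The partition covers every peak exactly once and, because
the scan order is defined on the pooled set, is independent of the order in
which cistromes are supplied.

Two conventions needed fixing:

* *Index-peak selection.* "Index peak" is under-determined by a verbal rule
  alone. We process pooled peaks left to right with ties broken by higher
  score then label; the first peak that does not join the open cluster
  founds the next one and becomes its index. This is deterministic and
  equivalent to a single left-to-right scan. Note the greedy chain
  consequence: centres 100, 300, 500 yield clusters {100, 300} and {500},
  because 500 is 400 bp from the index at 100.
* *Strictness.* The inequality is strict: two centres exactly 250 bp apart
  fall in separate clusters.

Coordinates are BED throughout (0-based, half-open). narrowPeak summit
offsets are converted to absolute centres; a summit of −1 falls back to the
interval midpoint, as does BED6 input.

A cluster's *occupancy signature* is the set of source cistrome labels among
its members, serialised in sorted order with underscores (`IRF4_SPIB`).
Signature counts over all clusters sum to the cluster count by construction.

## Gene assignment and promoter fractions

Two assignment geometries are provided and must be chosen explicitly:

* `upstream5kb_intragenic` — peak centre within 5 kb upstream of the TSS on
  the strand-appropriate side (for a − strand gene "upstream" lies at
  coordinates greater than the TSS), or anywhere inside the gene body;
* `tss_flank` — centre within TSS ± flank (default 2 kb).

The promoter fraction of a peak set uses TSS ± 2 kb by default; the promoter
definition is configurable since reasonable analyses differ here.

## Consensus motif scanning

Motifs are IUPAC consensus strings (defaults: EICE `GGAARTGAAAC`, AICE-1
`TTTCNNNNTGASTCA`, AICE-2 `GAAATGASTCA`, AP1 `TGASTCA`, ETS `RGGAAR`),
matched exactly within centre ± 100 bp of each region, on both strands when
flagged. Any non-ACGT genome base is a mismatch. Position-weight-matrix
scoring is deliberately out of scope — the scanner answers "how many
consensus matches near the peak centre", the question the downstream
summaries ask. An optional suppression map drops hits of one pattern whose
footprint overlaps a hit of a container pattern (e.g. an ETS core inside an
EICE is not an independent ETS site). Note that the AP1 heptamer is
reverse-palindromic, so its strand is unobservable; strand contracts are
tested with non-palindromic patterns.

## Binned occupancy correlation

Each cistrome is reduced to a sparse binned track (default **100 bp** bins);
in presence mode a bin is 1 when any peak interval overlaps it, and a signal
mode sums peak scores instead. Pearson correlation is computed over the
**union of occupied bins** by default: including the shared empty genome
would inflate every pairwise r towards 1. An `all_bins` mode is provided for
sensitivity analysis. One consequence of the union domain is that two
disjoint binary tracks of equal occupancy give r = −1, and a track constant
over the domain has undefined r, reported as NaN with a warning rather than
silently zero. Hierarchical ordering uses distance 1 − r with average
linkage (complete available); NaN entries are rejected.

## Knockdown differential occupancy

Per element, log2FC = log2(((kd + c)/N_kd) / ((ctl + c)/N_ctl)) with
pseudocount c = 1 and library sizes N as sequencing-depth normalisers
(reads/million style). Classes are the occupancy signatures; summaries are
median and IQR, matching a box-plot presentation, and class contrasts use
the two-sided Mann–Whitney U test on per-element log2FC — distribution-free
and robust to the heavy right tail of element strengths.

The *stable subset* is the set of elements with linear fold change inside
(1/1.4, 1.4); its enrichment for a focus signature against all elements is
an exact hypergeometric test.

At a mean element coverage of ~100 reads, the pseudocount biases a true 0.4
retained fraction from log2 0.4 = −1.32 to about −1.30; recovery tests use a
±0.15 log2 tolerance that absorbs this known attenuation plus Poisson noise.

## Quadrants, differential expression, meta-profiles

Quadrant assignment median-splits each marker gene independently on ranks:
samples are ordered by expression with ties broken by stable sample order,
the top ⌊n/2⌋ are "high", and with odd n the middle sample goes to "low" so
that "high" is strictly the top half. The partition of class-filtered
samples is exhaustive and exclusive, and the two split sizes differ by at
most one.

Per-cohort differential expression between the extreme quadrants uses
Welch's unequal-variance t-test on log2 values (Mann–Whitney optional),
significance at unadjusted p < 0.05, log2FC = mean(x) − mean(y) with
positive values meaning higher in the first group. A gene with zero variance
in both groups gets p = 1 when the means agree (flagged degenerate) and
p = 0 in the perfectly separated limit.

The consensus *meta-profile* for a direction contains the genes significant
with that sign in at least **4** cohorts. No additional FDR layer is applied
at this step: the cross-cohort replication requirement is the multiplicity
control. The gene universe is the intersection of gene ids across cohorts so
support counts share a denominator; genes qualifying in both directions are
conflicts, excluded from both and reported. Raising `min_support` can only
shrink a profile (monotonicity, under test).

Knockdown expression lists use Welch tests with BH adjustment: list A =
adjusted p < 0.05, list B = list A further restricted to linear
|FC| ≥ 1.5.

## Enrichment statistics

* **Hypergeometric test** — exact tail sums via the scipy hypergeometric
  survival/cumulative functions; over-tail P(X ≥ k), under-tail P(X ≤ k).
  Verified against exact rational enumeration for all margins N ≤ 25.
* **BH FDR** — Benjamini–Hochberg step-up (the correction method is
  pluggable in principle; BH is the conventional default).
* **Bootstrap category z** — the null draws query-sized sets uniformly
  without replacement from the universe. The per-category overlap counts of
  such draws are realised directly as multivariate-hypergeometric samples
  over the category partition, which is distributionally identical to
  drawing sets and counting, preserves cross-category dependence, and makes
  10^7 draws cheap. z = (observed − null mean)/null sd; the empirical
  two-sided p uses the (r + 1)/(n_iter + 1) estimator so it is never zero.
  The null moments converge to the closed forms nK/N and
  nK(N−K)(N−n)/(N²(N−1)), which is the auditable consequence of sampling
  without replacement. Default n_iter is 10^7; tests run at 10^5–10^6.
* **Signature-collection screening** — sets of ≥ 1000 genes are excluded
  before testing (strictly "less than 1000"), one hypergeometric test per
  surviving set, BH across the batch, sorted by q.
* **Proportion comparison** — Pearson chi-squared on the 2×2, df = 1, no
  continuity correction by default; a warning suggests an exact test when an
  expected cell falls below 1.

## Survival and mutation association

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
behind the module's own record/curve containers; with no censoring the KM
curve equals the empirical survival function exactly, and ties between
events and censorings at one instant are resolved events-first. The group
comparison is the standard log-rank chi-squared with df = groups − 1.

Mutation association builds, per quadrant, the 2×2 of (in-quadrant vs rest)
× (mutated vs not) and reports the one-sided Fisher exact enrichment p. The
default collapse rule reflects targeted L265P testing in the clinic:
non-L265P sequence changes count as wild type; a `drop` action handles
unknowns explicitly, and an unmapped status is an error rather than a silent
guess.

## Synthetic data model

The generators use the simplest distribution families with closed-form
checks — Gaussian log2 expression noise, Poisson read counts, exponential
survival — and every one takes an explicit seed (no global random state).

* *Cistromes.* Latent elements are placed on a minimum-spacing grid
  (default 1 kb = 4× the clustering radius, configurable) so truth clusters
  are unambiguous. A pairwise sharing matrix under-determines a joint
  binding law, so the model gives each element a *base factor* that always
  binds while every other factor binds with probability sharing[base,
  other]; this reproduces the intended marginals (sharing 0.8 ⇒ 80% of a
  factor's elements carry the partner's peak) and is what the truth table
  records. Peak centres are element centres plus rounded Gaussian summit
  jitter.
* *Element counts.* Lognormal element strengths scaled so the control arm
  totals the design library size (default mean coverage ≈ 100 reads per
  element), Poisson sampling per arm, knockdown means multiplied by the
  signature's retained fraction. The reported library sizes are the nominal
  design depths for both arms, not realised count sums: normalising to
  realised totals would let a genuine genome-wide depletion bias every
  class's fold change, including unaffected classes.
* *Expression cohorts.* Marker (SPIB/BATF) values are independent standard
  normals per sample; the planted quadrant is derived with the same
  median-split rule the analysis uses. Planted genes receive the mean shift
  in their quadrant's samples only. Survival is exponential with baseline
  median 30 months — a realistic order for aggressive lymphoma on
  chemoimmunotherapy — the planted hazard ratio applied in the
  SPIB^high/BATF^low quadrant, and administrative censoring at 120 months.
  Mutation status is Bernoulli at a 30% baseline (the rough prevalence of
  MYD88 mutation in the ABC class) with the planted odds multiplier in that
  quadrant; mutated samples are labelled L265P with probability 0.8, else
  "other". Cohorts whose quadrants fall below 3 samples are regenerated
  (or fail loudly, flag-controlled).
* *Motif sequences.* I.i.d. background at a given GC content; each
  embedding instantiates its IUPAC pattern literally at a known position
  and strand (reverse-strand embeddings insert the reverse complement).

What the generators do **not** emulate: raw sequencing reads and mapping
artefacts, cross-platform batch effects, correlated marker genes, copy-number
structure, non-exponential survival shapes, and probe-level microarray
effects. Passing recovery tests therefore demonstrate that the analysis
logic is correct under its own assumptions, not that those assumptions hold
for any particular public cohort.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at the study's design scale where that is cheap
(9 cohorts × 50 samples × 10,000 genes for meta-profile recovery; 500
elements per class for knockdown recovery; 100 per arm × 100 simulations for
log-rank power; 100 seeds for correlation-structure recovery; 1000 sequences
for the motif oracle) and at 10^5–10^6 draws for bootstrap moment checks,
with the full 10^7 iterations available behind the `bootstrap_iter`
parameter. Oracle-exactness checks (hypergeometric N ≤ 25, Fisher margins
≤ 15) enumerate their full grids.

## Known limitations

* Consensus matching treats all bases of a motif as equally informative; a
  PWM scanner would rank degenerate matches, at the cost of needing fitted
  matrices.
* The pipeline operates on gene-level expression; probe collapse is provided
  (max-mean) but probe re-annotation is out of scope.
* No automated cohort-outlier rule: dataset inclusion is explicit user
  configuration.
* Cox regression and covariate adjustment are out of scope; the clinical
  module answers the univariate subgroup questions only.
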