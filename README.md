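# cofbal

Co-occupancy and cofactor-balance analysis for transcription-factor genomics
in B-cell lymphoma.

## The problem

IRF4 is a central transcription factor of activated-B-cell-like diffuse large
B-cell lymphoma (ABC-DLBCL). Its regulatory output depends on which partner
it binds DNA with: ETS-family partners (SPIB, PU.1) at ETS/IRF composite
elements (EICE), or the AP1-family partner BATF at AP1/IRF composite elements
(AICE). `cofbal` implements, as a tested reusable pipeline, the analyses
needed to link cofactor genome occupancy to expression-defined tumour
subgroups:

* **Cistrome intersection** — ChIP-seq peaks of several factors are merged
  into regulatory elements by a greedy scan: any peak whose centre lies
  strictly within 250 bp of the current cluster's *index peak* centre joins
  the cluster. Each merged element carries an occupancy signature such as
  `IRF4_SPIB_PU.1`, and the signature census gives the Venn-style overlap of
  cistromes.
* **Genome-wide occupancy correlation** — binding landscapes reduced to
  100 bp binned tracks, compared by Pearson *r* over the union of occupied
  bins, ordered by hierarchical clustering on 1 − *r*.
* **Knockdown differential occupancy** — per-element log2 fold change of
  depth-normalised read counts between control and knockdown chromatin,
  summarised per occupancy class, with a "stable subset" (fold change < 1.4)
  tested for enrichment of a focus signature by the hypergeometric test.
* **Quadrant subgroups and meta-profiles** — ABC-class samples split into
  four quadrants by independent median splits of *SPIB* and *BATF*
  expression; differential expression between the two extreme quadrants at
  p < 0.05 per cohort; genes significant with a consistent sign in ≥ 4
  cohorts form the consensus *meta-profile* for each direction.
* **Enrichment statistics** — exact hypergeometric set enrichment with BH
  FDR, a bootstrap category z-score (query-sized draws without replacement
  from the universe), and 2×2 chi-squared / Fisher tests.
* **Clinical association** — Kaplan–Meier curves and log-rank tests of
  quadrant subgroups, and one-sided Fisher enrichment of mutations (e.g.
  MYD88-L265P) per quadrant.

A synthetic-data module generates every input the pipeline consumes —
multi-factor peak sets with planted co-occupancy and summit jitter, element
read counts with planted knockdown depletion, multi-cohort expression
matrices with planted quadrant, survival and mutation effects, and
motif-embedded sequences — so every stage is testable without downloads.

## Worked example

Simulate nine 50-sample cohorts with 40 planted genes per direction
(1.5 log2-unit effect, 0.7 noise sd, hazard ratio 0.3 in the
SPIB^high/BATF^low quadrant), then run the subgroup analysis:

```python
import numpy as np
from cofbal import synthetic as syn, subgroups as sub, clinical as clin

spec = syn.CohortSimSpec(n_datasets=9, n_samples=50, n_genes=2000,
                         n_planted_per_direction=40, seed=1)
datasets, truth = syn.gen_expression_cohorts(spec)

de = []
for ds in datasets:
    q = sub.assign_quadrants(ds)                      # median-split quadrants
    de.append(sub.differential_expression(
        ds, list(q.index[q == "SPIBhigh_BATFlow"]),
        list(q.index[q == "SPIBlow_BATFhigh"])))
up, down, conflicts = sub.consensus_meta_profile(de, min_support=4)
print(f"meta-profile sizes: {len(up)} up in SPIBhigh/BATFlow, "
      f"{len(down)} up in SPIBlow/BATFhigh")
planted = set(truth["up_in_SPIBhigh_BATFlow"])
print(f"planted genes recovered: {len(up.genes & planted)}/40")

ds, q = datasets[0], sub.assign_quadrants(datasets[0])
ann = ds.annotations
groups = {lab: [clin.SurvivalRecord(s, float(ann.loc[s, "os_time"]),
                                    int(ann.loc[s, "os_event"]))
                for s in q.index[q == lab]]
          for lab in ("SPIBhigh_BATFlow", "SPIBlow_BATFhigh")}
chi2, p, df = clin.logrank_test(groups)
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.4f}")
```

Output:

```
meta-profile sizes: 41 up in SPIBhigh/BATFlow, 41 up in SPIBlow/BATFhigh
planted genes recovered: 40/40
log-rank chi2 = 7.79, p = 0.0053
```

The meta-profiles recover all 40 planted genes per direction with one or two
chance entries, and the planted protective hazard ratio in the
SPIB^high/BATF^low quadrant is detected by the log-rank test in a single
50-sample cohort.

The `cofbal` CLI wraps the same library: `cofbal simulate
cistromes|cohorts|sequences` writes synthetic inputs, and `cofbal
cooccupancy|subgroups --config cfg.yaml` runs the two end-to-end workflows,
emitting TSV tables plus a reproducibility manifest of SHA-256 output
hashes.

## Layout

```
src/cofbal/
  synthetic.py    # generators for every pipeline input, with truth tables
  cistrome.py     # peak I/O, overlap clustering, signatures, motif scanning
  occupancy.py    # binned correlation, knockdown differential occupancy
  subgroups.py    # quadrants, DE, consensus meta-profiles, marker stats
  enrichment.py   # hypergeometric, BH FDR, bootstrap z, chi-squared, GMT I/O
  clinical.py     # Kaplan-Meier, log-rank, mutation association
  pipeline.py     # config-driven end-to-end workflows with manifests
  cli.py          # `cofbal` command line
docs/methods.md   # model, parameters, numerical choices, limitations
```
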