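# Methods

## Data model

The unit of analysis is a curated drug record: generic name, initial FDA
approval year (1949–2014 in the packaged catalog), mechanism-of-action
category (*cytotoxic* — mitotic/DNA-replication poisons — or *targeted* —
agents acting on a specific molecular target), the set of approved cancer
classes, the printed target tokens, and the delivery mode (*single*,
*combination*, or *both*). Cancer classes are the 33 canonical labels of the
cancer table; indications are validated against it at load time. Loading
fails loudly, naming the offending row, on unknown enum values, missing
columns, or unresolvable indications.

Target tokens are kept verbatim; `gene_targets` removes the five
mechanism-of-action phrases ("DNA synthesis", "RNA synthesis", "Protein
synthesis", "Unknown", "Biological"), matched case-insensitively, and
deduplicates. This is the single definition of "protein target" used by the
tripartite network, the shared-target index, and the genetics stage; on the
packaged catalog it gives 102 distinct targets for the 89 targeted drugs.
BCR-ABL is printed — and kept — as one fusion-target token; splitting it
would silently change the target count and every downstream degree.

The per-gene annotation table (subcellular location, family, subfamily) is a
reconstruction: the published classification reports only category counts,
so genes were assigned by domain knowledge such that every marginal count
matches the published table exactly (45 plasma membrane / 27 cytoplasm / 23
nucleus / 7 extracellular; 58 enzymes of which 28 tyrosine kinases; 27
receptors; 5 antigens; …). Analyses and tests assert only those marginals,
never a specific gene's cell within a family.

## Catalog statistics

Decade summaries use closed year intervals (default 1941–1990, 1991–2000,
2001–2010, 2011–2014; configurable). Percentages are rounded half-up to
whole percent, matching the precision of the curated tables.

Delivery trends are Pearson correlations between two annual count series —
drugs of a category per calendar year versus drugs with a delivery mode per
calendar year — over every year from the earliest to the latest approval,
zero-filled (66 years for the packaged catalog). The p-value is the
two-sided t transform. Constant series raise instead of returning NaN. With
this convention the targeted-vs-single correlation on the packaged catalog
is r = 0.93 (p ≈ 4 × 10⁻³⁰); the cytotoxic-vs-combination and
cytotoxic-vs-both correlations are sensitive to the year-window convention
and are only tested qualitatively.

## Networks

Both networks are undirected with typed nodes, and edges are associations,
not multiplicities (duplicate pairs collapse). The bipartite network has one
edge per approved (drug, indication); the tripartite network restricts to
targeted drugs and adds one edge per (drug, gene target). Degree is the
incident edge count; for tripartite drug nodes an edge-type filter yields
the target degree and cancer degree separately. Summaries report mean, min,
max, and the sample skewness g1 (defined as 0 for constant or singleton
degree vectors, where g1 is undefined).

Degree-bin breakdowns take predicates (`"=1"`, `"2-9"`, `">=10"`); the bins
must partition the observed degrees — overlap or a gap raises rather than
silently mis-tallying.

## Two-sample Kolmogorov–Smirnov convention

The K-S statistic is the maximum ECDF gap evaluated at every observed point
(ties allowed; degree and frequency data are heavily tied integers/ratios).
P-values are the classic asymptotic forms with effective size
en = m·n/(m+n): two-sided P = Q_KS(√en · D); one-sided
P = exp(−2·en·D±²) — the conventions of R's `ks.test` with `exact = FALSE`.
These differ from scipy's `ks_2samp(method="asymp")`, which applies further
small-sample refinements; the classic forms are used because they are what
degree-comparison results in this literature reproduce. On the packaged
catalog the cytotoxic-vs-targeted degree comparison gives D = 0.213 with
one-sided P = 0.0378 (two-sided 0.0755). An exhaustive ECDF-gap enumeration
serves as the independent oracle for the statistic in tests.

## Common-target repurposing

For every ordered pair (A, B) of distinct targeted drugs with
gene_targets(A) ∩ gene_targets(B) ≠ ∅ and every approved indication D of B
with (A, D) not approved anywhere in the catalog, the pair (A, D) is
proposed. Proposals are deduplicated on (drug, cancer) with shared targets
and source drugs merged — provenance is pooled, never multiplied. Cytotoxic
drugs can neither receive nor donate indications, and drugs sharing only a
mechanism phrase are not linked. The production predictor uses a
target→drugs index; an exhaustive triple-loop enumerator with no indexing
shortcuts is kept as a separate code path and asserted equal on random
catalogs (and inside the acceptance script before anything is reported).

Trial support: each prediction is annotated from a (drug, cancer
abbreviation, n_trials) table. Drug names resolve case-insensitively with a
unique-prefix fallback (so "Sorafenib" finds "Sorafenib tosylate");
predictions missing from the table count as 0 trials with a warning, and
table pairs that are not predictions are surfaced in
`unmatched_trial_pairs` rather than dropped. On the packaged tables the
procedure yields 133 predictions over 52 drugs and 16 cancer types, 115 of
which have ≥1 trial; the table itself contains one already-approved pair
(axitinib–kidney cancer) and lacks one forced prediction (afatinib–breast
cancer), which is why 115 — not 116 of 133 — annotated predictions are
supported. The discrepancy is reported, not reconciled.

## Target genetics

The gene universe is partitioned into target∩cancer genes, target-only,
cancer-only-with-mutation-data, and everything else with mutation data; the
four sets are asserted pairwise disjoint. Overlap enrichment is the
upper-tail hypergeometric probability P(X ≥ k) — for the packaged counts
(k=32 of n=102 targets, K=594 cancer genes, N=20,729 protein-coding genes)
this evaluates to 8.80 × 10⁻²⁵.

Mutation frequency of a gene is 100 × (distinct samples with ≥1 qualifying
record) / (total study samples). The denominator is the declared study size
(`#n_samples=` header directive), not the number of samples carrying any
mutation, so genes absent from a cohort dilute correctly; duplicate records
of one (sample, gene) count once. All seven variant classes (missense,
silent, nonsense, splice site, readthrough, frameshift indel, inframe indel)
count by default; `include_classes` can drop silent (or any) classes, since
published set means do not state whether silent variants were included.
Set-level comparisons run the K-S test on per-gene frequency vectors;
threshold analyses compare the fraction of genes at ≥2% (default) frequency
between sets with 2×2 chi-squared tests without continuity correction
(a flag enables it); the frequency-vs-drug-count relation is a Pearson
correlation and refuses constant vectors.

The frequency statistics that depend on the external pan-cancer mutation
table (set means, their K-S p-values, threshold fractions, the r = 0.40
drug-count correlation, oncogene/TSG overlaps) are computed by the pipeline
whenever a user supplies a MAF-like table and gene lists; packaged tests
validate them on synthetic tables with planted truth instead of asserting
any external-data value.

## Synthetic generators

All generators consume one explicit integer seed driving a single
`numpy.random.Generator`; identical spec + seed is byte-identical after
serialization. Names are deterministic templates (DRUG0001, GENE0001,
CANCER01) for stable diffs.

* **Catalogs** default to the curated study's shape: 150 drugs, 33 cancers,
  a 102-gene target pool, P(targeted) = 89/150, approval years 1949–2014,
  and shifted-geometric counts for indications (p = 0.6) and targets per
  drug (p = 0.5), giving the right-skewed degree distributions real
  catalogs show. Cytotoxic drugs receive mechanism phrases (sometimes plus
  a gene) so the mechanism-token filtering is exercised. Generated catalogs
  pass every loader invariant.
* **Mutation tables** default to 3268 samples across 12 cohort codes with
  per-set per-gene rates 2.41 / 1.19 / 1.85 / 0.97 percent — the four
  observed set means used as planted truth — over 32 / 70 / 537 / 2000
  genes. The "other" set is 2000 genes rather than the full ~20k of a real
  exome: recovery tests measure per-set means, and their standard errors at
  2000 genes are already far below the tolerances tested, so the larger set
  would only add runtime. Per gene, the number of carriers is one
  Binomial(n_samples, rate) draw (distributionally identical to per-sample
  Bernoulli draws), each carrier gets one record with uniform variant class
  and cohort.
* **Trial tables** mark each prediction unsupported with probability
  1 − p_supported (default 116/133) and otherwise draw 1 + Geometric counts.

What the generators do *not* emulate: real pharmacology (ATC chemistry,
class structure), cohort-specific mutation signatures, hypermutator
samples, or gene-length effects. Green tests on synthetic data therefore
demonstrate that the statistics and the bookkeeping are correct, not that
any biological conclusion transfers to a particular external dataset.

## Pipeline and report

`run_pipeline` executes catalog → networks → repurposing → genetics; the
genetics stage is skipped with a logged notice when mutation inputs are
absent. The report is a nested dict rendered as JSON with sorted keys or as
markdown; the only non-deterministic field (timestamp) is isolated in the
provenance block alongside the config hash and package version, so reports
diff cleanly. Stage outputs (network edge lists, annotated predictions) are
written as TSVs next to the report.

## Known limitations

* The packaged tables are transcriptions of a published curation frozen at
  end-2014; they are inputs, not a maintained registry.
* The curated drug table and its accompanying narrative disagree by one
  drug on the single/both delivery split (the table sums to 97/22/31); the
  package reports what the table yields.
* The trial-count table carries the one approved pair / one missing pair
  inconsistency described above; support tallies reflect the computed
  prediction set.
* Per-gene annotation placements inside a family are reconstructions
  (marginals exact, cells not guaranteed).
* The common-target rule is deliberately unscored: predictions are
  annotated with trial counts but not ranked beyond that.
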