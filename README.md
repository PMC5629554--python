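# oncodrug

Catalog, network, and repurposing analysis of the 150 anticancer drugs
approved by the FDA between 1949 and 2014.

Oncology drug development increasingly reuses what is already known: if two
drugs act on the same molecular target and one of them is approved for a
cancer the other is not, that indication is a natural repurposing candidate.
`oncodrug` packages this *common-target* (guilt-by-association) analysis as a
tested pipeline for anyone studying drug–disease networks or triaging
repurposing hypotheses:

* a validated **catalog** of 150 drugs (61 cytotoxic, 89 targeted) with
  approval years, approved cancer classes, molecular-target tokens, and
  delivery modes, plus per-target subcellular/functional annotations and the
  33 cancer classes — shipped as plain TSVs and loadable from user files in
  the same schema;
* the **drug–cancer bipartite network** (183 nodes, 248 associations) and the
  **cancer–drug–target tripartite network** (214 nodes, 313 edges) with
  degree summaries, degree-bin breakdowns, K-S comparison of degree
  distributions, and export to edge-TSV / SIF / GraphML;
* the **common-target predictor**: for targeted drugs A, B sharing a
  gene-level target, every approved indication of B that A lacks becomes a
  candidate (A, cancer) pair, deduplicated with merged provenance and
  annotated with clinical-trial counts;
* **target genetics**: four-way gene-set partition (targets ∩ cancer genes,
  targets only, cancer genes only, rest), upper-tail hypergeometric
  enrichment P(X ≥ k) for the target/cancer-gene overlap, per-gene somatic
  mutation frequencies from a MAF-like table, K-S set comparisons,
  ≥threshold fractions with 2×2 chi-squared tests, and the
  frequency-vs-drug-count correlation;
* **synthetic generators** for catalogs, mutation tables, and trial tables
  with planted ground truth, so every stage is testable without downloads.

Target cells mix gene symbols with mechanism phrases ("DNA synthesis",
"Unknown", …); those phrases are stripped before any gene-level analysis, so
"102 protein targets" means the same thing everywhere. The fusion target
BCR-ABL is kept as a single node.

## Worked example

```python
import oncodrug as od

catalog = od.load_packaged_catalog()

summary = od.summarize_catalog(catalog)
print("drugs:", summary.n_total, "| cytotoxic:", summary.n_cytotoxic,
      "| targeted:", summary.n_targeted)

net = od.build_drug_cancer_network(catalog)
drug_deg = od.degree_summary(net, "drug")
print(f"drug-cancer network: {net.n_nodes} nodes, {len(net.edges)} edges; "
      f"mean indications/drug = {drug_deg.mean:.2f} (max {drug_deg.max})")

predictions = od.predict_common_target(catalog)
trials = od.load_packaged_trial_counts(catalog)
report = od.evaluate_support(predictions, trials)
top = report.top_association
print(f"novel associations: {report.n_predictions} over {report.n_drugs} drugs "
      f"and {report.n_cancers} cancer types; {report.n_supported} with >=1 trial")
print(f"best-supported: {top.drug} -> {top.cancer} ({top.trial_count} trials)")

p = od.hypergeometric_enrichment(32, 102, 594, 20729)
print(f"target/cancer-gene overlap enrichment: P = {p:.2e}")
```

prints

```
drugs: 150 | cytotoxic: 61 | targeted: 89
drug-cancer network: 183 nodes, 248 edges; mean indications/drug = 1.65 (max 11)
novel associations: 133 over 52 drugs and 16 cancer types; 115 with >=1 trial
best-supported: Thalidomide -> Lymphoma (174 trials)
target/cancer-gene overlap enrichment: P = 8.80e-25
```

Reading: the 150-drug catalog yields 248 approved drug–cancer associations
(a typical drug treats 1.65 cancer classes; doxorubicin tops out at 11).
Among the 89 targeted drugs, shared targets propose 133 not-yet-approved
drug–cancer pairs touching 52 drugs and 16 cancers; 115 of them already have
at least one registered clinical trial in the packaged trial table, led by
thalidomide in lymphoma with 174 trials — repurposing candidates the trial
record itself treats as plausible. The 32-gene overlap between the 102
targets and the 594 cancer genes is far beyond chance (hypergeometric
P ≈ 8.8 × 10⁻²⁵ against 20,729 protein-coding genes).

One transcription caveat is worth knowing: the packaged trial table contains
one pair (axitinib–kidney cancer) that the drug table lists as already
approved, and lacks one forced prediction (afatinib–breast cancer); the
predictor reports both discrepancies (`unmatched_trial_pairs` and a logged
warning) instead of hiding them.

The same pipeline runs from the shell:

```sh
oncodrug run --config run.yaml          # full pipeline -> report.json
oncodrug predict --catalog drugs.tsv --cancers cancers.tsv \
    --trials trial_counts.tsv --out predictions.tsv
oncodrug networks --catalog drugs.tsv --cancers cancers.tsv --format graphml
oncodrug simulate --kind catalog --seed 7 --outdir synthetic/
```

See `docs/methods.md` for the statistical conventions (K-S p-value forms,
enrichment tail, frequency denominators) and the synthetic generators'
design.

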