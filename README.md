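# acumine

Data mining over acupoint prescription datasets: frequency, meridian and
body-region summaries, co-occurrence networks, apriori association rules,
and Ward hierarchical clustering.

## The problem

Clinical acupuncture studies report *prescriptions* — the set of acupoints
a protocol stimulates. Across a literature corpus these form a
transaction database (one study = one set of WHO-coded acupoints), and
the questions practitioners ask of it are classic market-basket
questions: which points dominate, which meridians and body regions they
sit on, which points co-occur, which combinations are associated beyond
chance, and how the frequently used points group. `acumine` packages that
analysis for the published corpus of 42 acupuncture prescriptions for
amyotrophic lateral sclerosis (ALS) — 141 distinct acupoints used 626
times in total — and for any user-supplied or synthetic prescription
dataset in the same shape.

The raw 42-transaction table behind that corpus was never deposited; only
per-acupoint marginal counts are published. `acumine` therefore ships

* a **registry fixture** transcribing the published per-acupoint counts,
  with meridian and body-region assignments and a synonym table for name
  standardization ("Hegu", "LI 4", "Jiaji (EX-B 2)" → `LI4`, `EX-B2`);
* a **seeded synthetic generator** producing transaction datasets with
  those exact marginals (or any targets) and configurable pairwise
  co-occurrence blocks, so the transaction-level stages are fully
  testable.

## Methods at a glance

* **Frequency stage** — per-acupoint counts and percent of prescriptions;
  meridian / region totals and proportions; yang vs yin channel shares
  (the six yang channels LI, ST, BL, GB, SJ, SI against the six yin
  channels LU, SP, HT, KI, PC, LR; DU/RN vessels and EX extra points are
  excluded from both).
* **Co-occurrence network** — edge weight w(a,b) = |{t : a ∈ t, b ∈ t}|,
  filtered at a minimum edge weight (preset 30).
* **Association rules** — from-scratch level-wise apriori;
  support(A→B) = P(A∪B), confidence = P(A∪B)/P(A), lift =
  confidence/P(B); preset thresholds support ≥ 0.15, confidence ≥ 0.90,
  lift > 1, items restricted to acupoints used ≥ 10 times.
* **Clustering** — binary acupoint × prescription incidence vectors,
  Euclidean distance, Ward minimum-variance linkage via the
  Lance–Williams recurrence with deterministic lexicographic
  tie-breaking; tree cut into k clusters (preset k = 7); Newick export.

## Worked example

Fixture-only summary of the published corpus (no transaction data
needed):

```sh
$ acumine summarize
141 acupoints, total frequency 626 over 42 prescriptions
  LI4   28      67%
  ST36  28      67%
  LI11  22      52%
  SP6   20      48%
  GB34  19      45%
yang share: 58%
yin share: 15%
```

Hegu (LI4) and Zusanli (ST36) each appear in 28 of the 42 prescriptions
(67%); yang-channel points carry 58% of the 626 total applications.

Full pipeline on a synthetic corpus with the published marginals:

```sh
$ acumine simulate --seed 5 --out ds.json
42 synthetic prescriptions -> ds.json
$ acumine run --input ds.json --seed 5 --outdir out
summary: out/summary.json
edges: out/edges.tsv
rules: out/rules.tsv
newick: out/dendrogram.nwk
clusters: out/clusters.tsv
log: out/run_log.txt
```

Every stage threshold (`--min-support`, `--min-confidence`, `--min-lift`,
`--min-edge-weight`, `--min-item-frequency`, `--k`) is a flag; the same
seed reproduces the bundle byte for byte.

The library mirrors the CLI: `load_registry()`, `read_dataset()`,
`generate()`, `summarize()`, `pair_counts()` / `threshold_network()`,
`frequent_itemsets()` / `generate_rules()`, `occurrence_matrix()` /
`ward_linkage()` / `cut_tree()`, and `run()`.

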