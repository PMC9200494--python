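# Methods

## Data model

A *prescription* is the set of WHO-coded acupoints one clinical study's
protocol uses; a dataset is an ordered list of such sets (transactions).
A point is counted at most once per prescription — within-study repeated
sessions are out of model, consistent with the corpus's maximum
per-point count (28) being below its 42 prescriptions. Codes are
uppercase without internal whitespace, hyphen retained for extra points
(`LI4`, `EX-B2`, `EX-HN12`).

## The registry fixture

`src/acumine/data/acupoints.tsv` transcribes the published per-acupoint
corpus counts with meridian and body-region assignments: 141 points, 626
total applications, region totals (lower limbs 189, upper limbs 134,
back/lumbar 116, head/face/neck 113, chest/abdomen 74) over (31, 27, 29,
32, 22) points respectively, with 10 extra (EX) points totalling 33.

The published report prints two frequency tables, and its
meridian-grouped table does not reconcile internally: the ST row's listed
entries sum to 94 against a printed total of 89; the BL row lists 21
entries summing to 83 against a printed 88 over 22 points; the GB row
prints 14 points but lists 15. The region-grouped table reconciles
exactly, row by row and to the 141/626 grand totals, so it is the
canonical per-acupoint source. The meridian-grouped table's printed row
totals are shipped separately (`claimed_meridian_totals.tsv`) as
reference values only. Note the computed LI total (90) matches its
printed value, and the computed LI+ST+BL sum is 267 either way.

Two evident romanization slips are normalized by code, which governs:
BL10 is registered under its WHO name Tianzhu (printed "Tianshu", which
is ST25's name), and DU12 under its WHO name Shenzhu (printed "Shenshu",
which is BL23's name). "Tianchi" is registered as PC1 per the WHO
assignment (the source prints both "PC 1" and "PC 2"). The synonym table
resolves these printed variants, plus the misspelling "Wailiing" (ST26).
Bare names that are ambiguous in the registry ("Futu" is both ST32 and
LI18) are rejected unless accompanied by a code; standardization never
guesses.

Percentages are never stored in the fixture; they are always recomputed.

## Frequency stage

Per-acupoint percent = round(100·count/n_prescriptions); meridian,
region, and polarity proportions use the grand total of applications as
denominator. Rounding is half-up to the nearest integer (14.54% → 15%),
chosen because it reproduces every printed percentage in the corpus
report; the source does not state its rounding rule. The yang share sums
the six yang channels (LI, ST, BL, GB, SJ, SI) and the yin share the six
yin channels (LU, SP, HT, KI, PC, LR); the governor (DU) and conception
(RN) vessels and extra points are excluded from both numerators —
folding DU into yang would inflate the yang share from 58% to 69% and
contradicts the reported convention. Top-k ranking breaks count ties by
ascending code.

## Co-occurrence network

Edge weight is the plain joint transaction count. The filtered network
keeps edges at or above the minimum weight (preset 30) and ranks them by
weight descending, then lexicographic pair. The corpus report prints
pair weights (e.g. 75) that exceed its own 42 transactions and therefore
cannot be per-prescription co-occurrence counts under any definition;
they appear to be an artifact of the analysis platform's internal
weighting and are deliberately not reproduced. This package reproduces
the procedure, not those numbers.

## Association rules

Level-wise apriori: size-k candidates from a (k−1)-prefix join of sorted
frequent (k−1)-itemsets, pruned by downward closure, counted by a
transaction scan. Support denominator is the total transaction count.
Rules are all ordered splits of each frequent itemset (size ≥ 2) into
nonempty antecedent/consequent, kept at confidence ≥ the floor and lift
strictly above the lift floor, ranked by (support desc, confidence desc,
lexicographic serialization).

Preset thresholds: support 0.15, confidence 0.90, lift > 1, maximum
itemset size 3 (every published rule involves ≤ 3 points; configurable
upward). The item-frequency floor is **inclusive** at 10: the corpus
report describes its eligible set as ">10 times" yet counts 23
qualifying points and clusters points of frequency exactly 10 (SJ5,
ST32); only ≥ 10 yields 23, so the floor is interpreted as ≥.

The published set of 27 rules depends on the undeposited transaction
table and is not reproducible; correctness is instead established by
exact equivalence with an exhaustive enumerator (all itemsets up to the
size cap over the filtered items, all splits), which is feasible at the
23-item scale and is the test oracle throughout.

## Hierarchical clustering

What the platform clustered over is unstated in the corpus report;
binary acupoint × prescription incidence vectors are the only structure
available from transactions and make Euclidean distance meaningful, so
they are the feature representation here — recorded prominently as an
assumption; co-occurrence-profile or frequency-profile alternatives are
not implemented. Rows are the acupoints passing the (inclusive)
frequency floor, in lexicographic order.

Ward linkage starts from singletons and merges the pair minimizing the
within-cluster sum-of-squares increase, maintained via the
Lance–Williams recurrence on squared distances. Heights follow the
common dendrogram convention d = √(2·ΔSSE), so a two-singleton merge sits
at the pair's Euclidean distance (the same convention as standard
scientific linkage routines, which serve as an independent cross-check
on tie-free data in the tests). Binary data produces many exact cost
ties; ties (within a 1e-9 relative tolerance) are broken by the
lexicographically smallest pair of clusters, clusters being identified by
their sorted leaf-index tuples — this makes the tree fully deterministic
and lets a brute-force oracle that recomputes ΔSSE from raw points at
every step reproduce it merge for merge. Ward linkage is reducible, so
heights are nondecreasing, which the Dendrogram type asserts.

Cutting at k removes the k−1 highest (equivalently, last) merges;
cluster labels run 1..k in order of each cluster's lexicographically
smallest leaf. The preset k = 7 matches the published analysis. Exports:
Newick (branch length = parent height − child height) and a merge-table
TSV.

## Synthetic generator

The generator emulates the study conditions: 42 transactions over the
141 registry acupoints with the published marginal counts as defaults.

* **Exact-marginal mode** places each code in a uniform random subset of
  transactions of exactly its target size. Block coupling then relocates
  occurrences of block members into transactions holding the block's
  anchor (the member with the largest target), preserving every per-code
  margin; the boost ∈ [0, 1] sets the fraction of possible relocations
  performed. At boost 1 the smaller member's occurrences become a subset
  of the anchor's, so the realized joint count equals the smaller
  target — recorded as bookkeeping and used as the oracle for
  co-occurrence counting. The coupling strength between boost 0 and 1 is
  a heuristic and is not calibrated to any real dependence structure.
* **Bernoulli mode** includes each code independently with probability
  target/n, plus a latent per-transaction indicator per block
  (probability = boost) that forces joint inclusion of all members, so a
  same-block pair co-occurs with probability boost + (1−boost)·p_a·p_b.
  Marginals are correspondingly inflated; this mode is for dependence-
  sensitive property tests, not marginal fidelity.

One integer seed drives a single numpy generator; identical config and
seed reproduce the dataset byte for byte.

What the generator does **not** emulate: the real corpus's unknown
dependence structure between acupoints (beyond user-planted blocks),
study-level covariates (syndrome types, comparators), and any
heterogeneity in prescription sizes beyond what random placement
induces. Passing tests therefore establish that the algorithms are
correct and deterministic on data with the published marginals — not
that they reproduce the unpublished transaction-level results (the 44
network edges, the 27 rules, the printed lift range, or the published
dendrogram topology).

## Pipeline

One config runs summarize → network → rules → clusters on the same
dataset and writes summary JSON, edge TSV, rules TSV, Newick, cluster
TSV, and a run log recording all thresholds and the seed (and nothing
volatile, so reruns are byte-identical). Fixture-only mode (no input, no
generator) runs the descriptive stage from the packaged fixture with the
corpus's 42 prescriptions as denominator and skips the transaction-level
stages with a logged notice. Preset thresholds: support 0.15, confidence
0.90, lift > 1, edge weight 30, item frequency 10, k = 7 — each
overridable per run.

## Numerical and degenerate-input choices

* Half-up integer rounding for all reported percentages.
* Merge-cost tie tolerance 1e-9 relative (plus 1e-12 absolute for
  zero-height ties from identical rows).
* Empty transactions are allowed and contribute nothing; a dataset must
  contain at least one transaction; clustering requires ≥ 2 surviving
  rows; an empty post-filter item set is an error, not an empty result.
* Duplicate codes within a read prescription collapse with a warning;
  unresolvable names are errors naming the row and token.

## Problem sizes

The test suite and the acceptance script run the full corpus-scale
pipeline (42 × 141, 23 filtered items) throughout — these are the study
conditions themselves, so nothing is scaled down. Oracle equivalence
checks use the sizes at which exhaustive enumeration is the natural
oracle: all itemsets up to size 3–4 over ≤ 23 items, and Ward
recomputation on ≤ 10-row matrices; independence and coupling checks in
Bernoulli mode use n = 10,000 transactions for tight binomial error
bars. The whole suite runs in a few seconds.

## Known limitations

* The published transaction-level outputs are unverifiable without the
  undeposited raw data; only the descriptive layer is exactly
  reproduced.
* The registry covers exactly the 141 corpus acupoints plus the synonyms
  needed here; it is not a general acupoint ontology, and carries no
  anatomical locations or indications.
* Rule mining performs no statistical significance testing; lift is a
  descriptive ratio.
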