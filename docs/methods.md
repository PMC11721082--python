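# Methods

## Model

A genome is represented by a vector of one continuous feature (GC content,
fraction in [0, 1], computed length-weighted over all contigs with ambiguity
codes excluded from numerator and denominator) and several hundred binary
features: presence/absence of giant virus orthologous groups (GVOGs). A
GVOG is present when at least one of the genome's predicted proteins hits
that profile HMM with full-sequence E-value ≤ 1e-10. Presence is binary by
design — hit counts or bit scores would scale with genome completeness, and
robustness to incomplete MAGs is the point of the approach; genome size is
excluded for the same reason. Two independent random-forest classifiers are
trained on this representation, one per taxonomic level (order, family).
They are applied independently at prediction time; a disagreement between
the family call's order prefix and the order call is flagged, not repaired.

The E-value filter reads the full-sequence E-value column (tblout column 5)
inclusively (≤). hmmsearch reports both full-sequence and best-domain
E-values; full-sequence is its primary significance measure and is the one
used here. Protein ids map to genomes by the Prodigal `<contig>_<n>`
convention (strip the trailing `_<n>`), with longest-prefix resolution
against known genome ids for multi-contig naming; the pattern is
configurable for other gene callers.

## Fragmentation simulator

Completeness = fragment length / source length. Mechanics (the choice is
ours; only the completeness ranges are externally specified): a
single-contig genome yields one uniformly placed contiguous window of the
target length; a multi-contig genome has its contigs shuffled (seeded),
whole contigs accumulated until the next would overshoot, and the last
contig trimmed to a uniform window — mimicking how binning loses whole
contigs while preserving local contiguity. Completeness is drawn uniformly
from per-rule bounds. The stock training policy gives giant-virus genomes 2
fragments at 23–99 % completeness, non-giant-virus genomes 1 fragment at
29–99 %, and the two-member incertae sedis group 6 extra fragments; applied
to the documented group sizes (1242 / 289 / 2, originals kept) it yields
4316 sequences. Policy rules are additive predicates, so a rare group's
extra fragments stack on its lineage default.

## Feature selection

1. **Prevalence screen**: keep a GVOG if its prevalence within an order
   reaches `min_prevalence` (default 0.25). "Within each order" is read as
   *any* order (union) by default — the alternative every-order reading is
   available by config but would leave almost nothing given how little is
   shared across orders. GC content is always retained.
2. **RFE curve**: for each requested size, recursive elimination of the
   lowest-impurity-importance features in steps of 10 % of the remainder,
   scored by stratified k-fold accuracy; used to find the plateau.
3. **Collinearity clustering**: Ward linkage on 1 − Spearman ρ (computed as
   Pearson correlation of column ranks so constant columns stay defined,
   with their correlation set to 0), cut at a configurable threshold
   (default 0.5; no external value exists). One representative per cluster
   — the highest-ranked when a ranking is supplied. Threshold 0 is
   special-cased to singletons. Rationale: permuting one of two correlated
   features barely moves accuracy because the model reads the same signal
   from the twin, so per-feature permutation importance underestimates
   correlated features unless one retrains on representatives.
4. **Importance**: permutation importance (mean decrease in held-out
   accuracy over `n_repeats` shuffles, default 10) and impurity importance
   (MDI, normalized to sum to 1, sd across trees). Final feature sets are
   the top-k by mean importance with lexicographic tie-break and GC forced
   in; defaults k = 150 (order) and 200 (family), from the accuracy-plateau
   region — the exact original sizes are not documented, so both are config.

## Training

Hyperparameters are tuned in two stages: `RandomizedSearchCV` over a broad
conventional grid (trees 100–1000, depth unbounded–50, features-per-split
sqrt/log2/0.1–0.5, min-split 2–10, min-leaf 1–5, bootstrap on/off), then
`GridSearchCV` over ±1 step around the randomized winner. All searches use
stratified 10-fold CV scored by accuracy. Nested CV runs the grid search
inside each outer-training fold and scores on the untouched outer test
fold. Learning curves subsample each CV training fold (stratified, floored
at one member per class) at fractions 0.25–1.0. Class imbalance is handled
by stratification only; balanced class weights sit behind a flag, off by
default, reporting the imbalance toward the most
populous order rather than correcting it. Classes smaller than the
fold count reduce the fold count with a warning. Every routine is
deterministic under a fixed seed. Models persist as a joblib forest plus a
JSON sidecar (feature order, class list, hyperparameters, format version);
loading a mismatched format version is an error, never a silent fallback.

## Evaluation

Accuracy, per-class precision/recall/F1 with the zero-denominator → 0
convention, support-weighted averages, and confusion matrices (rows =
truth; the normalized form divides each row by its class size, so the
diagonal is per-class recall). Report tables round to 2 decimals;
machine-readable TSVs keep full precision. Families with fewer than 30
genomes are aggregated into their order's bin (AF, AG, IM, PM, PV, …)
before family-level training; the threshold and the bin map are config.

## One-way AAI

Query proteins are searched one-way against a reference database (one
proteome per genus, with order/family/genus annotations). Per reference
genome, the best hit per query protein is kept; AAI is the mean best-hit
percent identity (identities / alignment columns, gaps included) and AF is
100 × (query proteins with a hit) / (query proteins). AF is defined
query-side — protein-count-based, not aligned-length-based — because the
floor rule is applied per input genome and the search is one-way; an
aligned-length variant would need the reference's protein count, which a
one-way search does not normalise by. Pairs with AF < 20 report AAI 0 (the
raw mean is kept in a side field). Best match maximizes reported AAI, ties
broken by higher AF then lexicographic genome id.

The default backend is an in-process Smith–Waterman (Biopython
`PairwiseAligner`, local mode, BLOSUM62, gap open −11 / extend −1) with a
reporting threshold of raw score ≥ 50 — comfortably above the ~20–25 that
random same-length protein pairs reach, and far below genuinely homologous
pairs. External `blastp` and `lastal` backends can be selected for large
databases; selecting one without the binary on PATH raises an error with a
remediation hint.

## Synthetic data generator

The generator emulates the structural properties the classifier exploits:
each order owns a core block of signature GVOGs shared by its families,
each family adds a disjoint block (the block pattern of real
presence/absence heatmaps); class members carry each signature GVOG with
probability `p_signature` (default 0.9) and any other pool GVOG with
`p_background` (default 0.02); orders have distinct GC means (spread over
0.30–0.60, sd 0.02); genomes are 1–5 contigs; hits are materialized
directly as tblout text with significant E-values (10⁻⁴⁰–10⁻¹²), plus a 5 %
decoy rate of absent GVOGs emitted above the threshold so the E-value
filter is genuinely exercised. Each present GVOG gets a 900-bp gene
coordinate; fragmenting a genome retains only GVOGs whose genes lie fully
inside retained windows, so completeness genuinely degrades the feature
signature. The benchmark preset has 8 order-level classes (including
Not_GV) holding 13 family-level classes.

What it does **not** emulate: real protein sequence evolution (protein
strings are random), codon structure, assembly chimerism, or bin
contamination. Passing recovery tests on this generator therefore shows the
pipeline machinery is correct and that the statistical procedure recovers
planted class structure of realistic shape and noise — not that real
lineage boundaries are as separable as the planted ones. The reported
headline accuracies depend on curated genome databases and thousands of
real HMMs that are out of scope here; on the synthetic preset the pipeline
reaches nested-CV accuracy ≥ 0.95 at both levels (in practice 1.0), and
50 %-complete fragments cost ≤ 5 accuracy points.

## Problem sizes and numerical choices

The recovery checks run at 100 genomes per family class (1300 genomes,
~350-feature pool, ~230 after screening) with 100-tree forests and a
compact explicit search grid; unit tests use smaller draws. Forest, fold
and generator seeds are all derived from the single seed an entry point
takes. Ties in predicted-class probability fall to the lexicographically
first class (scikit-learn's class ordering). Degenerate inputs are errors,
not silent repairs: sequences with no unambiguous bases, empty proteomes,
unlabeled genomes, hits referencing unknown proteins, feature-set
mismatches at prediction time.

## Known limitations

- The generator's independence assumptions (Bernoulli per GVOG given the
  class) understate real within-lineage correlation beyond the planted
  blocks.
- The builtin AAI backend is quadratic in proteome size; it is meant for
  small reference sets and tests, with blastp the pragmatic choice at
  scale.
- The LAST backend is a stub behind an explicit error unless the binary and
  a formatted database are supplied.
- Family-level class definitions (which families are "named" vs aggregated)
  are configuration, not shipped curation.
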