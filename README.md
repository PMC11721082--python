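# gvtax

Taxonomic classification of giant-virus genomes from protein-family profiles.

## The problem

Giant viruses (phylum *Nucleocytoviricota*) recovered from metagenomes are
often incomplete, fragmented MAGs that lack the handful of core marker genes
alignment-based phylogenetics depends on. `gvtax` instead assigns a genome to
its taxonomic **order** and **family** from a broad genomic signature: the
genome's GC content plus the binary presence/absence of giant virus
orthologous groups (GVOGs, protein families modelled as profile HMMs). A
random forest trained on this signature needs no alignment or tree, tolerates
missing genes, and reports a class-membership probability (the forest's vote
fraction) with every call; wrong calls concentrate below probability 0.5 and
are flagged low-confidence.

It is intended for virus ecologists and metagenomics pipelines that need fast
taxonomic triage of putative giant-virus bins, including material that merely
resembles giant viruses (*Mirusviricota*, jumbo phage — grouped as `Not_GV`).

## Method

For genome *g* and GVOG *v*, the feature is
x<sub>gv</sub> = 1 iff ≥ 1 predicted protein of *g* hits profile *v* with
full-sequence E-value ≤ 10⁻¹⁰ (hmmsearch tblout), plus
x<sub>g,GC</sub> = (G+C)/(A+C+G+T). Genome size is deliberately not a
feature, and presence is binary rather than counts, so incompleteness does
not bias the signature. Around the forest sit:

- **Prevalence screening** — keep GVOGs present in ≥ 25 % of the genomes of
  an order, so only broadly represented families enter training.
- **Fragmentation augmentation** — training genomes are supplemented with
  fragments at uniform-random completeness (23–99 %), mimicking binning
  losses, so the model learns from degraded signatures too.
- **Feature reduction** — RFE accuracy curves, Ward clustering on
  1 − Spearman ρ to defeat collinearity masking of permutation importance,
  and impurity (MDI) importance, yielding compact final feature sets
  (defaults: 150 order-level, 200 family-level).
- **Tuning and validation** — randomized-then-grid hyperparameter search and
  nested 10-fold cross-validation, all stratified and seeded.
- **Evaluation** — accuracy = (TP+TN)/(TP+TN+FP+FN),
  precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), weighted
  averages, and row-normalized confusion matrices.
- **One-way AAI** — optional best-match search of query proteomes against a
  taxonomy-annotated reference database: AAI = mean best-hit percent
  identity, AF = % of query proteins with a hit; AF < 20 reports AAI 0.

## Worked example

Everything below runs on a synthetic fixture set (no downloads); see
`docs/methods.md` for what the generator does and does not emulate.

```bash
gvtax simulate --seed 7 --genomes-per-class 12 -o fixtures
gvtax featurize --genomes fixtures/genomes.fna --proteins fixtures/proteins.faa \
      --tblout fixtures/hits.tblout --gvog-list fixtures/gvogs.txt -o matrix.tsv
gvtax train --config config.json          # matrix + labels + seed 7
gvtax classify --model-dir run --matrix matrix.tsv -o preds
gvtax evaluate --pred preds/predictions.tsv --truth fixtures/labels.tsv \
      --level order -o report
```

prints

```
wrote 156 genomes to fixtures
wrote 156 x 349 matrix to matrix.tsv
order: nested CV 1.000 +- 0.000 (150 features)
family: nested CV 1.000 +- 0.000 (200 features)
classified 156 genomes -> preds/predictions.tsv
accuracy 1.000; reports in report
```

and the predictions table carries both levels with their vote-fraction
probabilities:

```
genome_id  order        order_prob  family_class  family_prob  low_confidence
GEN00001   Algavirales  0.91        AG_01         0.88         False
GEN00002   Algavirales  0.98        AG_01         0.91         False
```

The nested-CV accuracy of 1.000 says the forest recovers the simulated class
signatures perfectly — expected here, since the fixture classes are
well-separated by construction; real data is harder (see the methods note).
Python users can do the same through `gvtax.run_train_pipeline` /
`gvtax.run_classify_pipeline`, or call the individual functions
(`build_feature_matrix`, `prevalence_screen`, `tune`, `nested_cv`,
`predict`, `evaluate`, `best_match`, …) directly.

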