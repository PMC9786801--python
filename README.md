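# concise-annotate

Consensus annotation propagation for untargeted LC-MS/MS molecular
networks.

In untargeted metabolomics, molecular networking groups MS/MS ion
features into subnetworks of structurally related compounds, but spectral
library matching typically identifies fewer than 10% of features. In
silico tools such as CANOPUS predict chemical-class membership
(ClassyFire/ChemOnt superclass > class > subclass) for many more
features, with less certainty per feature. This package fuses the two: it
derives, per subnetwork, a *consensus* chemical classification by
thresholded majority voting over the hierarchy, and propagates it to
every member feature — turning sparsely annotated networks into densely
class-annotated ones while the voting threshold controls false positives.
It is aimed at metabolomics researchers working with GNPS feature-based
molecular networking outputs and SIRIUS/CANOPUS class predictions.

## The algorithm

For each subnetwork (connected component) with at least one annotation:

1. **Source selection.** Spectral library matches outrank in silico
   predictions: if any member feature has a voting-eligible library
   annotation (one with structural information — SMILES/InChI — or
   explicit ontology labels), only library annotations vote; otherwise
   the in silico annotations vote.
2. **Hierarchical thresholded vote.** Let *n* be the number of annotated
   member features from the selected source. At superclass level the
   modal label must satisfy count/*n* ≥ *t*₁ (default 50%); at class and
   subclass a stricter *t*₂ = *t*₃ = 70% applies. Deeper votes are
   constrained to extend the shallower winner (votes count label
   *prefixes*), and blank labels stay in the denominator. The consensus
   is the most granular level that passes its cutoff and every shallower
   cutoff; a subnetwork that cannot clear 50% at superclass returns
   "no consensus".
3. **Propagation.** Every member feature — annotated or not — receives
   the subnetwork's consensus path, the score (percent agreement at the
   returned level), the count of voting nodes, and the source.
4. **Singleton rule.** A feature with no network neighbors only ever
   receives its own library match; an in silico annotation is never
   propagated to a singleton.

The output is `ConCISEConsensus.csv`: one row per feature with columns
`feature_id, superclass, class, subclass, score, level, n_nodes, source`.

Validation statistics are built in: a no-library rerun scores the
in-silico-derived consensus against the withheld library identities
(per-level true positive rate), plus annotation-rate/expansion summaries
and intensity-weighted per-sample class abundance.

## Worked example

`examples/validate_tpr.py` plants a known 5% corruption into synthetic in
silico labels, withholds the library identities from voting and measures
how often the propagated consensus still matches them:

```
True positive rate (library truth vs consensus):
  superclass     94.33%  (566/600 evaluable)
  class          94.33%  (566/600 evaluable)
  subclass       94.33%  (566/600 evaluable)
  across levels: 94.33% ± 0.00%
```

With 5% of labels corrupted the expected TPR is 95%; the measured 94.33%
over 600 evaluable features is within one binomial standard error (0.9%)
of that. `examples/run_consensus.py` shows the end-to-end run (parsing
the GNPS-dialect tables, voting, propagation and the CSV export) and
prints, per feature, the propagated path, score and source;
`examples/class_abundance.py` turns consensus superclasses plus feature
intensities into per-sample percent-of-classified-signal summaries.

## Command line

```sh
concise run --network clusterinfo_summary.tsv \
            --canopus canopus_summary.tsv \
            --library-file db_result.tsv --lookup ontology_lookup.tsv \
            --thresholds 50 70 70 --out results/
concise fixtures --out fixture/ --seed 7        # synthetic test study
```

`--task-id <32-hex GNPS id>` fetches the library-match table from GNPS
(cached under `.concise_cache/`); `--no-library` withholds library
matches from voting and appends a TPR report; `--strict-greater` and
`--fallback` switch the threshold comparison and the library→in-silico
fallback.

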