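# polyasig

Recognition of poly(A) signals (PAS) versus pseudo-signals in 206-nt human
genomic DNA windows (100-nt flanks around a 6-nt signal hexamer). The toolkit
covers the full pipeline:

- **`polyasig.seqio`** — FASTA/GTF/BED handling, extraction of 206-nt windows
  from a genome for annotated signal hexamers (both strands), and seeded
  sampling of pseudo-signal windows from a chromosome with positional
  exclusion of true sites. Twelve hexamer variants are supported, split into
  *strong* (`AATAAA`, `ATTAAA`) and *weak* (the ten rarer variants).
- **`polyasig.features`** — the versioned 218-value feature registry:
  class log-odds scores from two position-specific dinucleotide weight
  matrices, a positional information-gain score, nucleotide frequencies at
  the 40 most discriminant positions, 16 bundled physicochemical structural
  scales averaged over 25-nt windows per flank (128 values), compositional
  blocks (mono/di/in-frame codon-position frequencies), whole-window
  descriptors, and min-max normalization to (−1, 1) fitted on training rows
  only.
- **`polyasig.omnitree`** — a binary decision tree whose internal nodes are
  heterogeneous classifiers (C4.5-style entropy tree, single-hidden-layer
  neural net, random forest, ridge-regularized multinomial logistic
  regression). Samples are routed left/right by the node's predicted class;
  leaves carry the majority label and class-1 fraction of the data routed to
  them.
- **`polyasig.ga`** — a seeded genetic algorithm (tournament selection,
  uniform crossover, per-gene mutation, elitism) over an integer genome
  encoding per-node pruning, classifier family, and hyperparameter grid
  indices; fitness is validation error, evaluated with genome-derived seeds
  so serial and parallel runs are bit-identical.
- **`polyasig.evaluation`** — stratified 5-fold cross-validation with a 15%
  validation holdout per fold, leakage-free per-fold fitting of all
  training-dependent components, weak-variant training-data pooling, and
  error-rate / FPR / FNR / size-weighted-average reporting.
- **`polyasig.synthetic`** — a generator of labeled synthetic datasets with a
  planted hexamer and tunable positional signal (enriched upstream/downstream
  bands), used throughout the test suite as ground truth.

## CLI

A single executable with subcommands:

```bash
# generate a synthetic labeled dataset
polyasig simulate --kind strong --signal-strength 1.0 \
    --n-true 200 --n-pseudo 200 --seed 1 --out sim.fa

# extract 206-nt windows from a genome + polyA GTF annotation
polyasig extract genome.fa annotation.gtf --outdir windows/ \
    --pseudo-chrom chr21 --seed 1

# fit feature components and export a 218-column feature table
polyasig featurize sim.fa --out features.tsv

# train a GA-optimized tree, then score new sequences
polyasig train true.fa pseudo.fa --model-out model.joblib --seed 1
polyasig predict model.joblib sim.fa --out predictions.tsv

# cross-validated evaluation (one labeled FASTA per variant)
polyasig evaluate AATAAA.fa --out report.tsv --seed 1
```

Every run echoes its configuration to `run_config.json` in the output
directory; all stochastic paths take `--seed`.

## Notes

- The bundled structural-scale tables (`src/polyasig/features/data/scales/`)
  are fixtures with per-scale provenance; the pipeline treats them as opaque
  k-mer→value maps (k ∈ {2, 3}).
- Real-data benchmark reproduction requires the external benchmark FASTA
  files or a GENCODE r19 GTF + hg19 genome; `polyasig extract` implements
  that path but no large data ships with the repository.
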