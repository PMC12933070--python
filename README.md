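# codonlm

A codon language model for host-adapted codon optimization.

Heterologous protein expression depends on which synonymous codons a
construct uses, and genome-wide codon-usage metrics (CAI-style indices, GC
content, rare-codon fractions) capture only global preferences — not the
positional and contextual patterns a host genome actually exhibits. `codonlm`
learns a host's amino-acid→codon mapping directly from its coding sequences
with a GRU encoder–decoder and back-translates new proteins with greedy,
synonymous-family-constrained decoding, so the designed CDS translates back
to the input protein exactly while following the host's learned codon
"language". The package is aimed at protein-expression and synthetic-biology
groups who want a trainable, reproducible alternative to frequency-based
codon optimizers, plus the standard codon-usage-bias metric suite to analyse
the results.

## What it computes

- **Model**: bidirectional-GRU encoder over the amino-acid sequence; decoder
  combining the previous codon's embedding with the position-aligned encoder
  context through two dense layers into a GRU and a softmax over 66 codon
  tokens. Teacher-forced training with pad-masked cross-entropy, early
  stopping on a 20% validation split; 80/20 train/test splitting; final
  refit on the complete corpus. Implemented in numpy with hand-written
  backpropagation (gradients verified against finite differences in the
  test suite).
- **Metrics** (per-family relative frequencies x_ij from the host corpus):
  relative adaptiveness w_ij = x_ij/x_i,max; CSI = exp((1/L)Σ ln w_k);
  GC and GC3; rare-codon count/fraction (x < 0.3 and x < 1/|family|);
  codon-level sequence identity; Jaccard similarity of codon sets;
  sliding-window %MinMax profiles; algorithm ranking by #BestTiter and
  aggregated (row-normalized) score; metric–outcome correlations.
- **Hyperparameter search**: Gaussian-process Bayesian optimization of the
  five architecture hyperparameters against validation loss.
- **Synthetic corpora**: seeded generators with order-0 (frequency-only) or
  order-1 (previous-residue-conditioned) codon usage, plus the closed-form
  Bayes-optimal accuracy oracle used to benchmark the model.

## Worked example

Train on a synthetic host whose codon choice depends on the neighbouring
residue, then design a sequence:

```python
from codonlm import (ModelConfig, default_fixture_spec, generate_corpus,
                     split_corpus, train, bayes_optimal_accuracy,
                     compute_usage_table, csi, translate)

spec = default_fixture_spec(seed=7)          # 2,000 pairs, 30-120 residues
pairs = generate_corpus(spec)
split = split_corpus(pairs, seed=7)
model = train(ModelConfig(max_epochs=30, seed=7), split)

accs, acc = model.prediction_accuracy(split.test)
print(f"held-out accuracy {acc:.4f}")
print(f"Bayes optimum     {bayes_optimal_accuracy(spec):.4f}")
print(f"unigram bound     {bayes_optimal_accuracy(spec, order=0):.4f}")

cds = model.optimize_sequence("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
table = compute_usage_table(pairs)
print(cds[:30], "...", translate(cds))
print(f"CSI {csi(cds, table):.3f}")
```

Output:

```
held-out accuracy 0.9030
Bayes optimum     0.9026
unigram bound     0.4343
ATGAAAACAGCATATATTGCTAAACAGCGC ... MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ
CSI 0.938
```

The model reaches the information-theoretic ceiling of the generator (90.30%
held-out accuracy vs the 90.26% Bayes optimum) and more than doubles the
43.4% ceiling of any
context-free frequency method — the extra accuracy can only come from the
encoder exploiting neighbouring-residue context. The designed CDS
back-translates exactly (guaranteed by constrained decoding) and scores a
CSI typical of the host's own genes.

The same pipeline is scriptable from the shell:

```bash
codonlm simulate --n-sequences 2000 --seed 7 --out runs/sim
codonlm build-corpus --cds runs/sim/cds.fasta --out runs/corpus
codonlm train --cds runs/sim/cds.fasta --seed 7 --out runs/model
codonlm optimize --model runs/model --protein target.fasta --out runs/design
codonlm metrics --cds runs/design/optimized_cds.fasta \
    --usage-table runs/corpus/usage_table.tsv --out runs/report
```

Every subcommand writes a `manifest.json` (arguments, version, input
checksums) so runs are exactly reproducible.

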