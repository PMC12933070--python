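# Methods

## Problem

Synonymous codons are used non-uniformly within a genome, and the choice of
codon at a given position depends on its context, not only on genome-wide
frequencies. `codonlm` treats back-translation as a sequence-to-sequence
learning problem: given a host's CDS–protein pairs, learn the conditional
distribution of the codon at each position given the whole amino-acid
sequence and the codons already emitted, then design coding sequences for new
proteins by greedy decoding from that model. A suite of codon-usage-bias
(CUB) metrics quantifies how the designed sequences relate to the host's own
genes.

## Model

**Tokenization.** Proteins are framed as `<START> a_1 … a_L <END>` over the
20 canonical residues (23 amino-acid tokens including `<PAD>`); coding
sequences as `<START> c_1 … c_L c_stop` over the 61 sense codons plus the 3
stop codons (66 codon tokens including `<PAD>`). `<PAD>` is excluded from
the loss and from every accuracy count. CDS records lacking a terminal stop
receive `TAA` (the most common yeast stop) on the token track only.

**Architecture.** The encoder embeds the amino-acid track and runs a
bidirectional GRU (update/reset gates, candidate `n = tanh(xW_n + (r∘h)W_hn)`,
`h' = z∘h + (1−z)∘n`), producing one context vector per position that sees
residues on both sides. Because exactly one codon is emitted per residue, no
attention is needed: decoder step *t* consumes the previous codon's embedding
through a codon-side dense layer (ReLU) concatenated with the encoder context
at position *t* through an amino-acid-side dense layer (ReLU), feeds a
unidirectional GRU, and projects to a softmax over codon tokens. The five
architecture hyperparameters are the two embedding dimensions, the encoder
width per direction, and the two dense-layer sizes.

**Training.** Teacher forcing (gold previous codon as decoder input);
pad-masked categorical cross-entropy on integer codon targets; Adam with
global-norm gradient clipping at 5. Early stopping monitors validation loss
with patience 5 and restores the best-epoch parameters. Everything is plain
numpy with hand-written backpropagation through time — the models involved
are small (10⁴–10⁵ parameters) and train in minutes on one CPU; the analytic
gradients are verified against central finite differences in the test suite.

Defaults: embedding dims 16, encoder units 32 per direction, dense sizes 32,
decoder units 64, learning rate 3·10⁻³, batch size 32, patience 5. The
learning rate and batch size were chosen so that Adam converges within tens
of epochs on corpora of hundreds to a few thousand pairs (at 10⁻³ with large
batches the loss is still near the uniform-distribution bound ln 66 ≈ 4.19
after 50 epochs on such corpora). Batches are length-sorted to minimise
padding; batch order is shuffled per epoch from the config seed, so runs are
exactly reproducible.

**Splitting.** 20% of the corpus (ceiling) is reserved as a test set; 20% of
the remainder (ceiling) is the early-stopping validation set; `N=100` gives
20/16/64. The final production fit (`refit_full`) skips the test reservation
but keeps an internal 20% validation carve-out for early stopping. Identical
(protein, CDS) duplicates are removed before splitting to prevent leakage.

**Decoding.** Greedy autoregressive, starting from `<START>`, one step per
residue plus a terminal step restricted to the stop codons. In constrained
mode (the default for sequence design) the argmax at step *t* is taken over
the synonymous family of residue *t* only, so the output back-translates to
the input exactly, by construction. Unconstrained mode takes the global
argmax and is used for accuracy evaluation; an early stop-codon emission is
reported as a truncated, flagged result. No sampling or beam search: one
designed construct per protein.

**Accuracy.** Fully predictive: the previous-codon input at each step is the
model's own prediction, not the reference. Accuracy is the fraction of sense
codon positions predicted exactly, averaged per sequence and then over
sequences; stop steps are not scored.

## CUB metrics

With `x_ij` the relative synonymous frequency of codon *j* within amino acid
*i* (per-family shares summing to 1, counted over sense codons of the whole
corpus, terminal stops excluded):

- relative adaptiveness `w_ij = x_ij / x_i,max`;
- CSI = exp((1/L) Σ ln w_k), the geometric mean of w over a sequence's sense
  codons — a codon-adaptation-style index computed directly from the
  genome-wide table;
- GC = (G+C)/length over nucleotides; GC3 = share of third codon positions
  that are G or C (stops excluded);
- a codon is **rare** iff `x_ij < 0.3` and `x_ij < Avg_i = 1/|family|`, both
  strict (equality cases are not rare, so a perfectly uniform table yields
  zero rare codons); the rare fraction divides by sense-codon count;
- sequence identity is the fraction of positions with the identical codon
  (codon granularity — 1 of 2 codons, not 5 of 6 nucleotides); Jaccard
  similarity compares the *sets* of codons used, ignoring position;
- %MinMax over sliding windows (default 17 codons, the method's customary
  width; exposed as a parameter): with window means X_actual/X_max/X_min/
  X_avg of the actual codon frequency and its family's max/min/mean, the
  score is `+100·(X_actual−X_avg)/(X_max−X_avg)` above average,
  `−100·(X_avg−X_actual)/(X_avg−X_min)` below, 0 at equality. +100 means a
  window of exclusively most-frequent codons, −100 exclusively least-frequent.

The 0.3 rare threshold presumes `x` on the relative-frequency scale in
[0, 1]; the w ratio would be invariant to a per-1000 convention but the
threshold is not, so the relative-frequency reading is used. A CAI against a
curated high-expression reference set is deliberately not implemented — it
requires a reference-set choice the genome-wide table cannot supply; CSI is
the in-scope analogue.

**Benchmark ranking.** Given a titer matrix (proteins × algorithms),
`#BestTiter` counts row maxima per algorithm (ties credit all), and the
aggregated score sums row-normalized titers (bounded by the number of
proteins). Metric–outcome correlations are Pearson by default (Spearman
exposed), with zero-variance columns reported as undefined (NaN), never 0.

## Hyperparameter search

Sequential model-based optimization over integer boxes for the five
architecture hyperparameters, on a log2 scale (widths act multiplicatively):
5 random trials, then a Gaussian-process surrogate (Matern-5/2 + white noise,
normalized targets) with expected-improvement acquisition maximised over a
random candidate set, skipping already-tried points. Each trial trains with
a reduced epoch budget (default 30) and scores the best validation loss; the
search returns the argmin and the full trial log and is reproducible from
(space, corpus, seed). Default bounds: embedding dims 8–128, encoder units
32–512, dense sizes 16–256.

## Synthetic data

The generator emulates a genome's CDS–protein pairs with explicit, analysable
codon usage. Proteins are i.i.d. draws from an amino-acid composition
(default uniform); codons come from an order-0 model (per-residue
distribution — what a frequency-based optimizer sees) or an order-1 model
conditioned on the **previous residue**. Conditioning on the neighbouring
amino acid rather than the previous codon is deliberate: the signal is
visible to the sequence encoder but invisible in marginal codon frequencies,
so beating the unigram bound is evidence of context learning specifically.

The standard fixture is 2,000 sequences of 30–120 residues (seed 7) under
the rotation context model: for amino acid *i* after context residue *j*,
family member `(i+j) mod k` carries probability 0.9, the rest share 0.1; the
first residue uses the uniform-context marginal, so position 0 carries no
context signal. This corpus trains to convergence in about a minute on one
CPU. Its exact Bayes-optimal accuracy (computed in closed form, with the
first-position term weighted by E[1/L]) is 0.9026 and its context-free
unigram bound is 0.4343, leaving a wide margin in which context learning is
unambiguous.

What the generator does **not** emulate: real amino-acid composition, gene
length distributions, expression-level-dependent codon bias, GC pressure
gradients, cis-regulatory or repeat elements, and mRNA-structure constraints.
Tests passing on these corpora therefore demonstrate that the architecture,
training loop and decoding are correct and can extract contextual codon
preferences; they do not certify expression improvements for any real host,
which require training on the host's genome and wet-lab validation.

## Numerical choices and degenerate inputs

- float64 throughout; GRU pad steps carry the hidden state unchanged in both
  directions, so padding never contaminates real positions.
- Untrained-model cross-entropy starts at ln 66 ≈ 4.19 (small-scale Glorot
  initialisation, zero biases); non-finite loss aborts with the epoch index.
- Usage-table rows for amino acids absent from a corpus are flagged
  `unobserved` rather than filled; CSI on a codon with w = 0 reports the
  position unless an explicit pseudocount is requested.
- Ties in greedy decoding resolve to the lowest codon index (alphabetical);
  ties in `#BestTiter` credit every tied algorithm; an all-zero titer row is
  an error (normalisation undefined).
- `%MinMax` windows require odd width and at least window-many codons
  (shorter sequences yield an empty profile by contract, reported as an
  error when a profile is requested).
- RNA input (`U`) is normalised to `T` with a logged warning; proteins with
  non-canonical symbols (X, B, Z, U) are rejected at corpus build and at
  design time — the vocabulary cannot emit codons for them.

## Known limitations

Single-host modelling only (no species tokens); greedy decoding returns one
construct and cannot trade off alternatives; CPU-bound numpy training is not
meant for corpora far beyond ~10⁴ pairs; the Bayes oracle assumes i.i.d.
residues as generated, so it does not transfer to real genomes where the
true ceiling is unknown.
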