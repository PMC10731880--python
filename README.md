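# grelex

Sentence-level biomedical relation extraction with **sentence graphs**
and a **graph pointer layer**.

Deciding whether (and which) relation holds between a marked entity
pair — e.g. the chemical–protein relation groups of CHEMPROT — is
usually attacked by fine-tuning a sequence encoder. Sequences, however,
understate how close two words are syntactically: a chemical and the
verb governing it can be ten tokens apart yet three dependency edges
apart. grelex models each sentence as an undirected graph over its
word-piece tokens, built from a dependency parse (first pieces of
dependency-linked words connected, pieces of one word chained), and
refines every token's contextual vector with a pointer mechanism over
its multi-hop graph neighborhood before classifying.

The pipeline, per sentence *s* with token vectors `X ∈ R^{m×d1}`:

1. **Graph construction** — adjacency `A` (symmetric 0/1, zero
   diagonal) from the parse + subword alignment.
2. **GCN** — `X̂ = σ(D^{-1/2} A D^{-1/2} X W)`, no self-loops.
3. **Sampling** — per node, a BFS hop-ordered neighbor sequence
   (random order within a hop), capped at `L` slots.
4. **Pointer selection** — an LSTM encoder reads the sequence; an LSTM
   decoder with additive attention `softmax(vᵀ tanh(W₁e_q + W₂d_p))`
   points at the `M` most relevant neighbors, one per step, without
   repetition.
5. **Aggregation** — a shared 1-D convolution over the ordered
   selections, max-pooled → `Z ∈ R^{m×d2}`.
6. **Head** — per-token fusion of `[X | X̂ | Z]`, a sentence vector,
   and a softmax over the label scheme.

Evaluation is micro-averaged P/R/F1 over the evaluated positive classes
(for CHEMPROT: CPR:3, CPR:4, CPR:5, CPR:6, CPR:9; everything else is
`False` and excluded from the micro sums).

The neural core is implemented in NumPy on a small reverse-mode
autodiff engine (`grelex.autograd`), so the whole package — including
training — runs on one CPU with no deep-learning framework. The
built-in `ToyEncoder` (trainable embeddings + a bidirectional tanh
recurrence over a WordPiece-style vocabulary) satisfies the same
encoder contract as a pre-trained transformer; a transformer checkpoint
can be plugged in through `PretrainedEncoder` when `torch` and
`transformers` are installed.

## Worked example

Evaluating the published CHEMPROT test-set confusion matrix shipped
with the package (`examples/03_evaluate_printed_matrix.py`):

```
label           P%      R%     F1%
CPR:3        78.99   81.95   80.44
CPR:4        84.86   90.13   87.42
CPR:5        74.65   81.54   77.94
CPR:6        77.13   86.35   81.48
CPR:9        59.53   59.63   59.58
micro        77.97   82.07   79.97
```

The micro row is the headline CHEMPROT result: of everything the model
predicted as one of the five positive classes, 77.97% was exactly
right; of all gold positive instances, 82.07% were recovered with the
exact class. The gold column sums (13475 / 665 / 1661 / 195 / 293 /
644) recover the test-split class sizes.

`examples/01_sentence_graph.py` and `examples/02_neighbor_sampling.py`
walk through graph wiring and BFS sampling on tiny inputs;
`examples/04_train_synthetic.py` trains the full model on a small
planted-topology corpus where the label is readable only from the parse
tree, and prints the held-out accuracy against the bag-of-tokens
ceiling.

There is also a thin CLI (`grelex synth|preprocess|train|evaluate|
predict|sweep`); `grelex evaluate --matrix <tsv>` reproduces the table
above from any printed matrix.

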