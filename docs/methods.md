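# Methods

## Model

grelex classifies the relation of one marked entity pair per sentence.
A sentence arrives as (a) text with the two mentions wrapped
`@mention#`, and (b) a dependency parse in CoNLL-U. The encoder
tokenizes the text into word-pieces and produces one contextual vector
per piece (`X`, m×d1). The parse is re-segmented to the encoder's word
boundaries (consecutive parse words merged when their concatenation
matches an encoder word; unalignable sentences are dropped with a
logged reason — the encoder's segmentation is authoritative).

**Sentence graph.** Nodes are word-pieces. Edges: first piece of a
dependent word ↔ first piece of its head word; consecutive pieces of
one word. Entity-marker characters ride on the mention's token and are
never separate nodes. Punctuation nodes are kept (the parse includes
them; no removal rule is part of the construction). For a tree-valid
parse the piece graph is a tree (p nodes, p−1 edges): the within-word
chains graft leaves onto the word tree. Adjacency is symmetric 0/1 with
a zero diagonal — no self-loops; a token's own features re-enter at the
fusion stage instead.

**GCN.** One symmetric-normalized convolution,
`x̂_p = σ(W Σ_{q∈N(p)} x_q / √(d_p d_q))`, ReLU by default. Degree-0
factors are clamped to 1 so isolated nodes map to σ(0) rather than
dividing by zero.

**Neighbor sampling.** Per node: BFS to depth k, hop-h nodes before
hop-(h+1) nodes, uniformly shuffled within a hop, truncated at L slots;
shorter sequences are padded with a masked zero-vector sentinel.
Randomness is counter-based per (seed, sentence, node), so batches are
reproducible and order-independent. During training the sequences are
resampled every epoch (a mild regularizer); evaluation uses one fixed
seed. Default k = 2 with L = 32: at that budget the 2-hop neighborhoods
of ordinary parse trees are almost always fully sampled (the
`two_hop_coverage` statistic makes this checkable per corpus); k is
configurable when deeper reach is wanted.

**Pointer selection.** An encoder recurrence reads the sampled
sequence (masked pad steps copy the previous state; the initial state
is zero). A decoder recurrence, started from a learned `[start]`
vector, produces M states; at each step additive attention
`softmax(vᵀ tanh(W₁e_q + W₂d_p))` over the L encoder positions ranks
the neighbors, pads and previously selected positions are masked
(re-normalized), and the argmax is selected — so the M selections are
distinct real positions whenever enough exist, and the zero sentinel
fills in otherwise. Both recurrences are standard single-layer LSTMs by
default; a "strict" mode implements the bare tanh-gate recurrences
(`e_t = tanh(W[e_{t−1}, x̂_{n_t}])`) and is what the hand-computed unit
tests pin down. Selection is hard at train and test time; gradients
reach the attention weights through a straight-through estimator whose
backward path is the attention-weighted soft readout.

**Aggregation and head.** The ordered M selections pass through a
shared, same-padded 1-D convolution (width 3 by default) and a max
(optionally mean) reduction, giving the pointer output Z per node.
Per-token fusion is a ReLU affine map of `[X | X̂ | Z]`; the sentence
vector is, by default, the zero-padded token stack flattened and
affinely mapped (position-sensitive), with max/mean pooling available
as a configuration; a softmax layer over the label scheme closes the
model. Ties in the argmax prediction break toward the earlier label in
scheme order (negative label first).

**Training.** Cross-entropy, AdamW-style decoupled weight decay,
linear warmup for a configured proportion of steps then linear decay.
Defaults follow the published recipe where one exists (50 epochs,
warmup 0.1, classifier dropout 0.0, L = 32, M = 4, one pointer layer,
max sequence length 128); learning rates were not published — defaults
are 1e-3 for the from-scratch toy stack, 2e-5 being the conventional
choice when fine-tuning a pre-trained backbone. Model selection keeps
the best development micro-F1 across epochs. Everything is seeded; the
same seed reproduces the same loss curve with the toy encoder.

## Evaluation conventions

Micro P/R/F1 sum TP/FP/FN over the evaluated positive classes only;
the catch-all negative class contributes FP/FN to positive classes but
is itself excluded. This is the only reading under which the published
CHEMPROT confusion matrix reproduces its own micro row
(77.97/82.07/79.97), which the package verifies arithmetically.
Percentages are rounded to two decimals at the report boundary only.
Zero denominators yield 0 with a warning. A matrix-TSV input mode lets
printed tables be evaluated without any model run. Within the matrix
shipped for CHEMPROT, three per-class precision cells of the published
breakdown table (CPR:3, CPR:4, CPR:9) are inconsistent with the matrix
itself; the package reports the matrix-derived values and pins only the
mutually consistent cells in its tests.

## Synthetic data: what it emulates and what it does not

The generator produces CHEMPROT-shaped files (instance TSV, CoNLL-U
parses, a subword vocabulary) with a *planted topological signal*: each
sentence has two marked entities (chemical-like and gene-like words),
exactly one trigger token, and fillers. In positives the trigger sits
3 tree-hops from the chemical entity; in negatives a decoy trigger from
the same lexicon sits ≥5 hops away. Word order is an independent random
permutation of the tree nodes. Consequently: trigger identity is
uninformative (a per-trigger majority vote — the bag-of-tokens ceiling
— stays near the majority-class rate), sequence distance is
uninformative, and the label is recoverable only from the parse
topology, with Bayes accuracy exactly 1 − noise. Labels are flipped to
a random other label with the configured noise rate (default 0.05).

Design choices that make the signal representable by the architecture
under study: entity mentions are tree leaves (extra modifiers attach to
non-entity nodes — also the linguistically ordinary case for noun
arguments), and sentences span 8–12 words, so a 3-hop neighborhood at
L = 8 slots is nearly saturated — the same saturation consideration
that motivates L = 32 for 2-hop neighborhoods on real parses. The
positive distance of 3 is chosen because a single GCN layer cannot see
it (no common neighbor), making the pointer-ablation contrast
meaningful; distances are configurable.

What the generator does **not** emulate: real lexical statistics,
parser errors, non-tree or non-projective structure arising from real
syntax (its random word order freely produces non-projective trees),
multi-sentence context, or entity-mention ambiguity. Passing the
planted benchmark therefore shows that the architecture can read parse
topology end to end — not that it reaches any particular score on real
corpora, which requires a pre-trained encoder and the original data.

## End-to-end benchmark conditions

`grelex.workflows.planted_topology_benchmark`: 2000 instances, noise
0.05, 70/15/15 train/dev/test split, toy encoder d1 = 32, sampler
k = 3 / L = 8, M = 2 selections, a 64-wide max-pool fusion head
(entity positions are random under the generator, so position-tied
flatten weights would need far more data), 10 epochs, batch 4,
learning rate 3e-3, warmup 0.1. Because the from-scratch pointer stack
must co-adapt three components (token embeddings, neighbor ranking,
and the head's conjunction units) inside a short epoch budget, the
benchmark trains two initializations and keeps the one with the better
development micro-F1 — the same dev-based selection already applied
across epochs. The ablated control (Z forced to zero) is trained once:
without the pointer output its development score never differentiates
between initializations. Expected behavior: the full model approaches
the 0.95 Bayes accuracy while the control stays near the ~0.5 majority
rate, since X and X̂ carry no class signal at distance 3. Accuracy is
measured against the emitted (noise-flipped) labels, so even a perfect
rule-learner scores about 0.95·a + 0.05·(1−a) for true-rule accuracy
a — the noisy-label ceiling sits near 0.905 at a ≈ 0.95.

## Numerical choices and degenerate inputs

- float64 throughout; attention masking is additive (−1e9) with
  re-normalization after masking.
- A node with every sequence position exhausted "selects" the zero
  sentinel; an isolated node yields a finite degenerate output.
- Empty sentences, truncations that would drop a mention, non-tree
  parses (cycles, multiple roots), and unalignable tokenizations are
  rejected with named reasons, never guessed at.
- Checkpoints are a `.npz` weight map plus a JSON sidecar (config,
  label scheme, vocabulary); loading restores predictions bit-for-bit.

## Known limitations

- The `@`/`#` markers are literal and unescaped in instance TSVs;
  sentences containing those characters natively are not representable.
- Self-relations (an entity paired with a duplicate mention of itself)
  are excluded during pair expansion.
- The pure-NumPy core is built for clarity and desk-scale experiments,
  not throughput; fine-tuning a real transformer encoder requires the
  optional torch/transformers backend and appropriate hardware.
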