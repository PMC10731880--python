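"""Download-free synthetic corpora with a planted graph-topological signal.

Each generated instance is a sentence over an artificial vocabulary:
two marked entity tokens (a chemical-like and a gene-like word), exactly
one *trigger* token, and filler words. The dependency tree is built so
that the trigger sits at a controlled tree distance from the first
entity: close (default 3 hops) for positive instances, far (default
5 hops) for negatives. Word order is an independent random permutation
of the tree nodes, so the trigger is sequence-far in both classes and
trigger *identity* is uninformative (negatives carry a decoy trigger
drawn from the same lexicon): the label is recoverable only from the
parse topology. The emitted gold label is the topological rule's output,
flipped to a random other label with the configured noise rate — so the
Bayes-optimal accuracy of the task is 1 − noise by construction.

A configurable fraction of filler/trigger words is split into two
word-pieces by the toy tokenizer, exercising the alignment machinery.
Outputs use the same TSV / CoNLL-U formats as real corpora, plus a
manifest JSON recording the spec and seed.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .corpus_io import (BINARY_SCHEME, LabelScheme, RelationInstance,
                        mark_entities, write_instances)
from .parse_graph import DependencyParse, write_conllu

__all__ = ["SyntheticSpec", "SyntheticCorpus", "generate_random_tree",
           "generate_corpus", "topological_label",
           "trigger_majority_accuracy"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the planted-topology task.

    Distances are tree hops between the trigger token and the first
    entity: `positive_distance` for planted positives, `negative_distance`
    for the decoy trigger in negatives. `noise` is the label-flip
    probability; `multipiece_fraction` of the non-entity vocabulary is
    split into two word-pieces.
    """

    n_instances: int = 2000
    min_words: int = 8
    max_words: int = 12
    noise: float = 0.05
    negative_fraction: float = 0.5
    positive_distance: int = 3
    negative_distance: int = 5
    multipiece_fraction: float = 0.3
    n_fillers: int = 120
    n_entities: int = 20
    triggers_per_label: int = 3
    seed: int = 0
    scheme: LabelScheme = BINARY_SCHEME

    def __post_init__(self):
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("noise must be in [0, 0.5)")
        if self.min_words < self.negative_distance + 2:
            raise ValueError("sentences too short to place the decoy trigger")
        if self.positive_distance >= self.negative_distance:
            raise ValueError("positive_distance must be < negative_distance")


@dataclass
class SyntheticCorpus:
    instances: list[RelationInstance]
    parses: dict[str, DependencyParse]
    vocab: list[str]
    trigger_lexicon: dict[str, list[str]]
    true_labels: list[str]  # pre-noise topological labels

    def write(self, outdir: str | Path, spec: SyntheticSpec) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_instances(self.instances, outdir / "instances.tsv")
        write_conllu([self.parses[i.instance_id] for i in self.instances],
                     outdir / "parses.conllu")
        (outdir / "vocab.txt").write_text("\n".join(self.vocab) + "\n",
                                          encoding="utf-8")
        manifest = {"spec": {k: v for k, v in asdict(spec).items()
                             if k != "scheme"},
                    "labels": list(spec.scheme.labels),
                    "trigger_lexicon": self.trigger_lexicon}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                              encoding="utf-8")


def generate_random_tree(n_words: int, rng: np.random.Generator,
                         words: list[str] | None = None,
                         deprel: str = "dep") -> DependencyParse:
    """Random-attachment rooted tree: node i heads to a uniform earlier node."""
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    heads = [-1] + [int(rng.integers(0, i)) for i in range(1, n_words)]
    if words is None:
        words = [f"w{i}" for i in range(n_words)]
    return DependencyParse(tuple(words), tuple(heads), (deprel,) * n_words)


def _random_word(rng: np.random.Generator, lo=3, hi=7) -> str:
    letters = string.ascii_lowercase
    n = int(rng.integers(lo, hi))
    return "".join(letters[int(rng.integers(0, 26))] for _ in range(n))


def _make_vocabulary(spec: SyntheticSpec, rng: np.random.Generator):
    """Word lists + the piece vocabulary the toy tokenizer will use."""
    seen: set[str] = set()

    def fresh(prefix="", lo=3, hi=7) -> str:
        while True:
            w = prefix + _random_word(rng, lo, hi)
            if w not in seen and not any(w.startswith(s) or s.startswith(w)
                                         for s in seen):
                seen.add(w)
                return w

    fillers = [fresh() for _ in range(spec.n_fillers)]
    chems = [fresh("c") for _ in range(spec.n_entities)]
    genes = [fresh("g") for _ in range(spec.n_entities)]
    triggers = {lab: [fresh("t") for _ in range(spec.triggers_per_label)]
                for lab in spec.scheme.evaluated_labels}
    pieces: list[str] = []
    splittable = fillers + [t for ts in triggers.values() for t in ts]
    n_split = int(round(spec.multipiece_fraction * len(splittable)))
    split_set = set(rng.choice(len(splittable), size=n_split, replace=False))
    for i, w in enumerate(splittable):
        if i in split_set and len(w) >= 4:
            cut = len(w) // 2
            pieces += [w[:cut], "##" + w[cut:]]
        else:
            pieces.append(w)
    for e in chems + genes:
        pieces += [e, f"@{e}#"]  # unmarked and marked surface forms
    return fillers, chems, genes, triggers, pieces


def topological_label(parse: DependencyParse,
                      trigger_lexicon: dict[str, list[str]],
                      spec: SyntheticSpec) -> str:
    """The generative rule, recomputable from emitted files alone.

    Class of the sentence's unique trigger token if its tree distance to
    the chemical entity (the marked word whose surface form starts with
    'c') is at most `positive_distance`; otherwise the negative label.
    """
    trigger_class = {t: lab for lab, ts in trigger_lexicon.items() for t in ts}
    words = list(parse.words)
    trig = next(i for i, w in enumerate(words) if w in trigger_class)
    ent1 = next(i for i, w in enumerate(words)
                if w.startswith("@") and w[1:].startswith("c"))

    def ancestors(i):
        out = []
        while i != -1:
            out.append(i)
            i = parse.heads[i]
        return out

    # unique tree path length via the lowest common ancestor
    a1, a2 = ancestors(trig), ancestors(ent1)
    common = set(a1) & set(a2)
    dist = min(a1.index(c) + a2.index(c) for c in common)
    if dist <= spec.positive_distance:
        return trigger_class[words[trig]]
    return spec.scheme.negative_label


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate instances, parses, and the tokenizer vocabulary.

    Deterministic per (spec, seed): every instance draws from its own
    counter-based RNG stream, so corpora are byte-identical across runs.
    """
    master = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    fillers, chems, genes, triggers, pieces = _make_vocabulary(spec, master)
    pos_labels = list(spec.scheme.evaluated_labels)
    all_triggers = [t for ts in triggers.values() for t in ts]
    instances: list[RelationInstance] = []
    parses: dict[str, DependencyParse] = {}
    true_labels: list[str] = []

    for i in range(spec.n_instances):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, i]))
        negative = rng.random() < spec.negative_fraction
        if negative:
            true = spec.scheme.negative_label
            trigger = all_triggers[int(rng.integers(len(all_triggers)))]
            dist = spec.negative_distance
        else:
            true = pos_labels[int(rng.integers(len(pos_labels)))]
            trigger = triggers[true][int(rng.integers(spec.triggers_per_label))]
            dist = spec.positive_distance
        n_words = int(rng.integers(spec.min_words, spec.max_words + 1))
        n_words = max(n_words, dist + 2)

        # tree over abstract nodes 0..n-1:
        # chain trigger(0) - path(1..dist-1) - entity1(dist), entity2 leaf
        edges = [(j, j + 1) for j in range(dist)]
        ent1, ent2 = dist, dist + 1
        edges.append((ent1, ent2))
        n_core = dist + 2
        # extra modifiers attach >= 3 hops from the chemical entity: its
        # local neighborhood stays sparse (the regime the sampler's L
        # budget targets), and entity mentions remain tree leaves
        d_ent1 = [dist - j for j in range(dist + 1)] + [1]
        for j in range(n_core, n_words):
            cands = [x for x in range(j) if d_ent1[x] >= 3]
            parent = cands[int(rng.integers(len(cands)))]
            edges.append((parent, j))
            d_ent1.append(d_ent1[parent] + 1)

        # words per node
        node_words = [""] * n_words
        node_words[0] = trigger
        node_words[ent1] = chems[int(rng.integers(len(chems)))]
        node_words[ent2] = genes[int(rng.integers(len(genes)))]
        for j in list(range(1, dist)) + list(range(n_core, n_words)):
            node_words[j] = fillers[int(rng.integers(len(fillers)))]

        # orient the tree from a random root
        root = int(rng.integers(0, n_words))
        adj: dict[int, list[int]] = {j: [] for j in range(n_words)}
        for u, v in edges:
            adj[u].append(v)
            adj[v].append(u)
        heads_node = [-2] * n_words
        heads_node[root] = -1
        stack = [root]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if heads_node[v] == -2:
                    heads_node[v] = u
                    stack.append(v)

        # scatter nodes over sentence positions
        pos_of_node = rng.permutation(n_words)
        node_at = np.empty(n_words, dtype=np.int64)
        node_at[pos_of_node] = np.arange(n_words)
        sent_words = [node_words[node_at[p]] for p in range(n_words)]
        plain = " ".join(sent_words)
        p1, p2 = int(pos_of_node[ent1]), int(pos_of_node[ent2])
        off = np.cumsum([0] + [len(w) + 1 for w in sent_words])
        span1 = (int(off[p1]), int(off[p1]) + len(sent_words[p1]))
        span2 = (int(off[p2]), int(off[p2]) + len(sent_words[p2]))
        marked = mark_entities(plain, span1, span2)

        # label noise: flip to a uniformly random *other* label
        label = true
        if rng.random() < spec.noise:
            others = [l for l in spec.scheme.labels if l != true]
            label = others[int(rng.integers(len(others)))]

        iid = f"syn{i}"
        instances.append(RelationInstance(iid, marked, span1, span2, label))
        true_labels.append(true)
        # parse over *marked* words (markers ride on the mention token)
        marked_words = tuple(marked.split())
        heads_pos = tuple(
            -1 if heads_node[node_at[p]] == -1
            else int(pos_of_node[heads_node[node_at[p]]])
            for p in range(n_words))
        parses[iid] = DependencyParse(marked_words, heads_pos,
                                      ("dep",) * n_words, sent_id=iid)

    vocab = pieces + ["@", "#"]
    return SyntheticCorpus(instances, parses, vocab, triggers, true_labels)


def trigger_majority_accuracy(corpus: SyntheticCorpus) -> float:
    """Best accuracy any bag-of-tokens rule can reach from trigger identity.

    Trigger identity is the only token-level feature correlated with the
    label (fillers and entities are drawn independently of the class), so
    a per-trigger majority vote is the bag-of-words ceiling on this task.
    """
    trig_of = {t: lab for lab, ts in corpus.trigger_lexicon.items() for t in ts}
    by_trigger: dict[str, list[str]] = {}
    for inst in corpus.instances:
        words = inst.text.split()
        t = next(w for w in words if w in trig_of)
        by_trigger.setdefault(t, []).append(inst.label)
    hits = 0
    for labs in by_trigger.values():
        vals, counts = np.unique(labs, return_counts=True)
        hits += int(counts.max())
    return hits / len(corpus.instances)
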