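import numpy as np
import pytest

from grelex import (SamplerConfig, SyntheticSpec, ToyEncoder,
                    build_sentence_graph, generate_corpus)
from grelex.parse_graph import DependencyParse, SentenceGraph, WordPieceAlignment


def make_graph(adjacency, d1: int = 1) -> SentenceGraph:
    """SentenceGraph from a plain adjacency matrix (zero attributes)."""
    adjacency = np.asarray(adjacency, dtype=np.int8)
    m = adjacency.shape[0]
    return SentenceGraph(adjacency, np.zeros((m, d1)),
                         tuple(f"t{i}" for i in range(m)), tuple(range(m)))


def path_graph(n: int, d1: int = 1) -> SentenceGraph:
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return make_graph(adj, d1)


def star_graph(n_leaves: int, d1: int = 1) -> SentenceGraph:
    adj = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.int8)
    adj[0, 1:] = adj[1:, 0] = 1
    return make_graph(adj, d1)


def random_tree_graph(n: int, rng: np.random.Generator,
                      d1: int = 1) -> SentenceGraph:
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(1, n):
        j = int(rng.integers(0, i))
        adj[i, j] = adj[j, i] = 1
    return make_graph(adj, d1)


@pytest.fixture
def tiny_corpus():
    """40-instance noiseless planted corpus (binary scheme)."""
    spec = SyntheticSpec(n_instances=40, noise=0.0, seed=7)
    return spec, generate_corpus(spec)


@pytest.fixture
def tiny_encoder(tiny_corpus):
    _, corpus = tiny_corpus
    return ToyEncoder(corpus.vocab, d1=16, seed=0)


@pytest.fixture
def sampler_cfg():
    return SamplerConfig(k=2, L=8, seed=0)
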