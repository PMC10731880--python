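"""Multi-hop breadth-first neighbor sequence sampling.

For each node of a sentence graph, neighbors are collected hop by hop
out to depth ``k`` (BFS), hop-h nodes always preceding hop-(h+1) nodes,
with a uniformly random order inside each hop. Sampling stops once the
sequence reaches length ``L``; shorter sequences are padded with a
sentinel slot whose representation is the zero vector and which is
masked out of the downstream encoder.

Randomness is counter-based: every (seed, sentence, node) triple gets
its own generator stream, so batch results are independent of iteration
order and reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parse_graph import SentenceGraph

__all__ = ["SamplerConfig", "NeighborSequence", "sample_neighbor_sequence",
           "batch_sample", "two_hop_coverage", "PAD"]

PAD = -1  # sentinel node index for padding slots


@dataclass(frozen=True)
class SamplerConfig:
    """k: maximum hop depth; L: sequence cap; seed: base RNG seed."""

    k: int = 2
    L: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.k < 1 or self.L < 1:
            raise ValueError("k and L must be >= 1")


@dataclass(frozen=True)
class NeighborSequence:
    """Hop-ordered neighbor sample for one center node.

    `entries` is an ordered list of (node, hop) with non-decreasing hops,
    no duplicates, and never the center itself; `pad_count` slots were
    appended to reach length L.
    """

    center: int
    entries: tuple[tuple[int, int], ...]
    pad_count: int

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(n for n, _ in self.entries)

    @property
    def length(self) -> int:
        return len(self.entries) + self.pad_count

    def padded_nodes(self) -> np.ndarray:
        """Node indices padded with PAD to the full length L."""
        return np.array(list(self.nodes) + [PAD] * self.pad_count, dtype=np.int64)


def _node_rng(cfg: SamplerConfig, sentence_key: int, node: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(sentence_key), int(node)]))


def sample_neighbor_sequence(
    graph: SentenceGraph,
    center: int,
    cfg: SamplerConfig,
    rng: np.random.Generator | None = None,
    sentence_key: int = 0,
) -> NeighborSequence:
    """BFS sample of `center`'s neighborhood, capped at L entries.

    Hop-1 neighbors are exhausted before hop-2 begins, and so on, so a
    hop larger than L is truncated mid-hop (after its random shuffle).
    """
    if not (0 <= center < graph.node_count):
        raise IndexError(f"center {center} out of range")
    if rng is None:
        rng = _node_rng(cfg, sentence_key, center)
    entries: list[tuple[int, int]] = []
    visited = {center}
    frontier = [center]
    for hop in range(1, cfg.k + 1):
        nxt: list[int] = []
        for u in frontier:
            for v in graph.neighbors(u):
                v = int(v)
                if v not in visited:
                    visited.add(v)
                    nxt.append(v)
        if not nxt:
            break
        order = rng.permutation(len(nxt))
        for j in order:
            if len(entries) >= cfg.L:
                break
            entries.append((nxt[j], hop))
        if len(entries) >= cfg.L:
            break
        frontier = nxt
    return NeighborSequence(center, tuple(entries), cfg.L - len(entries))


def batch_sample(graph: SentenceGraph, cfg: SamplerConfig,
                 sentence_key: int = 0) -> list[NeighborSequence]:
    """One neighbor sequence per node, with per-node derived RNG streams."""
    return [
        sample_neighbor_sequence(graph, c, cfg, sentence_key=sentence_key)
        for c in range(graph.node_count)
    ]


def two_hop_coverage(graph: SentenceGraph, cfg: SamplerConfig) -> float:
    """Fraction of nodes whose full 2-hop neighborhood fits within L."""
    m = graph.node_count
    if m == 0:
        return 1.0
    a = graph.adjacency.astype(np.int64)
    within = (a + a @ a) > 0  # reachable in one or two steps
    np.fill_diagonal(within, False)
    counts = within.sum(axis=1)
    return float(np.mean(counts <= cfg.L))
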