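"""Multi-hop BFS neighbor sequences and two-hop coverage.

Each node gets a hop-ordered sample of its neighborhood, capped at L
slots; the coverage statistic is the fraction of nodes whose entire
2-hop neighborhood fits in L — the quantity that motivates choosing L
large enough to nearly saturate two hops.
"""

import numpy as np

from grelex import (SamplerConfig, batch_sample, sample_neighbor_sequence,
                    two_hop_coverage)
from grelex.parse_graph import SentenceGraph

# a star: one hub with 6 leaves
m = 7
adj = np.zeros((m, m), dtype=np.int8)
adj[0, 1:] = adj[1:, 0] = 1
graph = SentenceGraph(adj, np.zeros((m, 2)),
                      tuple(f"t{i}" for i in range(m)), tuple(range(m)))

cfg = SamplerConfig(k=2, L=4, seed=42)
seq = sample_neighbor_sequence(graph, 1, cfg)   # a leaf
print("leaf 1 sample (node, hop):", seq.entries, "pads:", seq.pad_count)
print("  hop 1 is the hub; hop 2 are sibling leaves, shuffled, capped at L=4")

seq_hub = sample_neighbor_sequence(graph, 0, cfg)
print("hub sample:", seq_hub.entries,
      "- 6 leaves but only L=4 slots, all hop 1")

print("two-hop coverage at L=4:",
      two_hop_coverage(graph, cfg),
      "(no node's 2-hop neighborhood of size 6 fits in 4 slots)")
print("two-hop coverage at L=8:",
      two_hop_coverage(graph, SamplerConfig(k=2, L=8, seed=0)))

batch = batch_sample(graph, cfg)
print("batch is per-node reproducible:",
      batch[1] == sample_neighbor_sequence(graph, 1, cfg))
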