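"""Build a sentence graph from a dependency parse and a subword split.

A word split into pieces (here 'tacrine' -> tac + ##rine) contributes a
chain of piece nodes; dependencies connect the *first* pieces of the two
words involved. The result is always a tree over pieces when the parse
is a tree over words.
"""

import numpy as np

from grelex import (DependencyParse, align_wordpieces, build_sentence_graph,
                    graph_distance)

parse = DependencyParse(
    words=("the", "drug", "tacrine", "inhibits", "@AChE#"),
    heads=(1, 3, 3, -1, 3),           # "inhibits" is the root
    deprels=("det", "nsubj", "appos", "root", "obj"),
)
pieces = ["the", "drug", "tac", "##rine", "inhibits", "@AChE#"]
align = align_wordpieces(parse.words, pieces)

reps = np.zeros((len(pieces), 4))     # attribute vectors (placeholder here)
graph = build_sentence_graph(parse, align, reps)

print("pieces:", graph.node_labels)
print("edges:")
for u, v in zip(*np.nonzero(np.triu(graph.adjacency))):
    print(f"  {graph.node_labels[u]} -- {graph.node_labels[v]}")
print("nodes:", graph.node_count, "edges:", graph.edge_count(),
      "(a tree: edges = nodes - 1)")
d = graph_distance(graph, 2, 5)
print(f"hops from 'tac' to '@AChE#': {d} "
      "(the dependency edge leaves from the first piece)")
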