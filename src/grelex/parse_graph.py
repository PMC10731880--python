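"""Sentence graphs from dependency parses and subword tokenizations.

A sentence is modelled as an undirected graph over its *word-piece*
tokens: if two words are linked by a dependency, the first pieces of
those words are connected; the pieces of a multi-piece word are chained
in order. The adjacency matrix is symmetric 0/1 with zero diagonal, and
for a tree-valid parse the resulting piece graph is again a tree
(p nodes, p−1 edges, connected).

Parses are consumed as CoNLL-U (standard 10-column); only the head
structure matters downstream — dependency relation labels are retained
but never influence the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, shortest_path

__all__ = [
    "DependencyParse",
    "WordPieceAlignment",
    "SentenceGraph",
    "ParseError",
    "read_conllu",
    "write_conllu",
    "align_wordpieces",
    "build_sentence_graph",
    "graph_distance",
    "UNREACHABLE",
]

UNREACHABLE = -1  # explicit encoding for disconnected node pairs


class ParseError(ValueError):
    """Raised for non-tree parses or unalignable tokenizations."""


@dataclass(frozen=True)
class DependencyParse:
    """A rooted dependency tree over surface words.

    `heads[i]` is the 0-based index of word i's syntactic head, or -1 for
    the single root. Exactly one root is required and the head relation
    must be acyclic.
    """

    words: tuple[str, ...]
    heads: tuple[int, ...]
    deprels: tuple[str, ...]
    sent_id: str = ""

    def __post_init__(self):
        n = len(self.words)
        if not (len(self.heads) == len(self.deprels) == n):
            raise ParseError("words/heads/deprels length mismatch")
        roots = [i for i, h in enumerate(self.heads) if h == -1]
        if len(roots) != 1:
            raise ParseError(f"expected exactly one root, found {roots}")
        for i, h in enumerate(self.heads):
            if h != -1 and not (0 <= h < n):
                raise ParseError(f"head index {h} of word {i} out of range")
        # cycle check: walk to the root from every word
        for i in range(n):
            seen, j = set(), i
            while j != -1:
                if j in seen:
                    raise ParseError(f"head cycle through word indices {sorted(seen)}")
                seen.add(j)
                j = self.heads[j]


@dataclass(frozen=True)
class WordPieceAlignment:
    """Mapping between a word segmentation and its word-piece expansion.

    Pieces of one word are contiguous and ordered; every word has at
    least one piece, so the map piece→word is surjective.
    """

    pieces: tuple[str, ...]
    word_of_piece: tuple[int, ...]
    first_piece_of_word: tuple[int, ...]


def align_wordpieces(words: Sequence[str], pieces: Sequence[str],
                     continuation: str = "##") -> WordPieceAlignment:
    """Align a piece sequence to its source words.

    Concatenating a word's pieces (continuation prefixes stripped,
    case-folded) must reproduce the word; alignment fails on the first
    divergent word.
    """
    word_of_piece: list[int] = []
    first_piece: list[int] = []
    wi, buf = 0, ""
    for pi, piece in enumerate(pieces):
        if wi >= len(words):
            raise ParseError(f"pieces left over after last word: {pieces[pi:]}")
        chunk = piece[len(continuation):] if piece.startswith(continuation) else piece
        if not buf:
            first_piece.append(pi)
        buf += chunk
        word_of_piece.append(wi)
        target = words[wi].casefold()
        if buf.casefold() == target:
            wi, buf = wi + 1, ""
        elif not target.startswith(buf.casefold()):
            raise ParseError(
                f"pieces diverge at word {wi} ({words[wi]!r}): accumulated {buf!r}")
    if wi != len(words) or buf:
        raise ParseError(f"pieces exhausted at word {wi} of {len(words)}")
    return WordPieceAlignment(tuple(pieces), tuple(word_of_piece), tuple(first_piece))


@dataclass(frozen=True)
class SentenceGraph:
    """Undirected graph over word-piece tokens with per-node attributes."""

    adjacency: np.ndarray          # (m, m) symmetric 0/1, zero diagonal
    attributes: np.ndarray         # (m, d1)
    node_labels: tuple[str, ...]   # piece strings
    word_of_node: tuple[int, ...]  # node → source word index

    def __post_init__(self):
        a = self.adjacency
        if a.shape[0] != a.shape[1]:
            raise ParseError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ParseError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ParseError("adjacency diagonal must be zero")
        if self.attributes.shape[0] != a.shape[0]:
            raise ParseError("attribute row count != node count")

    @property
    def node_count(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, u: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[u])

    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2


def build_sentence_graph(parse: DependencyParse, align: WordPieceAlignment,
                         reps: np.ndarray) -> SentenceGraph:
    """Wire the piece graph from the dependency tree and the alignment.

    Edges: (i) first piece of a dependent word ↔ first piece of its head
    word; (ii) consecutive pieces of one word. Attributes `reps` (one row
    per piece) attach to the nodes.
    """
    m = len(align.pieces)
    reps = np.asarray(reps, dtype=np.float64)
    if reps.shape[0] != m:
        raise ParseError(f"got {reps.shape[0]} attribute rows for {m} pieces")
    if len(parse.words) != len(align.first_piece_of_word):
        raise ParseError("alignment does not cover the parse's words")
    adj = np.zeros((m, m), dtype=np.int8)
    for dep, head in enumerate(parse.heads):
        if head == -1:
            continue
        u = align.first_piece_of_word[dep]
        v = align.first_piece_of_word[head]
        adj[u, v] = adj[v, u] = 1
    for pi in range(1, m):
        if align.word_of_piece[pi] == align.word_of_piece[pi - 1]:
            adj[pi, pi - 1] = adj[pi - 1, pi] = 1
    return SentenceGraph(adj, reps, tuple(align.pieces),
                         tuple(align.word_of_piece))


def graph_distance(graph: SentenceGraph, u: int, v: int) -> int:
    """Shortest-path hop count between nodes, or UNREACHABLE."""
    m = graph.node_count
    if not (0 <= u < m and 0 <= v < m):
        raise IndexError(f"node out of range: {u}, {v}")
    if u == v:
        return 0
    d = shortest_path(csr_matrix(graph.adjacency), method="D", unweighted=True,
                      indices=u)[v]
    return UNREACHABLE if np.isinf(d) else int(d)


def hop_distances(graph: SentenceGraph, center: int) -> np.ndarray:
    """All hop distances from `center` (UNREACHABLE where disconnected)."""
    d = shortest_path(csr_matrix(graph.adjacency), method="D", unweighted=True,
                      indices=center)
    out = np.where(np.isinf(d), UNREACHABLE, d).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# CoNLL-U I/O (10-column subset; multi-word token ranges are skipped)


def _parse_block(lines: list[str], sent_id: str) -> DependencyParse:
    words, heads, deprels = [], [], []
    id_map: dict[int, int] = {}
    rows = []
    for ln in lines:
        cols = ln.split("\t")
        if len(cols) != 10:
            raise ParseError(f"expected 10 columns, got {len(cols)}: {ln!r}")
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:  # multiword ranges / empty nodes
            continue
        rows.append(cols)
        id_map[int(tok_id)] = len(rows) - 1
    for cols in rows:
        words.append(cols[1])
        head = int(cols[6])
        if head == 0:
            heads.append(-1)
        else:
            if head not in id_map:
                raise ParseError(f"head id {head} not present in sentence")
            heads.append(id_map[head])
        deprels.append(cols[7])
    return DependencyParse(tuple(words), tuple(heads), tuple(deprels), sent_id)


def read_conllu(source: str | Path) -> list[DependencyParse]:
    """Read all sentence blocks from a CoNLL-U file or string."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    parses: list[DependencyParse] = []
    block: list[str] = []
    sent_id = ""
    for line in text.splitlines() + [""]:
        line = line.rstrip("\n")
        if line.startswith("#"):
            if line.startswith("# sent_id"):
                sent_id = line.split("=", 1)[1].strip()
            continue
        if not line.strip():
            if block:
                parses.append(_parse_block(block, sent_id))
                block, sent_id = [], ""
            continue
        block.append(line)
    return parses


def write_conllu(parses: Iterable[DependencyParse], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for parse in parses:
            if parse.sent_id:
                fh.write(f"# sent_id = {parse.sent_id}\n")
            for i, (word, head, rel) in enumerate(
                    zip(parse.words, parse.heads, parse.deprels)):
                # CoNLL-U is 1-based with head 0 for the root
                fh.write("\t".join([
                    str(i + 1), word, "_", "_", "_", "_",
                    str(head + 1), rel, "_", "_",
                ]) + "\n")
            fh.write("\n")
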