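"""The graph pointer layer.

Per sentence graph, four stages produce an optimized representation for
every node:

1. **GCN local encoding** — one symmetric-normalized graph convolution
   (no self-loops; self-information re-enters at the fusion stage):
   ``x̂_p = σ(W Σ_{q∈N(p)} x_q / √(d_p d_q))`` with degree-0 factors
   clamped to 1.
2. **Sequence encoder** — a recurrence over each node's hop-ordered
   neighbor sample (padded slots copy the previous state). Two cells are
   available: a standard LSTM (default) and the simplified tanh gate
   ``e_t = tanh(W[e_{t−1}, x̂_{n_t}])`` ("strict" mode, used for
   hand-computed checks).
3. **Pointer decoder** — M decode steps; at each, additive attention
   ``softmax(vᵀ tanh(W1 e_q + W2 d_p))`` over the L encoder positions
   ranks neighbors; the argmax (pads and prior picks masked, rows
   renormalized) is selected. Selection is hard; gradients reach the
   attention logits through a straight-through soft readout.
4. **Aggregation** — a shared same-padded 1-D convolution over the
   ordered M selections, then a max (or mean) reduction → one d2 vector
   per center node.

All computation is vectorized over the m nodes of a sentence: each
recurrence step is one batched matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .autograd import Tensor, concat, stack, straight_through
from .parse_graph import SentenceGraph
from .sampler import NeighborSequence, PAD

__all__ = ["GpnnConfig", "init_gpnn_params", "normalized_adjacency",
           "gcn_forward", "encode_neighbors", "pointer_decode",
           "aggregate_selected", "gpnn_layer", "PointerSelection"]

_NEG = -1e9  # additive mask for forbidden attention positions


@dataclass(frozen=True)
class GpnnConfig:
    """Shapes and behavioural switches of the pointer layer.

    d1/d2: input attribute and GCN output dimensions (d2 defaults to d1
    at the model level); L: sampled neighbors per node; M: screened-out
    neighbors (M ≤ L); layers ∈ {1, 2}; conv_kernel: width of the 1-D
    aggregation convolution; activation: GCN nonlinearity; cell: "lstm"
    or the printed-equation "tanh" recurrence; aggregation: "max"/"mean".
    """

    d1: int
    d2: int
    L: int = 32
    M: int = 4
    layers: int = 1
    conv_kernel: int = 3
    activation: str = "relu"
    cell: str = "lstm"
    aggregation: str = "max"

    def __post_init__(self):
        if not (1 <= self.M <= self.L):
            raise ValueError(f"require 1 <= M <= L, got M={self.M}, L={self.L}")
        if self.layers not in (1, 2):
            raise ValueError("layers must be 1 or 2")
        if self.cell not in ("lstm", "tanh"):
            raise ValueError("cell must be 'lstm' or 'tanh'")
        if self.aggregation not in ("max", "mean"):
            raise ValueError("aggregation must be 'max' or 'mean'")
        if self.conv_kernel < 1 or self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd and >= 1")


@dataclass
class PointerSelection:
    """Selected neighbor-sequence indices and the attention that chose them.

    `indices` is (m, M) into each node's length-L sequence (L encodes the
    zero sentinel used when every position was exhausted); `attention` is
    (m, M, L), each unexhausted row summing to 1.
    """

    indices: np.ndarray
    attention: np.ndarray


def _init(rng: np.random.Generator, *shape) -> Tensor:
    scale = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def init_gpnn_params(cfg: GpnnConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """All trainable weights, keyed by canonical names (per layer)."""
    params: dict[str, Tensor] = {}
    for layer in range(cfg.layers):
        d_in = cfg.d1 if layer == 0 else cfg.d2
        d = cfg.d2
        p = f"layer{layer}."
        params[p + "gcn.W"] = _init(rng, d_in, d)
        gate = 4 if cfg.cell == "lstm" else 1
        for rec in ("enc", "dec"):
            params[p + f"{rec}.Wx"] = _init(rng, d, gate * d)
            params[p + f"{rec}.Wh"] = _init(rng, d, gate * d)
            bias = np.zeros(gate * d)
            if cfg.cell == "lstm":
                bias[d:2 * d] = 1.0  # forget-gate bias: retain memory early
            params[p + f"{rec}.b"] = Tensor(bias, requires_grad=True)
        params[p + "ptr.v"] = _init(rng, d)
        params[p + "ptr.W1"] = _init(rng, d, d)
        params[p + "ptr.W2"] = _init(rng, d, d)
        params[p + "start"] = _init(rng, d)
        params[p + "conv.K"] = _init(rng, cfg.conv_kernel, d, d)
        params[p + "conv.b"] = Tensor(np.zeros(d), requires_grad=True)
    return params


# ---------------------------------------------------------------------------
# Stage 1: GCN


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """D^{-1/2} A D^{-1/2} with no self-loops; degree-0 factors clamp to 1."""
    a = np.asarray(adjacency, dtype=np.float64)
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    deg = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1.0))
    return inv_sqrt[:, None] * a * inv_sqrt[None, :]


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "tanh":
        return x.tanh()
    if name == "identity":
        return x
    raise ValueError(f"unknown activation {name!r}")


def gcn_forward(X: Tensor, adjacency: np.ndarray, W: Tensor,
                activation: str = "relu") -> Tensor:
    """One graph convolution: σ(N X W), N the normalized adjacency."""
    n = Tensor(normalized_adjacency(adjacency))
    return _activate(n @ X @ W, activation)


# ---------------------------------------------------------------------------
# Stage 2: neighbor-sequence encoder


def _gather_sequences(X_hat: Tensor, sequences: Sequence[NeighborSequence],
                      L: int) -> tuple[Tensor, np.ndarray]:
    """(m, L, d) per-node neighbor representations + (m, L) real-slot mask.

    Pad slots index a zero sentinel row appended below X̂.
    """
    m, d = X_hat.shape
    idx = np.stack([s.padded_nodes() for s in sequences])  # (m, L), PAD = -1
    if idx.shape != (m, L):
        raise ValueError(f"expected {m} sequences of length {L}, got {idx.shape}")
    mask = (idx != PAD).astype(np.float64)
    idx = np.where(idx == PAD, m, idx)
    X_ext = concat([X_hat, Tensor(np.zeros((1, d)))], axis=0)
    return X_ext[idx], mask


def _cell_step(x: Tensor, h: Tensor, c: Tensor | None, wx: Tensor, wh: Tensor,
               b: Tensor, cell: str, d: int):
    """One recurrence step, batched over nodes; returns (h, c)."""
    pre = x @ wx + h @ wh + b
    if cell == "tanh":
        return pre.tanh(), None
    i = pre[:, 0 * d:1 * d].sigmoid()
    f = pre[:, 1 * d:2 * d].sigmoid()
    g = pre[:, 2 * d:3 * d].tanh()
    o = pre[:, 3 * d:4 * d].sigmoid()
    c_new = f * c + i * g
    return o * c_new.tanh(), c_new


def encode_neighbors(X_hat: Tensor, sequences: Sequence[NeighborSequence],
                     cfg: GpnnConfig, params: dict[str, Tensor],
                     prefix: str = "layer0.") -> tuple[Tensor, np.ndarray]:
    """Run the encoder over every node's sequence.

    Returns E of shape (m, L, d2) — hidden state after each of the L
    steps — and the (m, L) real-slot mask. Masked (padding) steps copy
    the previous state, so an all-pad sequence yields all-zero states.
    """
    seqX, mask = _gather_sequences(X_hat, sequences, cfg.L)
    m, d = X_hat.shape[0], cfg.d2
    wx, wh, b = params[prefix + "enc.Wx"], params[prefix + "enc.Wh"], params[prefix + "enc.b"]
    h = Tensor(np.zeros((m, d)))
    c = Tensor(np.zeros((m, d))) if cfg.cell == "lstm" else None
    states = []
    for t in range(cfg.L):
        x_t = seqX[:, t, :]
        h_new, c_new = _cell_step(x_t, h, c, wx, wh, b, cfg.cell, d)
        keep = Tensor(mask[:, t:t + 1])
        h = keep * h_new + (1.0 - keep) * h
        if c is not None:
            c = keep * c_new + (1.0 - keep) * c
        states.append(h)
    return stack(states, axis=1), mask  # (m, L, d)


# ---------------------------------------------------------------------------
# Stage 3: pointer decoder


def pointer_decode(E: Tensor, X_hat: Tensor,
                   sequences: Sequence[NeighborSequence], cfg: GpnnConfig,
                   params: dict[str, Tensor], prefix: str = "layer0.",
                   mask: np.ndarray | None = None
                   ) -> tuple[Tensor, PointerSelection]:
    """Select M distinct real neighbors per node by pointer attention.

    Returns the selected representations stacked as (m, M, d2) and the
    bookkeeping :class:`PointerSelection`. When a node runs out of real
    positions, remaining selections are the zero sentinel (index L).
    """
    seqX, real = _gather_sequences(X_hat, sequences, cfg.L)
    if mask is None:
        mask = real
    m, d = X_hat.shape[0], cfg.d2
    wx, wh, b = params[prefix + "dec.Wx"], params[prefix + "dec.Wh"], params[prefix + "dec.b"]
    v, w1, w2 = params[prefix + "ptr.v"], params[prefix + "ptr.W1"], params[prefix + "ptr.W2"]
    proj_E = E @ w1  # (m, L, d), shared across decode steps
    # sentinel row (zeros) appended so exhausted rows can "select" index L
    seq_ext = concat([seqX, Tensor(np.zeros((m, 1, d)))], axis=1)

    h = Tensor(np.zeros((m, d)))
    c = Tensor(np.zeros((m, d))) if cfg.cell == "lstm" else None
    x_in = params[prefix + "start"].reshape(1, d) + Tensor(np.zeros((m, d)))

    forbidden = (mask == 0.0)  # (m, L): pads, then also prior selections
    sel_idx = np.zeros((m, cfg.M), dtype=np.int64)
    attn_rows = []
    picked = []
    for p in range(cfg.M):
        h, c = _cell_step(x_in, h, c, wx, wh, b, cfg.cell, d)
        scores = (proj_E + (h @ w2).reshape(m, 1, d)).tanh() @ v  # (m, L)
        add_mask = np.where(forbidden, _NEG, 0.0)
        attn = (scores + Tensor(add_mask)).softmax(axis=1)  # (m, L)
        exhausted = forbidden.all(axis=1)  # rows with nothing left to pick
        hard_idx = np.where(exhausted, cfg.L,
                            np.argmax(np.where(forbidden, -np.inf, attn.data),
                                      axis=1))
        sel_idx[:, p] = hard_idx
        live = Tensor((~exhausted).astype(np.float64)[:, None])
        soft = (attn.reshape(m, cfg.L, 1) * seqX).sum(axis=1) * live  # (m, d)
        hard = seq_ext[np.arange(m), hard_idx]  # (m, d)
        chosen = straight_through(hard, soft)
        picked.append(chosen)
        attn_out = attn.data.copy()
        attn_out[exhausted] = 0.0
        attn_rows.append(attn_out)
        forbidden = forbidden.copy()
        forbidden[np.arange(m)[~exhausted], hard_idx[~exhausted]] = True
        x_in = chosen
    selection = PointerSelection(sel_idx, np.stack(attn_rows, axis=1))
    return stack(picked, axis=1), selection  # (m, M, d)


# ---------------------------------------------------------------------------
# Stage 4: 1-D convolution + aggregation


def aggregate_selected(selected: Tensor, cfg: GpnnConfig,
                       params: dict[str, Tensor],
                       prefix: str = "layer0.") -> Tensor:
    """Same-padded width-`conv_kernel` 1-D convolution over the ordered M
    selections, then max/mean over positions → (m, d2)."""
    m, M, d = selected.shape
    half = cfg.conv_kernel // 2
    if half:
        zeros = Tensor(np.zeros((m, half, d)))
        padded = concat([zeros, selected, zeros], axis=1)
    else:
        padded = selected
    K, bias = params[prefix + "conv.K"], params[prefix + "conv.b"]
    terms = [padded[:, k:k + M, :] @ K[k] for k in range(cfg.conv_kernel)]
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    out = out + bias
    if cfg.aggregation == "max":
        return out.max(axis=1)
    return out.mean(axis=1)


# ---------------------------------------------------------------------------
# Full layer


def gpnn_layer(graph: SentenceGraph, sequences: Sequence[NeighborSequence],
               cfg: GpnnConfig, params: dict[str, Tensor],
               X: Tensor | None = None
               ) -> tuple[Tensor, Tensor, list[PointerSelection]]:
    """Compose the four stages (stacking a second layer if configured).

    Returns (X̂ from the last layer, Z of shape (m, d2), per-layer
    pointer selections). `X` defaults to the graph's stored attributes;
    pass the encoder's gradient-carrying tensor during training.
    """
    if X is None:
        X = Tensor(graph.attributes)
    selections: list[PointerSelection] = []
    X_in = X
    for layer in range(cfg.layers):
        prefix = f"layer{layer}."
        X_hat = gcn_forward(X_in, graph.adjacency, params[prefix + "gcn.W"],
                            cfg.activation)
        E, mask = encode_neighbors(X_hat, sequences, cfg, params, prefix)
        selected, sel = pointer_decode(E, X_hat, sequences, cfg, params,
                                       prefix, mask)
        Z = aggregate_selected(selected, cfg, params, prefix)
        selections.append(sel)
        X_in = Z  # second layer consumes the first layer's output
    return X_hat, Z, selections
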