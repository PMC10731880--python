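"""Graph pointer layer: GCN, neighbor encoder, pointer decoder, aggregation."""

import numpy as np
import pytest

from grelex.autograd import Tensor
from grelex.gpnn import (GpnnConfig, aggregate_selected, encode_neighbors,
                         gcn_forward, gpnn_layer, init_gpnn_params,
                         normalized_adjacency, pointer_decode)
from grelex.sampler import NeighborSequence, SamplerConfig, batch_sample

from conftest import make_graph, path_graph, random_tree_graph


def strict_cfg(d1=1, d2=1, L=2, M=1, **kw):
    kw.setdefault("cell", "tanh")
    kw.setdefault("activation", "identity")
    return GpnnConfig(d1=d1, d2=d2, L=L, M=M, **kw)


def seq(center, entries, L):
    return NeighborSequence(center, tuple(entries), L - len(entries))


class TestGcnForward:
    def test_isolated_node_gets_sigma_zero(self):
        adj = np.zeros((2, 2))
        X = Tensor([[5.0], [7.0]])
        out = gcn_forward(X, adj, Tensor([[1.0]]), activation="tanh")
        assert np.allclose(out.data, 0.0)  # empty neighbor sum -> tanh(0)

    def test_path_graph_hand_computation(self):
        # path a-b-c, scalar features [1,2,3], W=I, sigma=identity:
        # x_b_hat = 1/sqrt(2*1)*1 + 3/sqrt(2*1); x_a_hat = 2/sqrt(1*2)
        g = path_graph(3)
        X = Tensor([[1.0], [2.0], [3.0]])
        out = gcn_forward(X, g.adjacency, Tensor([[1.0]]), "identity")
        s2 = np.sqrt(2.0)
        assert np.allclose(out.data[:, 0], [2 / s2, (1 + 3) / s2, 2 / s2])

    def test_matches_dense_normalized_adjacency_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            m, d1, d2 = rng.integers(1, 8), rng.integers(1, 5), rng.integers(1, 5)
            upper = rng.random((m, m)) < 0.4
            adj = np.triu(upper, 1).astype(float)
            adj = adj + adj.T
            X = rng.normal(size=(m, d1))
            W = rng.normal(size=(d1, d2))
            out = gcn_forward(Tensor(X), adj, Tensor(W), "relu")
            deg = np.maximum(adj.sum(1), 1.0)
            dinv = np.diag(1.0 / np.sqrt(deg))
            oracle = np.maximum(dinv @ adj @ dinv @ X @ W, 0.0)
            assert np.allclose(out.data, oracle)

    def test_non_symmetric_adjacency_rejected(self):
        with pytest.raises(ValueError):
            normalized_adjacency(np.array([[0, 1], [0, 0]]))


class TestEncodeNeighbors:
    def test_all_pad_sequence_yields_zero_states(self):
        cfg = strict_cfg(L=3)
        params = init_gpnn_params(cfg, np.random.default_rng(0))
        X = Tensor([[1.0]])
        E, mask = encode_neighbors(X, [seq(0, [], 3)], cfg, params)
        assert np.allclose(E.data, 0.0)
        assert mask.tolist() == [[0.0, 0.0, 0.0]]

    def test_zero_weights_give_tanh_zero(self):
        cfg = strict_cfg(L=1)
        params = init_gpnn_params(cfg, np.random.default_rng(0))
        for k in ("enc.Wx", "enc.Wh", "enc.b"):
            params["layer0." + k].data[...] = 0.0
        X = Tensor([[3.0], [1.0]])
        E, _ = encode_neighbors(X, [seq(0, [(1, 1)], 1), seq(1, [(0, 1)], 1)],
                                cfg, params)
        assert np.allclose(E.data, 0.0)

    def test_two_step_recurrence_matches_hand_computation(self):
        # strict cell: e_t = tanh(wx*x_t + wh*e_{t-1}), e_0 = 0
        cfg = strict_cfg(L=2)
        params = init_gpnn_params(cfg, np.random.default_rng(0))
        params["layer0.enc.Wx"].data[...] = 0.5
        params["layer0.enc.Wh"].data[...] = 0.25
        params["layer0.enc.b"].data[...] = 0.0
        X = Tensor([[0.0], [2.0], [4.0]])  # node attributes
        E, _ = encode_neighbors(X, [seq(0, [(1, 1), (2, 2)], 2),
                                    seq(1, [], 2), seq(2, [], 2)], cfg, params)
        e1 = np.tanh(0.5 * 2.0)
        e2 = np.tanh(0.5 * 4.0 + 0.25 * e1)
        assert np.allclose(E.data[0, :, 0], [e1, e2])

    def test_masked_steps_copy_previous_state(self):
        cfg = strict_cfg(L=4)
        params = init_gpnn_params(cfg, np.random.default_rng(1))
        X = Tensor([[1.0], [2.0]])
        E, _ = encode_neighbors(X, [seq(0, [(1, 1)], 4), seq(1, [(0, 1)], 4)],
                                cfg, params)
        # after the single real step, the state persists through pads
        assert np.allclose(E.data[:, 1:], E.data[:, :1])


class TestPointerDecode:
    def test_single_real_neighbor_selected_with_full_attention(self):
        cfg = strict_cfg(L=1, M=1)
        params = init_gpnn_params(cfg, np.random.default_rng(0))
        X = Tensor([[1.0], [2.0]])
        sequences = [seq(0, [(1, 1)], 1), seq(1, [(0, 1)], 1)]
        E, mask = encode_neighbors(X, sequences, cfg, params)
        selected, sel = pointer_decode(E, X, sequences, cfg, params, mask=mask)
        assert np.allclose(sel.attention, 1.0)  # softmax over a singleton
        assert sel.indices.tolist() == [[0], [0]]
        assert np.allclose(selected.data[0, 0], 2.0)  # x_hat of node 1
        assert np.allclose(selected.data[1, 0], 1.0)

    def test_attention_rows_are_probability_vectors(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            cfg = GpnnConfig(d1=3, d2=3, L=5, M=3, cell="lstm")
            params = init_gpnn_params(cfg, rng)
            g = random_tree_graph(7, rng, d1=3)
            X = Tensor(rng.normal(size=(7, 3)))
            Xh = gcn_forward(X, g.adjacency, params["layer0.gcn.W"])
            sequences = batch_sample(g, SamplerConfig(k=3, L=5, seed=trial))
            E, mask = encode_neighbors(Xh, sequences, cfg, params)
            _, sel = pointer_decode(E, Xh, sequences, cfg, params, mask=mask)
            sums = sel.attention.sum(axis=2)
            real = np.array([len(s.entries) for s in sequences])
            for i in range(7):
                for p in range(3):
                    if p < real[i]:  # unexhausted rows are normalized
                        assert abs(sums[i, p] - 1.0) < 1e-6

    def test_selected_indices_distinct_real_positions(self):
        rng = np.random.default_rng(3)
        cfg = GpnnConfig(d1=2, d2=2, L=6, M=4)
        params = init_gpnn_params(cfg, rng)
        g = random_tree_graph(9, rng, d1=2)
        X = Tensor(rng.normal(size=(9, 2)))
        sequences = batch_sample(g, SamplerConfig(k=4, L=6, seed=0))
        E, mask = encode_neighbors(X, sequences, cfg, params)
        _, sel = pointer_decode(E, X, sequences, cfg, params, mask=mask)
        for i, s in enumerate(sequences):
            n_real = len(s.entries)
            picks = sel.indices[i]
            real_picks = picks[picks < cfg.L][:n_real]
            k = min(cfg.M, n_real)
            assert len(set(real_picks[:k])) == k
            assert all(p < n_real for p in real_picks[:k])
            # exhausted rows fall back to the zero sentinel (index L)
            assert all(p == cfg.L for p in picks[k:])

    def test_argmax_sequence_matches_exhaustive_evaluation(self):
        # L=3, M=2, scalar dims, strict tanh cell: replicate the decode
        # arithmetic with plain numpy and compare selections step by step
        cfg = strict_cfg(L=3, M=2)
        rng = np.random.default_rng(4)
        params = init_gpnn_params(cfg, rng)
        p = {k.split(".", 1)[1]: v.data.copy() for k, v in params.items()}
        X = Tensor(rng.normal(size=(4, 1)))
        sequences = [seq(0, [(1, 1), (2, 1), (3, 2)], 3)] + \
            [seq(i, [], 3) for i in (1, 2, 3)]
        E, mask = encode_neighbors(X, sequences, cfg, params)
        _, sel = pointer_decode(E, X, sequences, cfg, params, mask=mask)

        # independent numpy replay
        xs = X.data[[1, 2, 3], 0]
        e, E_or = 0.0, []
        for x in xs:
            e = np.tanh(p["enc.Wx"][0, 0] * x + p["enc.Wh"][0, 0] * e)
            E_or.append(e)
        forbidden = [False, False, False]
        d, x_in = 0.0, p["start"][0]
        expect = []
        for _ in range(2):
            d = np.tanh(p["dec.Wx"][0, 0] * x_in + p["dec.Wh"][0, 0] * d)
            scores = [p["ptr.v"][0] * np.tanh(p["ptr.W1"][0, 0] * e
                                              + p["ptr.W2"][0, 0] * d)
                      for e in E_or]
            masked = [(-np.inf if f else s) for s, f in zip(scores, forbidden)]
            c = int(np.argmax(masked))
            expect.append(c)
            forbidden[c] = True
            x_in = xs[c]
        assert sel.indices[0].tolist() == expect


class TestAggregateSelected:
    def test_identity_kernel_recovers_single_selection(self):
        cfg = strict_cfg(L=1, M=1, conv_kernel=1)
        params = init_gpnn_params(cfg, np.random.default_rng(0))
        params["layer0.conv.K"].data[...] = 1.0  # (1,1,1) identity
        params["layer0.conv.b"].data[...] = 0.0
        sel = Tensor(np.array([[[3.5]], [[-2.0]]]))
        Z = aggregate_selected(sel, cfg, params)
        assert np.allclose(Z.data[:, 0], [3.5, -2.0])

    def test_all_zero_selection_gives_zero(self):
        cfg = strict_cfg(L=4, M=4, conv_kernel=3)
        params = init_gpnn_params(cfg, np.random.default_rng(0))
        params["layer0.conv.b"].data[...] = 0.0
        Z = aggregate_selected(Tensor(np.zeros((2, 4, 1))), cfg, params)
        assert np.allclose(Z.data, 0.0)

    def test_hand_computed_convolution_and_max(self):
        # scalar sequence [1,0,2,0], kernel [1,2,3] same-padded:
        # conv = [2,7,4,2] -> max 7
        cfg = strict_cfg(L=4, M=4, conv_kernel=3, aggregation="max")
        params = init_gpnn_params(cfg, np.random.default_rng(0))
        params["layer0.conv.K"].data = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        params["layer0.conv.b"].data[...] = 0.0
        sel = Tensor(np.array([[1.0], [0.0], [2.0], [0.0]]).reshape(1, 4, 1))
        Z = aggregate_selected(sel, cfg, params)
        assert np.allclose(Z.data, 7.0)


class TestGpnnLayer:
    def _run(self, g, cfg, params, X, seed=0):
        sequences = batch_sample(g, SamplerConfig(k=3, L=cfg.L, seed=seed))
        return gpnn_layer(g, sequences, cfg, params, X=X)

    def test_single_node_graph_degenerate_output(self):
        cfg = GpnnConfig(d1=2, d2=2, L=4, M=2)
        params = init_gpnn_params(cfg, np.random.default_rng(0))
        g = make_graph(np.zeros((1, 1), dtype=np.int8), d1=2)
        X_hat, Z, sels = self._run(g, cfg, params, Tensor([[1.0, -1.0]]))
        assert Z.shape == (1, 2)
        assert np.all(np.isfinite(Z.data))
        assert (sels[0].indices == cfg.L).all()  # nothing to select

    def test_deterministic_under_fixed_params_and_sequences(self):
        rng = np.random.default_rng(1)
        cfg = GpnnConfig(d1=3, d2=3, L=5, M=2)
        params = init_gpnn_params(cfg, rng)
        g = random_tree_graph(8, rng, d1=3)
        X = Tensor(rng.normal(size=(8, 3)))
        _, Z1, _ = self._run(g, cfg, params, X, seed=5)
        _, Z2, _ = self._run(g, cfg, params, X, seed=5)
        assert np.array_equal(Z1.data, Z2.data)

    def test_no_cross_node_leakage_beyond_gcn(self):
        # zeroing every other node's neighbor sequence leaves node j's
        # pointer/aggregation output unchanged
        rng = np.random.default_rng(2)
        cfg = GpnnConfig(d1=3, d2=3, L=5, M=2)
        params = init_gpnn_params(cfg, rng)
        g = random_tree_graph(6, rng, d1=3)
        X = Tensor(rng.normal(size=(6, 3)))
        sequences = batch_sample(g, SamplerConfig(k=3, L=5, seed=0))
        _, Z_full, _ = gpnn_layer(g, sequences, cfg, params, X=X)
        j = 3
        blanked = [s if i == j else NeighborSequence(s.center, (), cfg.L)
                   for i, s in enumerate(sequences)]
        _, Z_blank, _ = gpnn_layer(g, blanked, cfg, params, X=X)
        assert np.allclose(Z_full.data[j], Z_blank.data[j])

    def test_output_invariant_to_pad_slot_count(self):
        # growing L only adds masked pad slots; Z must not change
        rng = np.random.default_rng(3)
        g = path_graph(3, d1=2)
        X = Tensor(rng.normal(size=(3, 2)))
        zs = []
        for L in (4, 9):
            cfg = GpnnConfig(d1=2, d2=2, L=L, M=2, cell="tanh")
            params = init_gpnn_params(cfg, np.random.default_rng(42))
            sequences = batch_sample(g, SamplerConfig(k=3, L=L, seed=1))
            _, Z, _ = gpnn_layer(g, sequences, cfg, params, X=X)
            zs.append(Z.data)
        assert np.allclose(zs[0], zs[1])

    def test_two_layer_stacking_shapes(self):
        rng = np.random.default_rng(4)
        cfg = GpnnConfig(d1=3, d2=3, L=4, M=2, layers=2)
        params = init_gpnn_params(cfg, rng)
        g = random_tree_graph(5, rng, d1=3)
        X_hat, Z, sels = self._run(g, cfg, params, Tensor(rng.normal(size=(5, 3))))
        assert Z.shape == (5, 3) and len(sels) == 2

    def test_gradient_reaches_selected_neighbor_representations(self):
        # finite-difference of the forward map w.r.t. a selected neighbor's
        # input attribute is nonzero (hard selection still passes gradient)
        rng = np.random.default_rng(5)
        cfg = GpnnConfig(d1=2, d2=2, L=4, M=2, cell="tanh")
        params = init_gpnn_params(cfg, rng)
        g = path_graph(4, d1=2)
        Xd = rng.normal(size=(4, 2))
        sequences = batch_sample(g, SamplerConfig(k=3, L=4, seed=0))

        def f():
            _, Z, _ = gpnn_layer(g, sequences, cfg, params, X=Tensor(Xd))
            return float(Z.data.sum())

        _, Z, sels = gpnn_layer(g, sequences, cfg, params,
                                X=Tensor(Xd, requires_grad=True))
        target = sequences[0].nodes[sels[0].indices[0][0]]
        eps = 1e-5
        Xd[target, 0] += eps
        hi = f()
        Xd[target, 0] -= 2 * eps
        lo = f()
        Xd[target, 0] += eps
        assert abs(hi - lo) / (2 * eps) > 1e-8
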