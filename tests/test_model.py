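"""Fusion head, sentence representation, classification, and training loop."""

import numpy as np
import pytest

from grelex import (GpnnConfig, HeadConfig, RelationModel, SamplerConfig,
                    ToyEncoder, TrainConfig)
from grelex.autograd import Tensor
from grelex.corpus_io import BINARY_SCHEME
from grelex.model import (classify, fuse_features, init_head_params,
                          prepare_instances, realign_parse,
                          sentence_representation)
from grelex.parse_graph import DependencyParse, ParseError


def head_params(d1=2, d_f=2, d_s=2, mode="flatten", max_tokens=4, labels=2,
                seed=0):
    cfg = HeadConfig(d_f=d_f, d_s=d_s, max_tokens=max_tokens, mode=mode)
    return cfg, init_head_params(d1, d1, cfg, labels, np.random.default_rng(seed))


class TestFuseFeatures:
    def test_zero_inputs_zero_bias_zero_output(self):
        cfg, params = head_params()
        params["fuse.b"].data[...] = 0.0
        Z = Tensor(np.zeros((3, 2)))
        out = fuse_features(Z, Z, Z, params)
        assert np.allclose(out.data, 0.0)

    def test_identity_block_recovers_first_stream(self):
        cfg, params = head_params()
        W = np.zeros((6, 2))
        W[:2, :2] = np.eye(2)  # project the X block through
        params["fuse.W"].data = W
        params["fuse.b"].data[...] = 0.0
        X = Tensor(np.abs(np.random.default_rng(0).normal(size=(3, 2))))
        out = fuse_features(X, Tensor(np.zeros((3, 2))),
                            Tensor(np.zeros((3, 2))), params)
        assert np.allclose(out.data, X.data)

    def test_hand_set_weights_scalar_streams(self):
        cfg, params = head_params(d1=1, d_f=1)
        params["fuse.W"].data = np.array([[2.0], [3.0], [5.0]])
        params["fuse.b"].data[...] = 0.0
        out = fuse_features(Tensor([[1.0]]), Tensor([[10.0]]), Tensor([[100.0]]),
                            params)
        assert np.allclose(out.data, 2 + 30 + 500)

    def test_row_mismatch_rejected(self):
        cfg, params = head_params()
        with pytest.raises(ValueError):
            fuse_features(Tensor(np.zeros((2, 2))), Tensor(np.zeros((3, 2))),
                          Tensor(np.zeros((2, 2))), params)


class TestSentenceRepresentation:
    def test_all_pad_input_is_bias_only(self):
        cfg, params = head_params(mode="flatten")
        out = sentence_representation(Tensor(np.zeros((0, 2)).reshape(0, 2)),
                                      params, cfg)
        expect = np.maximum(params["sent.b"].data, 0.0)
        assert np.allclose(out.data, expect)

    def test_padding_rows_do_not_matter(self):
        cfg, params = head_params(mode="flatten", max_tokens=6)
        rng = np.random.default_rng(1)
        real = rng.normal(size=(2, 2))
        a = sentence_representation(Tensor(real), params, cfg)
        # explicit zero rows appended by hand give the same stack
        b = sentence_representation(Tensor(np.vstack([real, np.zeros((2, 2))])),
                                    params, cfg)
        assert np.allclose(a.data, b.data)

    def test_flatten_mode_is_position_sensitive(self):
        cfg, params = head_params(mode="flatten", max_tokens=4, seed=3)
        rng = np.random.default_rng(2)
        rows = rng.normal(size=(2, 2))
        a = sentence_representation(Tensor(rows), params, cfg)
        b = sentence_representation(Tensor(rows[::-1].copy()), params, cfg)
        assert not np.allclose(a.data, b.data)

    def test_token_budget_enforced(self):
        cfg, params = head_params(mode="flatten", max_tokens=2)
        with pytest.raises(ValueError, match="budget"):
            sentence_representation(Tensor(np.zeros((3, 2))), params, cfg)

    def test_max_mode_is_permutation_invariant(self):
        cfg, params = head_params(mode="max")
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(5, 2))
        a = sentence_representation(Tensor(rows), params, cfg)
        b = sentence_representation(Tensor(rows[::-1].copy()), params, cfg)
        assert np.allclose(a.data, b.data)


class TestClassify:
    def test_zero_logits_uniform(self):
        cfg, params = head_params(labels=4)
        params["cls.W"].data[...] = 0.0
        params["cls.b"].data[...] = 0.0
        logp = classify(Tensor(np.ones(2)), params)
        assert np.allclose(np.exp(logp.data), 0.25)

    def test_probabilities_normalized_for_random_vectors(self):
        cfg, params = head_params(labels=6)
        rng = np.random.default_rng(4)
        for _ in range(1000):
            logp = classify(Tensor(rng.normal(size=2)), params)
            assert abs(np.exp(logp.data).sum() - 1.0) < 1e-9

    def test_softmax_monotone_in_logits(self):
        cfg, params = head_params(labels=3)
        params["cls.W"].data = np.eye(2, 3)
        params["cls.b"].data = np.array([0.0, 0.0, -1.0])
        logp = classify(Tensor(np.array([2.0, 1.0])), params)
        assert list(np.argsort(-logp.data)) == [0, 1, 2]


class TestRealignParse:
    def test_identity_when_segmentations_agree(self):
        p = DependencyParse(("a", "b"), (-1, 0), ("r", "d"))
        assert realign_parse(p, ["a", "b"]) is p

    def test_merges_split_hyphen_words(self):
        # parser split "x-y" into x, -, y; encoder keeps one word
        p = DependencyParse(("x", "-", "y", "z"), (3, 0, 0, -1),
                            ("d", "p", "d", "root"))
        merged = realign_parse(p, ["x-y", "z"])
        assert merged.words == ("x-y", "z")
        assert merged.heads == (1, -1)

    def test_unmatchable_segmentation_rejected(self):
        p = DependencyParse(("ab", "cd"), (-1, 0), ("r", "d"))
        with pytest.raises(ParseError):
            realign_parse(p, ["abc", "d"])


def small_model(corpus, scheme, seed=0, **head_kw):
    enc = ToyEncoder(corpus.vocab, d1=8, seed=seed)
    head_kw.setdefault("mode", "max")
    return RelationModel(enc, GpnnConfig(d1=8, d2=8, L=4, M=2),
                         SamplerConfig(k=2, L=4, seed=seed),
                         HeadConfig(d_f=8, d_s=8, **head_kw), scheme,
                         seed=seed)


class TestTraining:
    def test_single_instance_overfits(self, tiny_corpus):
        spec, corpus = tiny_corpus
        model = small_model(corpus, spec.scheme)
        prep = prepare_instances(corpus.instances[:1], corpus.parses,
                                 model.encoder, spec.scheme, [])
        log = model.fit(prep, [], TrainConfig(epochs=30, batch_size=1,
                                              lr=1e-2, seed=0))
        assert log[-1].train_loss < log[0].train_loss
        assert log[-1].train_loss < 0.1

    def test_same_seed_identical_loss_curves(self, tiny_corpus):
        spec, corpus = tiny_corpus
        curves = []
        for _ in range(2):
            model = small_model(corpus, spec.scheme, seed=3)
            prep = prepare_instances(corpus.instances[:8], corpus.parses,
                                     model.encoder, spec.scheme, [])
            log = model.fit(prep[:6], prep[6:],
                            TrainConfig(epochs=3, batch_size=2, seed=3))
            curves.append([e.train_loss for e in log])
        assert curves[0] == curves[1]

    def test_loss_finite_at_initialization(self, tiny_corpus):
        spec, corpus = tiny_corpus
        for seed in range(3):
            model = small_model(corpus, spec.scheme, seed=seed)
            prep = prepare_instances(corpus.instances[:4], corpus.parses,
                                     model.encoder, spec.scheme, [])
            for p in prep:
                logp = model.forward(p)
                assert np.all(np.isfinite(logp.data))
                assert abs(np.exp(logp.data).sum() - 1.0) < 1e-9

    def test_empty_corpus_rejected(self, tiny_corpus):
        spec, corpus = tiny_corpus
        model = small_model(corpus, spec.scheme)
        with pytest.raises(ValueError):
            model.fit([], [], TrainConfig(epochs=1))

    def test_predict_rows_sum_to_one(self, tiny_corpus):
        spec, corpus = tiny_corpus
        model = small_model(corpus, spec.scheme)
        prep = prepare_instances(corpus.instances[:5], corpus.parses,
                                 model.encoder, spec.scheme, [])
        for label, probs in model.predict(prep):
            assert label in spec.scheme.labels
            assert abs(probs.sum() - 1.0) < 1e-9


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tiny_corpus, tmp_path):
        spec, corpus = tiny_corpus
        model = small_model(corpus, spec.scheme, seed=1)
        prep = prepare_instances(corpus.instances[:6], corpus.parses,
                                 model.encoder, spec.scheme, [])
        model.fit(prep[:4], prep[4:], TrainConfig(epochs=2, batch_size=2))
        before = [p for _, p in model.predict(prep)]
        model.save(tmp_path / "ckpt")
        restored = RelationModel.load(tmp_path / "ckpt")
        prep2 = prepare_instances(corpus.instances[:6], corpus.parses,
                                  restored.encoder, spec.scheme, [])
        after = [p for _, p in restored.predict(prep2)]
        for a, b in zip(before, after):
            assert np.allclose(a, b)

    def test_state_dict_name_mismatch_rejected(self, tiny_corpus):
        spec, corpus = tiny_corpus
        model = small_model(corpus, spec.scheme)
        state = model.state_dict()
        state.pop(next(iter(state)))
        with pytest.raises(KeyError):
            model.load_state_dict(state)
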