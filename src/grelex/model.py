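"""Feature fusion, sentence representation, classification, and training.

Three per-token feature streams — the raw contextual vectors X, the
GCN-smoothed X̂, and the pointer-layer output Z — are concatenated and
passed through a fully-connected layer (the fusion step). Token vectors
are then combined into one sentence vector (flattened over a fixed
token budget by default, or max/mean-pooled), and a softmax layer over
the label scheme yields the class distribution.

Training minimizes cross-entropy with a decoupled-weight-decay adaptive
optimizer, linear warmup for a configured proportion of steps followed
by linear decay, per-epoch micro-F1 on the development split, and
best-development checkpoint retention. Neighbor sequences are resampled
every epoch (a mild regularizer); evaluation uses a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .autograd import Tensor, concat
from .corpus_io import LabelScheme, RelationInstance, CHEMPROT_SCHEME
from .encoder import EncodingError, ToyEncoder
from .gpnn import GpnnConfig, gpnn_layer, init_gpnn_params
from .parse_graph import (DependencyParse, ParseError, SentenceGraph,
                          align_wordpieces, build_sentence_graph)
from .sampler import SamplerConfig, batch_sample
from . import evaluation

__all__ = ["HeadConfig", "TrainConfig", "RelationModel", "PreparedInstance",
           "fuse_features", "sentence_representation", "classify",
           "prepare_instances", "realign_parse"]


@dataclass(frozen=True)
class HeadConfig:
    """Fusion/sentence head shapes.

    d_f: fused per-token width; d_s: sentence vector width; max_tokens:
    token budget for the flatten mode; mode: "flatten" (default — the
    stacked tokens are flattened then mapped) or "max"/"mean" pooling;
    dropout: classifier dropout rate.
    """

    d_f: int = 32
    d_s: int = 32
    max_tokens: int = 128
    mode: str = "flatten"
    dropout: float = 0.0

    def __post_init__(self):
        if self.mode not in ("flatten", "max", "mean"):
            raise ValueError("mode must be flatten|max|mean")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule (defaults follow the published recipe where
    one was printed: 50 epochs, warmup proportion 0.1, dropout 0.0)."""

    epochs: int = 50
    batch_size: int = 64
    lr: float = 1e-3
    weight_decay: float = 0.0
    warmup_proportion: float = 0.1
    seed: int = 0
    log_every: int = 0

    def __post_init__(self):
        if not (0.0 <= self.warmup_proportion <= 1.0):
            raise ValueError("warmup_proportion must be in [0, 1]")


def init_head_params(d1: int, d2: int, cfg: HeadConfig, n_labels: int,
                     rng: np.random.Generator) -> dict[str, Tensor]:
    def init(*shape):
        return Tensor(rng.normal(0, 1.0 / np.sqrt(shape[0]), size=shape),
                      requires_grad=True)

    d_in = d1 + 2 * d2
    d_sent_in = cfg.max_tokens * cfg.d_f if cfg.mode == "flatten" else cfg.d_f
    return {
        "fuse.W": init(d_in, cfg.d_f),
        "fuse.b": Tensor(np.zeros(cfg.d_f), requires_grad=True),
        "sent.W": init(d_sent_in, cfg.d_s),
        "sent.b": Tensor(np.zeros(cfg.d_s), requires_grad=True),
        "cls.W": init(cfg.d_s, n_labels),
        "cls.b": Tensor(np.zeros(n_labels), requires_grad=True),
    }


def fuse_features(X: Tensor, X_hat: Tensor, Z: Tensor,
                  params: Mapping[str, Tensor]) -> Tensor:
    """Row-wise ReLU affine map of [X | X̂ | Z] → (m, d_f)."""
    if not (X.shape[0] == X_hat.shape[0] == Z.shape[0]):
        raise ValueError("feature streams disagree on token count")
    return (concat([X, X_hat, Z], axis=1) @ params["fuse.W"]
            + params["fuse.b"]).relu()


def sentence_representation(fused: Tensor, params: Mapping[str, Tensor],
                            cfg: HeadConfig) -> Tensor:
    """Combine per-token fused vectors into one sentence vector."""
    m = fused.shape[0]
    if cfg.mode == "flatten":
        if m > cfg.max_tokens:
            raise ValueError(f"{m} tokens exceed the budget {cfg.max_tokens}")
        if m < cfg.max_tokens:
            pad = Tensor(np.zeros((cfg.max_tokens - m, cfg.d_f)))
            fused = concat([fused, pad], axis=0)
        flat = fused.reshape(cfg.max_tokens * cfg.d_f)
    elif cfg.mode == "max":
        flat = fused.max(axis=0)
    else:
        flat = fused.mean(axis=0)
    return (flat @ params["sent.W"] + params["sent.b"]).relu()


def classify(sentence_vec: Tensor, params: Mapping[str, Tensor]) -> Tensor:
    """Log-probabilities over the label scheme (softmax classifier)."""
    logits = sentence_vec @ params["cls.W"] + params["cls.b"]
    return logits.log_softmax(axis=-1)


# ---------------------------------------------------------------------------
# Instance preparation: join text, parse, tokenization, and graph topology


@dataclass
class PreparedInstance:
    """Everything static about one instance: the graph topology and the
    piece-id sequence; only attribute vectors change during training."""

    instance_id: str
    token_ids: np.ndarray
    graph: SentenceGraph            # attributes are placeholder zeros
    label_index: int
    index: int                      # position in the corpus (RNG key)


def realign_parse(parse: DependencyParse, target_words: Sequence[str]
                  ) -> DependencyParse:
    """Re-segment a parse to the encoder's word segmentation.

    Consecutive parse words whose concatenation equals a target word are
    merged into one node (the encoder's segmentation is authoritative).
    The merged node keeps the first sub-word whose head lies outside the
    group; edges into the group re-point to the merged node. Raises
    :class:`ParseError` when no grouping matches.
    """
    if tuple(parse.words) == tuple(target_words):
        return parse
    groups: list[list[int]] = []
    pi = 0
    for tw in target_words:
        buf, members = "", []
        while pi < len(parse.words) and len(buf) < len(tw):
            buf += parse.words[pi]
            members.append(pi)
            pi += 1
        if buf != tw:
            raise ParseError(f"cannot align parse words to {tw!r} (got {buf!r})")
        groups.append(members)
    if pi != len(parse.words):
        raise ParseError("parse words left over after alignment")
    group_of = {w: g for g, members in enumerate(groups) for w in members}
    heads, deprels = [], []
    for g, members in enumerate(groups):
        head = None
        for w in members:
            h = parse.heads[w]
            if h == -1 or group_of[h] != g:
                head = -1 if h == -1 else group_of[h]
                deprels.append(parse.deprels[w])
                break
        if head is None:  # group closed under heads: cycle at word level
            raise ParseError(f"merged group {members} has no external head")
        heads.append(head)
    return DependencyParse(tuple(target_words), tuple(heads), tuple(deprels),
                           parse.sent_id)


def prepare_instances(
    instances: Sequence[RelationInstance],
    parses: Mapping[str, DependencyParse],
    encoder: ToyEncoder,
    scheme: LabelScheme,
    dropped: list[dict] | None = None,
) -> list[PreparedInstance]:
    """Tokenize, align, and wire the sentence graph for each instance.

    Instances with a missing parse, an unalignable tokenization, or a
    truncation that would drop a mention are skipped and recorded in
    `dropped` as (instance_id, reason) entries.
    """
    label_index = {lab: i for i, lab in enumerate(scheme.labels)}
    out: list[PreparedInstance] = []
    for idx, inst in enumerate(instances):
        try:
            parse = parses.get(inst.instance_id)
            if parse is None:
                raise ParseError("no parse for instance")
            words, pieces = encoder.tokenize(inst.text)
            parse = realign_parse(parse, words)
            align = align_wordpieces(words, pieces)
            graph = build_sentence_graph(parse, align,
                                         np.zeros((len(pieces), 1)))
            out.append(PreparedInstance(
                inst.instance_id, encoder.tokenizer.ids(pieces), graph,
                label_index[inst.label], idx))
        except (ParseError, EncodingError) as err:
            if dropped is None:
                raise
            dropped.append({"instance_id": inst.instance_id, "reason": str(err)})
    return out


# ---------------------------------------------------------------------------
# Optimizer


class AdamW:
    """Adam with decoupled weight decay and a warmup/linear-decay schedule."""

    def __init__(self, params: Mapping[str, Tensor], lr: float,
                 weight_decay: float = 0.0, total_steps: int = 1,
                 warmup_proportion: float = 0.1,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.total = max(total_steps, 1)
        self.warmup = max(int(round(warmup_proportion * self.total)), 0)
        self.t = 0
        self.state = {k: (np.zeros_like(v.data), np.zeros_like(v.data))
                      for k, v in self.params.items()}

    def _schedule(self) -> float:
        t = self.t
        if self.warmup and t < self.warmup:
            return t / self.warmup
        denom = max(self.total - self.warmup, 1)
        return max(0.0, (self.total - t) / denom)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr = self.lr * self._schedule()
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m, v = self.state[k]
            g = p.grad
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


# ---------------------------------------------------------------------------
# Model


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    dev_micro_f1: float


class RelationModel:
    """Encoder + graph pointer layer + fusion head, trained end to end."""

    def __init__(self, encoder: ToyEncoder, gpnn_cfg: GpnnConfig,
                 sampler_cfg: SamplerConfig, head_cfg: HeadConfig,
                 scheme: LabelScheme = CHEMPROT_SCHEME, seed: int = 0,
                 ablate_pointer: bool = False):
        if gpnn_cfg.d1 != encoder.d1:
            raise ValueError("gpnn d1 must match the encoder output width")
        self.encoder = encoder
        self.gpnn_cfg = gpnn_cfg
        self.sampler_cfg = sampler_cfg
        self.head_cfg = head_cfg
        self.scheme = scheme
        self.seed = seed
        #: when set, Z is forced to zero (architecture-value ablation)
        self.ablate_pointer = ablate_pointer
        rng = np.random.default_rng(seed)
        self.gpnn_params = init_gpnn_params(gpnn_cfg, rng)
        self.head_params = init_head_params(gpnn_cfg.d1, gpnn_cfg.d2, head_cfg,
                                            len(scheme.labels), rng)
        self.epoch_log: list[EpochLog] = []
        self._rng = rng

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out = {f"encoder.{k}": v for k, v in self.encoder.parameters().items()}
        out.update({f"gpnn.{k}": v for k, v in self.gpnn_params.items()})
        out.update({f"head.{k}": v for k, v in self.head_params.items()})
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in params.items():
            v.data = np.array(state[k], dtype=np.float64)

    # -- forward -----------------------------------------------------------
    def forward(self, prep: PreparedInstance, sampler_seed: int | None = None,
                train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Log-probabilities over labels for one prepared instance."""
        cfg = self.sampler_cfg if sampler_seed is None else SamplerConfig(
            self.sampler_cfg.k, self.sampler_cfg.L, sampler_seed)
        sequences = batch_sample(prep.graph, cfg, sentence_key=prep.index)
        X = self.encoder.encode_ids(prep.token_ids)
        X_hat, Z, _ = gpnn_layer(prep.graph, sequences, self.gpnn_cfg,
                                 self.gpnn_params, X=X)
        if self.ablate_pointer:
            Z = Tensor(np.zeros(Z.shape))
        fused = fuse_features(X, X_hat, Z, self.head_params)
        sent = sentence_representation(fused, self.head_params, self.head_cfg)
        if train and self.head_cfg.dropout > 0.0:
            keep = 1.0 - self.head_cfg.dropout
            mask = (rng or self._rng).random(sent.shape) < keep
            sent = sent * Tensor(mask / keep)
        return classify(sent, self.head_params)

    def predict(self, prepared: Sequence[PreparedInstance]
                ) -> list[tuple[str, np.ndarray]]:
        """(predicted label, probability vector) per instance; ties break
        toward the earlier label in scheme order."""
        out = []
        for prep in prepared:
            probs = np.exp(self.forward(prep).data)
            out.append((self.scheme.labels[int(np.argmax(probs))], probs))
        return out

    # -- training ----------------------------------------------------------
    def fit(self, train_set: Sequence[PreparedInstance],
            dev_set: Sequence[PreparedInstance],
            cfg: TrainConfig) -> list[EpochLog]:
        """Cross-entropy training with best-dev-micro-F1 model selection."""
        if not train_set:
            raise ValueError("empty training set")
        rng = np.random.default_rng(cfg.seed)
        params = self.parameters()
        steps_per_epoch = int(np.ceil(len(train_set) / cfg.batch_size))
        opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay,
                    total_steps=cfg.epochs * steps_per_epoch,
                    warmup_proportion=cfg.warmup_proportion)
        best_f1, best_state = -1.0, self.state_dict()
        self.epoch_log = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_set))
            total_loss = 0.0
            # neighbor sequences are resampled each epoch via the seed
            epoch_seed = (cfg.seed + 1000003 * (epoch + 1)) % (2 ** 31)
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                opt.zero_grad()
                for i in batch:
                    prep = train_set[i]
                    logp = self.forward(prep, sampler_seed=epoch_seed,
                                        train=True, rng=rng)
                    loss = -logp[prep.label_index] * (1.0 / len(batch))
                    loss.backward()
                    total_loss += float(loss.data) * len(batch)
                opt.step()
            if dev_set:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # transient all-one-class epochs
                    dev_f1 = self.evaluate(dev_set).micro[2]
            else:
                dev_f1 = 0.0
            log = EpochLog(epoch, total_loss / len(train_set), dev_f1)
            self.epoch_log.append(log)
            if cfg.log_every and (epoch + 1) % cfg.log_every == 0:
                print(f"epoch {epoch + 1}: loss {log.train_loss:.4f} "
                      f"dev micro-F1 {dev_f1:.2f}")
            if dev_set and dev_f1 >= best_f1:
                best_f1, best_state = dev_f1, self.state_dict()
        if dev_set:
            self.load_state_dict(best_state)
        return self.epoch_log

    def evaluate(self, prepared: Sequence[PreparedInstance]
                 ) -> "evaluation.EvalReport":
        golds = [self.scheme.labels[p.label_index] for p in prepared]
        preds = [lab for lab, _ in self.predict(prepared)]
        matrix = evaluation.confusion_matrix(preds, golds, self.scheme.labels)
        return evaluation.build_report(matrix, self.scheme.evaluated_labels)

    def accuracy(self, prepared: Sequence[PreparedInstance]) -> float:
        preds = self.predict(prepared)
        hits = sum(lab == self.scheme.labels[p.label_index]
                   for (lab, _), p in zip(preds, prepared))
        return hits / len(prepared) if prepared else 0.0

    # -- persistence -------------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write `<prefix>.npz` (weights) and `<prefix>.json` (config)."""
        prefix = Path(prefix)
        np.savez(str(prefix) + ".npz", **self.state_dict())
        meta = {
            "version": 1,
            "gpnn": asdict(self.gpnn_cfg),
            "sampler": asdict(self.sampler_cfg),
            "head": asdict(self.head_cfg),
            "scheme": {
                "evaluated_labels": list(self.scheme.evaluated_labels),
                "negative_label": self.scheme.negative_label,
                "raw_to_evaluated": dict(self.scheme.raw_to_evaluated),
            },
            "encoder": {"vocab": self.encoder.tokenizer.vocab,
                        "d1": self.encoder.d1,
                        "max_len": self.encoder.max_len},
            "seed": self.seed,
        }
        with open(str(prefix) + ".json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix: str | Path) -> "RelationModel":
        prefix = Path(prefix)
        with open(str(prefix) + ".json", encoding="utf-8") as fh:
            meta = json.load(fh)
        scheme = LabelScheme(tuple(meta["scheme"]["evaluated_labels"]),
                             meta["scheme"]["negative_label"],
                             meta["scheme"]["raw_to_evaluated"])
        enc = ToyEncoder(meta["encoder"]["vocab"], d1=meta["encoder"]["d1"],
                         max_len=meta["encoder"]["max_len"])
        model = cls(enc, GpnnConfig(**meta["gpnn"]),
                    SamplerConfig(**meta["sampler"]),
                    HeadConfig(**meta["head"]), scheme, seed=meta["seed"])
        with np.load(str(prefix) + ".npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model
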