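"""Token encoders: marked sentence → word-pieces + contextual vectors.

Two interchangeable backends satisfy one contract: given a sentence with
its two ``@…#``-marked mentions, produce the word-piece strings, an
``m × d1`` matrix of per-piece contextual vectors, and the word-level
segmentation used to align the dependency parse.

* :class:`ToyEncoder` — a small trainable backend (embedding lookup plus
  a one-layer bidirectional tanh recurrence) over a vocabulary-driven
  WordPiece-style tokenizer. It runs everywhere, is fully seeded, and is
  what all tests and the synthetic end-to-end runs use.
* :class:`PretrainedEncoder` — a named transformer checkpoint consumed
  through ``torch``/``transformers`` when those are installed; it is an
  optional integration point, not a dependency.

Sentences whose tokenization exceeds the maximum length are truncated
from the right only when both marked mentions survive; otherwise the
instance is rejected with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .autograd import Tensor, concat

__all__ = ["EncodedSentence", "WordPieceTokenizer", "ToyEncoder",
           "PretrainedEncoder", "EncodingError"]

UNK = "[UNK]"
CONTINUATION = "##"


class EncodingError(ValueError):
    """Raised when a sentence cannot be encoded under the active policy."""


@dataclass
class EncodedSentence:
    """Word-pieces, per-piece vectors, and the word segmentation used."""

    pieces: tuple[str, ...]
    vectors: Tensor                 # (m, d1); carries gradients for ToyEncoder
    words: tuple[str, ...]          # whitespace words of the marked sentence

    @property
    def d1(self) -> int:
        return self.vectors.shape[1]


class EncoderBackend(Protocol):
    d1: int

    def encode(self, text: str) -> EncodedSentence: ...


class WordPieceTokenizer:
    """Greedy longest-match subword tokenizer over an explicit vocabulary.

    A word is split into the longest vocabulary prefix followed by
    ``##``-prefixed continuation pieces. Characters not covered by the
    vocabulary fall back to single-character pieces (so the piece strings
    always concatenate back to the word); such pieces embed as ``[UNK]``.
    """

    def __init__(self, vocab: Sequence[str]):
        self.vocab = list(dict.fromkeys(list(vocab) + [UNK]))
        self.piece_id = {p: i for i, p in enumerate(self.vocab)}
        self._heads = {p for p in self.vocab if not p.startswith(CONTINUATION)}
        self._conts = {p[len(CONTINUATION):] for p in self.vocab
                       if p.startswith(CONTINUATION)}

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    def tokenize_word(self, word: str) -> list[str]:
        pieces: list[str] = []
        pos = 0
        while pos < len(word):
            table = self._heads if pos == 0 else self._conts
            best = None
            for end in range(len(word), pos, -1):
                if word[pos:end] in table:
                    best = word[pos:end]
                    break
            if best is None:
                best = word[pos]  # character fallback
            pieces.append(best if pos == 0 else CONTINUATION + best)
            pos += len(best)
        return pieces

    def tokenize(self, text: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Return (words, pieces) for a whitespace-segmented sentence."""
        words = tuple(text.split())
        pieces: list[str] = []
        for w in words:
            pieces.extend(self.tokenize_word(w))
        return words, tuple(pieces)

    def ids(self, pieces: Sequence[str]) -> np.ndarray:
        unk = self.piece_id[UNK]
        return np.array([self.piece_id.get(p, unk) for p in pieces],
                        dtype=np.int64)


def _truncate(words: tuple[str, ...], pieces: tuple[str, ...],
              max_len: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Right-truncate to `max_len` pieces, keeping whole words and both
    marked mentions; reject if a mention would be dropped."""
    if len(pieces) <= max_len:
        return words, pieces
    kept_words: list[str] = []
    kept_pieces: list[str] = []
    # walk pieces, attributing them to words in order
    wi = 0
    word_piece_spans: list[tuple[int, int]] = []
    start = 0
    buf = ""
    for pi, p in enumerate(pieces):
        buf += p[len(CONTINUATION):] if p.startswith(CONTINUATION) else p
        if buf.casefold() == words[wi].casefold():
            word_piece_spans.append((start, pi + 1))
            wi += 1
            start = pi + 1
            buf = ""
    for (a, b), w in zip(word_piece_spans, words):
        if b <= max_len:
            kept_words.append(w)
            kept_pieces.extend(pieces[a:b])
        elif "@" in w or "#" in w:
            raise EncodingError(
                f"truncation to {max_len} pieces would drop marked mention {w!r}")
    return tuple(kept_words), tuple(kept_pieces)


class ToyEncoder:
    """Trainable embedding + one-layer bidirectional tanh recurrence.

    Each word-piece embeds to ``d1`` dims; a forward and a backward
    recurrence of width ``d1 // 2`` run over the piece sequence and their
    states concatenate to the contextual vector. Deterministic given the
    seed; all weights live in :meth:`parameters` and train end to end.
    """

    def __init__(self, vocab: Sequence[str], d1: int = 32, seed: int = 0,
                 max_len: int = 128):
        if d1 % 2:
            raise ValueError("d1 must be even (two recurrence directions)")
        self.tokenizer = WordPieceTokenizer(vocab)
        self.d1 = d1
        self.max_len = max_len
        h = d1 // 2
        rng = np.random.default_rng(seed)

        def init(*shape, scale=None):
            scale = scale or 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        self.params: dict[str, Tensor] = {
            "emb": init(self.tokenizer.vocab_size, d1, scale=1.0),
            "fwd.Wx": init(d1, h), "fwd.Wh": init(h, h),
            "fwd.b": Tensor(np.zeros(h), requires_grad=True),
            "bwd.Wx": init(d1, h), "bwd.Wh": init(h, h),
            "bwd.b": Tensor(np.zeros(h), requires_grad=True),
        }

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    # -- encoding ----------------------------------------------------------
    def tokenize(self, text: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
        words, pieces = self.tokenizer.tokenize(text)
        return _truncate(words, pieces, self.max_len)

    def encode_ids(self, token_ids: np.ndarray) -> Tensor:
        """Contextual vectors for a piece-id sequence (gradient-carrying)."""
        emb = self.params["emb"][token_ids]  # (m, d1)
        m = len(token_ids)
        h = self.d1 // 2

        def run(direction: str, order: range) -> list[Tensor]:
            wx, wh, b = (self.params[f"{direction}.Wx"],
                         self.params[f"{direction}.Wh"],
                         self.params[f"{direction}.b"])
            state = Tensor(np.zeros((1, h)))
            states: dict[int, Tensor] = {}
            for t in order:
                x = emb[t:t + 1]
                state = (x @ wx + state @ wh + b).tanh()
                states[t] = state
            return [states[t] for t in range(m)]

        fwd = run("fwd", range(m))
        bwd = run("bwd", range(m - 1, -1, -1))
        rows = [concat([fwd[t], bwd[t]], axis=1) for t in range(m)]
        out = rows[0] if m == 1 else concat(rows, axis=0)
        return out.reshape(m, self.d1)

    def encode(self, text: str) -> EncodedSentence:
        if not text.strip():
            raise EncodingError("empty sentence")
        words, pieces = self.tokenize(text)
        vectors = self.encode_ids(self.tokenizer.ids(pieces))
        return EncodedSentence(pieces, vectors, words)


class PretrainedEncoder:
    """Final-hidden-layer vectors from a named transformer checkpoint.

    Requires the optional ``torch`` and ``transformers`` packages; the
    constructor raises immediately with an actionable message when they
    are missing, so the rest of the library stays importable offline.
    """

    def __init__(self, checkpoint: str, max_len: int = 128):
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as err:
            raise ImportError(
                "PretrainedEncoder requires the optional 'torch' and "
                "'transformers' packages; install them or use ToyEncoder"
            ) from err
        from transformers import AutoModel, AutoTokenizer

        self._tok = AutoTokenizer.from_pretrained(checkpoint)
        self._model = AutoModel.from_pretrained(checkpoint).eval()
        self.d1 = int(self._model.config.hidden_size)
        self.max_len = max_len

    def encode(self, text: str) -> EncodedSentence:
        import torch

        enc = self._tok(text, return_tensors="pt", add_special_tokens=True)
        pieces = self._tok.convert_ids_to_tokens(enc["input_ids"][0])
        if len(pieces) > self.max_len:
            raise EncodingError(f"sentence exceeds max length {self.max_len}")
        with torch.no_grad():
            hidden = self._model(**enc).last_hidden_state[0].numpy()
        # drop sequence-start/end specials: they are not sentence tokens
        keep = [i for i, p in enumerate(pieces)
                if p not in (self._tok.cls_token, self._tok.sep_token)]
        pieces = tuple(pieces[i] for i in keep)
        return EncodedSentence(pieces, Tensor(hidden[keep]), tuple(text.split()))
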