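"""Relation-instance I/O for sentence-level biomedical relation extraction.

A *relation instance* is one sentence with exactly one candidate entity
pair marked in-line — the chemical/gene mentions wrapped as ``@mention#``
— plus a gold relation label. Sentences containing several candidate
pairs are expanded into one instance per pair, with unannotated pairs
receiving the negative label.

The CHEMPROT task evaluates five chemical–protein relation (CPR) groups
as positive classes (CPR:3, CPR:4, CPR:5, CPR:6, CPR:9); all remaining
groups (CPR:1, CPR:2, CPR:7, CPR:8, CPR:10) and unannotated pairs map to
``False``. A two-label scheme covers binary tasks (GAD/EU-ADR style).

Instance files are UTF-8 TSV with columns ``(index, sentence, label)``,
the sentence already carrying the ``@…#`` markers. The marker characters
are literal and unescaped: sentences that themselves contain ``@`` or
``#`` are a known limitation of the format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Span",
    "RelationInstance",
    "LabelScheme",
    "CHEMPROT_SCHEME",
    "BINARY_SCHEME",
    "Mention",
    "mark_entities",
    "expand_pairs",
    "map_label",
    "read_instances",
    "write_instances",
]

Span = tuple[int, int]  # 0-based, half-open character interval

UNANNOTATED = ""  # raw-label marker for a pair with no gold annotation


class CorpusError(ValueError):
    """Raised for malformed spans, labels, or instance files."""


@dataclass(frozen=True)
class LabelScheme:
    """An ordered label set with a designated catch-all negative label."""

    evaluated_labels: tuple[str, ...]
    negative_label: str
    raw_to_evaluated: Mapping[str, str]

    @property
    def labels(self) -> tuple[str, ...]:
        return (self.negative_label,) + self.evaluated_labels

    def __contains__(self, label: str) -> bool:
        return label in self.labels


_CPR_POSITIVE = ("CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9")
_CPR_NEGATIVE = ("CPR:1", "CPR:2", "CPR:7", "CPR:8", "CPR:10")

#: Six-class chemical–protein scheme: five evaluated CPR groups, everything
#: else (including unannotated pairs) collapsed to ``False``. Label order
#: (False first) matches the published confusion-matrix layout.
CHEMPROT_SCHEME = LabelScheme(
    evaluated_labels=_CPR_POSITIVE,
    negative_label="False",
    raw_to_evaluated={
        **{g: g for g in _CPR_POSITIVE},
        **{g: "False" for g in _CPR_NEGATIVE},
        UNANNOTATED: "False",
    },
)

#: Two-class scheme for binary association tasks.
BINARY_SCHEME = LabelScheme(
    evaluated_labels=("positive",),
    negative_label="negative",
    raw_to_evaluated={"positive": "positive", "negative": "negative",
                      UNANNOTATED: "negative"},
)


@dataclass(frozen=True)
class RelationInstance:
    """One sentence, one marked entity pair, one gold label."""

    instance_id: str
    text: str  # marked sentence: exactly two @…# mentions
    entity1_span: Span
    entity2_span: Span
    label: str

    def __post_init__(self):
        if self.text.count("@") != 2 or self.text.count("#") != 2:
            raise CorpusError(
                f"instance {self.instance_id!r}: text must contain exactly two "
                f"'@…#' mentions, got {self.text!r}"
            )


@dataclass(frozen=True)
class Mention:
    """A typed entity mention located in the unmarked sentence."""

    text: str
    span: Span
    etype: str  # e.g. "CHEMICAL" or "GENE"


def _check_span(span: Span, sentence: str, name: str) -> None:
    a, b = span
    if not (0 <= a < b <= len(sentence)):
        raise CorpusError(f"{name} {span} out of bounds for sentence of length "
                          f"{len(sentence)}")


def mark_entities(sentence: str, span1: Span, span2: Span) -> str:
    """Wrap the two mentions as ``@mention#``, leaving all else unchanged.

    Spans are 0-based half-open intervals into the *unmarked* sentence and
    must not overlap; offsets of the later mention are adjusted for the two
    characters inserted before it. Identical surface strings at different
    offsets are disambiguated purely by offset.
    """
    _check_span(span1, sentence, "span1")
    _check_span(span2, sentence, "span2")
    (a1, b1), (a2, b2) = span1, span2
    if max(a1, a2) < min(b1, b2):
        raise CorpusError(f"overlapping entity spans {span1} and {span2}")
    first, second = sorted([span1, span2])
    (fa, fb), (sa, sb) = first, second
    return (sentence[:fa] + "@" + sentence[fa:fb] + "#"
            + sentence[fb:sa] + "@" + sentence[sa:sb] + "#" + sentence[sb:])


def map_label(raw: str, scheme: LabelScheme = CHEMPROT_SCHEME) -> str:
    """Map a raw annotation group (or the unannotated marker) to its
    evaluated label under `scheme`."""
    try:
        return scheme.raw_to_evaluated[raw]
    except KeyError:
        raise CorpusError(f"unknown raw label {raw!r} for scheme "
                          f"{scheme.evaluated_labels}") from None


def expand_pairs(
    sentence: str,
    entities: Sequence[Mention],
    gold_relations: Mapping[tuple[Span, Span], str],
    scheme: LabelScheme = CHEMPROT_SCHEME,
    sentence_id: str = "s",
    pair_types: tuple[str, str] | None = ("CHEMICAL", "GENE"),
) -> list[RelationInstance]:
    """Expand a multi-mention sentence into single-pair instances.

    One instance is emitted per valid cross-type pair (every chemical with
    every gene/protein when `pair_types` is set, else every unordered
    mention pair). Pairs absent from `gold_relations` get the scheme's
    negative label. Gold relations are keyed by the ordered span pair
    (first-type mention span, second-type mention span). Self-pairs —
    duplicate mentions of one entity string paired with themselves — never
    arise because pairs are formed across distinct mentions by offset.
    """
    if pair_types is not None:
        t1, t2 = pair_types
        firsts = [m for m in entities if m.etype == t1]
        seconds = [m for m in entities if m.etype == t2]
        pairs = [(a, b) for a in firsts for b in seconds]
    else:
        pairs = [(entities[i], entities[j])
                 for i in range(len(entities)) for j in range(i + 1, len(entities))]
    out: list[RelationInstance] = []
    for n, (m1, m2) in enumerate(pairs):
        raw = gold_relations.get((m1.span, m2.span),
                                 gold_relations.get((m2.span, m1.span), UNANNOTATED))
        out.append(RelationInstance(
            instance_id=f"{sentence_id}.{n}",
            text=mark_entities(sentence, m1.span, m2.span),
            entity1_span=m1.span,
            entity2_span=m2.span,
            label=map_label(raw, scheme),
        ))
    return out


# ---------------------------------------------------------------------------
# TSV I/O


@dataclass
class ReadReport:
    """Rows rejected while reading, as (line_no, reason) records."""

    errors: list[dict] = field(default_factory=list)

    def add(self, line_no: int, reason: str) -> None:
        self.errors.append({"line_no": line_no, "reason": reason})

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.errors:
                fh.write(json.dumps(rec) + "\n")


_HEADER = ("index", "sentence", "label")


def _find_spans(marked: str) -> tuple[Span, Span, str]:
    """Recover unmarked text + mention spans from a marked sentence."""
    spans: list[Span] = []
    plain: list[str] = []
    i = 0
    pos = 0
    while i < len(marked):
        ch = marked[i]
        if ch == "@":
            close = marked.find("#", i + 1)
            if close < 0:
                raise CorpusError("unclosed '@' marker")
            mention = marked[i + 1:close]
            spans.append((pos, pos + len(mention)))
            plain.append(mention)
            pos += len(mention)
            i = close + 1
        else:
            plain.append(ch)
            pos += 1
            i += 1
    if len(spans) != 2:
        raise CorpusError(f"expected 2 marked mentions, found {len(spans)}")
    return spans[0], spans[1], "".join(plain)


def read_instances(
    path: str | Path,
    scheme: LabelScheme = CHEMPROT_SCHEME,
    report: ReadReport | None = None,
) -> list[RelationInstance]:
    """Read instances from TSV, collecting malformed rows into `report`.

    Raises on a missing/incorrect header; individual bad rows are skipped
    and recorded (raised instead if no `report` is supplied).
    """
    path = Path(path)
    out: list[RelationInstance] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _HEADER:
            raise CorpusError(f"expected header {_HEADER}, got {tuple(header)}")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                cols = line.split("\t")
                if len(cols) != 3:
                    raise CorpusError(f"expected 3 columns, got {len(cols)}")
                iid, marked, label = cols
                if label not in scheme:
                    raise CorpusError(f"label {label!r} not in scheme")
                s1, s2, _ = _find_spans(marked)
                out.append(RelationInstance(iid, marked, s1, s2, label))
            except CorpusError as err:
                if report is None:
                    raise CorpusError(f"{path}:{line_no}: {err}") from None
                report.add(line_no, str(err))
    return out


def write_instances(instances: Iterable[RelationInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for inst in instances:
            fh.write(f"{inst.instance_id}\t{inst.text}\t{inst.label}\n")
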