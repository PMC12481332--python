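"""Data model for annotated brain-MRI report corpora and JSON Lines I/O.

A report is a raw text plus its token sequence (character-offset anchored)
and one or more named annotation sets ("gold", an annotator id, a model id),
each a set of labelled token spans.  Spans are contiguous token intervals,
half-open ``[start_tok, end_tok)``, carrying exactly one of the six target
categories; spans may overlap or nest freely (multilabel span categorisation,
as opposed to disjoint single-label NER), but a (start, end, label) triple is
unique within one set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Category",
    "BASE_CATEGORIES",
    "PRESENT_ABSENT_PAIRS",
    "Token",
    "SpanAnnotation",
    "Report",
    "AnnotatedCorpus",
    "CorpusValidationError",
    "tokenize",
    "read_corpus",
    "write_corpus",
]


class Category(str, Enum):
    """The six target categories: three kinds of volume loss, each present/absent."""

    GLOBAL_PRESENT = "GLOBAL_PRESENT"
    GLOBAL_ABSENT = "GLOBAL_ABSENT"
    REGIONAL_PRESENT = "REGIONAL_PRESENT"
    REGIONAL_ABSENT = "REGIONAL_ABSENT"
    HIPPO_PRESENT = "HIPPO_PRESENT"
    HIPPO_ABSENT = "HIPPO_ABSENT"

    @property
    def base(self) -> str:
        """Anatomical base category: GLOBAL, REGIONAL or HIPPO."""
        return self.value.rsplit("_", 1)[0]

    @property
    def polarity(self) -> str:
        """PRESENT or ABSENT."""
        return self.value.rsplit("_", 1)[1]

    @property
    def opposite(self) -> "Category":
        """Same base category with the other polarity."""
        other = "ABSENT" if self.polarity == "PRESENT" else "PRESENT"
        return Category(f"{self.base}_{other}")


BASE_CATEGORIES = ("GLOBAL", "REGIONAL", "HIPPO")

PRESENT_ABSENT_PAIRS = {
    base: (Category(f"{base}_PRESENT"), Category(f"{base}_ABSENT"))
    for base in BASE_CATEGORIES
}


class CorpusValidationError(ValueError):
    """An invariant of the corpus data model is violated."""


@dataclass(frozen=True)
class Token:
    """A token anchored to its character offsets in the report text."""

    text: str
    start: int  # 0-based character offset, inclusive
    end: int  # character offset, exclusive

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusValidationError(
                f"token offsets must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.end - self.start != len(self.text):
            raise CorpusValidationError(
                f"token text {self.text!r} does not span [{self.start}, {self.end})"
            )


@dataclass(frozen=True, order=True)
class SpanAnnotation:
    """A contiguous token interval [start_tok, end_tok) with one category label."""

    start_tok: int
    end_tok: int
    label: Category

    def __post_init__(self) -> None:
        if not (0 <= self.start_tok < self.end_tok):
            raise CorpusValidationError(
                f"span must satisfy 0 <= start < end, got [{self.start_tok}, {self.end_tok})"
            )

    def __len__(self) -> int:
        return self.end_tok - self.start_tok

    def overlaps(self, other: "SpanAnnotation") -> bool:
        """True if the two token intervals share at least one token."""
        return min(self.end_tok, other.end_tok) > max(self.start_tok, other.start_tok)


@dataclass
class Report:
    """One radiology report with its tokens and named span-annotation sets."""

    report_id: str
    text: str
    tokens: list[Token]
    annotation_sets: dict[str, set[SpanAnnotation]] = field(default_factory=dict)

    def validate(self) -> None:
        prev_end = -1
        for tok in self.tokens:
            if self.text[tok.start : tok.end] != tok.text:
                raise CorpusValidationError(
                    f"report {self.report_id!r}: token {tok.text!r} does not match "
                    f"text[{tok.start}:{tok.end}]"
                )
            if tok.start < prev_end:
                raise CorpusValidationError(
                    f"report {self.report_id!r}: tokens overlap or are unsorted"
                )
            prev_end = tok.end
        n = len(self.tokens)
        for source, spans in self.annotation_sets.items():
            for span in spans:
                if span.end_tok > n:
                    raise CorpusValidationError(
                        f"report {self.report_id!r}, set {source!r}: span "
                        f"[{span.start_tok}, {span.end_tok}) exceeds {n} tokens"
                    )

    def spans(self, source: str) -> set[SpanAnnotation]:
        try:
            return self.annotation_sets[source]
        except KeyError:
            raise KeyError(
                f"report {self.report_id!r} has no annotation set {source!r}"
            ) from None

    @property
    def n_words(self) -> int:
        """Word count: tokens that contain at least one alphanumeric character."""
        return sum(1 for t in self.tokens if any(c.isalnum() for c in t.text))


@dataclass
class AnnotatedCorpus:
    """A collection of reports with unique ids."""

    reports: list[Report] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(set(ids)) != len(ids):
            raise CorpusValidationError("report_ids are not unique")

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedCorpus):
            return NotImplemented
        return self.reports == other.reports

    def validate(self) -> None:
        self.__post_init__()
        for r in self.reports:
            r.validate()

    def subset(self, report_ids: Iterable[str]) -> "AnnotatedCorpus":
        wanted = set(report_ids)
        return AnnotatedCorpus([r for r in self.reports if r.report_id in wanted])


# Punctuation characters split off token edges.  Radiology prose needs no
# model-based tokeniser: whitespace plus edge punctuation is reproducible
# and keeps character offsets trivial.
_EDGE_PUNCT = set(".,;:()/-")


def tokenize(text: str) -> list[Token]:
    """Deterministic whitespace tokeniser that splits edge punctuation.

    Each whitespace-delimited chunk is peeled of leading and trailing
    punctuation characters (``.,;:()/-``), which become single-character
    tokens of their own; interior punctuation (hyphenated words, decimals)
    is preserved.  Concatenating token texts with the skipped separators
    reconstructs the input exactly.
    """
    tokens: list[Token] = []
    i = 0
    n = len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        lo, hi = i, j
        # peel leading punctuation
        while lo < hi and text[lo] in _EDGE_PUNCT:
            tokens.append(Token(text[lo], lo, lo + 1))
            lo += 1
        # locate trailing punctuation run
        tail = hi
        while tail > lo and text[tail - 1] in _EDGE_PUNCT:
            tail -= 1
        if lo < tail:
            tokens.append(Token(text[lo:tail], lo, tail))
        for k in range(tail, hi):
            tokens.append(Token(text[k], k, k + 1))
        i = j
    return tokens


def _report_to_record(report: Report) -> dict:
    return {
        "id": report.report_id,
        "text": report.text,
        "tokens": [{"text": t.text, "start": t.start, "end": t.end} for t in report.tokens],
        "spans": {
            source: [
                {"start_tok": s.start_tok, "end_tok": s.end_tok, "label": s.label.value}
                for s in sorted(spans)
            ]
            for source, spans in sorted(report.annotation_sets.items())
        },
    }


def _record_to_report(rec: dict, line_no: int) -> Report:
    try:
        tokens = [Token(t["text"], t["start"], t["end"]) for t in rec["tokens"]]
        sets: dict[str, set[SpanAnnotation]] = {}
        for source, spans in rec["spans"].items():
            out: set[SpanAnnotation] = set()
            for s in spans:
                try:
                    label = Category(s["label"])
                except ValueError:
                    raise CorpusValidationError(
                        f"line {line_no}: unknown category label {s['label']!r}"
                    ) from None
                ann = SpanAnnotation(s["start_tok"], s["end_tok"], label)
                if ann in out:
                    raise CorpusValidationError(
                        f"line {line_no}: duplicate span {ann} in set {source!r}"
                    )
                out.add(ann)
            sets[source] = out
        report = Report(rec["id"], rec["text"], tokens, sets)
    except (KeyError, TypeError) as exc:
        raise CorpusValidationError(f"line {line_no}: malformed record ({exc})") from exc
    report.validate()
    return report


def read_corpus(path: str | Path) -> AnnotatedCorpus:
    """Read a JSON Lines corpus file, validating every invariant.

    Raises :class:`CorpusValidationError` naming the offending line for
    malformed records, unknown labels or out-of-range spans.
    """
    reports: list[Report] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusValidationError(f"line {line_no}: invalid JSON ({exc})") from exc
            reports.append(_record_to_report(rec, line_no))
    corpus = AnnotatedCorpus(reports)
    corpus.validate()
    return corpus


def write_corpus(corpus: AnnotatedCorpus, path: str | Path) -> None:
    """Write a corpus as JSON Lines with stable key order (byte-deterministic)."""
    with open(path, "w", encoding="utf-8") as fh:
        for report in corpus:
            fh.write(json.dumps(_report_to_record(report), ensure_ascii=False))
            fh.write("\n")
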