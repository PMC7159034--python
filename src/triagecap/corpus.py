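"""Document model, corpus I/O and dictionary-based concept masking.

A triage corpus is a labeled collection of publication records, each carrying
an identifier, title, abstract and the captions of all figures in the paper.
Concept masking collapses sparse biomedical surface forms (gene/protein,
enzyme, mutation and anatomy mentions) onto four generic category tokens
(``PRGE``, ``ENZI``, ``MUTN``, ``ANAT``) so that downstream bag-of-words
features aggregate over concept classes rather than individual names.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"
LABELS = frozenset({RELEVANT, IRRELEVANT})

#: Generic tokens substituted for masked concept mentions.
CATEGORY_TOKENS = ("PRGE", "ENZI", "MUTN", "ANAT")

#: Fixed composition order of the document parts.
PART_ORDER = ("title", "abstract", "captions")


class CorpusError(ValueError):
    """Raised for malformed corpus files or invalid document collections."""


@dataclass(frozen=True)
class Document:
    """One publication record.

    ``captions`` holds the caption text of each figure, in figure order, and
    may be empty. ``label`` is ``None`` for prediction-time documents.
    """

    id: str
    title: str = ""
    abstract: str = ""
    captions: tuple[str, ...] = ()
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("document id must be non-empty")
        object.__setattr__(self, "captions", tuple(self.captions))
        if self.label is not None and self.label not in LABELS:
            raise CorpusError(
                f"document {self.id!r}: label must be one of {sorted(LABELS)}, "
                f"got {self.label!r}"
            )


@dataclass
class Corpus:
    """Ordered document collection with unique ids."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.id in seen:
                raise CorpusError(f"duplicate document id {doc.id!r}")
            seen.add(doc.id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    @property
    def n_rel(self) -> int:
        return sum(d.label == RELEVANT for d in self.documents)

    @property
    def n_irr(self) -> int:
        return sum(d.label == IRRELEVANT for d in self.documents)

    @property
    def imbalance_ratio(self) -> float:
        """Majority-to-minority size ratio n_irr / n_rel (requires n_rel > 0)."""
        n_rel = self.n_rel
        if n_rel == 0:
            raise CorpusError("imbalance ratio undefined: no relevant documents")
        return self.n_irr / n_rel

    def subset(self, ids: Iterable[str]) -> "Corpus":
        wanted = set(ids)
        return Corpus([d for d in self.documents if d.id in wanted])


def _document_from_record(record: Mapping, lineno: int) -> Document:
    if not isinstance(record, Mapping):
        raise CorpusError(f"line {lineno}: record is not an object")
    if "id" not in record or "title" not in record:
        raise CorpusError(f"line {lineno}: record must have 'id' and 'title'")
    captions = record.get("captions") or ()
    if isinstance(captions, str):
        captions = (captions,) if captions else ()
    label = record.get("label")
    if label is not None and label not in LABELS:
        raise CorpusError(
            f"line {lineno}: unknown label {label!r} (expected one of {sorted(LABELS)})"
        )
    try:
        return Document(
            id=str(record["id"]),
            title=record.get("title", "") or "",
            abstract=record.get("abstract", "") or "",
            captions=tuple(str(c) for c in captions),
            label=label,
        )
    except CorpusError as exc:
        raise CorpusError(f"line {lineno}: {exc}") from exc


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from a JSON-lines or delimited-table file.

    ``format`` is ``"jsonl"`` or ``"csv"``; when ``None`` it is inferred from
    the file suffix. CSV files carry columns id,title,abstract,captions,label
    with captions joined by ``"|"``. Malformed records raise :class:`CorpusError`
    naming the offending line.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() in {".csv", ".tsv"} else "jsonl"
    docs: list[Document] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
                docs.append(_document_from_record(record, lineno))
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):  # header is line 1
                record = dict(row)
                caps = record.get("captions") or ""
                record["captions"] = tuple(c for c in caps.split("|") if c)
                record["label"] = record.get("label") or None
                docs.append(_document_from_record(record, lineno))
    else:
        raise CorpusError(f"unknown corpus format {format!r}")
    return Corpus(docs)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus in the format accepted by :func:`read_corpus`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() in {".csv", ".tsv"} else "jsonl"
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for doc in corpus:
                record = {
                    "id": doc.id,
                    "title": doc.title,
                    "abstract": doc.abstract,
                    "captions": list(doc.captions),
                }
                if doc.label is not None:
                    record["label"] = doc.label
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "title", "abstract", "captions", "label"])
            for doc in corpus:
                writer.writerow(
                    [doc.id, doc.title, doc.abstract, "|".join(doc.captions), doc.label or ""]
                )
    else:
        raise CorpusError(f"unknown corpus format {format!r}")


def compose_text(doc: Document, parts: Iterable[str]) -> str:
    """Concatenate the requested document parts in fixed order.

    Order is always title -> abstract -> captions (captions in stored order),
    joined with single spaces; absent/empty parts contribute nothing.
    """
    parts = set(parts)
    if not parts:
        raise ValueError("parts must be a non-empty subset of {title, abstract, captions}")
    unknown = parts - set(PART_ORDER)
    if unknown:
        raise ValueError(f"unknown document parts: {sorted(unknown)}")
    pieces: list[str] = []
    if "title" in parts and doc.title:
        pieces.append(doc.title)
    if "abstract" in parts and doc.abstract:
        pieces.append(doc.abstract)
    if "captions" in parts:
        pieces.extend(c for c in doc.captions if c)
    return " ".join(pieces)


class MaskingLexicon:
    """Case-insensitive mapping from surface terms to concept categories.

    Categories are restricted to the four generic tokens in
    :data:`CATEGORY_TOKENS`. Matching is word-boundary anchored and resolves
    overlaps by longest match, ties by leftmost start.
    """

    def __init__(self, entries: Mapping[str, str]):
        normalized: dict[str, str] = {}
        for term, category in entries.items():
            key = " ".join(term.split()).lower()
            if not key:
                raise CorpusError("lexicon surface terms must be non-empty")
            if category not in CATEGORY_TOKENS:
                raise CorpusError(
                    f"lexicon category for {term!r} must be one of {CATEGORY_TOKENS}, "
                    f"got {category!r}"
                )
            normalized[key] = category
        self.entries: dict[str, str] = normalized
        self._pattern = self._compile()

    def _compile(self) -> re.Pattern | None:
        if not self.entries:
            return None
        # Longest alternative first => longest match wins at each position;
        # the regex engine's leftmost scan gives leftmost-start tie-breaking.
        terms = sorted(self.entries, key=lambda t: (-len(t.split()), -len(t), t))
        alts = [r"\s+".join(re.escape(tok) for tok in t.split()) for t in terms]
        return re.compile(r"\b(?:%s)\b" % "|".join(alts), flags=re.IGNORECASE)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "MaskingLexicon":
        """Load a two-column tab-separated file: term<TAB>category."""
        entries: dict[str, str] = {}
        with Path(path).open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise CorpusError(
                        f"line {lineno}: expected 'term<TAB>category', got {line!r}"
                    )
                entries[fields[0]] = fields[1]
        return cls(entries)

    def mask(self, text: str) -> str:
        if self._pattern is None:
            return text
        def _sub(match: re.Match) -> str:
            key = " ".join(match.group(0).split()).lower()
            return self.entries[key]
        return self._pattern.sub(_sub, text)


def mask_concepts(text: str, lexicon: MaskingLexicon | None) -> str:
    """Replace every maximal lexicon match in ``text`` by its category token.

    Matching is greedy longest-match left-to-right on word boundaries and
    case-insensitive; non-matching text is unchanged. An empty (or ``None``)
    lexicon returns the input unchanged.
    """
    if lexicon is None or len(lexicon) == 0:
        return text
    return lexicon.mask(text)
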