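"""Corpus and vocabulary I/O plus rule-based sentence splitting.

Abstracts arrive either as MEDLINE flat files (PMID/TI/AB tags, parsed with
Biopython) or as JSON-lines ``{"doc_id":..., "title":..., "abstract":...}``.
Sentence splitting is deliberately rule-based: a punctuation splitter with an
abbreviation guard is enough for clause-level frequency counting, and its
offsets reconstruct the source text exactly, which keeps every downstream
match auditable.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from Bio import Medline

logger = logging.getLogger(__name__)

_TERMINAL = ".!?"

#: Lower-cased tokens whose trailing period does not end a sentence.
ABBREVIATIONS = frozenset({
    "e.g", "i.e", "cf", "vs", "al", "et", "etc", "ca", "approx",
    "dr", "mr", "mrs", "ms", "prof", "st", "no", "fig", "figs",
    "ref", "refs", "eq", "eqs", "resp", "spp", "sp",
})


class CorpusError(ValueError):
    """Raised for malformed corpus or vocabulary files."""


@dataclass(frozen=True)
class DocumentRecord:
    """One abstract: a PMID-like identifier, an optional title, and the body."""

    doc_id: str
    title: str
    body: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("document with empty doc_id")

    def text(self, include_title: bool = True) -> str:
        """Title and body period-joined (titles carry causal statements too)."""
        if not include_title or not self.title:
            return self.body
        sep = " " if self.title.rstrip().endswith(tuple(_TERMINAL)) else ". "
        return self.title + sep + self.body


@dataclass(frozen=True)
class SentenceSpan:
    """A sentence with 0-based half-open character offsets into the source text."""

    doc_id: str
    index: int
    text: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class DiseaseEntry:
    disease_id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()
    category: Optional[str] = None

    def name_forms(self) -> tuple[str, ...]:
        return (self.preferred_name,) + self.synonyms


class DiseaseVocabulary:
    """Disease dictionary: id, preferred name, synonyms, optional category."""

    def __init__(self, entries: Iterable[DiseaseEntry]) -> None:
        self.entries: tuple[DiseaseEntry, ...] = tuple(entries)
        self._by_id: dict[str, DiseaseEntry] = {}
        for e in self.entries:
            if e.disease_id in self._by_id:
                raise CorpusError(f"duplicate disease_id {e.disease_id!r}")
            if not e.preferred_name:
                raise CorpusError(f"disease {e.disease_id!r} has no name form")
            self._by_id[e.disease_id] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[DiseaseEntry]:
        return iter(self.entries)

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self._by_id

    def get(self, disease_id: str) -> DiseaseEntry:
        try:
            return self._by_id[disease_id]
        except KeyError:
            raise CorpusError(f"unknown disease_id {disease_id!r}") from None

    def surface_forms(self) -> list[tuple[str, str]]:
        """(surface, disease_id) pairs, longest surface first."""
        pairs = [(form, e.disease_id)
                 for e in self.entries for form in e.name_forms()]
        return sorted(pairs, key=lambda p: len(p[0]), reverse=True)


def load_vocabulary(path: Union[str, Path]) -> DiseaseVocabulary:
    """Read a disease vocabulary TSV (disease_id, preferred_name, synonyms, category)."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["disease_id", "preferred_name"]:
            raise CorpusError(f"{path}: unexpected vocabulary header {header}")
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise CorpusError(f"{path}:{i}: too few columns")
            disease_id, name = fields[0], fields[1]
            synonyms = tuple(s for s in fields[2].split("|") if s) \
                if len(fields) > 2 else ()
            category = fields[3] if len(fields) > 3 and fields[3] else None
            entries.append(DiseaseEntry(disease_id, name, synonyms, category))
    return DiseaseVocabulary(entries)


def default_vocabulary() -> DiseaseVocabulary:
    """The small packaged demonstration vocabulary (MeSH-style entries)."""
    ref = resources.files("causalminer.data") / "diseases.tsv"
    with resources.as_file(ref) as path:
        return load_vocabulary(path)


def read_corpus(path: Union[str, Path],
                format: str = "jsonl") -> list[DocumentRecord]:
    """Read an abstract corpus; records with an empty body are skipped."""
    if format == "jsonl":
        docs = list(_read_jsonl(path))
    elif format == "medline":
        docs = list(_read_medline(path))
    else:
        raise CorpusError(f"unknown corpus format {format!r}")
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise CorpusError(f"duplicate doc_id {d.doc_id!r} in {path}")
        seen.add(d.doc_id)
    return docs


def _read_jsonl(path: Union[str, Path]) -> Iterator[DocumentRecord]:
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                doc_id = str(obj["doc_id"])
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise CorpusError(f"{path}: malformed record {i}: {exc}") from None
            body = obj.get("abstract") or ""
            if not body.strip():
                logger.warning("record %d (%s): empty abstract, skipped",
                               i, doc_id)
                continue
            yield DocumentRecord(doc_id=doc_id, title=obj.get("title") or "",
                                 body=body)


def _read_medline(path: Union[str, Path]) -> Iterator[DocumentRecord]:
    with open(path, encoding="utf-8") as fh:
        for i, rec in enumerate(Medline.parse(fh), start=1):
            pmid = rec.get("PMID")
            if not pmid:
                raise CorpusError(f"{path}: record {i} has no PMID")
            body = rec.get("AB") or ""
            if not body.strip():
                logger.warning("record %d (PMID %s): empty abstract, skipped",
                               i, pmid)
                continue
            yield DocumentRecord(doc_id=pmid, title=rec.get("TI") or "",
                                 body=body)


def write_corpus(docs: Sequence[DocumentRecord],
                 path: Union[str, Path]) -> None:
    """Write documents to the JSON-lines corpus dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps({"doc_id": d.doc_id, "title": d.title,
                                 "abstract": d.body}) + "\n")


_WORD_BEFORE = re.compile(r"[A-Za-z][A-Za-z.]*$")


def _is_boundary(text: str, i: int) -> bool:
    """Is the terminal character at position ``i`` a sentence boundary?"""
    j = i + 1
    if j >= len(text):
        return True
    if not text[j].isspace():
        return False  # covers decimals like "3.5" and "e.g." internals
    k = j
    while k < len(text) and text[k].isspace():
        k += 1
    if k == len(text):
        return True
    if not (text[k].isupper() or text[k].isdigit() or text[k] in "(\"'["):
        return False
    if text[i] != ".":
        return True
    m = _WORD_BEFORE.search(text, 0, i)
    if m:
        word = m.group(0).rstrip(".").lower()
        if word in ABBREVIATIONS:
            return False
    return True


def split_sentences(doc: DocumentRecord,
                    include_title: bool = True) -> list[SentenceSpan]:
    """Split a document into sentence spans over ``doc.text(include_title)``.

    Offsets are 0-based half-open; spans are ordered, non-overlapping, and
    slice the source text exactly, so concatenating the spans with the
    skipped inter-sentence whitespace reproduces it byte-for-byte.
    """
    text = doc.text(include_title)
    if not text.strip():
        return []
    boundaries = [i for i, ch in enumerate(text)
                  if ch in _TERMINAL and _is_boundary(text, i)]
    spans: list[SentenceSpan] = []
    start = 0
    for b in boundaries + [len(text) - 1]:
        end = b + 1
        if end <= start:
            continue
        chunk = text[start:end]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        s, e = start + lead, end - trail
        if e > s:
            spans.append(SentenceSpan(doc_id=doc.doc_id, index=len(spans),
                                      text=text[s:e], char_start=s,
                                      char_end=e))
        start = end
    return spans
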