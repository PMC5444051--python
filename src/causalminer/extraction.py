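"""Causality-clause extraction: ``<disease> <term> <disease>`` in a sentence.

A causality clause relates two disease mentions through a lexicon term that
lies strictly between them.  The extractor is dictionary- and rule-based:
disease mentions are longest-match dictionary hits, sentences are segmented
at ";" and at ", which"/", that" boundaries, and each term occurrence is
paired with the nearest mention on either side within its segment.  The
term's direction flag then resolves which disease is the cause (*prior*) and
which the effect (*posterior*): "A causes B" and its passive "B caused by A"
yield the same ordered pair.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .corpus import DiseaseVocabulary, DocumentRecord, SentenceSpan, \
    split_sentences
from .lexicon import FORWARD, CausalityTermEntry, Lexicon


@dataclass(frozen=True)
class DiseaseMention:
    """A dictionary hit for a disease name within one sentence."""

    disease_id: str
    surface: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class CausalityClauseMatch:
    """One extracted causality clause, with the cause/effect roles resolved."""

    doc_id: str
    sentence_index: int
    term: CausalityTermEntry
    left_disease: str
    right_disease: str
    prior: str
    posterior: str

    def __post_init__(self) -> None:
        if self.prior == self.posterior:
            raise ValueError("clause match pairing a disease with itself")
        if {self.prior, self.posterior} != {self.left_disease,
                                            self.right_disease}:
            raise ValueError("prior/posterior must be a permutation of "
                             "left/right diseases")


def _boundary_pattern(forms: Sequence[str]) -> re.Pattern[str]:
    alternation = "|".join(re.escape(f) for f in forms)
    return re.compile(rf"(?<![A-Za-z0-9])(?:{alternation})(?![A-Za-z0-9])",
                      re.IGNORECASE)


def _vocab_matcher(vocab: DiseaseVocabulary):
    cached = getattr(vocab, "_matcher_cache", None)
    if cached is None:
        pairs = vocab.surface_forms()  # longest first
        pattern = _boundary_pattern([p[0] for p in pairs])
        by_surface = {}
        for surface, disease_id in pairs:
            by_surface.setdefault(surface.lower(), disease_id)
        cached = (pattern, by_surface)
        vocab._matcher_cache = cached  # type: ignore[attr-defined]
    return cached


def _lexicon_pattern(lexicon: Lexicon) -> re.Pattern[str]:
    cached = getattr(lexicon, "_pattern_cache", None)
    if cached is None:
        cached = _boundary_pattern(lexicon.variant_forms())
        lexicon._pattern_cache = cached  # type: ignore[attr-defined]
    return cached


def find_disease_mentions(sentence: SentenceSpan,
                          vocab: DiseaseVocabulary) -> list[DiseaseMention]:
    """Longest-match, case-insensitive dictionary matching of disease names.

    Overlapping candidates are resolved in favour of the longer surface
    ("subarachnoid hemorrhage" beats "hemorrhage"), so each character
    position belongs to at most one mention.
    """
    pattern, by_surface = _vocab_matcher(vocab)
    mentions = []
    for m in pattern.finditer(sentence.text):
        mentions.append(DiseaseMention(
            disease_id=by_surface[m.group(0).lower()],
            surface=m.group(0), char_start=m.start(), char_end=m.end()))
    return mentions


_SEGMENT_BREAK = re.compile(r";|,\s+(?:which|that)\b", re.IGNORECASE)


def _segments(text: str) -> list[tuple[int, int]]:
    """Clause segments of a sentence as half-open character ranges."""
    segments, start = [], 0
    for m in _SEGMENT_BREAK.finditer(text):
        segments.append((start, m.start()))
        start = m.end()
    segments.append((start, len(text)))
    return segments


def match_causality_clauses(
    sentence: SentenceSpan,
    mentions: Sequence[DiseaseMention],
    lexicon: Lexicon,
) -> list[CausalityClauseMatch]:
    """Pair each causality-term occurrence with its nearest flanking mentions.

    A term occurrence yields at most one clause (a clause relates one subject
    to one object); both flanking mentions must lie in the term's segment,
    and self-pairs are discarded.  Distinct term occurrences in one sentence
    each yield their own clause — clause frequency counts clauses, not
    sentences.
    """
    if not mentions:
        return []
    matches = []
    segs = _segments(sentence.text)
    pattern = _lexicon_pattern(lexicon)
    for occ in pattern.finditer(sentence.text):
        entry = lexicon.entry_for_variant(occ.group(0))
        if entry is None:  # pragma: no cover - variants map is exhaustive
            continue
        if any(m.char_start < occ.end() and occ.start() < m.char_end
               for m in mentions):
            continue  # term surface inside a disease name
        seg = next(((s, e) for s, e in segs if s <= occ.start() < e), None)
        if seg is None or occ.end() > seg[1]:
            continue
        left = max((m for m in mentions
                    if m.char_end <= occ.start() and m.char_start >= seg[0]),
                   key=lambda m: m.char_end, default=None)
        right = min((m for m in mentions
                     if m.char_start >= occ.end() and m.char_end <= seg[1]),
                    key=lambda m: m.char_start, default=None)
        if left is None or right is None:
            continue
        if left.disease_id == right.disease_id:
            continue
        if entry.direction == FORWARD:
            prior, posterior = left.disease_id, right.disease_id
        else:
            prior, posterior = right.disease_id, left.disease_id
        matches.append(CausalityClauseMatch(
            doc_id=sentence.doc_id, sentence_index=sentence.index,
            term=entry, left_disease=left.disease_id,
            right_disease=right.disease_id, prior=prior, posterior=posterior))
    return matches


def extract_clauses(
    docs: Iterable[DocumentRecord],
    vocab: DiseaseVocabulary,
    lexicon: Lexicon,
    include_title: bool = True,
) -> list[CausalityClauseMatch]:
    """Run sentence splitting, mention finding and clause matching over a corpus."""
    matches = []
    for doc in docs:
        for sentence in split_sentences(doc, include_title=include_title):
            mentions = find_disease_mentions(sentence, vocab)
            if len(mentions) >= 2:
                matches.extend(
                    match_causality_clauses(sentence, mentions, lexicon))
    return matches


def write_matches(matches: Sequence[CausalityClauseMatch],
                  path: Union[str, Path]) -> None:
    """Write the clause-match interchange TSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("doc_id\tsentence_index\tterm\tprior\tposterior\n")
        for m in matches:
            fh.write(f"{m.doc_id}\t{m.sentence_index}\t{m.term.canonical}\t"
                     f"{m.prior}\t{m.posterior}\n")


def read_matches(path: Union[str, Path],
                 lexicon: Lexicon) -> list[CausalityClauseMatch]:
    """Read a clause-match TSV, resolving terms against ``lexicon``."""
    matches = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entry = lexicon.get(row["term"])
            prior, posterior = row["prior"], row["posterior"]
            if entry.direction == FORWARD:
                left, right = prior, posterior
            else:
                left, right = posterior, prior
            matches.append(CausalityClauseMatch(
                doc_id=row["doc_id"],
                sentence_index=int(row["sentence_index"]), term=entry,
                left_disease=left, right_disease=right,
                prior=prior, posterior=posterior))
    return matches
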