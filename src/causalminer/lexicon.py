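"""Causality-term lexicon: survey aggregation, loading, and term lookup.

The lexicon assigns each causality cue (``cause``, ``due to``, ``triggered
by`` ...) a *term strength* alpha in {0.25, 0.50, 0.75, 1.00} — the modal
rating of a four-point Likert survey divided by the scale size — and a
*direction* flag saying whether the grammatical subject of the cue is the
cause (``forward``, as in "A causes B") or the effect (``reverse``, as in
"B is caused by A").  The packaged default lexicon has 105 entries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

ALLOWED_STRENGTHS = (0.25, 0.50, 0.75, 1.00)

FORWARD = "forward"
REVERSE = "reverse"


class LexiconError(ValueError):
    """Raised for malformed lexicon files or invalid survey tallies."""


@dataclass(frozen=True)
class LikertTally:
    """Respondent counts per Likert level for one causality term.

    ``counts[l]`` is the number of respondents who rated the term at level
    ``l`` on the four-point scale (1 = simple relation ... 4 = very strong).
    """

    term: str
    counts: Mapping[int, int]
    total: int

    def __post_init__(self) -> None:
        if not self.counts:
            raise LexiconError(f"no survey data for term {self.term!r}")
        bad = [l for l in self.counts if l not in (1, 2, 3, 4)]
        if bad:
            raise LexiconError(
                f"term {self.term!r}: Likert levels outside 1-4: {bad}")
        if any(c < 0 for c in self.counts.values()):
            raise LexiconError(f"term {self.term!r}: negative counts")
        if sum(self.counts.values()) != self.total or self.total < 1:
            raise LexiconError(
                f"term {self.term!r}: counts sum to "
                f"{sum(self.counts.values())}, expected total {self.total}")


@dataclass(frozen=True)
class CausalityTermEntry:
    """One lexicon entry: canonical surface, strength alpha, direction, variants."""

    canonical: str
    strength: float
    direction: str
    variants: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.strength not in ALLOWED_STRENGTHS:
            raise LexiconError(
                f"entry {self.canonical!r}: strength {self.strength} not in "
                f"{ALLOWED_STRENGTHS}")
        if self.direction not in (FORWARD, REVERSE):
            raise LexiconError(
                f"entry {self.canonical!r}: direction must be "
                f"'forward' or 'reverse', got {self.direction!r}")
        if self.canonical not in self.variants:
            raise LexiconError(
                f"entry {self.canonical!r}: variants must include the "
                "canonical form")


class Lexicon:
    """An immutable collection of causality-term entries with variant lookup."""

    def __init__(self, entries: Iterable[CausalityTermEntry]) -> None:
        self.entries: tuple[CausalityTermEntry, ...] = tuple(entries)
        self._by_canonical: dict[str, CausalityTermEntry] = {}
        for entry in self.entries:
            if entry.canonical in self._by_canonical:
                raise LexiconError(
                    f"duplicate canonical form {entry.canonical!r}")
            self._by_canonical[entry.canonical] = entry
        # variant (lower-cased) -> entry; on collision the longer canonical
        # wins so that e.g. "caused by" shadows "cause" for the span "caused by"
        self._by_variant: dict[str, CausalityTermEntry] = {}
        for entry in self.entries:
            for v in entry.variants:
                key = v.lower()
                prev = self._by_variant.get(key)
                if prev is None or len(entry.canonical) > len(prev.canonical):
                    self._by_variant[key] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CausalityTermEntry]:
        return iter(self.entries)

    def __contains__(self, canonical: str) -> bool:
        return canonical in self._by_canonical

    def get(self, canonical: str) -> CausalityTermEntry:
        try:
            return self._by_canonical[canonical]
        except KeyError:
            raise LexiconError(f"unknown causality term {canonical!r}") from None

    def variant_forms(self) -> list[str]:
        """All surface forms, longest first (for longest-match scanning)."""
        return sorted(self._by_variant, key=len, reverse=True)

    def entry_for_variant(self, surface: str) -> Optional[CausalityTermEntry]:
        return self._by_variant.get(surface.lower())


def aggregate_term_strength(
    tally: LikertTally,
    scale_size: int = 4,
    tie_break: str = "lowest",
) -> float:
    """Aggregate a Likert tally into a term strength.

    Returns the modal Likert level divided by ``scale_size`` — the majority
    consensus of the survey.  Multimodal tallies are resolved by ``tie_break``:
    ``"lowest"`` (default, conservative causal strength) or ``"highest"``.
    """
    if scale_size < 1:
        raise LexiconError("scale_size must be positive")
    if max(tally.counts) > scale_size:
        raise LexiconError(
            f"term {tally.term!r}: level {max(tally.counts)} exceeds "
            f"scale size {scale_size}")
    if tie_break not in ("lowest", "highest"):
        raise LexiconError(f"unknown tie_break {tie_break!r}")
    top = max(tally.counts.values())
    tied = [l for l, c in tally.counts.items() if c == top]
    mode = min(tied) if tie_break == "lowest" else max(tied)
    return mode / scale_size


def load_survey(path: Union[str, Path]) -> list[LikertTally]:
    """Read a survey tally TSV with columns term, n1, n2, n3, n4."""
    tallies = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"term", "n1", "n2", "n3", "n4"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise LexiconError(
                f"survey file {path}: expected columns {sorted(required)}")
        for row in reader:
            counts = {l: int(row[f"n{l}"]) for l in (1, 2, 3, 4)}
            counts = {l: c for l, c in counts.items() if c > 0}
            tallies.append(LikertTally(term=row["term"], counts=counts,
                                       total=sum(counts.values())))
    return tallies


def load_lexicon(path: Union[str, Path]) -> Lexicon:
    """Load a lexicon TSV (canonical, strength, direction, variants)."""
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"canonical", "strength", "direction", "variants"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise LexiconError(
                f"lexicon file {path}: expected columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                strength = float(row["strength"])
            except (TypeError, ValueError):
                raise LexiconError(
                    f"{path}:{i}: non-numeric strength {row['strength']!r}"
                ) from None
            if strength not in ALLOWED_STRENGTHS:
                raise LexiconError(
                    f"{path}:{i} ({row['canonical']!r}): strength {strength} "
                    f"not in {ALLOWED_STRENGTHS}")
            variants = tuple(v for v in row["variants"].split("|") if v)
            entries.append(CausalityTermEntry(
                canonical=row["canonical"], strength=strength,
                direction=row["direction"], variants=variants))
    return Lexicon(entries)


def write_lexicon(lexicon: Lexicon, path: Union[str, Path]) -> None:
    """Write a lexicon back to its TSV interchange format."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("canonical\tstrength\tdirection\tvariants\n")
        for e in lexicon:
            fh.write(f"{e.canonical}\t{e.strength:.2f}\t{e.direction}\t"
                     + "|".join(e.variants) + "\n")


def default_lexicon() -> Lexicon:
    """The packaged 105-entry causality lexicon."""
    ref = resources.files("causalminer.data") / "causality_terms.tsv"
    with resources.as_file(ref) as path:
        return load_lexicon(path)


def lookup_term(lexicon: Lexicon, span: str) -> Optional[CausalityTermEntry]:
    """Resolve a candidate token span to a lexicon entry, or ``None``.

    Matching is case-insensitive over all variants; whitespace is collapsed.
    """
    return lexicon.entry_for_variant(" ".join(span.split()))
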