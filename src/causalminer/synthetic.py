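"""Seedable synthetic corpora with planted causality clauses.

The generator emulates the structure the scoring statistic consumes: abstracts
whose sentences contain ``<disease> <term> <disease>`` clauses with controlled
per-(pair, term) document and clause frequencies, diluted with filler
sentences (no causality pattern) and distractor documents (diseases without
causality terms).  Sentence templates are simple and grammatical, so the
rule-based extractor recovers every planted clause by construction — the
corpus exercises counting and scoring, not NLP recall.

Ground truth travels with the corpus as :class:`PlantedEvidenceSpec` rows, so
extraction + aggregation can be checked against exact planted (df, cf).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .corpus import DiseaseVocabulary, DocumentRecord, default_vocabulary
from .lexicon import FORWARD, CausalityTermEntry, Lexicon, default_lexicon

VOICES = ("active", "passive", "mixed")

#: Sentences free of disease names and causality-term variants.
FILLER_SENTENCES = (
    "The cohort comprised ninety adult participants.",
    "Samples were processed in triplicate under standard conditions.",
    "Mean follow-up was 3.5 years.",
    "Statistical analyses were performed with nonparametric tests.",
    "Written informed consent was obtained from all participants.",
    "No adverse events were recorded during the observation period.",
    "Demographic characteristics were balanced across groups.",
    "Laboratory values remained within normal limits throughout.",
)

TITLES = (
    "A retrospective cohort study.",
    "A single-center case series.",
    "Findings from a population-based registry.",
    "Observations from routine clinical practice.",
)

_DISTRACTOR_TEMPLATES = (
    "Patients with {a} and {b} were monitored for two years.",
    "Both {a} and {b} were observed in the cohort.",
    "The prevalence of {a} and of {b} was recorded separately.",
)

_WRAPPERS = (
    "{clause}.",
    "It was reported that {clause}.",
    "Our data suggest that {clause}.",
)


class SyntheticSpecError(ValueError):
    """Raised for invalid planted-evidence specifications."""


@dataclass(frozen=True)
class PlantedEvidenceSpec:
    """Ground-truth recipe: plant ``cf`` clauses over ``df`` documents."""

    prior: str
    posterior: str
    term: str
    df: int
    cf: int
    voice: str = "active"

    def __post_init__(self) -> None:
        if self.prior == self.posterior:
            raise SyntheticSpecError("spec pairs a disease with itself")
        if not 1 <= self.df <= self.cf:
            raise SyntheticSpecError(
                f"spec {self.prior}->{self.posterior} ({self.term}): "
                f"require 1 <= df <= cf, got df={self.df}, cf={self.cf}")
        if self.voice not in VOICES:
            raise SyntheticSpecError(f"voice must be one of {VOICES}")


@dataclass(frozen=True)
class SyntheticCorpus:
    """Documents plus the planted ground truth and the generating seed."""

    documents: tuple[DocumentRecord, ...]
    truth: tuple[PlantedEvidenceSpec, ...]
    seed: int


def _prose_name(vocab: DiseaseVocabulary, disease_id: str) -> str:
    """A name form usable in running text (prefer comma-free synonyms)."""
    entry = vocab.get(disease_id)
    if "," not in entry.preferred_name:
        return entry.preferred_name.lower() \
            if entry.preferred_name[1:].islower() else entry.preferred_name
    for syn in entry.synonyms:
        if "," not in syn:
            return syn
    return entry.preferred_name.replace(",", "")


def _inflected_surface(entry: CausalityTermEntry) -> str:
    """A third-person-singular variant when one exists, else the canonical."""
    head = entry.canonical.split()[0]
    candidates = [v for v in entry.variants
                  if v.split()[0] in (head + "s", head + "es")]
    if candidates:
        return max(candidates, key=len)
    return entry.canonical


def render_clause(spec: PlantedEvidenceSpec, vocab: DiseaseVocabulary,
                  lexicon: Lexicon) -> str:
    """The planted clause text, oriented by the term's direction flag."""
    entry = lexicon.get(spec.term)
    prior = _prose_name(vocab, spec.prior)
    posterior = _prose_name(vocab, spec.posterior)
    if entry.direction == FORWARD:
        clause = f"{prior} {_inflected_surface(entry)} {posterior}"
    else:
        clause = f"{posterior} {entry.canonical} {prior}"
    return clause


def _frame(clause: str, voice: str, rng: random.Random) -> str:
    if voice == "active":
        wrapper = _WRAPPERS[0]
    elif voice == "passive":
        wrapper = _WRAPPERS[1]
    else:
        wrapper = rng.choice(_WRAPPERS)
    sentence = wrapper.format(clause=clause)
    return sentence[0].upper() + sentence[1:]


def _partition_clauses(df: int, cf: int, rng: random.Random) -> list[int]:
    """Clauses per document: df-1 singletons plus one bulk slot, shuffled."""
    sizes = [1] * (df - 1) + [cf - df + 1]
    rng.shuffle(sizes)
    return sizes


def generate_corpus(
    specs: Sequence[PlantedEvidenceSpec],
    n_filler_sentences: int = 2,
    n_distractor_docs: int = 0,
    seed: int = 0,
    vocab: Optional[DiseaseVocabulary] = None,
    lexicon: Optional[Lexicon] = None,
) -> SyntheticCorpus:
    """Generate a corpus realising each spec's exact (df, cf).

    Each spec receives its own ``df`` documents; clauses are distributed over
    them as a seeded random shuffle of the (1, ..., 1, cf-df+1) partition and
    interleaved with ``n_filler_sentences`` filler sentences per document.
    Distractor documents mention two diseases with no causality term between
    them, so they must not change any evidence count.
    """
    vocab = vocab if vocab is not None else default_vocabulary()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    keys = [(s.prior, s.posterior, s.term) for s in specs]
    if len(keys) != len(set(keys)):
        raise SyntheticSpecError("duplicate (prior, posterior, term) specs")
    rng = random.Random(seed)
    docs: list[tuple[str, list[str]]] = []  # (title, sentences)
    for spec in specs:
        clause = render_clause(spec, vocab, lexicon)
        for size in _partition_clauses(spec.df, spec.cf, rng):
            sentences = [_frame(clause, spec.voice, rng)
                         for _ in range(size)]
            for _ in range(n_filler_sentences):
                pos = rng.randrange(len(sentences) + 1)
                sentences.insert(pos, rng.choice(FILLER_SENTENCES))
            docs.append((rng.choice(TITLES), sentences))
    disease_ids = [e.disease_id for e in vocab]
    for _ in range(n_distractor_docs):
        a, b = rng.sample(disease_ids, 2)
        template = rng.choice(_DISTRACTOR_TEMPLATES)
        sentences = [template.format(a=_prose_name(vocab, a),
                                     b=_prose_name(vocab, b))]
        for _ in range(n_filler_sentences):
            sentences.append(rng.choice(FILLER_SENTENCES))
        docs.append((rng.choice(TITLES), sentences))
    rng.shuffle(docs)
    documents = tuple(
        DocumentRecord(doc_id=f"SYN{i:07d}", title=title,
                       body=" ".join(sentences))
        for i, (title, sentences) in enumerate(docs, start=1))
    return SyntheticCorpus(documents=documents, truth=tuple(specs),
                           seed=seed)


HEPATITIS_C = "D006526"
HEPATOCELLULAR_CARCINOMA = "D006528"

#: The worked example's forward evidence: (term, df, cf) for the ordered pair
#: Hepatitis C -> Hepatocellular Carcinoma, keyed by canonical lexicon terms.
WORKED_EXAMPLE_FORWARD_EVIDENCE: tuple[tuple[str, int, int], ...] = (
    ("affect", 1, 1),
    ("cause", 26, 27),
    ("contribute", 1, 1),
    ("develop", 10, 10),
    ("due to", 8, 8),
    ("educe", 1, 1),
    ("effectuate", 3, 3),
    ("induce", 1, 4),
    ("infect", 4, 4),
    ("lead", 10, 10),
    ("link", 1, 1),
    ("relate", 21, 21),
    ("result", 1, 1),
    ("rise", 1, 1),
    ("secondary to", 1, 1),
    ("triggered by", 1, 1),
)

#: Reverse-direction evidence (Hepatocellular Carcinoma as prior).  The
#: published aggregate reverse weight is 8.63 with no per-term breakdown, so
#: this composition is a synthetic stand-in verified by direct summation:
#: 1.00*8*log10(9) + 1.00*1*log10(10) = 8.6339 (8.63 at 2 d.p.).
WORKED_EXAMPLE_REVERSE_EVIDENCE: tuple[tuple[str, int, int], ...] = (
    ("caused by", 8, 8),
    ("due to", 1, 9),
)


def make_worked_example_fixture(seed: int = 0, n_filler_sentences: int = 2,
                        n_distractor_docs: int = 3) -> SyntheticCorpus:
    """A corpus realising the Hepatitis C / Hepatocellular Carcinoma example.

    Planted evidence equals the sixteen published (term, df, cf) rows for the
    forward direction plus the synthetic reverse composition above, so the
    full pipeline yields w(forward) = 76.84, w(reverse) = 8.63 and a final
    score of 68.21 (2 d.p.).
    """
    specs = [PlantedEvidenceSpec(prior=HEPATITIS_C,
                                 posterior=HEPATOCELLULAR_CARCINOMA,
                                 term=t, df=df, cf=cf, voice="mixed")
             for t, df, cf in WORKED_EXAMPLE_FORWARD_EVIDENCE]
    specs += [PlantedEvidenceSpec(prior=HEPATOCELLULAR_CARCINOMA,
                                  posterior=HEPATITIS_C,
                                  term=t, df=df, cf=cf, voice="mixed")
              for t, df, cf in WORKED_EXAMPLE_REVERSE_EVIDENCE]
    return generate_corpus(specs, n_filler_sentences=n_filler_sentences,
                           n_distractor_docs=n_distractor_docs, seed=seed)
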