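"""Document-clause frequency scoring and the antisymmetric causality statistic.

For an ordered disease pair (A, B) and a causality term t, the corpus yields
a document frequency ``df`` (distinct documents with at least one clause) and
a clause frequency ``cf`` (total clauses).  The document-clause frequency

    DCF = df * log10(cf + 1)

rewards evidence spread over many documents above repetition within one: four
clauses in one document score 0.70, one clause in each of four documents 2.80.
The directed weight for the pair sums the lexicon-weighted DCFs,

    w_AB = sum_t alpha_t * DCF_t,

and the final statistic alphaDCFC(A, B) = w_AB - w_BA is antisymmetric: its
sign gives the causal direction (positive means A is the prior disease), its
magnitude the causal confidence.

All accumulation is at full floating precision; rounding to two decimals is
presentation only.
"""

from __future__ import annotations

import csv
import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .extraction import CausalityClauseMatch
from .lexicon import Lexicon


class ScoringError(ValueError):
    """Raised for inconsistent evidence counts or mismatched pairs."""


@dataclass(frozen=True)
class EvidenceCounts:
    """Per-(ordered pair, term) document and clause frequencies."""

    prior: str
    posterior: str
    term: str
    df: int
    cf: int

    def __post_init__(self) -> None:
        if self.prior == self.posterior:
            raise ScoringError("evidence pairing a disease with itself")
        if not 1 <= self.df <= self.cf:
            raise ScoringError(
                f"evidence {self.prior}->{self.posterior} ({self.term}): "
                f"require 1 <= df <= cf, got df={self.df}, cf={self.cf}")


@dataclass(frozen=True)
class DirectedWeight:
    """Directed causality weight w for one ordered pair."""

    prior: str
    posterior: str
    weight: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ScoringError("directed weight must be non-negative")


@dataclass(frozen=True)
class CausalityScore:
    """The antisymmetric statistic for one unordered pair.

    Stored canonically with ``disease_a < disease_b``; ``score`` is
    w(a->b) - w(b->a) and ``direction`` is the resolved (prior, posterior)
    pair, or ``None`` when the evidence is exactly balanced.
    """

    disease_a: str
    disease_b: str
    score: float
    direction: Optional[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.disease_a >= self.disease_b:
            raise ScoringError("canonical storage requires disease_a < disease_b")
        expected = None if self.score == 0 else (
            (self.disease_a, self.disease_b) if self.score > 0
            else (self.disease_b, self.disease_a))
        if self.direction != expected:
            raise ScoringError("direction inconsistent with score sign")

    @property
    def prior(self) -> Optional[str]:
        return self.direction[0] if self.direction else None

    @property
    def posterior(self) -> Optional[str]:
        return self.direction[1] if self.direction else None


def aggregate_evidence(
    matches: Iterable[CausalityClauseMatch],
) -> list[EvidenceCounts]:
    """Collapse clause matches into (prior, posterior, term) -> (df, cf).

    ``cf`` is the total number of clauses; ``df`` the number of distinct
    documents contributing at least one of them.
    """
    cf: dict[tuple[str, str, str], int] = defaultdict(int)
    docs: dict[tuple[str, str, str], set[str]] = defaultdict(set)
    order: list[tuple[str, str, str]] = []
    for m in matches:
        key = (m.prior, m.posterior, m.term.canonical)
        if key not in cf:
            order.append(key)
        cf[key] += 1
        docs[key].add(m.doc_id)
    return [EvidenceCounts(prior=p, posterior=q, term=t,
                           df=len(docs[p, q, t]), cf=cf[p, q, t])
            for p, q, t in order]


def compute_dcf(df: int, cf: int) -> float:
    """Document-clause frequency df * log10(cf + 1); (0, 0) scores 0."""
    if df == 0 and cf == 0:
        return 0.0
    if df < 0 or cf < 0 or df == 0 or cf == 0 or df > cf:
        raise ScoringError(
            f"inconsistent counts df={df}, cf={cf}: require 1 <= df <= cf")
    return df * math.log10(cf + 1)


def compute_directed_weight(
    evidence: Iterable[EvidenceCounts],
    lexicon: Lexicon,
    prior: Optional[str] = None,
    posterior: Optional[str] = None,
) -> DirectedWeight:
    """Sum alpha_t * DCF_t over the evidence rows of one ordered pair."""
    rows = list(evidence)
    if rows:
        pairs = {(r.prior, r.posterior) for r in rows}
        if len(pairs) > 1:
            raise ScoringError(
                f"evidence mixes ordered pairs: {sorted(pairs)}")
        row_prior, row_posterior = rows[0].prior, rows[0].posterior
        if prior is not None and (prior, posterior) != (row_prior,
                                                        row_posterior):
            raise ScoringError(
                f"evidence is for {row_prior}->{row_posterior}, "
                f"not {prior}->{posterior}")
        prior, posterior = row_prior, row_posterior
    if prior is None or posterior is None:
        raise ScoringError("empty evidence needs explicit prior/posterior")
    weight = 0.0
    for r in rows:
        alpha = lexicon.get(r.term).strength
        weight += alpha * compute_dcf(r.df, r.cf)
    return DirectedWeight(prior=prior, posterior=posterior, weight=weight)


def compute_alpha_dcfc(w_ab: DirectedWeight,
                       w_ba: DirectedWeight) -> CausalityScore:
    """alphaDCFC = w_AB - w_BA for one unordered pair, direction by sign."""
    if (w_ab.prior, w_ab.posterior) != (w_ba.posterior, w_ba.prior):
        raise ScoringError(
            f"weights are not opposite orientations of one pair: "
            f"{w_ab.prior}->{w_ab.posterior} vs {w_ba.prior}->{w_ba.posterior}")
    a, b = sorted((w_ab.prior, w_ab.posterior))
    if a == w_ab.prior:
        score = w_ab.weight - w_ba.weight
    else:
        score = w_ba.weight - w_ab.weight
    direction = None if score == 0 else ((a, b) if score > 0 else (b, a))
    return CausalityScore(disease_a=a, disease_b=b, score=score,
                          direction=direction)


def score_evidence(evidence: Iterable[EvidenceCounts],
                   lexicon: Lexicon) -> list[CausalityScore]:
    """Directed weights and alphaDCFC for every unordered pair with evidence.

    Results are sorted by |alphaDCFC| descending (top-ranked pairs first).
    """
    by_pair: dict[tuple[str, str], list[EvidenceCounts]] = defaultdict(list)
    for r in evidence:
        by_pair[r.prior, r.posterior].append(r)
    scores = []
    for a, b in sorted({tuple(sorted(k)) for k in by_pair}):
        w_ab = compute_directed_weight(by_pair.get((a, b), []), lexicon,
                                       prior=a, posterior=b)
        w_ba = compute_directed_weight(by_pair.get((b, a), []), lexicon,
                                       prior=b, posterior=a)
        scores.append(compute_alpha_dcfc(w_ab, w_ba))
    scores.sort(key=lambda s: (-abs(s.score), s.disease_a, s.disease_b))
    return scores


def directed_weights(evidence: Iterable[EvidenceCounts],
                     lexicon: Lexicon) -> dict[tuple[str, str], float]:
    """w for every ordered pair present in the evidence."""
    by_pair: dict[tuple[str, str], list[EvidenceCounts]] = defaultdict(list)
    for r in evidence:
        by_pair[r.prior, r.posterior].append(r)
    return {key: compute_directed_weight(rows, lexicon).weight
            for key, rows in by_pair.items()}


def write_evidence(evidence: Sequence[EvidenceCounts],
                   path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("prior\tposterior\tterm\tdf\tcf\n")
        for r in evidence:
            fh.write(f"{r.prior}\t{r.posterior}\t{r.term}\t{r.df}\t{r.cf}\n")


def read_evidence(path: Union[str, Path]) -> list[EvidenceCounts]:
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(EvidenceCounts(
                prior=row["prior"], posterior=row["posterior"],
                term=row["term"], df=int(row["df"]), cf=int(row["cf"])))
    return rows


def write_scores(scores: Sequence[CausalityScore],
                 weights: dict[tuple[str, str], float],
                 path: Union[str, Path]) -> None:
    """Scores TSV: prior, posterior, w_ab, w_ba, alpha_dcfc (2 d.p. display)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("prior\tposterior\tw_ab\tw_ba\talpha_dcfc\n")
        for s in scores:
            if s.direction is None:
                prior, posterior = s.disease_a, s.disease_b
            else:
                prior, posterior = s.direction
            w_ab = weights.get((prior, posterior), 0.0)
            w_ba = weights.get((posterior, prior), 0.0)
            fh.write(f"{prior}\t{posterior}\t{round(w_ab, 2):.2f}\t"
                     f"{round(w_ba, 2):.2f}\t{round(abs(s.score), 2):.2f}\n")
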