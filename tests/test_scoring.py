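"""DCF arithmetic, directed weights, and the antisymmetric statistic."""

import math

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from causalminer.extraction import extract_clauses
from causalminer.scoring import (CausalityScore, DirectedWeight,
                                 EvidenceCounts, ScoringError,
                                 aggregate_evidence, compute_alpha_dcfc,
                                 compute_dcf, compute_directed_weight,
                                 directed_weights, read_evidence,
                                 score_evidence, write_evidence)
from causalminer.synthetic import (WORKED_EXAMPLE_FORWARD_EVIDENCE,
                                   PlantedEvidenceSpec, generate_corpus)

HEP_C = "D006526"
HCC = "D006528"

#: Published per-term values for the Hepatitis C -> Hepatocellular Carcinoma
#: evidence: canonical term -> (df, cf, DCF, alpha*DCF) at 2 d.p. display.
WORKED_EXAMPLE_PRINTED = {
    "affect": (1, 1, 0.30, 0.30),
    "cause": (26, 27, 37.63, 37.63),
    "contribute": (1, 1, 0.30, 0.23),
    "develop": (10, 10, 10.41, 10.41),
    "due to": (8, 8, 7.63, 7.63),
    "educe": (1, 1, 0.30, 0.23),
    "effectuate": (3, 3, 1.81, 1.81),
    "induce": (1, 4, 0.70, 0.52),
    "infect": (4, 4, 2.80, 2.10),
    "lead": (10, 10, 10.41, 7.81),
    "link": (1, 1, 0.30, 0.08),
    "relate": (21, 21, 28.19, 7.05),
    "result": (1, 1, 0.30, 0.30),
    "rise": (1, 1, 0.30, 0.30),
    "secondary to": (1, 1, 0.30, 0.15),
    "triggered by": (1, 1, 0.30, 0.30),
}


class _Match:
    """Minimal stand-in carrying the fields aggregate_evidence reads."""

    class _Term:
        def __init__(self, canonical):
            self.canonical = canonical

    def __init__(self, doc_id, term, prior, posterior):
        self.doc_id = doc_id
        self.term = self._Term(term)
        self.prior = prior
        self.posterior = posterior


class TestAggregateEvidence:
    def test_repetition_within_one_document(self):
        matches = [_Match("d1", "cause", "A", "B") for _ in range(4)]
        [ev] = aggregate_evidence(matches)
        assert (ev.df, ev.cf) == (1, 4)

    def test_spread_over_four_documents(self):
        matches = [_Match(f"d{i}", "cause", "A", "B") for i in range(4)]
        [ev] = aggregate_evidence(matches)
        assert (ev.df, ev.cf) == (4, 4)

    def test_single_clause(self):
        [ev] = aggregate_evidence([_Match("d1", "cause", "A", "B")])
        assert (ev.df, ev.cf) == (1, 1)

    def test_orientations_counted_separately(self):
        matches = [_Match("d1", "cause", "A", "B"),
                   _Match("d1", "cause", "B", "A")]
        assert len(aggregate_evidence(matches)) == 2

    def test_matches_brute_force_recount_on_small_corpora(self, vocab,
                                                          lexicon):
        """Pandas groupby recount over extracted triples agrees exactly."""
        specs = [
            PlantedEvidenceSpec(HEP_C, HCC, "cause", df=3, cf=5),
            PlantedEvidenceSpec(HCC, HEP_C, "due to", df=2, cf=2),
            PlantedEvidenceSpec("D000783", "D006470", "trigger", df=4, cf=6,
                                voice="mixed"),
        ]
        corpus = generate_corpus(specs, n_distractor_docs=2, seed=11)
        matches = extract_clauses(corpus.documents, vocab, lexicon)
        frame = pd.DataFrame(
            [(m.doc_id, m.prior, m.posterior, m.term.canonical)
             for m in matches],
            columns=["doc_id", "prior", "posterior", "term"])
        oracle = frame.groupby(["prior", "posterior", "term"]).agg(
            df=("doc_id", "nunique"), cf=("doc_id", "size"))
        got = {(e.prior, e.posterior, e.term): (e.df, e.cf)
               for e in aggregate_evidence(matches)}
        assert got == {key: (int(row.df), int(row.cf))
                       for key, row in oracle.iterrows()}


class TestComputeDcf:
    @pytest.mark.parametrize("df, cf, expected", [
        (26, 27, 37.63), (10, 10, 10.41), (8, 8, 7.63), (21, 21, 28.19),
        (1, 4, 0.70), (3, 3, 1.81), (4, 4, 2.80), (1, 1, 0.30),
    ])
    def test_published_values_at_2dp(self, df, cf, expected):
        assert round(compute_dcf(df, cf), 2) == expected

    def test_no_evidence_scores_zero(self):
        assert compute_dcf(0, 0) == 0.0

    @pytest.mark.parametrize("df, cf", [(5, 4), (0, 3), (3, 0), (-1, 2)])
    def test_inconsistent_counts_rejected(self, df, cf):
        with pytest.raises(ScoringError, match="df"):
            compute_dcf(df, cf)

    @given(df=st.integers(1, 50), cf=st.integers(1, 200))
    def test_monotone_in_each_argument(self, df, cf):
        cf = max(df, cf)
        assert compute_dcf(df, cf + 1) > compute_dcf(df, cf)
        assert compute_dcf(df + 1, cf + 1) > compute_dcf(df, cf + 1)

    @given(n=st.integers(2, 500))
    def test_spread_beats_repetition(self, n):
        """n clauses in n documents outrank n clauses in one document."""
        assert compute_dcf(n, n) > compute_dcf(1, n)


class TestDirectedWeight:
    def evidence_rows(self):
        return [EvidenceCounts(HEP_C, HCC, t, df, cf)
                for t, df, cf in WORKED_EXAMPLE_FORWARD_EVIDENCE]

    def test_worked_example_weight(self, lexicon):
        w = compute_directed_weight(self.evidence_rows(), lexicon)
        assert round(w.weight, 2) == 76.84

    def test_per_term_alpha_dcf_contributions(self, lexicon):
        for term, (df, cf, dcf, alpha_dcf) in WORKED_EXAMPLE_PRINTED.items():
            assert round(compute_dcf(df, cf), 2) == dcf
            contribution = lexicon.get(term).strength * compute_dcf(df, cf)
            assert round(contribution, 2) == alpha_dcf

    def test_full_precision_beats_rounded_column_sum(self, lexicon):
        """The printed 2 d.p. column sums to 76.85; full precision to 76.84."""
        rounded_sum = sum(v[3] for v in WORKED_EXAMPLE_PRINTED.values())
        assert round(rounded_sum, 2) == 76.85
        w = compute_directed_weight(self.evidence_rows(), lexicon)
        assert round(w.weight, 2) == 76.84

    def test_additivity_over_terms(self, lexicon):
        rows = self.evidence_rows()
        total = compute_directed_weight(rows, lexicon).weight
        parts = sum(compute_directed_weight([r], lexicon).weight
                    for r in rows)
        assert total == pytest.approx(parts, abs=1e-12)

    def test_empty_evidence_is_zero(self, lexicon):
        w = compute_directed_weight([], lexicon, prior="A", posterior="B")
        assert w.weight == 0.0

    def test_single_row_arithmetic(self, lexicon):
        [w] = [compute_directed_weight(
            [EvidenceCounts("A", "B", "cause", 1, 1)], lexicon)]
        assert w.weight == pytest.approx(math.log10(2))

    def test_unknown_term_named(self, lexicon):
        with pytest.raises(Exception, match="banana"):
            compute_directed_weight(
                [EvidenceCounts("A", "B", "banana", 1, 1)], lexicon)

    def test_mixed_pairs_rejected(self, lexicon):
        with pytest.raises(ScoringError, match="pairs"):
            compute_directed_weight(
                [EvidenceCounts("A", "B", "cause", 1, 1),
                 EvidenceCounts("B", "A", "cause", 1, 1)], lexicon)


class TestAlphaDcfc:
    def test_worked_example_direction_and_value(self):
        w_ab = DirectedWeight(HEP_C, HCC, 76.84)
        w_ba = DirectedWeight(HCC, HEP_C, 8.63)
        s = compute_alpha_dcfc(w_ab, w_ba)
        assert round(abs(s.score), 2) == 68.21
        assert s.direction == (HEP_C, HCC)

    def test_symmetric_evidence_has_no_direction(self):
        s = compute_alpha_dcfc(DirectedWeight("A", "B", 2.5),
                               DirectedWeight("B", "A", 2.5))
        assert s.score == 0 and s.direction is None

    def test_swapping_arguments_negates_nothing_observable(self):
        a = compute_alpha_dcfc(DirectedWeight("A", "B", 5.0),
                               DirectedWeight("B", "A", 2.0))
        b = compute_alpha_dcfc(DirectedWeight("B", "A", 2.0),
                               DirectedWeight("A", "B", 5.0))
        assert a == b  # canonical storage is orientation-free

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ScoringError, match="orientations"):
            compute_alpha_dcfc(DirectedWeight("A", "B", 1.0),
                               DirectedWeight("A", "C", 1.0))

    @given(w1=st.floats(0, 100), w2=st.floats(0, 100))
    def test_antisymmetry_by_construction(self, w1, w2):
        s = compute_alpha_dcfc(DirectedWeight("A", "B", w1),
                               DirectedWeight("B", "A", w2))
        assert s.score == w1 - w2
        if s.score > 0:
            assert s.direction == ("A", "B")
        elif s.score < 0:
            assert s.direction == ("B", "A")


class TestScoreEvidence:
    def test_sorted_by_magnitude(self, lexicon):
        evidence = [
            EvidenceCounts("A", "B", "cause", 2, 2),
            EvidenceCounts("C", "D", "cause", 9, 9),
            EvidenceCounts("B", "A", "link", 1, 1),
        ]
        scores = score_evidence(evidence, lexicon)
        mags = [abs(s.score) for s in scores]
        assert mags == sorted(mags, reverse=True)

    def test_round_trip_evidence_tsv(self, lexicon, tmp_path):
        evidence = [EvidenceCounts(HEP_C, HCC, t, df, cf)
                    for t, df, cf in WORKED_EXAMPLE_FORWARD_EVIDENCE]
        path = tmp_path / "evidence.tsv"
        write_evidence(evidence, path)
        assert read_evidence(path) == evidence

    def test_directed_weights_cover_both_orientations(self, lexicon):
        evidence = [EvidenceCounts("A", "B", "cause", 1, 1),
                    EvidenceCounts("B", "A", "link", 1, 2)]
        w = directed_weights(evidence, lexicon)
        assert set(w) == {("A", "B"), ("B", "A")}
        assert w["A", "B"] == pytest.approx(math.log10(2))
        assert w["B", "A"] == pytest.approx(0.25 * math.log10(3))
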