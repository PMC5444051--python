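# Methods

## Model

`causalminer` scores causal relations between diseases from clause-level
co-occurrence in abstracts. The underlying assumptions are:

- A clause `<disease A> <causality term> <disease B>` asserts a cause–effect
  relation whose *reliability* grows with (a) the semantic strength of the
  term and (b) how broadly the literature repeats the assertion.
- Terms differ in causal connotation. Each term t carries a strength
  α_t ∈ {0.25, 0.50, 0.75, 1.00}: the modal level of a four-point Likert
  survey ("simple relation" … "very strong") divided by the scale size,
  α_t = argmax_l freq_t(l) / |L|. The packaged lexicon of 105 terms ships
  these strengths as data; the aggregation operation is provided so users
  can rebuild strengths from their own survey tallies.
- Evidence spread across documents is worth more than repetition within
  one. For ordered pair (A, B) and term t, with document frequency df and
  clause frequency cf (1 ≤ df ≤ cf), the document-clause frequency is
  DCF = df · log10(cf + 1). The logarithm base is 10: it is the unique base
  consistent with every published per-term value (26·log10(28) = 37.63,
  10·log10(11) = 10.41, 1·log10(5) = 0.70, 4·log10(5) = 2.80).
- The directed weight w_AB = Σ_t α_t · DCF_t accumulates at full floating
  precision; rounding (half-even, 2 d.p.) happens only at display. This
  matters: summing the pre-rounded per-term column of the worked example
  gives 76.85, full-precision accumulation gives the published 76.84.
- The final statistic αDCFC(A, B) = w_AB − w_BA is antisymmetric by
  construction. Sign gives direction (positive: A is the prior disease),
  magnitude gives confidence. A pair with αDCFC exactly 0 has undefined
  direction and contributes no network edge (the direction rule is a strict
  inequality).

## Lexicon details

- **Tie-breaking.** A multimodal survey tally has no unique argmax; the
  default takes the *lowest* tied level (conservative causal strength).
  `aggregate_term_strength(..., tie_break="highest")` overrides this.
- **Direction flags** are not survey data; they are assigned from the
  surface form: entries whose subject is the effect ("… by", "arising
  from", "stem from", "resulting from", "due to", "because of",
  "attributable/attributed to", "secondary to") are `reverse`, all others
  `forward`. The flag ships as an explicit TSV column so users can
  override it.
- **Variants** are a hand-curated inflection table per entry (third-person
  -s, past, -ing, irregular forms), not a stemmer — matches stay
  auditable. Two published worked-example surfaces do not appear verbatim
  in the source lexicon: "effect" is carried as a variant of "effectuate"
  (strength 1.00) and "lead to" as a variant of "lead" (0.75). This keeps
  the lexicon at exactly 105 entries while making the worked example
  reproducible; we flag it as an inconsistency in the published table.
- `scale_size` is fixed at 4 (four-point Likert scale) but exposed as a
  parameter.

## Extraction

The published pipeline used a full dependency parser; re-implementing it is
out of scope and unnecessary for the scoring method, so extraction here is
rule-based. This is the package's main methodological approximation:

- Sentences are split on terminal punctuation with an abbreviation guard
  list and a decimal guard; offsets are 0-based half-open and reconstruct
  the source text exactly. Titles are period-joined to the body before
  splitting (titles carry causal statements too; `include_title=False`
  disables this).
- Disease mentions are case-insensitive longest-match dictionary hits over
  preferred names and synonyms; at overlaps the longest surface wins
  ("subarachnoid hemorrhage" beats "hemorrhage"), so each character
  position belongs to at most one mention.
- Sentences are segmented at ";" and at ", which" / ", that" boundaries.
  Each term occurrence is paired with the nearest mention strictly to its
  left and strictly to its right within its segment; both must exist and
  differ. One term occurrence yields at most one clause (a clause relates
  one subject to one object — pairing with the cross-product of mentions
  would inflate counts); multiple term occurrences in one sentence each
  yield a clause, because cf counts clauses, not sentences. Relative
  pronouns without a comma ("a virus that causes …") resolve naturally to
  the nearest preceding mention.
- Negation ("does not cause"), coreference, and hedging are not handled;
  this is a known limitation shared with the underlying method.

## Aggregation conventions

- df counts documents per *ordered* pair and term, consistent with the
  separate w_AB / w_BA accounting; a document asserting both orientations
  contributes to both.
- `compute_dcf(0, 0) = 0` (no evidence); any other inconsistency
  (df > cf, exactly one of df/cf zero) is an error rather than a silent 0.

## Network, scaling, evaluation

One directed edge per unordered pair with nonzero αDCFC; node attribute
`in_degree` records the number of influencing diseases. Min–max scaling
(v − min)/(max − min) is defined over an explicit population of compared
pairs — results depend on that scope, so it is an argument, not a default.
All-equal inputs make scaling undefined and raise. Spearman's ρ uses
average ranks on ties (scipy); the evaluation harness correlates αDCFC
magnitudes with per-pair total document frequency, the same relevance
check used to compare causality-ranking methods.

## Synthetic corpora

The generator emulates exactly the corpus structure the statistic consumes:
abstracts whose sentences contain planted `<disease> <term> <disease>`
clauses with controlled per-(pair, term) (df, cf), filler sentences free of
the causality pattern, and distractor documents mentioning diseases without
causality terms. Design choices:

- Templates are simple and grammatical; clause orientation on the page is
  dictated by the term's direction flag (a forward term renders
  "<prior> <term-inflected> <posterior>", a reverse term
  "<posterior> <term> <prior>"), so the extractor's recall on planted
  clauses is 100% by construction. The corpus therefore tests counting and
  scoring, not NLP recall — passing says nothing about recall on real
  prose, where parser-free extraction will miss long-range constructions.
- The `voice` field selects sentence framing (bare clause, reported-speech
  wrapper, or a seeded mix); orientation cannot vary with voice without
  planting clauses the extractor must misread.
- Clause-to-document partition: df − 1 documents receive one clause, the
  last receives cf − df + 1, then the assignment is shuffled by the seed —
  simple, reproducible, and it reaches every df ≤ cf boundary shape.
- Regeneration with the same seed is byte-identical.

The flagship fixture plants the sixteen published forward evidence rows for
Hepatitis C → Hepatocellular Carcinoma. The published *reverse* weight
(8.63) has no per-term breakdown, so the fixture's reverse evidence is a
synthetic composition — "caused by" (df=8, cf=8) plus "due to" (df=1, cf=9),
both α = 1.00 — verified by direct summation to equal 8.63 within ±0.005:
8·log10(9) + 1·log10(10) = 8.6339. Default fixture sizes (2 filler
sentences per document, 3 distractor documents) keep the corpus at ~100
short documents, which the full pipeline processes in well under a second.

## Problem sizes used in checks

Corpus-scale published results (6.6M abstracts screened down to 43,248
documents; 1011 causal pairs over 149 diseases; cross-method Spearman
comparisons) require the original corpus and an external knowledge base and
are not reproducible at desk scale. In their place the test suite exercises
the method's structural guarantees on randomized synthetic corpora: exact
(df, cf) recovery over 100 random spec sets (seeds 0–99), antisymmetry of
every scored pair, strict DCF monotonicity in df and cf, agreement of the
Spearman implementation with a brute-force rank oracle to 1e-12, and ρ = 1.0
on document-frequency-proportional scores.

## Known limitations

- Rule-based clause extraction under-recalls on real biomedical prose
  (coordination, apposition, anaphora); counts from real corpora are lower
  bounds relative to parser-based extraction.
- No negation or speculation handling: "X does not cause Y" counts as
  evidence for X → Y.
- Dictionary-based mention finding misses lexical variants absent from the
  vocabulary and does not disambiguate abbreviations beyond exact synonym
  lists.
- αDCFC carries no significance test; magnitudes are comparable only
  within one corpus.
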