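# Methods

## The pipeline model

litmine models the systematic-review workflow as three chained stages over
a *linked corpus*: review topics (research questions framed as PICO —
population, intervention, comparator, outcome — plus eligibility criteria),
publication citations, and clinical-trial registry records attached to
publications by NCT identifiers.

**Search.** A search strategy for a review with N target studies is built
from per-study keyword sets.  For study *n*, up to M = 10 population terms
and up to 10 intervention terms are extracted by a generative backend; the
terms of one study are AND-ed (a study must match its whole profile), the
per-study groups are OR-ed (any profile suffices), and the population and
intervention clauses are AND-ed together.  The within-group connective is
configurable (`inner_connective="or"`) because a ten-term conjunction is
very restrictive against real abstracts; the default follows the
construction above.  A strategy whose measured recall on the review's known
target studies is below 0.2 is discarded as poorly generated; the boundary
is inclusive-keep (recall exactly 0.2 survives), since it is queries
*below* 0.2 that are dropped.  Ensemble generation samples `n_runs` queries
with seeds `seed + run_index`, retrieves each, and returns the
first-occurrence-deduplicated concatenation; recall of the union is
non-decreasing in the number of runs by construction.

**Screening.** Every candidate is assessed per criterion; labels map to
scores YES→1, PARTIAL→0.5, UNCERTAIN→0, NO→−1 and the final eligibility
score is their arithmetic mean (so it always lies in [−1, 1], hitting the
extremes only for unanimous NO/YES).  A per-criterion answer that cannot be
parsed degrades to UNCERTAIN (score 0) with a warning rather than failing
the study — this keeps the ranking total under a flaky backend.  Ranking is
by descending score with ties broken by ascending study id, which makes
recall@K deterministic.  Score strata [−1, −0.5], (−0.5, 0.75), [0.75, 1]
partition results into predicted-ineligible / intermediate /
predicted-eligible bands.  Candidate pools put primary search hits first,
apply the strict publication-date constraint (strictly before the review's
date; same-day publications are excluded; records with no date are skipped
with a warning because real bibliographic data has missing dates), and pad
to the pool size with hits from population-only, intervention-only, then
outcome-only queries.

**Extraction.** The four tasks validate backend output against per-task
schemas (unique arm labels, participant results referencing declared group
ids, nonnegative denominators).  Numbers are parsed leniently — thousands
separators, percent signs, and surrounding unit words are stripped — but
values are never coerced across kinds and derived quantities are never
recomputed by the framework; computing, say, a pooled mean age is the
backend's job, the framework only checks the reported value.  Documents
are truncated to a 30,000-whitespace-token budget in the order title,
abstract, full text, tables, so the abstract is never sacrificed while
full text remains.

## Backends

All generation goes through one contract: `complete(prompt, seed, …) →
text`.  Prompts are rendered from a versioned template registry (rendering
fails loudly on a missing placeholder) and carry a machine-readable context
line naming the task and the ids involved.  The **oracle** backend resolves
those ids in its bound corpus and answers with the planted ground truth:
exact keyword sets for term-extraction and query prompts, all-YES analyses
for included studies, NO/PARTIAL analyses for other candidates (PARTIAL
exactly when all of a criterion element's planted terms occur in the
candidate's text — so a non-included candidate can never reach score 1.0),
and registry-truth serializations for extraction prompts.  The **noisy
oracle** corrupts these answers at rate ε: each YES eligibility label flips
to NO independently, and each per-study keyword group is dropped
independently (keeping at least one).  Corruptions are a pure function of
(backend seed, call seed, ids), so replicates are reproducible, and ε = 0
reproduces the oracle byte-for-byte.  The prompt texts are original
compositions; instruction records store the template version tag.

The default text embedder is a hashed character-3-gram count vector
(dimension 65,536, blake2s hashing), giving exactly reproducible cosine
similarities with no model dependency; an API embedding backend is a
drop-in replacement.  The soft-match threshold is 0.75 and the comparison
is inclusive (≥ 0.75 is correct).

## The synthetic corpus

The generator emulates the structure that makes the pipeline verifiable,
not the surface statistics of real literature:

* every included study's title/abstract contain its planted population and
  intervention terms verbatim (one real clinical term plus one unique
  pronounceable pseudo-term per element, so matching is non-trivial but
  unambiguous);
* comparator and outcome phrases carry a review-unique pseudo qualifier so
  element vocabularies never collide across reviews even though the real
  word lists cycle;
* distractors are generic trial prose sharing a Binomial(`overlap_rate`)
  subset of the review's planted vocabulary; at `overlap_rate = 0` no
  distractor contains any planted term, while the shared prose word
  "patients" keeps element fill queries productive;
* a fraction (`post_review_fraction`, default 0.1) of distractors post-date
  the review to exercise the time constraint; included studies always
  predate it;
* each included publication embeds its registry record (conditions,
  interventions, enrollment, study type, two arms, one baseline measure
  with two groups, one outcome with two results) verbatim into
  pseudo-full-text and table blocks, making extraction verifiable
  round-trip — `registry_value_strings` enumerates exactly the strings
  that must appear;
* study ids are drawn randomly (PMID-like 8-digit integers, `NCT` + 8
  digits for registries), so ranking tie-breaks by id are uncorrelated with
  inclusion status.

Generation is a pure function of the configuration including the seed;
identical configurations give byte-identical JSON.  What the corpus does
**not** emulate: realistic abstract language, synonymy and MeSH vocabulary,
citation-count skew, OCR noise, or ambiguous eligibility — so a perfect
oracle score here demonstrates the *plumbing* (assembly, execution,
scoring, ranking, round-tripping) is correct, not that any model is good
at the task on real literature.  Reported recalls from live search engines
additionally depend on their internal ranking when result sets exceed the
retrieval limit, which the deterministic date-ordered engine does not
attempt to replicate.

## Verification design

The heavier checks are calibrated experiments rather than examples:

* **Query correctness** — on 50 generated reviews, engine evaluation of the
  assembled query is compared to naive per-document truth-table evaluation,
  and pre-filter recall must be exactly 1.0; the 0.2 filter boundary is
  probed with constructed recalls of 0.19 / 0.20 / 0.21.
* **Ensemble monotonicity** — 20 replicates of a noisy generator
  (group-drop rate 0.5) at 1, 2, 5, 10 runs; the ensemble list must equal
  the order-preserving union of per-run retrievals.
* **Pipeline recovery** — 20 reviews (5–25 target studies, pools of 200,
  zero overlap so every non-target pool member scores exactly −1): the
  exact oracle must place every target in the top |truth|.  Under
  per-criterion YES→NO flips at ε = 0.1 with C = 4 criteria, a target
  drops out only if all criteria flip (probability ε⁴), after which it
  competes for the freed slots against the D distractors tied at −1 and
  wins with probability j/(j+D) by id exchangeability.  The total number
  of recovered targets over 200 seeded replicates must fall inside the
  binomial 95% interval of this analytic expectation (the tiny correlation
  ties induce between targets of one review is ignored; at ε⁴ = 10⁻⁴ it is
  far below the interval width).
* **Extraction** — oracle round trips on 30 linked studies must score 1.0
  on both numeric and text fields; corrupting exactly one numeric field
  per study must lower numeric accuracy to exactly (F−1)/F for the F = 5
  numeric fields each study carries (enrollment, two participant values,
  two outcome values).

Problem sizes (corpus sizes, replicate counts, pool sizes) were chosen so
the full suite and the acceptance script each complete in a couple of
minutes on one CPU while keeping the binomial checks sensitive.

## Numerical and design choices

* Matching is phrase-level over lowercase alphanumeric tokens — contiguous
  token subsequences, never substrings ("art" does not match "heart") —
  with an optional light plural-folding stemmer, off by default.
* Retrieval order is publication date descending, ties by ascending id: a
  reproducible stand-in for a live engine's undocumented relevance order.
* Degenerate inputs fail loudly where a silent default would bias results:
  empty truth sets (undefined recall), empty assessment lists, unknown
  labels, missing prompt placeholders, and unresolvable oracle ids all
  raise; unparseable backend *content* degrades (UNCERTAIN labels, absent
  field markers, scored-incorrect numerics) so pipelines keep running.
* Split assignment is per review (largest-remainder allocation over a
  seeded shuffle), never per record, to prevent leakage between splits;
  eligibility negatives are drawn uniformly from the candidate pool minus
  the truth set, one per kept positive (1:1 balance within ±1).
* Exclusion-role criteria are phrased in the negated direction so YES
  always means "satisfies the requirement" and the score mean needs no
  sign handling.
* "Partially Yes" is accepted as an alias of the canonical PARTIAL label.
* List-valued extraction fields are scored element-wise, aligned by key
  (arm label, group id, result title) where one exists and by position
  otherwise; truth records drive the totals, so missing predictions count
  as wrong rather than shrinking the denominator.
* Confidence intervals on binned recalls use the normal approximation
  (mean ± 1.96·sd/√n) and are omitted for bins with fewer than ten
  reviews.

## Known limitations

* The in-memory engine approximates, not replicates, live search-engine
  matching (no MeSH expansion, proximity operators, NOT clauses, or date
  syntax) — deliberately, since the queries here use only AND/OR over
  terms.
* The hashed-3-gram embedder is a lexical similarity; it will under-score
  true paraphrases that share no character 3-grams.  For real evaluations
  plug in a semantic embedding backend.
* The oracle's criterion logic is term presence; it cannot emulate graded
  clinical judgement, which is precisely why results on the synthetic
  corpus say nothing about model quality on real reviews.
* The ClinicalTrials.gov adapter maps the common v2 result structures
  (baseline measures, outcome measurements) and ignores rarer modules.
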