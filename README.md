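# litmine

An offline-testable framework for the three labour-intensive stages of a
systematic literature review: **search** (boolean query synthesis),
**screening** (criterion-level eligibility assessment and ranking of
candidate citations), and **data extraction** (structured fields from
clinical-trial publications).  It is aimed at researchers building or
evaluating LLM-assisted evidence-synthesis pipelines: every stage talks to a
pluggable generative backend, and a deterministic *oracle* backend bound to
a synthetic linked corpus makes the whole pipeline verifiable without a
trained model or network access.

## What it implements

**Query synthesis.** For a review with N target studies, per-study keyword
sets P_n (population) and I_n (intervention), each capped at ten terms, are
combined as

```
SP = (AND P_1) OR … OR (AND P_N)
SI = (AND I_1) OR … OR (AND I_N)
S  = SP AND SI
```

Queries are serialized in PubMed syntax (`"term"[tiab]`, upper-case
AND/OR), executed by an in-memory engine (phrase-level token matching,
deterministic date-descending retrieval), and filtered: queries with
retrieval recall below 0.2 on the review's target studies are discarded.
An ensemble mode samples several queries with run-indexed seeds and returns
the deduplicated union of their results.

**Screening.** Each candidate is assessed against every eligibility
criterion (categorised by PICO element); labels YES / PARTIAL / UNCERTAIN /
NO map to scores 1 / 0.5 / 0 / −1, and the final eligibility score is the
mean of criterion scores.  Candidates are ranked by score; quality is
measured as recall@K with K the number of target studies.  Candidate pools
are time-constrained (published before the review) and padded to a target
size with single-PICO-element fill queries.

**Extraction.** Four tasks — study characteristics, arm design,
participant statistics, trial results — with schema validation, lenient
numeric parsing, and a 30,000-token document budget.  Accuracy is exact
match for numeric fields and embedding-cosine soft match (threshold 0.75)
for text fields.

**Instruction building.** The six tasks are compiled into
(instruction, input, output) triples with review-level 6:2:2
train/dev/test splits, balanced eligibility sampling, and a filter that
drops included-study records whose generated analysis aggregates to a
negative score.

## Worked example

```python
from litmine import *
from litmine.backends import OracleBackend
from litmine.boolean_query import retrieve

config = SyntheticConfig(n_reviews=3, included_per_review=4,
                         distractors_per_review=30, overlap_rate=0.2, seed=7)
corpus = generate_corpus(config)
oracle = OracleBackend(corpus)

review = corpus.reviews[0]
truth = corpus.truth(review.review_id)

query = generate_query(review.pico, oracle, review_id=review.review_id)
decision = filter_by_recall(query, corpus, truth)

hits = retrieve(query, corpus, limit=3000)
pool = build_candidate_pool(review, corpus, hits, pool_size=200)
criteria = criteria_from_review(review)
ranked = rank_candidates([assess_study(criteria, corpus.study(s), oracle,
                                       review_id=review.review_id)
                          for s in pool])
```

Output:

```
query: ((("atrial fibrillation"[tiab] AND "mitike"[tiab]) OR ("atrial fibrillation"[tiab] AND "pokozumi ...
search recall: 1.00 (keep=True)
pool size: 89; recall@|truth|: 1.00
arm-design text accuracy: 1.00
```

The query's recall is 1.0 because the oracle answers from the keyword sets
the generator planted verbatim in each target study; the screening recall
of 1.0 means all four target studies outrank every distractor in the pool;
and arm-design accuracy 1.0 is the extraction round trip recovering the
registry ground truth embedded in the pseudo-full-text.  Swapping
`OracleBackend` for `NoisyOracleBackend(corpus, error_rate=0.1, seed=0)` —
or an HTTP backend serving a real model — changes no pipeline code.

A CLI wraps the same functions:

```
litmine gen-corpus --out corpus.json --reviews 10 --included 5 --distractors 50
litmine search-gen --corpus corpus.json --review REV0000 --out hits.csv --ensemble 10
litmine screen --corpus corpus.json --review REV0000 --out ranked.csv --pool 200
litmine extract --corpus corpus.json --study <PMID> --task arm_design --out arms.json
litmine build-instruct --corpus corpus.json --out data/
```

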