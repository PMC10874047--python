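# Methods

This note documents the models, procedures, and design choices behind
`screensieve`, and what the synthetic-data tests do and do not demonstrate.

## Record model and normalization

A record carries a three-valued label: RELEVANT, IRRELEVANT, or NOISY.
NOISY means "present in a reconstructed corpus but never screened" — its
true relevance is unknown. Records without a label tag default to NOISY,
never to IRRELEVANT: assuming unverified records are irrelevant is exactly
the failure mode the noisy-label filter exists to prevent.

Comparison keys for deduplication and presence checks are derived, never
stored: text keys are casefolded, Unicode-punctuation-stripped, and
whitespace-collapsed; DOIs are lowercased with `https://doi.org/` / `doi:`
prefixes removed. These operations are deterministic and
locale-independent, so two runs on the same files always agree.

## Deduplication

Phase 1 merges records sharing an identical non-empty normalized DOI, or
identical non-empty normalized title *and* abstract. Requiring both text
fields avoids over-merging records with generic titles; groups are closed
under chaining (a DOI match and a text match can connect three records),
implemented with union–find. The survivor is the group's first RELEVANT
member, else its earliest member in corpus order; the merged label is
RELEVANT > IRRELEVANT > NOISY over members, so a known inclusion can never
be lost to deduplication. The pass is idempotent and order-stable.

Phase 2 computes normalized edit-distance similarity
(1 − Levenshtein/max-length, via edlib) between normalized titles and flags
pairs at or above a threshold (default 0.9). Nothing is deleted: true
semi-duplicates — translations, follow-up reports, indexing variants — need
a human decision, applied through `apply_review_decisions` with the same
label-merge rule. A length prefilter skips pairs whose title lengths alone
rule the threshold out, keeping the O(n²) scan fast at corpus scale.

## Feature extraction and classifiers

Feature text is title ⊕ abstract; tokens are maximal alphanumeric runs
after casefolding; features are unigram tf-idf with smoothed idf
(ln((1+n)/(1+df)) + 1) and L2-normalized rows, no stop-word removal, no
vocabulary cap. This is the minimal deterministic choice; all knobs live in
`ModelSpec.hyperparameters`.

Four classifiers are supported: multinomial naive Bayes (Lidstone α = 1),
L2 logistic regression (C = 1, lbfgs), a linear SVM (hinge, decision-margin
scores), and a 100-tree random forest (seeded). Class imbalance — a percent
or two of relevant records is typical — is handled by inverse-frequency
sample weights passed to every classifier's fit, one mechanism for all four
(naive Bayes exposes no class-weight parameter, so weighting at the sample
level keeps the treatment uniform). This is deterministic and seed-free,
and may differ from the rebalancing defaults of specific screening tools.

Ranking uses the certainty (maximum) strategy: unlabeled records ordered by
score descending, ties broken by record id ascending, giving a total order
invariant under any positive affine transformation of the scores. The whole
pipeline — features → train → rank — is a pure function of (corpus, labels,
ModelSpec incl. seed).

## Noisy label filter

Training starts from all known-relevant records plus
`n_random_irrelevant_priors` (default 5) seeded-random noisy records
presumed irrelevant. The loop trains, ranks the noisy pool, presents the
top record to the screener, records the label, and retrains (cadence
configurable; default every label, a fixed initial ranking is the
`retrain_every → ∞` limit). Stopping: a run of
`consecutive_irrelevant_stop` (default 50) irrelevant labels — the counter
resets on any relevant label, making it a strict run-length condition — or
an optional `record_budget` (the testable stand-in for a wall-clock limit),
or pool exhaustion. The presumed-irrelevant priors are never screened,
never promoted, and reported separately.

Afterwards `apply_outcome` resolves every noisy label: flagged records go
per-record to keep_relevant / mark_irrelevant / remove; screened-irrelevant
and all unscreened noisy records become IRRELEVANT. Every input record
appears exactly once in the output unless explicitly removed.

## Screening simulation and metrics

The simulator requires a fully labeled corpus (it refuses NOISY labels and
points at the filter). Priors default to one random relevant and one random
irrelevant record, drawn per run from seeded substreams; runs differ only
by seed. Default stop is all-relevant-found, since the metrics only need
recall milestones; full-pool screening is available.

Metrics operate on the trace of non-prior screened records; priors are
excluded from numerator and denominator alike, since they are given, not
discovered. WSS@R uses the milestone ⌈R·ρ⌉ (95 % of 20 relevant = 19
records — integer targets must be reached, not approximated), so
WSS@95 ∈ [−0.05, 0.95]. ERF@f counts the relevant found within the first
⌊f·N⌋ screened records as a proportion of ρ. TD is the 1-based screening
position; ATD averages TD per record across runs, then across records.
Internally all values are proportions; percent formatting (e.g. 82.30)
happens only in the reporting layer. One subtlety: at discrete milestones
the exchangeability expectation of WSS@95 under random screening is
slightly positive — E[i*] = ⌈R·ρ⌉(N+1)/(ρ+1) puts it near +0.04 for
N = 200, ρ = 20 — which the test suite asserts exactly rather than assuming
zero.

## Synthetic corpus generator

The generator emulates the situation the toolkit targets: a heavily
imbalanced reconstructed corpus (defaults: 1050 records, 20 relevant)
whose relevant records share topical vocabulary. Tokens are drawn from a
long-tailed background distribution (rank-frequency ∝ 1/rank, mimicking
real vocabulary skew under tf-idf) or, with probability `signal_strength`
for relevant and planted records, from a disjoint signal vocabulary.
Disjointness makes the null case (s = 0: classes exchangeable by
construction) and the separable limit (s = 1) exact, and signal strength
monotonicity clean. Title/abstract lengths are Poisson (means 10 / 60
tokens — abstracts shorter than real ones, which only shrinks vocabulary
size, not the structure of the ranking problem). Exact duplicates are
verbatim copies under new ids; semi-duplicates get case/punctuation
perturbations, an occasionally dropped title word, a truncated abstract,
and no DOI, so they evade the exact key but stay within edit-similarity
reach. Ground truth records every planted id and duplicate pair.

What passing tests on these corpora show: the loop, stopping rule,
bookkeeping, and metrics behave correctly, the engine recovers a lexical
relevance signal, and the system is calibrated in the null. What they do
not show: performance on real abstracts, where relevant-class vocabulary
overlaps the background, labels carry human noise, and duplicates are
messier — absolute WSS/ERF values on synthetic corpora are far higher than
on real reviews and are not comparable across the boundary.

## Numerical and design choices

* Determinism: every stochastic step derives from an explicit seed through
  `numpy.random.SeedSequence` substreams (named per pipeline stage in the
  CLI, spawned per run in the simulator); the end-to-end pipeline is
  byte-identical across runs at a fixed seed.
* Ties: ranking ties break by record id; dedup survivors by corpus order.
* Degenerate inputs: empty corpora round-trip; all-empty texts yield a
  zero-column feature matrix with a warning; single-class training sets
  raise naming the missing class; traces that stop early because all
  relevant were found are held at full recall beyond their end.
* Count-audit asymmetry: the relative difference uses the *initial*
  (published) count as denominator, so the 5 % rule is phrased against the
  original publication; an initial count of zero with replicated hits is an
  undefined ratio and treated high-risk.
* Retracted inclusions are handled by an explicit exclusion list in the
  presence check rather than silent dropping.
* Problem sizes in the acceptance tests (N = 500–1000, 20 seeds) match the
  generator's default study conditions; the acceptance script runs the full
  pipeline once at the default corpus scale.

## Known limitations

* No author-based disambiguation or reference-manager-specific dedup
  emulation; dedup-method differences are themselves a noise source the
  audit quantifies but does not remove.
* The RIS reader covers the common tag dialect (TY/TI/T1/AB/N2/DO/PY/AU/
  DB/ID/ER plus a configurable label tag); exotic vendor extensions pass
  through as warnings.
* Interactive NLF screening is terminal-only; multi-screener adjudication
  and wall-clock tracking are out of scope.
* Exact reproduction of numbers published for specific screening tools
  would require mirroring those tools' (unstated) feature, balancer, and
  hyperparameter defaults; this package documents its own stack instead.
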