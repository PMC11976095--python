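# Methods

## Problem and pipeline

`molardiff` assesses the surgical difficulty of impacted mandibular
third molar extraction from the free text of CBCT radiology reports.
Four anatomical features determine the assessment: the tooth's
angulation relative to the second molar, the number of roots, the root
curvature, and the relationship of the roots to the mandibular
(inferior alveolar) canal. The pipeline is: text normalization and
segmentation → rule-based concept extraction → ordinal scoring →
four-class difficulty label → a small neural classifier trained on the
extracted features → evaluation against gold labels.

## Scoring model

Each feature category carries an ordinal score (angulation 1–4, root
count 1–3, curvature 1–3, canal relation 1–4); the total
`S ∈ [4, 14]` maps onto D1 (4–6), D2 (7–8), D3 (9–10) and D4 (≥11).
The published class table ends at 13, yet the per-feature maxima sum to
14 (4+3+3+4): a maximally unfavourable tooth — distoangular, three or
more roots, dilacerated, inside the canal — is scorable but falls
outside every printed range. We close the partition by extending D4 to
cover 14 and keep 13 as `printed_hi` metadata on the class. Any total
≥ 11 is unambiguously "very difficult", and the alternative (rejecting
a valid feature vector) would make the classifier's input domain
non-total. `classify_score` enforces the partition exhaustively; an
enumeration of all 144 feature combinations serves as the brute-force
oracle in the tests.

## Lexicon

A *concept* is the set of synonym phrases denoting one category of one
feature. The scales and their scores are fixed; the synonym inventory
is configuration. The shipped default (≥3 synonyms per category, 14
categories) is a clinically plausible stand-in authored for this
package — it is **synthetic**, not a published concept table — and can
be replaced entirely via a YAML/JSON config. Validation enforces:
category coverage, no synonym shared by two categories of a feature,
and the longest-match safety invariant that any phrase contained in
another category's phrase ranks strictly lower (token-count priority),
which guarantees "no contact" can never be consumed as "contact".

## Text processing

Normalization lowercases, folds unicode dashes/quotes to ASCII, strips
control characters and collapses whitespace; it is idempotent.
Sentences split at `.`/`;`/newline with guards for abbreviations
("no.", "e.g.") and decimal numbers; offsets are 0-based half-open into
the normalized text so every sentence slice equals its text. Tokens are
`[a-z0-9]` runs keeping intra-word hyphens; numerals stay tokens
because root counts appear numerically ("3 roots"). The tokenization
*contract* — not any particular NLP engine — is the interface, so the
implementation is a compact deterministic tokenizer conforming to it.

## Extraction rules

Per sentence, all synonym matches are collected at word boundaries and
accepted greedily longest-first; a consumed span blocks shorter
overlapping matches. A mention is negated when one of {no, not,
without, denies} occurs within the three tokens preceding it; a cue
inside the matched phrase itself ("no contact") never negates, which
falls out of longest-match. Per feature and report: negated mentions
are dropped; agreement resolves directly; disagreement across sentences
resolves to the last mentioning sentence, because radiology reports
conventionally end with the impression; two categories of one feature
in a single sentence are surfaced as CONFLICT rather than guessed. A
feature with no surviving mention makes the report INCOMPLETE; such
reports are excluded from scoring and training but logged and counted,
mirroring the exclusion of incomplete reports from the emulated study.
When a report is both incomplete and conflicting, INCOMPLETE takes
precedence (missing information is the stronger failure).

## Classifier

A feed-forward network with four input neurons (each score scaled to
[0, 1] by its feature maximum — bounded inputs stabilize training),
hidden layers (16, 8) with rectifier activations, and a four-way
softmax, trained with Adam (learning rate 0.01, batch 32) on
cross-entropy. The architecture is the smallest standard shape with
multiple hidden layers; the label is a deterministic threshold function
of the feature sum, so capacity is not the constraint. A seeded
stratified fraction (default 0.1) of the training data is held out and
early stopping halts training after 40 epochs without validation
log-loss improvement (tolerance 1e-6), restoring the best weights;
default epoch cap 800. The optimizer is scikit-learn's multilayer
perceptron driven one epoch at a time, which keeps the loss history and
the stopping criterion explicit. All randomness (split, init, batch
shuffling) derives from the config seed; identical inputs and seed give
bitwise-identical predictions. Trained on all 144 enumerated
combinations, the network reproduces the scoring rule exactly (checked
in the acceptance tests across seeds).

## Synthetic corpus

Because the real 738-report corpus is private, the generator emulates
it: 738 reports split 556 train / 182 validation (stratified by class,
falling back to a random split with a warning if a class is too rare),
feature categories drawn independently and uniformly per feature by
default — class prevalence in the real data is unpublished, so uniform
is a declared assumption, configurable to study imbalance. Each feature
is rendered as one sentence from a small template bank with a randomly
chosen synonym; 2–5 distractor sentences (demographics, incidental
findings, written to contain no lexicon phrase) are interleaved at
random positions. Noise:

* `typo_rate` (default 0) — per-token character perturbation (swap,
  drop, duplicate or substitute one character). Tokens inside a synonym
  phrase draw on a budget of **one** corruption per report, so noise
  can break at most one feature's extractability — errors degrade
  gracefully rather than destroying whole reports.
* `omission_rate` (default 0) — per-feature chance the sentence is
  dropped, producing gold-INCOMPLETE reports that the pipeline must
  exclude.

With both rates at zero the generator/extractor round-trip recovers
100% of gold features — a joint contract asserted in the tests. One
seeded generator drives everything, so corpora are byte-identical
across runs with the same config.

What the generator does **not** emulate: real radiologists' prose
style and length, inter-radiologist stylistic variation beyond synonym
choice, true class prevalence, non-English text, and report-level
discourse (hedging, differential phrasing). Passing tests therefore
demonstrate the internal correctness and determinism of the pipeline on
text whose phrasing the lexicon covers; they do not certify extraction
recall on real clinical reports, where the synonym inventory would need
curation against actual usage.

## Evaluation

Confusion matrices use fixed class order D1 < D2 < D3 < D4, rows =
true class. "Total" precision/recall/F1 are unweighted macro averages
over the four classes (micro variants, which collapse to accuracy in
single-label multiclass, are also emitted). Zero-division yields 0, not
NaN. Errors are triaged per report, mutually exclusively, in the order
tokenizer → concept → classification: a *tokenizer error* means the
gold synonym's token sequence is present in the document but
segmentation or intervening punctuation prevented the phrase match; a
*concept error* means extraction resolved a wrong category or missed a
feature the text does mention; a *classification error* means the
feature vector was right and the predicted class wrong. Reports whose
missing features were omitted by construction count as correctly
excluded, not as errors. These operational definitions are this
package's interpretation; the emulated study reports the three
categories without defining them.

## Problem sizes and numerical choices

The acceptance script runs the study-scale experiment (738 reports,
556/182, typo rate 0.01) and resolves the worked single-sentence
examples; the test suite exercises reduced corpora (120–240 reports)
for speed, plus the full 738-report run and the exhaustive
144-combination oracle. At typo rate 0.01 roughly 5–10% of reports lose
one feature phrase and are excluded as incomplete; accuracy on the
processed remainder stays at or near 1.0 because the label is a
deterministic function of the features. Ties in the softmax argmax
break toward the lower (easier) class. Degenerate inputs are rejected
loudly: out-of-range scores, totals outside [4, 14], training sets
under 20 cases or missing a class.

## Known limitations

Negation handling is a fixed three-token window with four cues — no
scope or hedging model. The last-mention tie-break is a convention, not
a learned resolution. The classifier adds no information over the
scoring rule (by design — it replicates the learning stage of the
emulated study); its value is as a template for richer feature sets.
The lexicon's synonym inventory is synthetic and must be re-curated for
deployment on real reports.
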