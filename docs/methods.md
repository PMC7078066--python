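# Methods

This note documents the models and procedures implemented in `afp-triage`,
the parameters that matter, the synthetic data the test suite runs on, and
the design choices made where more than one reasonable option existed.

## Document model

An article is plain text split into title, abstract and body. The
*searchable text* — abstract concatenated with body through a single
newline — is the document the mention thresholds apply to; the title is
searched separately because a single title mention is accepted as a true
positive on its own. This split matters: the toolkit deliberately does
**not** count title mentions toward the in-text threshold, so an entity
titled once and mentioned once in the body of a gene-threshold-2 paper is
included via the title rule, not via an inflated text count. Articles with
no non-whitespace abstract or body (e.g. failed text conversion) are legal
inputs; they are loaded, flagged, and discarded by the batch pipeline
before extraction. All strings are normalized to Unicode NFC on load so
typographic variants from text conversion cannot break name matching.

## Entity matching

Matching is dictionary-based: each lexicon entry carries a canonical
identifier and its surface forms (primary name plus synonyms, e.g. a
gene's sequence name). A candidate hit is accepted only if it is not
immediately preceded or followed by a letter, digit or hyphen. The hyphen
is part of the blocking class because nematode gene symbols contain
internal hyphens: `lin-3` inside `lin-39` is blocked by the digit rule,
and hyphen blocking additionally rejects `pre-lin-3`-style compounds.
Scanning is left-to-right and non-overlapping: at each position the
longest matching form wins, and the scan resumes after its end, so one
span of text contributes at most one mention per lexicon entry (different
entries may still match overlapping spans — counts are per entry).

Special rules:

* **Protein case (genes only).** Each gene form also matches in
  all-uppercase (`lin-3` → `LIN-3`), following community nomenclature for
  protein products. Sequence-name synonyms are unaffected (uppercasing
  them is a no-op). Configurable off.
* **Species.** A species entry's primary name must be a binomial. It
  matches written in full (`Drosophila melanogaster`) or genus-abbreviated
  (`D. melanogaster`), case-sensitively — a lowercase `d. melanogaster` is
  treated as a conversion artifact, not a mention. A small editable alias
  table (human/humans, mouse/mice, rat/rats, zebrafish, fruitfly/
  fruitflies, yeast) adds case-insensitive common-name matching for
  selected species; the table is configuration, not ground truth, and can
  be overridden per canonical id in the rule set.
* **Inclusion.** Entity type *t* is reported when its searchable-text
  count reaches the threshold (gene 2, allele 2, strain 1, transgene 1,
  species 10) or when it has ≥1 title mention. The species threshold is
  an order of magnitude higher because species names are routinely
  mentioned in passing (orthology arguments, antibody hosts) without
  being the subject of study. The title override applies to all five
  types and can be disabled.

The extraction result keeps two views: `included` (entries passing the
rule) and `all_counts` (every nonzero count), the latter for diagnostics
and curator review. Both are sorted by canonical id for deterministic
output.

## Data-type classifiers

Each of the eight automatically triaged data types gets an independent
binary classifier: an L2-regularized hinge-loss (max-margin) linear model
over bag-of-words features of title+abstract+body. Tokens are lowercased
and split on non-alphanumerics except internal hyphens, so gene symbols
survive as single features. Defaults, all overridable per training call:

* vocabulary minimum document frequency 2 (curbs hapax noise features);
* tf-idf weighting with smoothed idf, ln((1+n)/(1+df)) + 1, and L2
  document normalization; a raw-counts scheme is available;
* inverse regularization C = 1.0;
* decision threshold at margin 0 with ties negative — the downstream
  consumer is a pre-checked checkbox, so no probability calibration is
  attempted.

The fit is delegated to liblinear (scikit-learn's `LinearSVC`) with a
fixed random state; the fitted model is then self-contained — vocabulary,
weight vector, bias and idf serialize to portable JSON, and prediction
uses only that file. Training is deterministic: the same corpus and seed
produce a byte-identical model file. Papers negative for all eight labels
still yield a complete flag record; a missing model is an error, never a
silent skip.

## Batch triage

A run consumes the queue in lexicographic paper-id order (production
ordering is not specified anywhere authoritative; lexicographic makes
batches reproducible), capped at 50 papers per run — discarded papers
count toward the cap, since the cap models per-run examination effort.
Empty-text papers are discarded before extraction; papers whose gene,
allele, strain and transgene included lists are all empty are discarded
after it (species alone do not make a paper curatable). For each surviving
paper the corresponding author is the first email address, scanning left
to right with an RFC-lite pattern
(`local@domain.tld`, case-insensitive), whose lower-cased form is in the
person registry; unresolvable authors leave the paper processed but
flagged. Notifications carry a 32-hex-character token drawn from a seeded
generator and collision-checked against the state store.

Reminders: "after 1 and 2 months" is implemented as ≥30 and ≥60 days
since notification — calendar-month arithmetic is ambiguous and fixed-day
intervals are testable — with at most two reminders ever, and none once a
submission is complete. The pipeline emits notification and reminder
records; actual email delivery is an integration concern and out of
scope.

The state store (processed ids + notification records, JSON) makes runs
idempotent: an already-processed paper id is never re-consumed or
re-notified. "Refused" is implemented as skip-on-requeue rather than an
exception so that a re-queued file cannot crash a weekly run.

## Agreement analytics

* **Jaccard** |A∩B|/|A∪B| between machine-extracted and author-final
  entity sets, per type. Both-empty is defined as 1.0 (perfect agreement
  that nothing is present); the case cannot arise from the pipeline
  itself, which discards entity-free papers upstream, but the convention
  keeps the metric total.
* **Diffs**: added = final ∖ extracted, removed = extracted ∖ final;
  means of |added|, |removed| and Jaccard are reported per type across
  submissions.
* **Flag agreement**: confusion counts and accuracy = (TP+TN)/n,
  precision = TP/(TP+FP), recall = TP/(TP+FN), computed per flag
  independently (matching a one-row-per-type report layout). Zero
  denominators yield an explicit undefined marker (`None`), never 0, and
  are excluded from averages.
* **Dashboard statistics**: papers processed/discarded, complete and
  partial submissions, response rate = complete submissions / papers for
  which an email was sent (discarded papers are excluded from the
  denominator), per-type entity-count histograms, and mean genes per
  non-empty submission.

Submissions deliberately do not validate entity ids against the lexicons:
authors may contribute novel names. Manual data types (gene model update,
new antibody, site/time of action, RNA-seq, chemical/environmental
phenotype, enzymatic activity, human disease model) and manual entity
categories (new alleles/strains/transgenes, other antibodies) are carried
as free annotations.

## Synthetic fixtures

The generator is the test bed for everything above. An article spec
plants chosen surface forms exact numbers of times in title and body,
interleaved with distractor tokens drawn from a fixed word list shipped
with the package, inserts data-type signal keywords at controlled counts,
and places email addresses in a controlled order. Exactness is enforced,
not hoped for: generation fails upfront unless no planted form (including
synonyms, protein-case variants, abbreviated binomials and aliases) is a
substring of any other planted form, distractor or signal keyword.
Planted names follow community nomenclature shapes (gene
`[a-z]{3}-[0-9]+` with a sequence-name synonym, allele
`[a-z]{1,3}[0-9]+`, strain `[A-Z]{2}[0-9]+`, transgene
`[a-z]{2}(Is|Ex)[0-9]+`, real binomials for species), so the boundary
rules are exercised on realistic inputs. All generators are deterministic
per seed, byte-for-byte.

Labeled corpora for classifier tests put label-specific keywords into
positives with a configurable per-slot probability (4 slots per document,
60 distractor tokens; 200 documents per class in the standard runs) and
never into negatives. Simulated author submissions apply independent
errors to a machine extraction: each included entity removed with
probability `removal_prob`, each unextracted lexicon entry added with
`addition_prob`, each flag flipped with `flag_flip_prob`; the exact edit
record is returned so the agreement metrics can be checked against
binomial expectations.

What the fixtures do *not* emulate: real scientific prose (distractors
are i.i.d. words, so classifier accuracy here is an upper bound — real
corpora have correlated vocabulary and much subtler signals), PDF
conversion noise, ambiguous nomenclature (e.g. an allele name that is
also an SI unit), and author behavior beyond independent error rates
(real authors remove reagent genes systematically, not at random).
Passing tests therefore demonstrate correctness of the machinery — exact
counting, rule application, metric arithmetic, determinism — not expected
field performance on live literature.

## Numerical and scale choices

Standard runs use sizes that keep the full suite under ~10 s and the
acceptance script under ~10 s on one CPU: lexicons of 8 entries per type
(4 species), articles of 60–120 distractor tokens, 200 documents per
class for classifier evaluation (5 seeds for the signal condition), 1000
ten-entity papers for error-model recovery, and a 220-paper queue drained
in capped batches for the end-to-end study. Stochastic checks use 3
standard-error bands around analytic or Monte-Carlo expectations. Model
serialization round-trips exactly (JSON float repr); classifier
determinism is asserted at the byte level.

## Known limitations

* Dictionary matching cannot find entities absent from the lexicons;
  novel names arrive only through author submissions.
* No fuzzy matching, abbreviation expansion (beyond the species rules) or
  coreference; a paper that only ever says "the lin-3 mutant allele"
  without naming it will miss the allele.
* The classifiers are linear over unigrams; data types expressed mostly
  through phrasing (regulatory interactions, for instance) are hard for
  this model class regardless of training size.
* Thresholds are global per type, not per paper length; very long papers
  mention more entities in passing and will accrue more false positives.
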