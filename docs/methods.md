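# Methods

This note documents the models, numerical choices and open design
decisions behind veristyle, and what the synthetic test-bed does and does
not establish about real data.

## The style vector

The 26 features operationalize four psychological accounts of deception.
Cognitive Load predicts that fabrication yields shorter, simpler, less
elaborate statements, measured by sentence/word/syllable counts and the
Flesch formulas (reading ease `fk_read = 206.835 − 1.015·W/S − 84.6·Y/W`,
grade `fk_grade = 0.39·W/S + 11.8·Y/W − 15.59`). Distancing predicts liars
use fewer self-references and more other-references, measured as summed
pronoun-category percentages. Reality Monitoring predicts experienced
events carry more perceptual/contextual/affective detail and fewer
cognitive-operation words; its composite is
`Perceptual + Contextual + Affect − Cognition`, complemented by the mean
concreteness of content words. The Verifiability account predicts truthful
statements contain more checkable details, measured as unique named-entity
counts about people, times, places and quantities.

### Tokenization and sentence segmentation

All word counting uses one deterministic tokenizer: whitespace split,
leading/trailing punctuation separated into their own tokens, internal
characters kept attached (clitic apostrophes — "it's" is one word — and
internal symbols like "2:30"), numerals counted as words, and a word token
defined as containing at least one alphanumeric character. Sentences split
on terminal `.!?` followed by whitespace and an uppercase letter, with a
small abbreviation stop-list (`Mr.`, `e.g.`, …). Industrial NLP tokenizers
differ from these rules in edge cases; the package accepts that difference
in exchange for full reproducibility without a model dependency. An
external NER plugin may tokenize however it likes; package-level counts
never depend on it.

### Syllables

Syllables are counted by a vowel-group heuristic: runs of `aeiouy`, minus
a silent terminal `e` when it is not the word's only vowel group, minimum
one per word. This is the standard dictionary-free approximation; no claim
of exactness against pronunciation lexicons is made, and the Flesch values
inherit its error. Within one corpus the heuristic is applied uniformly,
so *group contrasts* in the syllable-based features are meaningful even
where absolute values drift.

### Lexicon scoring

A category score is `100 × matching word tokens / word tokens`,
case-insensitive, with trailing-asterisk entries matched as prefixes
(`run*` matches `running`, not `ran`); one token may feed several
categories. The reference dictionary used in the deception literature
(LIWC-22) is proprietary, so the package is dictionary-agnostic: it reads
any `.dic`-format lexicon and ships a small open fixture covering the 28
required categories for testing. **Feature values are comparable to
published LIWC-based numbers only when an equivalent dictionary is
supplied.**

### Summary scales

The three 0–100 scales are open approximations of proprietary composites,
clamped to [0, 100]:

* `Analytic` — the published categorical-dynamic index,
  `30 + article + prep − ppron − ipron − auxverb − conj − adverb − negate`.
* `Authentic` — an analogous composite in the spirit of the deception-
  language factor literature: `30 + i + we + Cognition − tone_neg − motion`
  (rewarding self-reference and cognitive elaboration, penalizing negative
  tone and motion framing).
* `Tone` — only a "standardized difference in [0, 100]" is specified in
  the literature, so the bounded ratio
  `50·(1 + (tone_pos − tone_neg)/(tone_pos + tone_neg))` is used: it is
  symmetric, maps equality (and the no-tone-words case) to 50, and
  respects the printed range.

### Concreteness

Lowercase → tokenize → drop stopwords and punctuation → lemmatize
(pluggable; identity by default, or any word→lemma mapping) → look up in a
word→score table in the [1, 5] convention of the published concreteness
norms. Unmatched words are *excluded* from the mean, not scored zero; a
statement with no matches carries an undefined (NaN) score, propagated as
missing through the statistics stage and dropped pairwise per feature.

### Named entities

Entity counts are unique normalized surfaces (case-folded,
whitespace-collapsed) per category and statement; the same surface in two
categories counts once in each. Recognizer labels map as: person → People;
date/time → Temporal; locations/facilities → Spatial;
percent/money/quantity/ordinal/cardinal → Quantity; anything else is
ignored. The mapping covers all the exemplar types the deception
literature lists for verifiable numeric detail ("20%", "5 $", "first",
"ten", "100 m"). The built-in recognizer is a deterministic gazetteer +
regex stub meant for testing and for the synthetic corpora; real analyses
should plug in a trained NER model via the one-callable protocol.

## Statistics

Both designs use the mean difference as the test statistic and Monte-Carlo
resampling with the add-one convention
`p = (1 + #{|T*| ≥ |T_obs|}) / (1 + n_permutations)`, so p-values are never
zero and the test is valid at finite n. The independent design permutes
pooled group assignments (memory/intention-style corpora); the paired
design first averages each subject's truthful and deceptive statements —
which cancels topic and stance effects in the opinion design — then flips
within-pair signs. Two-sided tests are used throughout, since effects in
both directions are substantively interpretable and reported. The default
`n_permutations = 10,000` follows the field convention; note that Holm
correction across m = 26 features needs `n_permutations ≥ m/α − 1` (519 at
α = 0.05) before a Monte-Carlo p can survive correction at all.

Holm–Bonferroni is applied within one family = the 26 features of one
dataset/design (and, in the explainability stage, within each
fold-contrast). CLES uses 0.5 tie weighting so identical groups score
exactly the 0.5 null, with a seeded percentile bootstrap CI (2,000
resamples by default; the CI construction used in the source literature is
unstated, so this choice is documented and swappable, and can be disabled
for large calibration sweeps). Cohen's *d* uses the pooled sample sd with
the normal-approximation CI variance `(n1+n2)/(n1·n2) + d²/(2(n1+n2))`.
Constant features return p = 1, CLES 0.5, d 0, direction `none`. One
master seed drives everything; per-feature generator streams are derived
from a CRC-32 of the feature name so adding or removing a feature never
perturbs the others.

## Evaluation harness

Folds are seeded shuffles of statements — or of subjects when grouping is
on — dealt into k near-equal partitions (first `n mod k` partitions take
the extra unit). Opinion-style corpora are always split by subject, since
five statements per author would otherwise leak authorial style across the
train/test boundary; for other corpora grouping defaults to on whenever
subject ids are informative. Splits are cached so every classifier sees
identical partitions within S1 and S3. The positive class is `truthful`;
per-fold confusion matrices `[[TP, FN], [FP, TN]]` are averaged
elementwise with their sample sd across folds.

Classifier adapters return one string per test text, parsed
case-insensitively with surrounding punctuation stripped; unparseable
outputs are tallied, logged and scored as a misclassification of the true
class — a deterministic rule that also keeps the confusion-quadrant
partition of every test set exact. The bag-of-words baseline uses
train-only vocabulary (out-of-vocabulary test tokens are ignored by
construction), default 5,000 count features and an L2 logistic classifier
at C = 1 — deliberately plain, configurable, and documented because no
standard values exist for this baseline. A fine-tuned text-to-text model
plugs into the same adapter contract; no training loop ships with the
package.

## Explainability

Quadrant contrasts (FN vs FP, TN vs FN, TP vs FP, TP vs TN) run the
independent-design machinery per fold with Holm within each fold-contrast;
CLES > 0.5 always reads "higher in the first-listed group". Contrasts with
a quadrant below two statements are skipped and logged (the behaviour of
tiny quadrants is otherwise undefined). Cross-fold aggregation counts the
folds in which each feature survived correction and takes arithmetic means
of the per-fold CLES/d points *and of their CI bounds* — the averaging
rule used in the source procedure; averaged CI bounds have no strict
coverage interpretation and are reported as descriptive summaries only.
Features never tested in any fold are omitted rather than zero-filled.

## Synthetic corpora

Statements are template-assembled word sequences from a neutral pool
(asserted inert against the lexicon, concreteness table and gazetteers),
with controlled injections: category carrier words chosen to match *only*
the target feature's categories (an injection rate of δ/100 in one class
shifts that percentage feature by exactly δ points in expectation); normal
length draws floored at six words (δ/2 per class for planted length
shifts); unique entity mentions from per-domain pools (Poisson baseline
rate 0.8 per category, class-asymmetric extra rate for planted count
shifts); and a high/low concreteness-pool mixture whose mixing fraction
sets the expected concreteness score. Per-statement injection
probabilities are rescaled for entity-occupied slots so expected planted
shifts are exact. A symmetric "background" draw from the whole lexicon
(rate 0.25) gives every category natural variation — without it,
rare-category features would be near-constant and their permutation tests
degenerate — and planted carrier words are excluded from it so they reach
a class only through their planted channel.

Opinion-like subjects contribute five statements (three truthful / two
deceptive or the reverse, alternating by subject), other domains one
statement per subject with alternating labels, keeping classes exactly
balanced. Class-marker words give classifiers a learnable signal, either
shared across domains or strictly domain-specific; the domain-specific
construction is what reproduces the within-domain-learnable /
cross-domain-chance scenario pattern. The generator publishes its full
recipe as a `GroundTruth` — expected shifts, carrier pools, marker words,
and the set of features *incidentally* contaminated (carrier words
touching parent categories such as `ppron`, plus the syllable/readability
block whenever any class-asymmetric word choice exists) — so recovery
tests read the recipe rather than reverse-engineering the generator.

Default sizes (120 subjects per domain, length 55 ± 20 words, ≥ 6-word
floor) mirror the short-statement deception corpora at reduced scale so
full pipelines run in seconds. Calibration and power studies in the
acceptance suite use 40 statements per class over 2,000 null replicates
and 200 per class over 25 planted replicates respectively, with 999
permutations per test — sizes chosen to give the Monte-Carlo estimates
useful resolution at interactive runtimes.

**What passing synthetic tests do and do not show.** They show the
pipeline's statistical machinery is correct: calibrated type-I error,
power against known effects, exact split hygiene, and classifier behaviour
under known signal structure. They do not show anything about real
deceptive language: the texts are not fluent prose, carry no semantics or
discourse structure, and their class signals are lexical by construction —
so a sequence-model adapter can be exercised but not meaningfully
evaluated on them, and effect sizes on real corpora depend on the supplied
dictionary and recognizer.

## Known limitations

* `Analytic`/`Authentic` are documented approximations; absolute values
  are not comparable to proprietary-software output.
* The fixture lexicon is test-scale (a few hundred entries); scientific
  use requires a real dictionary in `.dic` format.
* The gazetteer NER stub recognizes only its word lists and numeric
  patterns; multi-word entities beyond "number + unit" merges are out of
  its reach.
* Averaged CI bounds in the explainability aggregation are descriptive,
  not inferential.
* Loader profiles for the public corpora match the deposited column
  layouts but statement-count discrepancies against published totals are
  reported, not corrected; row filters are available in the loader for
  documented exclusions.
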