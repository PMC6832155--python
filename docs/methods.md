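# Methods

This note records the modelling choices behind `syncope_nlp`, the
parameters that matter, and what the synthetic benchmark can and cannot
demonstrate.

## Data model

The classification unit is the ED *record*, not the patient encounter:
one record carries a single ICD-9-CM code, three free-text channels
(triage note, medical-history note, discharge diagnosis), age, and an
optional tri-state gold label. Encounters may span several records; an
encounter-level OR-aggregation helper exists (`aggregate_encounters`) but
nothing in the pipeline uses it, because all performance accounting is
per record. Eligibility filtering keeps records with age ≥ 18 and at
least one non-empty text channel; the two removal reasons (underage,
incomplete) partition the removed set, age being tested first.

## Text normalisation and stemming

The normalisation rules are fixed here because the upstream cleaning
procedure is underspecified in general: lower-casing, punctuation mapped
to spaces, digits kept as tokens (vital signs like "120/80" become "120
80"), accented Italian letters preserved, whitespace collapsed.
Normalisation is idempotent and never yields empty tokens.

Unigrams are stemmed with the Snowball algorithm for Italian, implemented
in `stemming.py` directly from the published algorithm (accent
normalisation, R1/R2/RV regions, attached-pronoun removal, standard and
verb suffix stripping, vowel deletion). Bigrams and trigrams are matched
on raw tokens: stemming exists to merge inflection variants of single
clinical words, and the multiword phrases of interest ("perdita di
coscienza") are stable word-for-word. Two behaviours worth knowing:

- The stemmer is aggressive on deverbal nouns: *caduta* → `cad`,
  *svenimento* → `sven`. This is the algorithm working as designed, and
  it is exactly what merges *caduta*/*cadute*.
- The algorithm is not idempotent on every output: `capogir` (from
  *capogiro*) ends in the verb suffix "ir" and loses it on a second
  pass. Stems are therefore computed exactly once, from raw tokens.

Because no stemming library for Italian is available in the supported
dependency set, the implementation is first-class code here, tested
against hand-traced expected stems for the clinical lexicon plus
algebraic properties.

## Term selection

Document frequency is presence-based per record-field (a term repeated
five times in one note counts once), matching the binary feature model.
The frequency band [min_df, max_df] is expressed in proportions and is a
tunable hyper-parameter (defaults min_df ∈ {0.001, 0.005, 0.01}, max_df ∈
{0.5, 0.9} in the default search grids): rare terms have no statistical
support, ubiquitous terms no discriminative value.

The four selection statistics (GI, NGI, IG, χ²) are computed from the
2×2 presence-by-class table exactly as defined in the README. All four
are symmetric under swapping the class labels — a deliberate property of
the scalar statistics, preserved and tested. Symmetry, however, is wrong
for *ranking* in a rare-event problem: at 2% prevalence many background
terms happen to miss the small positive class entirely and would score a
perfect purity of 1.0 ("absent from positives" is as pure as "exclusive
to positives"). Ranked tables therefore restrict candidates to terms
positively associated with the event, P(w|pos) > P(w|neg); this is what
lets the GI ranking of ICD-9 codes surface 780.2 rather than a benign
code that is merely absent among positives. The tie-break is
deterministic: score descending, then document frequency descending,
then lexicographic.

A known limitation of the plain GI definition: it is dominated by the
class prior, so at 2% prevalence a class-neutral term scores ≈ 0.96
while a strong-but-imperfect positive marker scores lower (780.2 scores
≈ 0.86 at full scale). Even among positively-associated candidates GI
can therefore prefer noise-associated neutral terms. This is precisely
the pathology that the normalised variant (NGI) removes, and NGI is the
selector the pipeline favours; GI remains available for comparison and
for the ICD channel mechanics.

The manual "HuMan" lexicon is matched in any of the three text channels
(clinicians curated the terms, not their field of occurrence); automatic
selection is per-field, because per-field term counts are part of the
hyper-parameter space. Per-field counts use one shared k per n-gram
order (rather than three independent per-field counts) to keep the
search space tractable; the `select_features` operation accepts fully
per-(field, order) counts for callers that want them.

## Classifiers

Both classifiers delegate optimisation to scikit-learn; the contract
(loss, smoothing, weighting, determinism under seed) is what the tests
pin down.

- `UndersampledBernoulliNB`: all positives are kept and negatives are
  subsampled to `ratio` per positive (uniformly, reproducibly under the
  seed) before fitting a Bernoulli NB with additive smoothing α. With
  ratio → ∞ the fit equals the full-data fit. Prediction uses both
  presence and absence likelihoods. Grid defaults: ratio ∈ {1, 3, 10,
  off}, α ∈ {0.1, 1}.
- `WeightedLinearSVC`: hinge-loss linear separator with positive-class
  weight w (grid {1, 5, 10, 25, 50, balanced}) and inverse
  regularisation C ∈ {0.1, 1, 10}. Raising w monotonically favours
  sensitivity on a fixed training set (tested as a trend).

Undersampling happens strictly inside the training split of whatever
loop is running — never on evaluation data — since resampled test data
would fabricate precision. Additional families (decision trees, MLPs)
can be plugged in through `register_classifier` but are not part of the
evaluated set, which retains the two families above.

`TrainedModel` serialises NB log-probabilities or the SVM weight vector
to versioned JSON; prediction from a deserialised model uses only the
stored parameters, so archived models are portable.

## Nested cross-validation

Outer loop: stratified k = 5 folds (stratification is essential — an
unstratified 2%-prevalence fold can easily contain no positives),
repeated R times with reshuffled folds (default R = 4, giving 20
outer-fold F3 scores per algorithm for the Welch comparison). Inner
loop: the k−1 training folds are split into 4 stratified inner folds;
every grid point (vectorizer × classifier parameters) is scored by mean
inner-validation F3; the best point (first wins ties, in deterministic
grid order) is refit on the full outer-training split and scored once on
the held-out fold. Feature selection runs inside inner-training data
only. Every fold asserts that the record ids seen during
selection/training are disjoint from the outer test fold; a violation
raises rather than warns.

Fold-level metrics are aggregated as unweighted means (not pooled
confusion counts), so the aggregate F3 is the mean of per-fold F3
values. When a fold's classifier predicts no positives, PPV is
undefined and F3 is 0 by continuity; undefined values are reported as
explicit `None` markers, never silently coerced.

The Welch comparison is an unpaired two-sided unequal-variance t-test
with Welch–Satterthwaite degrees of freedom and a 95% CI on mean(a) −
mean(b); the sign convention of the interval always matches the reported
mean difference. The fold structure would permit a paired test, which
would be more powerful; the unpaired form is kept as the method of
record.

## Synthetic corpus generator

`default_paper_config()` encodes the study-scale conditions: 30,320
records, prevalence 0.019, ten planted discriminative Italian terms
(class-conditional inclusion 0.6 in positives, 0.01 in negatives,
distributed over the three channels), three equal-rate confounders,
background fields of Poisson(12) pseudo-word tokens from a
500-strong vocabulary, ICD-9 sensitivity 0.6 / specificity 0.999, seed
20131201. Field length and vocabulary size were chosen once as
realistic for terse ED notes (one to two sentences per channel);
planted inclusion rates make a planted term informative but far from
deterministic; the ICD rates encode the documented insensitivity of
code-only retrieval without asserting any published figure.

Background tokens are pronounceable three-syllable compounds, checked to
never collide (even after stemming) with the planted vocabulary, so
ground truth stays exact. Planted terms reuse genuine Italian clinical
vocabulary so that stemming is exercised on real inflections; with
`inflection_rate` > 0 a planted unigram appears as its number/gender
variant (*caduta* → *cadute*), each variant pair verified to share a
stem. Generation is vectorised and byte-identical under a fixed config.

What the synthetic benchmark shows: the selection statistics recover
planted signal, the nested CV is leak-free and its inner loop tracks the
amount of planted signal, stemming measurably helps under inflection
noise, and the full pipeline reaches high F3 when a strong signal
exists. What it does not show: performance on real clinical prose. Real
notes have correlated vocabulary, negations, misspellings and
institution-specific jargon, none of which the generator models — and
the manual lexicon coincides with the planted vocabulary, so the
manual-vs-automatic gap observed on real data does not reproduce here.
Published headline numbers (92.2% sensitivity at 47.4% PPV) depend on
private EMRs and are out of reach by construction; the package instead
reproduces their arithmetic identities exactly (F3 from the published
operating points, mean differences, workload).

## Numerical and scale choices

- Scoring kernels are shared between the scalar statistics and the
  vectorised ranking path, so a table row and a single lookup cannot
  disagree; non-finite kernel outputs in ranking are treated as score 0.
- Entropies use base-2 logs with 0·log 0 := 0.
- χ² uses no continuity correction and requires all four margins ≥ 1.
- Default test and acceptance runs use corpora of 1,200–5,000 records
  with reduced hyper-parameter grids (e.g. 8 grid points rather than the
  full 216-point default product); these sizes already separate signal
  from noise cleanly at the configured effect sizes, and the large-n
  law-of-large-numbers checks use 50,000–100,000 records with text
  generation only where needed.
- Seeds: every stochastic component (generator, undersampling, fold
  shuffling, SVM) takes an explicit seed; repeat r of the outer CV uses
  `seed + 7919·r` (mod 2³¹) so repeats differ but reproduce.

## Known limitations

- The Snowball implementation follows the published algorithm but has no
  reference implementation available in this dependency set to diff
  against exhaustively; its oracle is the hand-traced lexicon plus
  property tests.
- GI's prior domination (above) means `icd_selector="gi"` with one code
  can pick a noise code at very low prevalence; NGI-based pipelines are
  robust to this because the text features carry the signal.
- The generator plants terms independently per record; it does not model
  term co-occurrence, negation ("nega perdita di coscienza"), or
  encounter-level duplication of text across records.
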