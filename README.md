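# syncope-nlp

Automatic identification of syncope encounters in Emergency Department
(ED) electronic medical records (EMRs) from Italian free text.

Syncope — transient loss of consciousness from cerebral hypoperfusion — is
recorded in roughly 2% of ED visits, and retrieving those encounters from
administrative data by ICD-9-CM code alone (780.2, "syncope and collapse")
misses many cases. Assembling the large cohorts needed for risk
stratification therefore requires manual chart review at a cost of
hundreds of person-days. This package implements an NLP phenotyping
pipeline that classifies each ED record as syncope-positive or negative
from its three free-text channels (triage note, medical-history note,
discharge diagnosis) plus the ICD-9 code, and quantifies how much chart
review the classifier saves. It is aimed at clinical-informatics
researchers building rare-event cohorts from EMR repositories.

## Method

1. **Preprocessing.** Free text is lower-cased, punctuation is stripped,
   tokens are extracted, and unigrams are stemmed with the Snowball
   algorithm for Italian (implemented in-package) so inflection variants
   such as *caduta*/*cadute* collapse. Unigrams, bigrams and trigrams are
   counted per record-field with presence semantics, and candidates are
   kept inside a tunable document-frequency band [min_df, max_df].

2. **Term selection.** Either a fixed expert lexicon ("HuMan": 16 stemmed
   unigrams, *crisi epilettica*, *ferita lacero contusa*, *perdita di
   coscienza*, and the ICD-9 code 780.2), or a ranking of candidates by
   one of four statistics on the 2×2 presence-by-class table of each term
   w — with A positives containing w out of n⁺ and B negatives out of n⁻:

   - Gini Index: GI(w) = Σ_c P(c|w)²
   - Normalized Gini Index: NGI(w) = q² + (1−q)², where
     q = r⁺/(r⁺+r⁻) and r^c = P(w|c), which cancels the class prior —
     the decisive property at 2% prevalence
   - Information Gain: IG(w) = H(C) − [P(w)H(C|w) + P(w̄)H(C|w̄)] (bits)
   - Chi-squared: χ²(w) = N(AD−BC)² / [(A+B)(C+D)(A+C)(B+D)]

   The top-k terms per field and n-gram order become binary presence
   features (`TermSelectionVectorizer`, a scikit-learn transformer).

3. **Classification.** Two imbalance-aware scikit-learn-style estimators:
   Bernoulli Naive Bayes trained after undersampling negatives to a fixed
   ratio per positive (`UndersampledBernoulliNB`), and a linear SVM with
   an elevated positive-class weight (`WeightedLinearSVC`).

4. **Evaluation.** The working metric is F3 = 10·PPV·Sens/(9·PPV+Sens),
   weighting sensitivity nine-fold over precision: missing a syncope
   case costs more than reviewing a false positive. Hyper-parameters
   (term counts, frequency band, undersampling ratio, class weight) are
   tuned to maximise mean inner-fold F3 inside a stratified five-fold
   nested cross-validation with a per-fold leakage audit; algorithms are
   compared with Welch's two-sample t-test on per-fold F3 scores;
   annotation quality is checked with Cohen's kappa; and
   `workload_estimate` converts the flagged fraction into person-days of
   chart review.

5. **Synthetic corpora.** Because real EMRs cannot be shipped, a seeded
   generator (`syncope_nlp.synthetic_data`) emulates the study
   conditions: 30,320 records at 1.9% prevalence, ten planted
   discriminative Italian terms, background pseudo-word vocabulary,
   optional inflection noise, and an ICD-9 channel with 60% sensitivity.

## Worked example

```python
from dataclasses import replace
from syncope_nlp import (
    Algorithm, default_paper_config, generate_corpus,
    nested_cross_validate, compare_algorithms, workload_estimate,
)
from syncope_nlp.evaluation import report_table

cfg = replace(default_paper_config(seed=20131201), n_records=5_000)
corpus, truth = generate_corpus(cfg)

algorithms = [
    Algorithm("NB-HuMan", "human", "nb_bernoulli", {},
              {"ratio": [3.0, 10.0, None], "alpha": [1.0]}),
    Algorithm("SVM-NGI", "ngi", "svm_linear",
              {"n_unigrams": [10, 20], "min_df": [0.001, 0.01]},
              {"pos_weight": [5.0, 25.0], "C": [1.0]}),
]
reports = nested_cross_validate(corpus, algorithms, k=5, repeats=2, seed=1)
print(report_table(list(reports.values())))

res = compare_algorithms(reports["SVM-NGI"].f3_scores, reports["NB-HuMan"].f3_scores)
print(f"mean F3 difference {100*res.mean_difference:.1f} points, "
      f"t = {res.t_statistic:.2f}, df = {res.df:.1f}, p = {res.p_value:.2g}")

flagged = sum(f.confusion.tp + f.confusion.fp for f in reports["SVM-NGI"].folds)
total = sum(f.n_test for f in reports["SVM-NGI"].folds)
effort = workload_estimate(len(corpus), 221.0, flagged / total)
print(f"flagged {100*effort.flagged_fraction:.1f}% of records -> "
      f"{effort.review_days:.1f} person-days ({100*effort.reduction:.0f}% saved)")
```

Output:

```
Algorithm	Accuracy	Sensitivity	PPV	F3	NPV	Specificity
NB-HuMan	100.0	99.0	99.0	99.0	100.0	100.0
SVM-NGI	99.9	97.9	99.0	98.0	100.0	100.0

mean F3 difference -1.0 points, t = -0.99, df = 17.3, p = 0.33
flagged 1.9% of records -> 4.2 person-days (98% saved)
```

The table lists per-algorithm means over the 10 outer folds (percent).
Both pipelines recover the planted signal almost perfectly — on synthetic
corpora the manual lexicon coincides with the planted vocabulary, so the
two selectors converge (see `docs/methods.md` for what the synthetic
benchmark does and does not show). The Welch comparison finds no
significant difference here, and the workload model translates the 1.9%
flagged fraction into 4.2 of 221 person-days of review.

The same pipeline is scriptable from a shell:

```
syncope-nlp simulate --n 5000 --seed 7 --out corpus.csv
syncope-nlp ncv --input corpus.csv --algorithms NB-HuMan --out-dir results/
syncope-nlp workload --total-days 221 --fraction 0.04
```

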