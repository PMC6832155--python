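import math
from dataclasses import replace

import numpy as np
import pytest

from syncope_nlp.evaluation import (
    Algorithm,
    ConfusionCounts,
    cohen_kappa,
    compare_algorithms,
    confusion,
    fbeta,
    holdout_evaluate,
    mean_difference,
    metrics,
    nested_cross_validate,
    report_table,
    workload_estimate,
)
from syncope_nlp.feature_selection import TermSelectionVectorizer
from syncope_nlp.synthetic_data import default_paper_config, generate_corpus
from syncope_nlp._index import PreprocessedCorpus


def test_confusion_tally():
    y = [1, 1, 1, 0, 0, 0, 0, 1, 0, 0]
    p = [1, 0, 1, 0, 1, 0, 0, 1, 1, 0]
    c = confusion(y, p)
    assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 2, 4)
    assert c.total == 10
    perfect = confusion(y, y)
    assert (perfect.fp, perfect.fn) == (0, 0)
    all_neg = confusion(y, [0] * 10)
    assert (all_neg.tp, all_neg.fp) == (0, 0)
    with pytest.raises(ValueError):
        confusion([1, 0], [1])


def test_f3_reproduces_reported_rows():
    """F-beta(3) from the reported sensitivity/PPV pairs matches the reported
    F3 at one decimal (in percent)."""
    assert round(100 * fbeta(0.706, 0.518), 1) == 68.1
    assert round(100 * fbeta(0.893, 0.472), 1) == 82.0


def test_fbeta_of_equal_arguments_is_identity():
    for p in (0.1, 0.5, 0.93):
        assert fbeta(p, p) == pytest.approx(p)


def test_f3_between_min_and_max_and_monotone():
    rng = np.random.default_rng(5)
    for _ in range(100):
        s, p = rng.uniform(0.01, 1, 2)
        f = fbeta(s, p)
        assert min(s, p) - 1e-12 <= f <= max(s, p) + 1e-12
        assert fbeta(min(s * 1.1, 1.0), p) >= f - 1e-12
        assert fbeta(s, min(p * 1.1, 1.0)) >= f - 1e-12


def test_metrics_undefined_markers():
    # no true positives anywhere: sensitivity undefined, not zero
    m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
    assert m.sensitivity is None and m.f3 is None
    assert m.specificity == 1.0
    # positives exist but none predicted: F3 collapses to 0, ppv undefined
    m2 = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=2))
    assert m2.sensitivity == 0.0 and m2.ppv is None and m2.f3 == 0.0


def test_metrics_consistency_with_fbeta():
    c = ConfusionCounts(tp=40, fp=25, tn=900, fn=10)
    m = metrics(c)
    assert m.f3 == pytest.approx(fbeta(m.sensitivity, m.ppv))
    assert m.accuracy == pytest.approx(940 / 975)
    assert m.npv == pytest.approx(900 / 910)


# ---------------------------------------------------------------------------
# Welch's t-test against textbook formulas

def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def test_welch_matches_textbook_formulas():
    a = [0.84, 0.86, 0.83, 0.85, 0.88, 0.82, 0.84, 0.87, 0.85, 0.83]
    b = [0.78, 0.80, 0.77, 0.79, 0.81, 0.76, 0.79, 0.80, 0.78, 0.77]
    res = compare_algorithms(a, b)
    t_exp, df_exp = welch_oracle(a, b)
    assert res.t_statistic == pytest.approx(t_exp)
    assert res.df == pytest.approx(df_exp)
    assert res.mean_difference == pytest.approx(np.mean(a) - np.mean(b))
    assert res.ci_low < res.mean_difference < res.ci_high
    assert 0 < res.p_value < 0.05


def test_welch_identical_vectors():
    a = [0.5, 0.6, 0.7]
    res = compare_algorithms(a, a)
    assert res.mean_difference == 0.0
    assert res.t_statistic == 0.0
    assert res.p_value == 1.0


def test_welch_antisymmetric():
    a = [0.9, 0.8, 0.85, 0.95]
    b = [0.7, 0.75, 0.72, 0.68]
    ab, ba = compare_algorithms(a, b), compare_algorithms(b, a)
    assert ab.mean_difference == pytest.approx(-ba.mean_difference)
    assert ab.t_statistic == pytest.approx(-ba.t_statistic)
    assert ab.p_value == pytest.approx(ba.p_value)


def test_welch_requires_two_scores():
    with pytest.raises(ValueError):
        compare_algorithms([0.5], [0.4, 0.6])


def test_reported_mean_differences():
    assert round(100 * mean_difference([0.788], [0.681]), 1) == 10.7
    assert round(100 * mean_difference([0.840], [0.788]), 1) == 5.2


# ---------------------------------------------------------------------------
# kappa and workload

def test_kappa_worked_example():
    """Both raters positive on 10, both negative on 80, 3+3 discordant of 96."""
    a = [1] * 10 + [0] * 80 + [1, 1, 1] + [0, 0, 0]
    b = [1] * 10 + [0] * 80 + [0, 0, 0] + [1, 1, 1]
    p_o = 90 / 96
    p_e = (13 / 96) ** 2 + (83 / 96) ** 2
    assert cohen_kappa(a, b) == pytest.approx((p_o - p_e) / (1 - p_e))
    assert cohen_kappa(a, b) == pytest.approx(0.733, abs=5e-3)


def test_kappa_extremes_and_cross_check():
    from sklearn.metrics import cohen_kappa_score

    a = [1, 0, 1, 0, 1, 1, 0, 0]
    assert cohen_kappa(a, a) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 5000)
    y = rng.integers(0, 2, 5000)
    assert abs(cohen_kappa(x, y)) < 0.05  # independent raters sit near zero
    assert cohen_kappa(x, y) == pytest.approx(cohen_kappa_score(x, y))
    assert math.isnan(cohen_kappa([1, 1, 1], [1, 1, 1]))  # p_e = 1


def test_workload_estimate_arithmetic():
    effort = workload_estimate(30320, 221.0, 0.04)
    assert round(effort.review_days, 1) == 8.8
    assert round(100 * effort.reduction) == 96
    full = workload_estimate(30320, 221.0, 1.0)
    assert full.review_days == 221.0 and full.reduction == 0.0


# ---------------------------------------------------------------------------
# nested cross-validation

@pytest.fixture(scope="module")
def ncv_report(small_synthetic_module):
    corpus, _ = small_synthetic_module
    algo = Algorithm(
        "NB-HuMan", "human", "nb_bernoulli",
        {}, {"ratio": [3.0, None], "alpha": [1.0]},
    )
    return nested_cross_validate(corpus, [algo], k=5, repeats=1, inner_k=3, seed=13)["NB-HuMan"]


@pytest.fixture(scope="module")
def small_synthetic_module():
    cfg = replace(default_paper_config(seed=97), n_records=1200, prevalence=0.05)
    return generate_corpus(cfg)


def test_ncv_folds_partition_the_corpus(ncv_report):
    assert len(ncv_report.folds) == 5
    assert sum(f.n_test for f in ncv_report.folds) == 1200
    assert ncv_report.leakage_audited


def test_ncv_chosen_params_come_from_grid(ncv_report):
    for fold in ncv_report.folds:
        assert fold.params["clf__ratio"] in (3.0, None)
        assert fold.params["clf__alpha"] == 1.0


def test_ncv_aggregate_within_fold_range(ncv_report):
    f3s = ncv_report.f3_scores
    assert min(f3s) - 1e-12 <= ncv_report.aggregate.f3 <= max(f3s) + 1e-12


def test_ncv_report_serialises(ncv_report):
    import json

    data = json.loads(ncv_report.to_json())
    assert data["algorithm"] == "NB-HuMan"
    assert len(data["folds"]) == 5
    table = report_table([ncv_report])
    assert table.startswith("Algorithm\tAccuracy")


def test_ncv_rejects_too_few_positives(small_synthetic_module):
    corpus, _ = small_synthetic_module
    sub_records = [r for r in corpus.records if r.label is False][:50]
    from syncope_nlp.corpus_io import Corpus

    with pytest.raises(ValueError):
        nested_cross_validate(
            Corpus(records=sub_records),
            [Algorithm("x", "human", "nb_bernoulli", {}, {})],
            k=5, repeats=1, seed=0,
        )


def test_selection_cannot_see_held_out_records(small_synthetic_module):
    """A term occurring only in held-out records is invisible to selection:
    its training document frequency is zero, so it can never be selected."""
    corpus, _ = small_synthetic_module
    index = PreprocessedCorpus.from_corpus(corpus).labelled_subset()
    train_idx = np.arange(0, 1000)
    vec = TermSelectionVectorizer(selector="ngi", n_unigrams=50, min_df=0.0, max_df=1.0)
    vec.fit(index.subset(train_idx), index.label_array[train_idx])
    held_out_ids = set(index.record_ids[1000:])
    assert vec.fit_record_ids_.isdisjoint(held_out_ids)
    # every selected text term is present in at least one training record
    for feat in vec.feature_set_.features:
        if feat.channel == "icd9":
            continue
        col = index.subset(train_idx).presence_column(feat.channel, feat.order, feat.term)
        assert col.sum() >= 1


def test_inner_loop_term_count_grows_with_planted_signal():
    """Parameter recovery: with more planted discriminative terms, the inner
    search chooses larger per-field term counts (monotone trend over three
    generator settings, seeds fixed)."""
    mean_chosen = []
    for n_planted in (2, 6, 10):
        base = default_paper_config(seed=31)
        cfg = replace(
            base, n_records=2500, prevalence=0.04,
            planted_terms=base.planted_terms[:n_planted],
        )
        corpus, _ = generate_corpus(cfg)
        algo = Algorithm(
            "SVM-NGI", "ngi", "svm_linear",
            {"n_unigrams": [1, 2, 4, 8]}, {"pos_weight": [10.0]},
        )
        rep = nested_cross_validate(corpus, [algo], k=2, repeats=1, inner_k=3, seed=2)["SVM-NGI"]
        mean_chosen.append(np.mean([f.params["vec__n_unigrams"] for f in rep.folds]))
    assert mean_chosen[0] <= mean_chosen[1] <= mean_chosen[2]


def test_holdout_evaluation_is_leak_free(small_synthetic_module):
    corpus, _ = small_synthetic_module
    from syncope_nlp.corpus_io import Corpus

    half = len(corpus) // 2
    a = Corpus(records=corpus.records[:half])
    b = Corpus(records=corpus.records[half:])
    algo = Algorithm("NB-HuMan", "human", "nb_bernoulli", {}, {"ratio": [None]})
    report = holdout_evaluate(a, b, algo, inner_k=3, seed=5)
    assert len(report.folds) == 1
    assert report.folds[0].n_test == len(b)
    assert report.folds[0].metrics.f3 is not None
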