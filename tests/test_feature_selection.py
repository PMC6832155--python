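import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from syncope_nlp.corpus_io import Corpus, UndefinedValueError
from syncope_nlp.feature_selection import (
    Feature,
    FeatureSet,
    HUMAN_BIGRAMS,
    HUMAN_TRIGRAMS,
    HUMAN_UNIGRAMS,
    SYNCOPE_ICD9,
    TermSelectionVectorizer,
    TermStats,
    chi_squared,
    gini_index,
    human_selector,
    information_gain,
    normalized_gini_index,
    score_terms,
    select_features,
    term_stats,
    vectorize,
)
from syncope_nlp.preprocessing import document_frequencies, record_field_terms
from syncope_nlp.stemming import italian_stem
from .conftest import make_record


# ---------------------------------------------------------------------------
# independent brute-force oracles, written directly from the definitions

def oracle_gi(a, b):
    p = a / (a + b)
    return p * p + (1 - p) * (1 - p)


def oracle_ngi(a, b, n_pos, n_neg):
    r_pos, r_neg = a / n_pos, b / n_neg
    q = r_pos / (r_pos + r_neg)
    return q * q + (1 - q) * (1 - q)


def oracle_ig(a, b, n_pos, n_neg):
    """Mutual information by exhaustive sum over the four cells, in bits."""
    n = n_pos + n_neg
    cells = {
        (1, 1): a, (1, 0): n_pos - a, (0, 1): b, (0, 0): n_neg - b,
    }  # (class, presence) -> count
    marg_c = {1: n_pos / n, 0: n_neg / n}
    marg_w = {1: (a + b) / n, 0: (n - a - b) / n}
    total = 0.0
    for (c, w), count in cells.items():
        p = count / n
        if p > 0:
            total += p * math.log2(p / (marg_c[c] * marg_w[w]))
    return total


def oracle_chi2(a, b, n_pos, n_neg):
    c, d = n_pos - a, n_neg - b
    n = n_pos + n_neg
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


# ---------------------------------------------------------------------------

def test_selector_worked_examples():
    s = TermStats(15, 5, 20, 80)
    assert gini_index(s) == pytest.approx(0.625)
    assert normalized_gini_index(s) == pytest.approx(0.858, abs=5e-4)
    assert information_gain(s) == pytest.approx(0.290, abs=5e-4)
    assert chi_squared(s) == pytest.approx(100 * (15 * 75 - 5 * 5) ** 2 / (20 * 80 * 20 * 80))


def test_selector_extremes():
    pure = TermStats(10, 0, 20, 80)  # exclusive to positives
    assert gini_index(pure) == 1.0
    assert normalized_gini_index(pure) == 1.0
    balanced = TermStats(10, 10, 20, 20)  # P(pos|w) = 0.5 and equal rates
    assert gini_index(balanced) == 0.5
    assert normalized_gini_index(balanced) == 0.5


def test_equal_rates_give_zero_ig_and_chi2():
    s = TermStats(5, 20, 20, 80)  # both presence rates 0.25
    assert information_gain(s) == pytest.approx(0.0, abs=1e-12)
    assert chi_squared(s) == pytest.approx(0.0, abs=1e-12)


def test_perfect_one_bit_channel():
    s = TermStats(50, 0, 50, 50)  # balanced priors, term == class indicator
    assert information_gain(s) == pytest.approx(1.0)


def test_chi2_doubles_with_counts():
    s1 = TermStats(15, 5, 20, 80)
    s2 = TermStats(30, 10, 40, 160)
    assert chi_squared(s2) == pytest.approx(2 * chi_squared(s1))


def test_undefined_value_errors():
    absent = TermStats(0, 0, 20, 80)
    with pytest.raises(UndefinedValueError):
        gini_index(absent)
    with pytest.raises(UndefinedValueError):
        normalized_gini_index(absent)
    everywhere = TermStats(20, 80, 20, 80)  # zero "absent" margin
    with pytest.raises(UndefinedValueError):
        chi_squared(everywhere)


@st.composite
def contingency(draw):
    n_pos = draw(st.integers(1, 200))
    n_neg = draw(st.integers(1, 2000))
    a = draw(st.integers(0, n_pos))
    b = draw(st.integers(0, n_neg))
    return TermStats(a, b, n_pos, n_neg)


@given(contingency())
@settings(max_examples=300, deadline=None)
def test_selectors_match_oracles_and_swap_invariance(s):
    a, b, n_pos, n_neg = s.n_pos_with, s.n_neg_with, s.n_pos, s.n_neg
    swapped = TermStats(b, a, n_neg, n_pos)
    if a + b >= 1:
        assert gini_index(s) == pytest.approx(oracle_gi(a, b))
        assert 0.5 <= gini_index(s) <= 1.0
        assert gini_index(swapped) == pytest.approx(gini_index(s))
        assert normalized_gini_index(s) == pytest.approx(oracle_ngi(a, b, n_pos, n_neg))
        assert 0.5 <= normalized_gini_index(s) <= 1.0
        assert normalized_gini_index(swapped) == pytest.approx(normalized_gini_index(s))
    assert information_gain(s) == pytest.approx(oracle_ig(a, b, n_pos, n_neg), abs=1e-10)
    assert information_gain(s) >= -1e-12
    assert information_gain(swapped) == pytest.approx(information_gain(s), abs=1e-10)
    if min(a + b, n_pos + n_neg - a - b) >= 1:
        assert chi_squared(s) == pytest.approx(oracle_chi2(a, b, n_pos, n_neg))
        assert chi_squared(s) >= 0
        assert chi_squared(swapped) == pytest.approx(chi_squared(s))


@given(contingency(), st.integers(2, 10))
@settings(max_examples=100, deadline=None)
def test_ngi_invariant_under_majority_downsampling(s, factor):
    """Scaling the negative class and its presence count by the same factor
    leaves NGI unchanged — the prior-skew correction, exactly."""
    if s.n_pos_with + s.n_neg_with == 0:
        return
    scaled = TermStats(s.n_pos_with, s.n_neg_with * factor, s.n_pos, s.n_neg * factor)
    assert normalized_gini_index(scaled) == pytest.approx(normalized_gini_index(s))


# ---------------------------------------------------------------------------
# corpus-level operations

def test_term_stats_match_exhaustive_scan(tiny_corpus):
    y = [r.label for r in tiny_corpus]
    for field in ("triage", "history", "discharge"):
        for term in [("sincop",), ("dolor",), ("perdita", "di")]:
            s = term_stats(tiny_corpus, field, term)
            order = len(term)
            present = [term in record_field_terms(r, field, order) for r in tiny_corpus]
            assert s.n_pos_with == sum(p for p, lab in zip(present, y) if lab)
            assert s.n_neg_with == sum(p for p, lab in zip(present, y) if not lab)
            assert (s.n_pos, s.n_neg) == (3, 3)


def test_term_stats_extremes(tiny_corpus):
    absent = term_stats(tiny_corpus, "triage", ("zzz",))
    assert (absent.n_pos_with, absent.n_neg_with) == (0, 0)


@pytest.mark.parametrize("selector", ["gi", "ngi", "ig", "chi2"])
def test_planted_pure_term_ranked_first(selector):
    """A term exclusive to positives dominates all four rankings."""
    records = [
        make_record(i, label=True, discharge=f"puremark filler{i % 3}") for i in range(4)
    ] + [
        make_record(10 + i, label=False, discharge=f"filler{i % 3} other{i % 2}")
        for i in range(12)
    ]
    table = score_terms(Corpus(records=records), "discharge", 1, selector)
    assert table.rows[0].term == ("puremark",)


def test_score_table_tie_break_matches_brute_force(tiny_corpus):
    table = score_terms(tiny_corpus, "discharge", 1, "ngi")
    rows = [(r.term, r.score, r.df) for r in table.rows]
    expected = sorted(rows, key=lambda t: (-t[1], -t[2], " ".join(t[0])))
    assert rows == expected


def test_empty_candidate_set_after_filtering(tiny_corpus):
    table = score_terms(tiny_corpus, "discharge", 1, "ngi", min_df=0.99, max_df=1.0)
    assert table.rows == []


def test_human_selector_contents():
    fs = human_selector()
    assert fs.selector_name == "HuMan"
    assert len(fs) == 20  # 16 unigrams + 1 bigram + 2 trigrams + ICD code
    unigram_terms = {f.term[0] for f in fs.features if f.channel == "any" and f.order == 1}
    assert unigram_terms == {italian_stem(w) for w in HUMAN_UNIGRAMS}
    any_terms = {f.term for f in fs.features}
    assert ("perdita", "di", "coscienza") in any_terms
    assert ("crisi", "epilettica") in any_terms
    assert Feature(channel="icd9", term=(SYNCOPE_ICD9,)) in fs.features


def test_select_features_top_k_and_ties(tiny_corpus):
    tables = {("discharge", 1): score_terms(tiny_corpus, "discharge", 1, "ngi")}
    empty = select_features(tables, 0, icd_selector="none")
    assert len(empty) == 0
    one = select_features(tables, 1, icd_selector="none")
    assert one.features[0].term == tables[("discharge", 1)].rows[0].term
    # requesting more than available takes all, without error
    all_of_them = select_features(tables, 10_000, icd_selector="fixed")
    assert len(all_of_them) == len(tables[("discharge", 1)].rows) + 1


def test_feature_set_rejects_duplicates():
    with pytest.raises(ValueError):
        FeatureSet(
            features=[Feature("any", ("sincop",)), Feature("any", ("sincop",))],
            selector_name="x",
        )


def test_feature_set_json_round_trip():
    fs = human_selector()
    assert FeatureSet.from_json(fs.to_json()).features == fs.features


def test_vectorize_matches_brute_force_membership(tiny_corpus):
    fs = human_selector()
    fm = vectorize(tiny_corpus, fs)
    for i, rec in enumerate(tiny_corpus):
        for j, feat in enumerate(fs.features):
            if feat.channel == "icd9":
                expected = rec.icd9_code == feat.term[0]
            else:
                fields = ("triage", "history", "discharge") if feat.channel == "any" else (feat.channel,)
                expected = any(
                    feat.term in record_field_terms(rec, f, feat.order) for f in fields
                )
            assert fm.values[i, j] == int(expected), (rec.record_id, feat)


def test_vectorize_column_sums_equal_document_frequencies(tiny_corpus):
    table = score_terms(tiny_corpus, "discharge", 1, "ngi")
    fs = select_features({("discharge", 1): table}, 1000, icd_selector="none")
    fm = vectorize(tiny_corpus, fs)
    df = document_frequencies(tiny_corpus, "discharge", 1)
    for j, feat in enumerate(fs.features):
        assert fm.values[:, j].sum() == df.counts[feat.term]


def test_vectorizer_estimator_contract(tiny_corpus):
    from sklearn.base import clone

    vec = TermSelectionVectorizer(selector="ngi", n_unigrams=3, icd_selector="fixed")
    assert clone(vec).get_params() == vec.get_params()
    vec.fit(tiny_corpus)
    X = vec.transform(tiny_corpus)
    assert X.shape == (len(tiny_corpus), len(vec.feature_set_))
    assert set(np.unique(X.toarray())) <= {0, 1}
    assert vec.fit_record_ids_ == frozenset(r.record_id for r in tiny_corpus)
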