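"""Term selection and binary feature construction.

Candidate n-grams are ranked by how strongly their presence separates
syncope-positive from syncope-negative records.  Four selection statistics
are provided, all computed from the 2x2 presence-by-class contingency
table of a term:

* Gini Index (GI): sum_c P(c|w)^2, the purity of the class distribution
  among records containing the term.  With 1.9% prevalence this is
  dominated by the class prior.
* Normalized Gini Index (NGI): the same purity computed on class-conditional
  presence rates P(w|c) normalised to sum to one, which removes the prior
  skew — the key property for rare-event detection.
* Information Gain (IG): mutual information, in bits, between term presence
  and the class.
* Chi-squared: the standard 2x2 association statistic without continuity
  correction.

The manual "HuMan" selector is the fixed expert-curated lexicon (16 stemmed
unigrams, one bigram, two trigrams, matched in any text channel) plus the
ICD-9 syncope code 780.2.  Selected features become a binary record-by-
feature presence matrix consumed by the classifiers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from scipy import sparse

from ._index import CHANNELS, ICD_CHANNEL, PreprocessedCorpus
from .corpus_io import Corpus, TEXT_FIELDS, UndefinedValueError
from .preprocessing import ConfigurationError, NGram
from .stemming import italian_stem

logger = logging.getLogger(__name__)

__all__ = [
    "TermStats",
    "TermScore",
    "TermScoreTable",
    "Feature",
    "FeatureSet",
    "FeatureMatrix",
    "term_stats",
    "gini_index",
    "normalized_gini_index",
    "information_gain",
    "chi_squared",
    "score_terms",
    "human_selector",
    "select_features",
    "vectorize",
    "TermSelectionVectorizer",
    "SELECTORS",
    "HUMAN_UNIGRAMS",
    "HUMAN_BIGRAMS",
    "HUMAN_TRIGRAMS",
    "SYNCOPE_ICD9",
]

SELECTORS = ("gi", "ngi", "ig", "chi2")

#: expert-curated lexicon of terms associated with syncope presentations
HUMAN_UNIGRAMS = (
    "assenza", "caduta", "capogiro", "clonie", "ipotensione", "lipotimia",
    "malessere", "malore", "prelipotimia", "presincope", "prodromi",
    "sincope", "svenimento", "trauma", "trovato", "vertigini",
)
HUMAN_BIGRAMS = (("crisi", "epilettica"),)
HUMAN_TRIGRAMS = (("ferita", "lacero", "contusa"), ("perdita", "di", "coscienza"))
SYNCOPE_ICD9 = "780.2"


@dataclass(frozen=True)
class TermStats:
    """Presence-by-class contingency counts for one term.

    The implied 2x2 table is A = positives with the term,
    B = negatives with it, C = positives without, D = negatives without.
    """

    n_pos_with: int
    n_neg_with: int
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_pos_with <= self.n_pos):
            raise ValueError(f"invalid counts: {self}")
        if not (0 <= self.n_neg_with <= self.n_neg):
            raise ValueError(f"invalid counts: {self}")
        if self.n_pos + self.n_neg < 1:
            raise ValueError("empty contingency table")


def term_stats(corpus: Union[Corpus, PreprocessedCorpus], field: str, term: NGram) -> TermStats:
    """Presence counts by class for ``term`` in ``field`` over labelled records."""
    index = _as_index(corpus).labelled_subset()
    y = index.label_array
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedValueError("term_stats requires at least one record of each class")
    term = tuple(term) if not isinstance(term, str) else (term,)
    col = index.presence_column(field, len(term), term)
    return TermStats(
        n_pos_with=int(col[y == 1].sum()),
        n_neg_with=int(col[y == 0].sum()),
        n_pos=n_pos,
        n_neg=n_neg,
    )


# ---------------------------------------------------------------------------
# selection statistics (scalar API delegates to the vectorised kernels so a
# ranked table and a single lookup can never disagree)

def _gi_kernel(a, b, n_pos, n_neg):
    with np.errstate(invalid="ignore", divide="ignore"):
        p = a / (a + b)
    return p**2 + (1.0 - p) ** 2


def _ngi_kernel(a, b, n_pos, n_neg):
    r_pos = a / n_pos
    r_neg = b / n_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        q = r_pos / (r_pos + r_neg)
    return q**2 + (1.0 - q) ** 2


def _entropy2(p):
    """Binary entropy in bits with the 0*log0 := 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        mask = q > 0
        out = out - np.where(mask, q * np.log2(np.where(mask, q, 1.0)), 0.0)
    return out


def _ig_kernel(a, b, n_pos, n_neg):
    n = n_pos + n_neg
    p_w = (a + b) / n
    prior = _entropy2(np.full_like(np.asarray(a, dtype=float), n_pos / n))
    with np.errstate(invalid="ignore", divide="ignore"):
        h_with = _entropy2(np.where(a + b > 0, a / np.maximum(a + b, 1), 0.0))
        rest = n - (a + b)
        h_without = _entropy2(np.where(rest > 0, (n_pos - a) / np.maximum(rest, 1), 0.0))
    return prior - (p_w * h_with + (1.0 - p_w) * h_without)


def _chi2_kernel(a, b, n_pos, n_neg):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = n_pos - a
    d = n_neg - b
    n = n_pos + n_neg
    denom = (a + b) * (c + d) * n_pos * n_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    return chi2


_KERNELS = {"gi": _gi_kernel, "ngi": _ngi_kernel, "ig": _ig_kernel, "chi2": _chi2_kernel}


def _scalar(kernel, stats: TermStats) -> float:
    val = kernel(
        np.array([stats.n_pos_with], dtype=float),
        np.array([stats.n_neg_with], dtype=float),
        stats.n_pos,
        stats.n_neg,
    )[0]
    if not np.isfinite(val):
        raise UndefinedValueError(f"statistic undefined for {stats}")
    return float(val)


def gini_index(stats: TermStats) -> float:
    """GI(w) = P(pos|w)^2 + P(neg|w)^2, in [0.5, 1]; needs the term present somewhere."""
    if stats.n_pos_with + stats.n_neg_with < 1:
        raise UndefinedValueError("gini index undefined: term present in no record")
    return _scalar(_gi_kernel, stats)


def normalized_gini_index(stats: TermStats) -> float:
    """Gini purity on prior-normalised presence rates, in [0.5, 1].

    With q = r_pos / (r_pos + r_neg) for class-conditional presence rates
    r_c = P(w|c), NGI(w) = q^2 + (1-q)^2.  Scaling the negative class (and
    its presence count) by any factor leaves NGI unchanged, which is what
    makes it robust to the 1.9% prevalence.
    """
    if stats.n_pos_with + stats.n_neg_with < 1:
        raise UndefinedValueError("normalized gini undefined: term present in no record")
    if stats.n_pos == 0 or stats.n_neg == 0:
        raise UndefinedValueError("normalized gini requires both classes non-empty")
    return _scalar(_ngi_kernel, stats)


def information_gain(stats: TermStats) -> float:
    """Mutual information between term presence and class, in bits (>= 0)."""
    return _scalar(_ig_kernel, stats)


def chi_squared(stats: TermStats) -> float:
    """2x2 chi-squared statistic, no continuity correction; all margins must be >= 1."""
    a, b = stats.n_pos_with, stats.n_neg_with
    c, d = stats.n_pos - a, stats.n_neg - b
    if min(a + b, c + d, stats.n_pos, stats.n_neg) < 1:
        raise UndefinedValueError("chi-squared undefined: zero margin")
    return _scalar(_chi2_kernel, stats)


# ---------------------------------------------------------------------------
# ranked tables and feature sets

@dataclass(frozen=True)
class TermScore:
    term: NGram
    score: float
    df: int


@dataclass
class TermScoreTable:
    """Frequency-filtered candidates sorted by score.

    Tie-break is deterministic: score descending, then document frequency
    descending, then lexicographic on the term.
    """

    field: str
    order: int
    selector: str
    rows: list[TermScore] = dc_field(default_factory=list)

    def top(self, k: int) -> list[TermScore]:
        if k > len(self.rows):
            logger.warning(
                "requested top-%d of %d candidates for (%s, order %d); taking all",
                k, len(self.rows), self.field, self.order,
            )
        return self.rows[: max(k, 0)]

    def to_tsv(self) -> str:
        lines = ["field\torder\tterm\tscore\tdf"]
        for row in self.rows:
            lines.append(
                f"{self.field}\t{self.order}\t{' '.join(row.term)}\t{row.score:.6g}\t{row.df}"
            )
        return "\n".join(lines) + "\n"


def _as_index(corpus: Union[Corpus, PreprocessedCorpus]) -> PreprocessedCorpus:
    if isinstance(corpus, PreprocessedCorpus):
        return corpus
    return PreprocessedCorpus.from_corpus(corpus)


def _ranked_rows(terms, scores, dfs) -> list[TermScore]:
    keys = np.array([" ".join(t) for t in terms], dtype=object)
    # np.lexsort: last key is primary
    order = np.lexsort((keys, -np.asarray(dfs), -np.asarray(scores)))
    return [TermScore(term=tuple(terms[i]), score=float(scores[i]), df=int(dfs[i])) for i in order]


def score_terms(
    corpus: Union[Corpus, PreprocessedCorpus],
    field: str,
    order: int,
    selector: str,
    min_df: float = 0.0,
    max_df: float = 1.0,
) -> TermScoreTable:
    """Score all frequency-filtered candidate n-grams of one field and order."""
    if selector not in SELECTORS:
        raise ConfigurationError(f"unknown selector {selector!r}; expected one of {SELECTORS}")
    if not (0.0 <= min_df <= max_df <= 1.0):
        raise ConfigurationError(f"require 0 <= min_df <= max_df <= 1")
    index = _as_index(corpus).labelled_subset()
    y = index.label_array
    if y.sum() == 0 or (len(y) - y.sum()) == 0:
        raise UndefinedValueError("scoring requires at least one record of each class")
    return _score_index(index, y, field, order, selector, min_df, max_df)


@dataclass(frozen=True)
class Feature:
    """One selected feature: a term matched in a channel.

    ``channel`` is one of the three text fields, ``icd9``, or ``any``
    (matched in all three text fields, as the manual lexicon is).
    """

    channel: str
    term: NGram

    @property
    def order(self) -> int:
        return len(self.term)


@dataclass
class FeatureSet:
    features: list[Feature]
    selector_name: str

    def __post_init__(self) -> None:
        seen = set()
        for f in self.features:
            key = (f.channel, f.term)
            if key in seen:
                raise ValueError(f"duplicate feature {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.features)

    def to_json(self) -> str:
        return json.dumps(
            {
                "selector_name": self.selector_name,
                "features": [
                    {"channel": f.channel, "term": list(f.term)} for f in self.features
                ],
            },
            ensure_ascii=False,
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSet":
        data = json.loads(text)
        return cls(
            features=[Feature(channel=f["channel"], term=tuple(f["term"])) for f in data["features"]],
            selector_name=data["selector_name"],
        )


def human_selector() -> FeatureSet:
    """The fixed expert lexicon: 16 stemmed unigrams, 1 bigram, 2 trigrams
    matched in any text channel, plus the ICD-9 syncope code 780.2."""
    features = [Feature(channel="any", term=(italian_stem(w),)) for w in HUMAN_UNIGRAMS]
    features += [Feature(channel="any", term=bg) for bg in HUMAN_BIGRAMS]
    features += [Feature(channel="any", term=tg) for tg in HUMAN_TRIGRAMS]
    features.append(Feature(channel=ICD_CHANNEL, term=(SYNCOPE_ICD9,)))
    return FeatureSet(features=features, selector_name="HuMan")


def select_features(
    tables: Mapping[tuple[str, int], TermScoreTable],
    k: Union[int, Mapping[tuple[str, int], int]],
    icd_selector: str = "none",
    icd_table: Optional[TermScoreTable] = None,
    n_icd: int = 1,
    selector_name: Optional[str] = None,
) -> FeatureSet:
    """Take the top-k rows of each ranked table and concatenate.

    ``icd_selector`` is "gi" (take top ``n_icd`` codes of ``icd_table``),
    "fixed" (the single code 780.2), or "none".
    """
    features: list[Feature] = []
    for (field, order), table in tables.items():
        kk = k if isinstance(k, int) else k.get((field, order), 0)
        for row in table.top(kk):
            features.append(Feature(channel=field, term=row.term))
    if icd_selector == "fixed":
        features.append(Feature(channel=ICD_CHANNEL, term=(SYNCOPE_ICD9,)))
    elif icd_selector == "gi":
        if icd_table is None:
            raise ConfigurationError("icd_selector='gi' requires an icd_table")
        for row in icd_table.top(n_icd):
            features.append(Feature(channel=ICD_CHANNEL, term=row.term))
    elif icd_selector != "none":
        raise ConfigurationError(f"unknown icd_selector {icd_selector!r}")
    name = selector_name or (next(iter(tables.values())).selector if tables else "empty")
    return FeatureSet(features=features, selector_name=name)


@dataclass
class FeatureMatrix:
    """Binary presence matrix, one row per record and one column per feature."""

    record_ids: list[str]
    features: FeatureSet
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        assert self.values.shape == (len(self.record_ids), len(self.features))


def _feature_column(index: PreprocessedCorpus, feature: Feature) -> np.ndarray:
    if feature.channel == "any":
        col = np.zeros(index.n_records, dtype=np.int8)
        for fld in TEXT_FIELDS:
            col |= index.presence_column(fld, feature.order, feature.term)
        return col
    return index.presence_column(feature.channel, feature.order, feature.term)


def vectorize(
    corpus: Union[Corpus, PreprocessedCorpus], features: FeatureSet
) -> FeatureMatrix:
    """Binary presence matrix of the selected features over a corpus.

    Unigram features are matched against stemmed tokens, bigrams/trigrams
    against raw tokens, and ICD features by exact code string, mirroring
    how features were selected.
    """
    index = _as_index(corpus)
    if len(features) == 0:
        values = np.zeros((index.n_records, 0), dtype=np.int8)
    else:
        values = np.column_stack([_feature_column(index, f) for f in features.features])
    return FeatureMatrix(record_ids=list(index.record_ids), features=features, values=values)


class TermSelectionVectorizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer: select terms on the training split, emit
    binary presence features.

    Parameters
    ----------
    selector : {"gi", "ngi", "ig", "chi2", "human"}
        Term-selection statistic, or the fixed manual lexicon.
    n_unigrams, n_bigrams, n_trigrams : int
        Number of top-ranked terms kept per text field and order
        (ignored for the manual selector).
    min_df, max_df : float
        Document-frequency band (proportions) for candidate terms.
    icd_selector : {"gi", "fixed", "none"}
        How the ICD-9 code channel contributes features.
    n_icd : int
        Number of GI-ranked ICD codes when ``icd_selector="gi"``.

    The estimator operates on :class:`PreprocessedCorpus` slices so that
    repeated fits inside cross-validation never re-tokenise text.  After
    ``fit``, ``feature_set_`` holds the selected features and
    ``fit_record_ids_`` the ids of the records the selection saw — used by
    the cross-validation leakage audit.
    """

    def __init__(
        self,
        selector: str = "ngi",
        n_unigrams: int = 10,
        n_bigrams: int = 0,
        n_trigrams: int = 0,
        min_df: float = 0.001,
        max_df: float = 0.5,
        icd_selector: str = "fixed",
        n_icd: int = 1,
    ):
        self.selector = selector
        self.n_unigrams = n_unigrams
        self.n_bigrams = n_bigrams
        self.n_trigrams = n_trigrams
        self.min_df = min_df
        self.max_df = max_df
        self.icd_selector = icd_selector
        self.n_icd = n_icd

    def fit(self, X: PreprocessedCorpus, y=None):
        if not isinstance(X, PreprocessedCorpus):
            X = _as_index(X)
        if self.selector == "human":
            self.feature_set_ = human_selector()
        else:
            if y is None:
                y = X.label_array
            y = np.asarray(y, dtype=int)
            per_order = {1: self.n_unigrams, 2: self.n_bigrams, 3: self.n_trigrams}
            tables = {}
            for field in TEXT_FIELDS:
                for order, n_terms in per_order.items():
                    if n_terms > 0 and (field, order) in X.matrices:
                        tables[(field, order)] = _score_index(
                            X, y, field, order, self.selector, self.min_df, self.max_df
                        )
            icd_table = None
            if self.icd_selector == "gi":
                icd_table = _score_index(X, y, ICD_CHANNEL, 1, "gi", 0.0, 1.0)
            self.feature_set_ = select_features(
                tables,
                {key: per_order[key[1]] for key in tables},
                icd_selector=self.icd_selector,
                icd_table=icd_table,
                n_icd=self.n_icd,
                selector_name=self.selector,
            )
        self.n_features_out_ = len(self.feature_set_)
        self.fit_record_ids_ = frozenset(X.record_ids)
        return self

    def transform(self, X: PreprocessedCorpus) -> sparse.csr_matrix:
        if not hasattr(self, "feature_set_"):
            raise RuntimeError("TermSelectionVectorizer is not fitted")
        if not isinstance(X, PreprocessedCorpus):
            X = _as_index(X)
        fm = vectorize(X, self.feature_set_)
        return sparse.csr_matrix(fm.values)

    def get_feature_names_out(self, input_features=None):
        return np.array(
            [f"{f.channel}:{' '.join(f.term)}" for f in self.feature_set_.features],
            dtype=object,
        )


def _score_index(
    index: PreprocessedCorpus,
    y: np.ndarray,
    field: str,
    order: int,
    selector: str,
    min_df: float,
    max_df: float,
) -> TermScoreTable:
    """score_terms over a pre-labelled index without re-slicing."""
    matrix = index.matrices[(field, order)]
    vocab = index.vocabularies[(field, order)]
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if matrix.shape[1] == 0 or n_pos == 0 or n_neg == 0:
        return TermScoreTable(field=field, order=order, selector=selector)
    df = np.asarray(matrix.sum(axis=0)).ravel()
    n = matrix.shape[0]
    keep = (df >= min_df * n) & (df <= max_df * n) & (df >= 1)
    cols = np.flatnonzero(keep)
    if cols.size == 0:
        return TermScoreTable(field=field, order=order, selector=selector)
    sub = matrix[:, cols]
    pos_with = np.asarray(sub[y == 1].sum(axis=0)).ravel().astype(float)
    neg_with = np.asarray(sub[y == 0].sum(axis=0)).ravel().astype(float)
    # All four statistics are symmetric in the classes, so a term that is
    # merely absent from the (tiny) positive class scores as "pure" as a
    # genuine syncope marker.  Ranking therefore only considers candidates
    # whose presence rate is higher among positives than among negatives —
    # the event markers we are selecting for.
    assoc = pos_with * n_neg > neg_with * n_pos
    cols, pos_with, neg_with = cols[assoc], pos_with[assoc], neg_with[assoc]
    if cols.size == 0:
        return TermScoreTable(field=field, order=order, selector=selector)
    scores = _KERNELS[selector](pos_with, neg_with, n_pos, n_neg)
    scores = np.where(np.isfinite(scores), scores, 0.0)
    rows = _ranked_rows([vocab[j] for j in cols], scores, df[cols])
    return TermScoreTable(field=field, order=order, selector=selector, rows=rows)
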