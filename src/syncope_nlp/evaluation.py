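"""Evaluation: F3-centred metrics, nested cross-validation, Welch's t-test,
interrater kappa, and chart-review workload estimation.

The working metric is the F-beta score with beta = 3,

    F3 = (1 + 3^2) * PPV * Sens / (3^2 * PPV + Sens),

which weights sensitivity nine times more than precision: missing a syncope
record costs far more than reviewing a false positive.  Hyper-parameters
(term counts, frequency thresholds, undersampling ratio, class weight) are
tuned to maximise mean inner-fold F3 inside a stratified five-fold nested
cross-validation; the outer folds are touched only once per repeat, by the
refitted best model.  Feature selection and undersampling run strictly on
inner-training data, and every fold asserts that the records seen during
selection/training are disjoint from the outer test fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.model_selection import ParameterGrid, StratifiedKFold

from ._index import PreprocessedCorpus
from .classification import CLASSIFIER_FAMILIES
from .corpus_io import Corpus, UndefinedValueError
from .feature_selection import TermSelectionVectorizer, _as_index

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "FoldResult",
    "EvalReport",
    "WelchResult",
    "ReviewEffort",
    "Algorithm",
    "confusion",
    "metrics",
    "fbeta",
    "nested_cross_validate",
    "holdout_evaluate",
    "compare_algorithms",
    "mean_difference",
    "cohen_kappa",
    "workload_estimate",
    "default_algorithms",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    """Standard 2x2 counts for binary label vectors."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def fbeta(sensitivity: float, ppv: float, beta: float = 3.0) -> float:
    """F-beta from sensitivity and PPV; 0 when both are 0."""
    denom = beta**2 * ppv + sensitivity
    if denom == 0:
        return 0.0
    return (1 + beta**2) * ppv * sensitivity / denom


@dataclass(frozen=True)
class MetricSet:
    """Six evaluation metrics as proportions; ``None`` marks an undefined
    value (zero denominator), never silently coerced to 0."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f3: Optional[float]


def metrics(c: ConfusionCounts, beta: float = 3.0) -> MetricSet:
    """All six metrics from confusion counts.

    F-beta is computed from sensitivity and PPV.  When the classifier
    predicts no positives but positives exist (sensitivity 0, PPV
    undefined) F-beta is 0 by continuity; when sensitivity itself is
    undefined so is F-beta.
    """

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    sens = ratio(c.tp, c.tp + c.fn)
    ppv = ratio(c.tp, c.tp + c.fp)
    if sens is None:
        f3 = None
    elif ppv is None:
        f3 = 0.0 if sens == 0.0 else None
    else:
        f3 = fbeta(sens, ppv, beta)
    return MetricSet(
        accuracy=ratio(c.tp + c.tn, c.total),
        sensitivity=sens,
        specificity=ratio(c.tn, c.tn + c.fp),
        ppv=ppv,
        npv=ratio(c.tn, c.tn + c.fn),
        f3=f3,
    )


@dataclass
class Algorithm:
    """One selector-classifier combination with its hyper-parameter grids.

    ``vectorizer_grid`` ranges over :class:`TermSelectionVectorizer`
    parameters, ``classifier_grid`` over the classifier family's
    hyper-parameters.  The inner loop searches their Cartesian product.
    """

    name: str
    selector: str
    classifier: str
    vectorizer_grid: dict = dc_field(default_factory=dict)
    classifier_grid: dict = dc_field(default_factory=dict)


def default_algorithms() -> list[Algorithm]:
    """The four retained selector-classifier combinations with their default
    search grids."""
    nb_grid = {"ratio": [1.0, 3.0, 10.0, None], "alpha": [0.1, 1.0]}
    svm_grid = {"pos_weight": [1.0, 5.0, 10.0, 25.0, 50.0, "balanced"], "C": [0.1, 1.0, 10.0]}
    auto_vec = {
        "n_unigrams": [10, 20],
        "min_df": [0.001, 0.005, 0.01],
        "max_df": [0.5, 0.9],
    }
    return [
        Algorithm("NB-HuMan", "human", "nb_bernoulli", {}, nb_grid),
        Algorithm("SVM-HuMan", "human", "svm_linear", {}, svm_grid),
        Algorithm("NB-NGI", "ngi", "nb_bernoulli", dict(auto_vec), nb_grid),
        Algorithm("SVM-NGI", "ngi", "svm_linear", dict(auto_vec), svm_grid),
    ]


@dataclass
class FoldResult:
    confusion: ConfusionCounts
    metrics: MetricSet
    params: dict
    n_test: int


@dataclass
class EvalReport:
    """Per-outer-fold results of nested cross-validation for one algorithm.

    ``aggregate`` is the unweighted mean of the per-fold metrics (undefined
    fold values are excluded from the mean of that metric).
    """

    algorithm: str
    folds: list[FoldResult]
    k: int
    repeats: int
    seed: Optional[int]
    leakage_audited: bool = True

    @property
    def f3_scores(self) -> list[float]:
        return [f.metrics.f3 for f in self.folds if f.metrics.f3 is not None]

    @property
    def aggregate(self) -> MetricSet:
        def mean_of(name: str) -> Optional[float]:
            vals = [getattr(f.metrics, name) for f in self.folds]
            vals = [v for v in vals if v is not None]
            return float(np.mean(vals)) if vals else None

        return MetricSet(
            accuracy=mean_of("accuracy"),
            sensitivity=mean_of("sensitivity"),
            specificity=mean_of("specificity"),
            ppv=mean_of("ppv"),
            npv=mean_of("npv"),
            f3=mean_of("f3"),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "algorithm": self.algorithm,
                "k": self.k,
                "repeats": self.repeats,
                "seed": self.seed,
                "leakage_audited": self.leakage_audited,
                "aggregate": asdict(self.aggregate),
                "folds": [
                    {
                        "confusion": asdict(f.confusion),
                        "metrics": asdict(f.metrics),
                        "params": {k: repr(v) if v is None else v for k, v in f.params.items()},
                        "n_test": f.n_test,
                    }
                    for f in self.folds
                ],
            },
            indent=2,
            default=str,
        )

    def table_row(self) -> str:
        """One row in the standard report order: accuracy, sensitivity, PPV,
        F3, NPV, specificity — percent, one decimal."""
        agg = self.aggregate
        cells = [
            agg.accuracy, agg.sensitivity, agg.ppv, agg.f3, agg.npv, agg.specificity
        ]
        formatted = ["-" if v is None else f"{100 * v:.1f}" for v in cells]
        return "\t".join([self.algorithm] + formatted)


def report_table(reports: Sequence[EvalReport]) -> str:
    header = "Algorithm\tAccuracy\tSensitivity\tPPV\tF3\tNPV\tSpecificity"
    return "\n".join([header] + [r.table_row() for r in reports]) + "\n"


def _fit_eval_once(
    index: PreprocessedCorpus,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    algorithm: Algorithm,
    params: dict,
    seed: Optional[int],
) -> tuple[ConfusionCounts, frozenset]:
    """Fit selector+classifier on train rows, evaluate on test rows."""
    vec_params = {k[5:]: v for k, v in params.items() if k.startswith("vec__")}
    clf_params = {k[5:]: v for k, v in params.items() if k.startswith("clf__")}
    sub_train = index.subset(train_idx)
    sub_test = index.subset(test_idx)
    vec = TermSelectionVectorizer(selector=algorithm.selector, **vec_params)
    vec.fit(sub_train, y[train_idx])
    clf = CLASSIFIER_FAMILIES[algorithm.classifier](clf_params, seed)
    clf.fit(vec.transform(sub_train), y[train_idx])
    pred = clf.predict(vec.transform(sub_test))
    return confusion(y[test_idx], pred), vec.fit_record_ids_


def _param_grid(algorithm: Algorithm) -> list[dict]:
    grid = {f"vec__{k}": v for k, v in algorithm.vectorizer_grid.items()}
    grid.update({f"clf__{k}": v for k, v in algorithm.classifier_grid.items()})
    if not grid:
        return [{}]
    return list(ParameterGrid(grid))


def _inner_search(
    index: PreprocessedCorpus,
    y: np.ndarray,
    train_idx: np.ndarray,
    algorithm: Algorithm,
    inner_k: int,
    seed: Optional[int],
) -> dict:
    """Mean inner-validation F3 over the grid; first best point wins ties."""
    points = _param_grid(algorithm)
    if len(points) == 1:
        return points[0]
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    splits = list(inner.split(np.zeros(len(train_idx)), y[train_idx]))
    best_score, best_point = -1.0, points[0]
    for point in points:
        f3s = []
        for itr, ival in splits:
            c, _ = _fit_eval_once(
                index, y, train_idx[itr], train_idx[ival], algorithm, point, seed
            )
            m = metrics(c)
            f3s.append(m.f3 if m.f3 is not None else 0.0)
        score = float(np.mean(f3s))
        if score > best_score:
            best_score, best_point = score, point
    return best_point


def nested_cross_validate(
    corpus: Union[Corpus, PreprocessedCorpus],
    algorithms: Sequence[Algorithm],
    k: int = 5,
    repeats: int = 4,
    inner_k: int = 4,
    seed: int = 0,
) -> dict[str, EvalReport]:
    """Stratified k-fold nested cross-validation, repeated with reshuffled folds.

    For every outer fold, the inner loop (``inner_k`` stratified folds of
    the outer-training data) picks the grid point with the best mean
    validation F3; the model is refit on the full outer-training split and
    scored once on the held-out fold.  A leakage audit asserts, fold by
    fold, that the record ids used for selection/training never intersect
    the outer test fold.
    """
    index = _as_index(corpus).labelled_subset()
    y = index.label_array
    if int(y.sum()) < k:
        raise ValueError(f"need at least {k} positive records for {k}-fold stratification")

    reports: dict[str, EvalReport] = {}
    for algorithm in algorithms:
        folds: list[FoldResult] = []
        for r in range(repeats):
            outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + 7919 * r) % 2**31)
            for train_idx, test_idx in outer.split(np.zeros(len(y)), y):
                best = _inner_search(index, y, train_idx, algorithm, inner_k, seed)
                c, fit_ids = _fit_eval_once(
                    index, y, train_idx, test_idx, algorithm, best, seed
                )
                test_ids = frozenset(index.record_ids[test_idx])
                if fit_ids & test_ids:
                    raise RuntimeError(
                        f"leakage audit failed for {algorithm.name}: "
                        f"{len(fit_ids & test_ids)} test records seen during fit"
                    )
                folds.append(
                    FoldResult(confusion=c, metrics=metrics(c), params=best, n_test=len(test_idx))
                )
            logger.info("%s: repeat %d/%d done", algorithm.name, r + 1, repeats)
        reports[algorithm.name] = EvalReport(
            algorithm=algorithm.name, folds=folds, k=k, repeats=repeats, seed=seed
        )
    return reports


def holdout_evaluate(
    train_corpus: Union[Corpus, PreprocessedCorpus],
    test_corpus: Union[Corpus, PreprocessedCorpus],
    algorithm: Algorithm,
    inner_k: int = 4,
    seed: int = 0,
) -> EvalReport:
    """Train-on-one-corpus / test-on-another evaluation (e.g. one year of
    records as training set, the next as test set).  Hyper-parameters are
    chosen by cross-validation inside the training corpus only."""
    tr = _as_index(train_corpus).labelled_subset()
    te = _as_index(test_corpus).labelled_subset()
    merged = PreprocessedCorpus.from_corpus  # noqa: F841  (documentation aid)
    # build a joint index so vocabularies are shared between the two corpora
    y_tr = tr.label_array
    joint = _concat_indices(tr, te)
    y = joint.label_array
    train_idx = np.arange(len(y_tr))
    test_idx = np.arange(len(y_tr), len(y))
    best = _inner_search(joint, y, train_idx, algorithm, inner_k, seed)
    c, fit_ids = _fit_eval_once(joint, y, train_idx, test_idx, algorithm, best, seed)
    if fit_ids & frozenset(joint.record_ids[test_idx]):
        raise RuntimeError("leakage audit failed in holdout evaluation")
    fold = FoldResult(confusion=c, metrics=metrics(c), params=best, n_test=len(test_idx))
    return EvalReport(algorithm=algorithm.name, folds=[fold], k=1, repeats=1, seed=seed)


def _concat_indices(a: PreprocessedCorpus, b: PreprocessedCorpus) -> PreprocessedCorpus:
    """Stack two indices; vocabularies are the union, with b's columns remapped."""
    from scipy import sparse

    matrices, vocabularies = {}, {}
    for key, m_a in a.matrices.items():
        vocab_a = a.vocabularies[key]
        vocab_b = b.vocabularies.get(key, [])
        m_b = b.matrices.get(key)
        vocab = list(vocab_a)
        pos = {t: j for j, t in enumerate(vocab)}
        col_map = []
        for t in vocab_b:
            if t not in pos:
                pos[t] = len(vocab)
                vocab.append(t)
            col_map.append(pos[t])
        n_terms = len(vocab)
        m_a_pad = sparse.csr_matrix((m_a.data, m_a.indices, m_a.indptr), shape=(m_a.shape[0], n_terms))
        if m_b is not None and m_b.shape[1] > 0:
            coo = m_b.tocoo()
            m_b_pad = sparse.csr_matrix(
                (coo.data, (coo.row, np.asarray(col_map)[coo.col])), shape=(m_b.shape[0], n_terms)
            )
        else:
            m_b_pad = sparse.csr_matrix((b.n_records, n_terms), dtype=np.int8)
        matrices[key] = sparse.vstack([m_a_pad, m_b_pad]).tocsr()
        vocabularies[key] = vocab
    return PreprocessedCorpus(
        record_ids=np.concatenate([a.record_ids, b.record_ids]),
        labels=np.concatenate([a.labels, b.labels]),
        matrices=matrices,
        vocabularies=vocabularies,
    )


@dataclass(frozen=True)
class WelchResult:
    mean_difference: float
    t_statistic: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float


def mean_difference(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """mean(a) - mean(b); the point estimate reported alongside the test."""
    return float(np.mean(scores_a) - np.mean(scores_b))


def compare_algorithms(
    f3_a: Sequence[float], f3_b: Sequence[float], confidence: float = 0.95
) -> WelchResult:
    """Welch's unequal-variance two-sided t-test on per-fold F3 scores.

    The confidence interval is on mean(a) - mean(b), with the same sign
    convention as ``mean_difference``.  Two identical score vectors give
    t = 0 and p = 1.
    """
    a = np.asarray(f3_a, dtype=float)
    b = np.asarray(f3_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t-test requires at least 2 scores per group")
    diff = mean_difference(a, b)
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if not np.isfinite(t):
        if diff == 0.0:  # both groups constant and equal
            t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
            return WelchResult(diff, t, df, p, 0.0, 0.0)
        raise UndefinedValueError("Welch test undefined: zero variance, nonzero difference")
    ci = res.confidence_interval(confidence_level=confidence)
    return WelchResult(diff, t, df, p, float(ci.low), float(ci.high))


def cohen_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Chance-corrected interrater agreement, (p_o - p_e) / (1 - p_e).

    Expected agreement uses the product of the raters' marginal
    distributions.  Returns NaN when both raters are constant and equal
    (p_e = 1), where kappa is undefined.
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("empty label vectors")
    p_o = float((a == b).mean())
    p_a1, p_b1 = a.mean(), b.mean()
    p_e = p_a1 * p_b1 + (1 - p_a1) * (1 - p_b1)
    if p_e == 1.0:
        return float("nan")
    return (p_o - p_e) / (1 - p_e)


@dataclass(frozen=True)
class ReviewEffort:
    """Chart-review workload under classifier triage.

    Reviewing every record costs ``total_manual_days``; reviewing only the
    classifier-flagged fraction scales the cost linearly.
    """

    flagged_fraction: float
    review_days: float
    reduction: float


def workload_estimate(
    total_records: int, total_manual_days: float, flagged_fraction: float
) -> ReviewEffort:
    """Person-days to review only the flagged records, and the saving."""
    if not (0.0 <= flagged_fraction <= 1.0):
        raise ValueError("flagged_fraction must be in [0, 1]")
    if total_manual_days <= 0:
        raise ValueError("total_manual_days must be positive")
    return ReviewEffort(
        flagged_fraction=flagged_fraction,
        review_days=flagged_fraction * total_manual_days,
        reduction=1.0 - flagged_fraction,
    )
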