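"""Sparse presence index over a preprocessed corpus.

Nested cross-validation re-runs term selection on every inner training
split, so tokenisation and stemming are done once up front and presence is
stored as binary CSR matrices, one per (channel, order).  Row slicing then
makes per-split document frequencies and class-conditional counts cheap
column sums.  The ICD-9 code channel is indexed the same way, with each
code a one-element term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse

from .corpus_io import Corpus, TEXT_FIELDS
from .preprocessing import NGram, record_field_terms

__all__ = ["PreprocessedCorpus", "CHANNELS", "ICD_CHANNEL"]

ICD_CHANNEL = "icd9"
CHANNELS = tuple(TEXT_FIELDS) + (ICD_CHANNEL,)


@dataclass
class PreprocessedCorpus:
    """Immutable presence index; subsets share vocabularies with the parent."""

    record_ids: np.ndarray  # object array of str
    labels: np.ndarray  # float: 1.0, 0.0, or nan for unlabelled
    matrices: dict[tuple[str, int], sparse.csr_matrix]
    vocabularies: dict[tuple[str, int], list[NGram]]
    vocab_index: dict[tuple[str, int], dict[NGram, int]] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.vocab_index is None:
            self.vocab_index = {
                key: {term: j for j, term in enumerate(vocab)}
                for key, vocab in self.vocabularies.items()
            }

    @classmethod
    def from_corpus(
        cls,
        corpus: Corpus,
        orders: Sequence[int] = (1, 2, 3),
        stem_unigrams: bool = True,
    ) -> "PreprocessedCorpus":
        n = len(corpus)
        record_ids = np.array([r.record_id for r in corpus], dtype=object)
        labels = np.array(
            [np.nan if r.label is None else float(r.label) for r in corpus], dtype=float
        )
        matrices: dict[tuple[str, int], sparse.csr_matrix] = {}
        vocabularies: dict[tuple[str, int], list[NGram]] = {}

        for channel in TEXT_FIELDS:
            for order in orders:
                vocab: dict[NGram, int] = {}
                rows, cols = [], []
                for i, rec in enumerate(corpus):
                    for term in record_field_terms(rec, channel, order, stem_unigrams):
                        j = vocab.setdefault(term, len(vocab))
                        rows.append(i)
                        cols.append(j)
                matrices[(channel, order)] = sparse.csr_matrix(
                    (np.ones(len(rows), dtype=np.int8), (rows, cols)),
                    shape=(n, len(vocab)),
                )
                vocabularies[(channel, order)] = list(vocab)

        icd_vocab: dict[NGram, int] = {}
        rows, cols = [], []
        for i, rec in enumerate(corpus):
            code = rec.icd9_code.strip()
            if code:
                j = icd_vocab.setdefault((code,), len(icd_vocab))
                rows.append(i)
                cols.append(j)
        matrices[(ICD_CHANNEL, 1)] = sparse.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, len(icd_vocab))
        )
        vocabularies[(ICD_CHANNEL, 1)] = list(icd_vocab)

        return cls(
            record_ids=record_ids,
            labels=labels,
            matrices=matrices,
            vocabularies=vocabularies,
        )

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    def __len__(self) -> int:
        return self.n_records

    @property
    def label_array(self) -> np.ndarray:
        """Labels as int array; raises if any record is unlabelled."""
        if np.isnan(self.labels).any():
            raise ValueError("corpus contains unlabelled records")
        return self.labels.astype(int)

    def labelled_subset(self) -> "PreprocessedCorpus":
        return self.subset(np.flatnonzero(~np.isnan(self.labels)))

    def subset(self, indices: np.ndarray) -> "PreprocessedCorpus":
        """Row-sliced view sharing vocabularies with the parent index."""
        indices = np.asarray(indices)
        return PreprocessedCorpus(
            record_ids=self.record_ids[indices],
            labels=self.labels[indices],
            matrices={k: m[indices] for k, m in self.matrices.items()},
            vocabularies=self.vocabularies,
            vocab_index=self.vocab_index,
        )

    def presence_column(self, channel: str, order: int, term: NGram) -> np.ndarray:
        """Dense 0/1 presence vector for one term (all zeros if unseen)."""
        j = self.vocab_index[(channel, order)].get(term)
        if j is None:
            return np.zeros(self.n_records, dtype=np.int8)
        return np.asarray(
            self.matrices[(channel, order)][:, j].todense()
        ).ravel().astype(np.int8)
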