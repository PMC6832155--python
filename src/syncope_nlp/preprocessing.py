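"""Text normalisation, tokenisation, stemming, n-grams and document frequencies.

Free-text channels are normalised (lower-case, punctuation stripped to
spaces, digits and accented letters preserved), whitespace-tokenised, and
expanded into unigrams, bigrams and trigrams.  Unigrams are stemmed with
the Italian Snowball algorithm so inflection variants collapse; bigrams and
trigrams are matched on raw tokens.  Document frequency is presence-based:
a term counts once per record-field regardless of multiplicity, matching
the binary feature model used downstream.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

from .corpus_io import Corpus, TEXT_FIELDS
from .stemming import italian_stem

__all__ = [
    "ConfigurationError",
    "NGram",
    "DFTable",
    "normalize_text",
    "tokenize",
    "stem_tokens",
    "extract_ngrams",
    "record_field_terms",
    "document_frequencies",
    "frequency_filter",
]

#: an n-gram is a tuple of 1-3 token strings
NGram = tuple[str, ...]


class ConfigurationError(ValueError):
    """Invalid preprocessing or selection configuration."""


# anything that is not a unicode word character or whitespace, plus the
# underscore (a word character we do not want inside tokens)
_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lower-case, map punctuation to spaces, collapse whitespace.

    Digits survive as tokens (vital signs such as "120/80" become "120 80")
    and accented Italian letters are preserved.
    """
    text = unicodedata.normalize("NFC", text).lower()
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def tokenize(text: str) -> list[str]:
    """Split normalised text on whitespace; never yields empty tokens."""
    return text.split()


def stem_tokens(tokens: Sequence[str], language: str = "italian") -> list[str]:
    """Stem each token with the Snowball algorithm for ``language``."""
    if language != "italian":
        raise ConfigurationError(f"unsupported stemming language: {language!r}")
    return [italian_stem(tok) for tok in tokens]


def extract_ngrams(tokens: Sequence[str], order: int) -> list[NGram]:
    """All contiguous windows of ``order`` tokens, with multiplicity.

    Windows never cross record or field boundaries because tokens come from
    a single field.  A field with t tokens yields max(0, t - order + 1)
    n-grams.
    """
    if order not in (1, 2, 3):
        raise ConfigurationError(f"n-gram order must be 1, 2 or 3, got {order}")
    return [tuple(tokens[i : i + order]) for i in range(len(tokens) - order + 1)]


def record_field_terms(
    record, field: str, order: int, stem_unigrams: bool = True
) -> set[NGram]:
    """Set of n-grams present in one record's field (presence semantics).

    Stemming applies to unigrams only; bigrams and trigrams are raw.
    """
    if field not in TEXT_FIELDS:
        raise ConfigurationError(f"unknown text field {field!r}")
    tokens = tokenize(normalize_text(getattr(record, TEXT_FIELDS[field])))
    if order == 1 and stem_unigrams:
        tokens = stem_tokens(tokens)
    return set(extract_ngrams(tokens, order))


@dataclass
class DFTable:
    """Document frequencies of all n-grams of one order in one field."""

    field: str
    order: int
    counts: dict[NGram, int] = dc_field(default_factory=dict)
    total: int = 0

    def proportion(self, term: NGram) -> float:
        return self.counts.get(term, 0) / self.total if self.total else 0.0


def document_frequencies(
    corpus: Corpus, field: str, order: int, stem_unigrams: bool = True
) -> DFTable:
    """Count, per n-gram, the records whose ``field`` contains it at least once."""
    counts: dict[NGram, int] = {}
    for rec in corpus:
        for term in record_field_terms(rec, field, order, stem_unigrams):
            counts[term] = counts.get(term, 0) + 1
    return DFTable(field=field, order=order, counts=counts, total=len(corpus))


def frequency_filter(table: DFTable, min_df: float, max_df: float) -> set[NGram]:
    """Keep n-grams with min_df <= df/total <= max_df (proportions).

    Rare terms carry no statistical support; near-ubiquitous terms carry no
    discriminative signal.  Both cut-offs are tuned as hyper-parameters.
    """
    if not (0.0 <= min_df <= max_df <= 1.0):
        raise ConfigurationError(
            f"require 0 <= min_df <= max_df <= 1, got min_df={min_df}, max_df={max_df}"
        )
    if table.total == 0:
        return set()
    return {
        term
        for term, count in table.counts.items()
        if min_df <= count / table.total <= max_df
    }
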