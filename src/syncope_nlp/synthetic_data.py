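"""Synthetic emergency-department corpora with known ground truth.

No real EMR corpus ships with this package, so the generator emulates the
shape of the study data: ~30,000 records at ~1.9% syncope prevalence,
three Italian-style free-text channels, class-discriminative planted terms
mixed into background vocabulary, and an ICD-9 code channel whose syncope
code (780.2) is deliberately insensitive — the premise that motivates
free-text classification in the first place.

Background tokens are pronounceable consonant-vowel compounds (not real
Italian) so they can never collide with the clinical lexicon; planted
terms reuse genuine Italian clinical vocabulary so that stemming is
exercised on real inflections ("caduta"/"cadute").  Every draw comes from
one seeded generator, making corpora byte-identical under a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import Corpus, EMRRecord
from .preprocessing import ConfigurationError

__all__ = [
    "PlantedTerm",
    "SynthConfig",
    "GroundTruth",
    "generate_corpus",
    "default_paper_config",
    "inflect",
    "BENIGN_ICD9_CODES",
    "SYNCOPE_CODE",
]

SYNCOPE_CODE = "780.2"
#: plausible non-syncope ED discharge codes (abdominal pain, chest pain,
#: lumbago, cervicalgia, malaise, urinary infection, nausea, injury)
BENIGN_ICD9_CODES = ("789.0", "786.5", "724.2", "723.1", "780.7", "599.0", "787.0", "959.9")


def inflect(term: str) -> str:
    """Italian-style inflection variant of a unigram (number/gender swap).

    Chosen so that variant and base form share a Snowball stem:
    final -a -> -e, final -e/-o -> -i, otherwise append -i.
    """
    if term.endswith("a"):
        return term[:-1] + "e"
    if term.endswith(("e", "o")):
        return term[:-1] + "i"
    return term + "i"


@dataclass(frozen=True)
class PlantedTerm:
    """A term planted with class-conditional inclusion probabilities."""

    term: str
    p_in_positive: float
    p_in_negative: float
    field: str

    def __post_init__(self) -> None:
        for p in (self.p_in_positive, self.p_in_negative):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"invalid probability {p} for term {self.term!r}")
        if self.field not in ("triage", "history", "discharge"):
            raise ConfigurationError(f"unknown field {self.field!r} for term {self.term!r}")


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters of a synthetic EMR corpus."""

    n_records: int
    prevalence: float = 0.019
    vocab_background: int = 500
    planted_terms: tuple[PlantedTerm, ...] = ()
    confounders: tuple[PlantedTerm, ...] = ()
    field_length: float = 12.0
    icd_sensitivity: float = 0.6
    icd_specificity: float = 0.999
    inflection_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ConfigurationError("n_records must be >= 1")
        for name in ("prevalence", "icd_sensitivity", "icd_specificity", "inflection_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for c in self.confounders:
            if c.p_in_positive != c.p_in_negative:
                raise ConfigurationError(
                    f"confounder {c.term!r} must have equal class rates"
                )


@dataclass
class GroundTruth:
    """True labels and the planted vocabulary, per field."""

    labels: np.ndarray
    planted: dict[str, list[str]]
    config: SynthConfig


def default_paper_config(seed: int = 20131201) -> SynthConfig:
    """Study-scale conditions: 30,320 records at 1.9% prevalence, ten
    discriminative terms, three non-discriminative confounders, and an
    ICD-9 channel with 60% sensitivity / 99.9% specificity."""
    planted = (
        PlantedTerm("sincope", 0.6, 0.01, "discharge"),
        PlantedTerm("presincope", 0.6, 0.01, "discharge"),
        PlantedTerm("lipotimia", 0.6, 0.01, "discharge"),
        PlantedTerm("svenimento", 0.6, 0.01, "history"),
        PlantedTerm("caduta", 0.6, 0.01, "history"),
        PlantedTerm("vertigine", 0.6, 0.01, "history"),
        PlantedTerm("ipotensione", 0.6, 0.01, "triage"),
        PlantedTerm("malore", 0.6, 0.01, "triage"),
        PlantedTerm("capogiro", 0.6, 0.01, "triage"),
        PlantedTerm("prodromo", 0.6, 0.01, "triage"),
    )
    confounders = (
        PlantedTerm("dolore", 0.15, 0.15, "triage"),
        PlantedTerm("febbre", 0.15, 0.15, "history"),
        PlantedTerm("paziente", 0.15, 0.15, "discharge"),
    )
    return SynthConfig(
        n_records=30_320,
        prevalence=0.019,
        vocab_background=500,
        planted_terms=planted,
        confounders=confounders,
        field_length=12.0,
        icd_sensitivity=0.6,
        icd_specificity=0.999,
        inflection_rate=0.0,
        seed=seed,
    )


_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]


def _background_vocab(size: int, forbidden: set[str], rng: np.random.Generator) -> list[str]:
    """Pronounceable three-syllable pseudo-words, disjoint from ``forbidden``."""
    vocab: list[str] = []
    seen: set[str] = set(forbidden)
    while len(vocab) < size:
        draws = rng.integers(0, len(_SYLLABLES), size=(size, 3))
        for a, b, c in draws:
            word = _SYLLABLES[a] + _SYLLABLES[b] + _SYLLABLES[c]
            if word not in seen:
                seen.add(word)
                vocab.append(word)
                if len(vocab) == size:
                    break
    return vocab


def generate_corpus(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Sample a labelled corpus and its ground truth.

    Per record: the label is Bernoulli(prevalence); each text field gets a
    Poisson(field_length) stretch of background tokens (at least one) plus
    each planted/confounder term of that field, included independently with
    its class-conditional probability and spliced in at a random position.
    Planted unigrams appear as their inflection variant with probability
    ``inflection_rate``.  Positives carry the ICD-9 code 780.2 with
    probability ``icd_sensitivity``; negatives with ``1 - icd_specificity``;
    otherwise a random benign code.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    fields = ("triage", "history", "discharge")

    all_special = set()
    for t in tuple(config.planted_terms) + tuple(config.confounders):
        for w in t.term.split():
            all_special.add(w)
            all_special.add(inflect(w))
    vocab = np.array(
        _background_vocab(config.vocab_background, all_special, rng), dtype=object
    )

    labels = rng.random(n) < config.prevalence

    # background token streams, one per field
    field_tokens: dict[str, list[list[str]]] = {}
    for fld in fields:
        lengths = np.maximum(rng.poisson(config.field_length, size=n), 1)
        flat = vocab[rng.integers(0, len(vocab), size=int(lengths.sum()))]
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        field_tokens[fld] = [
            list(flat[offsets[i] : offsets[i + 1]]) for i in range(n)
        ]

    # splice planted terms and confounders in
    for planted in tuple(config.planted_terms) + tuple(config.confounders):
        probs = np.where(labels, planted.p_in_positive, planted.p_in_negative)
        include = rng.random(n) < probs
        words = planted.term.split()
        is_unigram = len(words) == 1
        variants = rng.random(n) < config.inflection_rate
        positions = rng.integers(0, 1_000_000, size=n)  # drawn for all rows: keeps
        # the stream layout independent of how many records include the term
        tokens_of = field_tokens[planted.field]
        for i in np.flatnonzero(include):
            toks = tokens_of[i]
            insert = words
            if is_unigram and variants[i]:
                insert = [inflect(words[0])]
            pos = positions[i] % (len(toks) + 1)
            tokens_of[i] = toks[:pos] + list(insert) + toks[pos:]

    # ICD-9 channel
    icd_draw = rng.random(n)
    benign = np.array(BENIGN_ICD9_CODES, dtype=object)[
        rng.integers(0, len(BENIGN_ICD9_CODES), size=n)
    ]
    codes = np.where(
        labels,
        np.where(icd_draw < config.icd_sensitivity, SYNCOPE_CODE, benign),
        np.where(icd_draw < 1.0 - config.icd_specificity, SYNCOPE_CODE, benign),
    )

    ages = rng.integers(18, 96, size=n)

    width = len(str(n))
    records = [
        EMRRecord(
            record_id=f"r{i:0{width}d}",
            encounter_id=f"e{i:0{width}d}",
            age=int(ages[i]),
            icd9_code=str(codes[i]),
            triage_text=" ".join(field_tokens["triage"][i]),
            history_text=" ".join(field_tokens["history"][i]),
            discharge_text=" ".join(field_tokens["discharge"][i]),
            label=bool(labels[i]),
        )
        for i in range(n)
    ]
    corpus = Corpus(records=records, provenance=f"synthetic(seed={config.seed})")
    planted_by_field: dict[str, list[str]] = {f: [] for f in fields}
    for t in config.planted_terms:
        planted_by_field[t.field].append(t.term)
    truth = GroundTruth(labels=labels.astype(int), planted=planted_by_field, config=config)
    return corpus, truth
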