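"""EMR record data model and corpus I/O.

A corpus is an ordered collection of emergency-department records, each with
an ICD-9-CM discharge code, three Italian free-text channels (triage note,
medical-history note, discharge diagnosis), patient age, and an optional
gold label for the presence of syncope.  Records — not patient encounters —
are the classification unit: one record corresponds to a single ICD-9 code,
and one encounter may span several records.

Supported on-disk formats are CSV, TSV (RFC-4180 quoting, UTF-8) and JSON
Lines, all with the same seven required columns plus ``label``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "EMRRecord",
    "Corpus",
    "CorpusFormatError",
    "CorpusIntegrityError",
    "UndefinedValueError",
    "read_corpus",
    "write_corpus",
    "filter_eligible",
    "merge_corpora",
    "prevalence",
    "aggregate_encounters",
    "REQUIRED_COLUMNS",
    "TEXT_FIELDS",
]

REQUIRED_COLUMNS = (
    "record_id",
    "encounter_id",
    "age",
    "icd9_code",
    "triage_text",
    "history_text",
    "discharge_text",
    "label",
)

#: map from text-channel name to the EMRRecord attribute that holds it
TEXT_FIELDS = {
    "triage": "triage_text",
    "history": "history_text",
    "discharge": "discharge_text",
}

_LABEL_TO_STR = {True: "positive", False: "negative", None: ""}
_STR_TO_LABEL = {"positive": True, "negative": False, "": None, "1": True, "0": False}


class CorpusFormatError(ValueError):
    """Input file does not conform to the expected tabular schema."""


class CorpusIntegrityError(ValueError):
    """Corpus-level invariant violated (e.g. duplicate record ids)."""


class UndefinedValueError(ValueError):
    """A requested quantity is undefined for the given input."""


@dataclass(frozen=True)
class EMRRecord:
    """One emergency-department record.

    ``label`` is tri-state: True (syncope present), False (absent), or None
    (unlabelled).  Empty ``icd9_code`` means no code available.
    """

    record_id: str
    encounter_id: str
    age: int
    icd9_code: str = ""
    triage_text: str = ""
    history_text: str = ""
    discharge_text: str = ""
    label: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise CorpusIntegrityError(f"record {self.record_id!r}: negative age {self.age}")
        for name in ("triage_text", "history_text", "discharge_text", "icd9_code"):
            if getattr(self, name) is None:
                raise CorpusIntegrityError(f"record {self.record_id!r}: {name} is null")

    @property
    def is_complete(self) -> bool:
        """At least one of the three text channels is non-empty."""
        return any(getattr(self, attr).strip() for attr in TEXT_FIELDS.values())


@dataclass
class Corpus:
    """Ordered collection of :class:`EMRRecord` with unique record ids."""

    records: list[EMRRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise CorpusIntegrityError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EMRRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.records == other.records

    @property
    def labelled(self) -> list[EMRRecord]:
        return [r for r in self.records if r.label is not None]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": r.record_id,
                "encounter_id": r.encounter_id,
                "age": r.age,
                "icd9_code": r.icd9_code,
                "triage_text": r.triage_text,
                "history_text": r.history_text,
                "discharge_text": r.discharge_text,
                "label": _LABEL_TO_STR[r.label],
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "Corpus":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise CorpusFormatError(f"missing required column(s): {', '.join(missing)}")
        records = []
        for row in df.itertuples(index=False):
            raw_label = getattr(row, "label")
            if raw_label is None or (isinstance(raw_label, float) and pd.isna(raw_label)):
                raw_label = ""
            raw_label = str(raw_label).strip().lower()
            if raw_label not in _STR_TO_LABEL:
                raise CorpusFormatError(
                    f"record {getattr(row, 'record_id')!r}: unrecognised label {raw_label!r}"
                )
            records.append(
                EMRRecord(
                    record_id=str(getattr(row, "record_id")),
                    encounter_id=str(getattr(row, "encounter_id")),
                    age=int(getattr(row, "age")),
                    icd9_code=_clean(getattr(row, "icd9_code")),
                    triage_text=_clean(getattr(row, "triage_text")),
                    history_text=_clean(getattr(row, "history_text")),
                    discharge_text=_clean(getattr(row, "discharge_text")),
                    label=_STR_TO_LABEL[raw_label],
                )
            )
        return cls(records=records, provenance=provenance)


def _clean(value: object) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "tsv", "jsonl"}:
        return suffix
    raise CorpusFormatError(f"cannot infer format from extension of {path}")


def read_corpus(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Read a corpus from a CSV/TSV/JSONL file.

    Raises :class:`CorpusFormatError` if a required column is missing and
    :class:`CorpusIntegrityError` on duplicate record ids.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    elif fmt == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) if not rows else None)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise CorpusFormatError(f"missing required column(s): {', '.join(missing)}")
    else:
        raise CorpusFormatError(f"unsupported format {fmt!r}")
    return Corpus.from_dataframe(df, provenance=str(path))


def write_corpus(corpus: Corpus, path: str | Path, format: Optional[str] = None) -> None:
    """Write a corpus losslessly; ``read_corpus`` round-trips all fields."""
    path = Path(path)
    fmt = _infer_format(path, format)
    df = corpus.to_dataframe()
    if fmt == "csv":
        df.to_csv(path, index=False, encoding="utf-8")
    elif fmt == "tsv":
        df.to_csv(path, index=False, sep="\t", encoding="utf-8")
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in df.to_dict(orient="records"):
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    else:
        raise CorpusFormatError(f"unsupported format {fmt!r}")


def filter_eligible(
    corpus: Corpus, min_age: int = 18, return_report: bool = False
) -> Corpus | tuple[Corpus, dict[str, int]]:
    """Apply the study inclusion criteria: age >= ``min_age`` and data completeness.

    A record is incomplete when all three text channels are empty.  With
    ``return_report=True`` also returns counts of removed records per reason
    (``{"underage": ..., "incomplete": ...}``); the reasons partition the
    removed set, age being checked first.
    """
    kept, report = [], {"underage": 0, "incomplete": 0}
    for rec in corpus:
        if rec.age < min_age:
            report["underage"] += 1
        elif not rec.is_complete:
            report["incomplete"] += 1
        else:
            kept.append(rec)
    out = Corpus(records=kept, provenance=corpus.provenance)
    return (out, report) if return_report else out


def merge_corpora(a: Corpus, b: Corpus) -> Corpus:
    """Concatenate two corpora with disjoint record-id sets."""
    ids_a = {r.record_id for r in a}
    clash = ids_a.intersection(r.record_id for r in b)
    if clash:
        raise CorpusIntegrityError(
            f"record_id collision on merge: {sorted(clash)[:5]}{'...' if len(clash) > 5 else ''}"
        )
    provenance = " + ".join(p for p in (a.provenance, b.provenance) if p)
    return Corpus(records=list(a.records) + list(b.records), provenance=provenance)


def prevalence(corpus: Corpus) -> float:
    """Proportion of positive records among labelled records."""
    labelled = corpus.labelled
    if not labelled:
        raise UndefinedValueError("prevalence undefined: corpus has no labelled records")
    return sum(r.label for r in labelled) / len(labelled)


def aggregate_encounters(corpus: Corpus) -> pd.DataFrame:
    """Encounter-level view: a positive encounter is one with any positive record.

    Helper for encounter-level analyses; the pipeline itself classifies
    records.  Unlabelled records are ignored in the label OR.
    """
    rows = {}
    for rec in corpus:
        entry = rows.setdefault(
            rec.encounter_id, {"encounter_id": rec.encounter_id, "n_records": 0, "label": None}
        )
        entry["n_records"] += 1
        if rec.label is not None:
            entry["label"] = bool(entry["label"]) or rec.label
    return pd.DataFrame(list(rows.values()), columns=["encounter_id", "n_records", "label"])
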