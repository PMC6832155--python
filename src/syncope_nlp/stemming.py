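"""Snowball stemmer for Italian.

Emergency-department notes in this pipeline are Italian free text, and the
manual lexicon is matched on stems so that inflection variants ("caduta",
"cadute") collapse onto a single feature.  This module implements the
Snowball stemming algorithm for Italian: accent normalisation, the three
regions R1/R2/RV, attached-pronoun removal, standard and verb suffix
stripping, and final-vowel deletion.

The implementation is self-contained (pure Python, no model files) and is
exercised in the test suite against hand-traced expected stems for the
clinical lexicon plus algebraic properties (idempotence, inflection
merging).
"""

from __future__ import annotations

from functools import lru_cache

__all__ = ["italian_stem"]

_VOWELS = "aeiouàèìòù"

# acute accents are normalised to grave before any other processing
_ACUTE_TO_GRAVE = str.maketrans("áéíóú", "àèìòù")

_STEP0_SUFFIXES = sorted(
    [
        "ci", "gli", "la", "le", "li", "lo", "mi", "ne", "si", "ti", "vi",
        "sene", "gliela", "gliele", "glieli", "glielo", "gliene",
        "mela", "mele", "meli", "melo", "mene",
        "tela", "tele", "teli", "telo", "tene",
        "cela", "cele", "celi", "celo", "cene",
        "vela", "vele", "veli", "velo", "vene",
    ],
    key=len,
    reverse=True,
)

# step-1 suffix groups; the action applies only when the longest matching
# suffix over ALL groups belongs to that group
_STEP1_DELETE_R2 = [
    "anza", "anze", "ico", "ici", "ica", "ice", "iche", "ichi", "ismo",
    "ismi", "abile", "abili", "ibile", "ibili", "ista", "iste", "isti",
    "istà", "istè", "istì", "oso", "osi", "osa", "ose", "mente",
    "atrice", "atrici", "ante", "anti",
]
_STEP1_AZIONE = ["azione", "azioni", "atore", "atori"]
_STEP1_LOGIA = ["logia", "logie"]
_STEP1_UZIONE = ["uzione", "uzioni", "usione", "usioni"]
_STEP1_ENZA = ["enza", "enze"]
_STEP1_AMENTO = ["amento", "amenti", "imento", "imenti"]
_STEP1_ITA = ["ità"]
_STEP1_IVO = ["ivo", "ivi", "iva", "ive"]

_STEP1_ALL = sorted(
    _STEP1_DELETE_R2
    + _STEP1_AZIONE
    + _STEP1_LOGIA
    + _STEP1_UZIONE
    + _STEP1_ENZA
    + _STEP1_AMENTO
    + ["amente"]
    + _STEP1_ITA
    + _STEP1_IVO,
    key=len,
    reverse=True,
)

_STEP2_SUFFIXES = sorted(
    [
        "ammo", "ando", "ano", "are", "arono", "asse", "assero", "assi",
        "assimo", "ata", "ate", "ati", "ato", "ava", "avamo", "avano",
        "avate", "avi", "avo", "emmo", "enda", "ende", "endi", "endo",
        "erà", "erai", "eranno", "ere", "erebbe", "erebbero", "erei",
        "eremmo", "eremo", "ereste", "eresti", "erete", "erò", "erono",
        "essero", "ete", "eva", "evamo", "evano", "evate", "evi", "evo",
        "Iamo", "iamo", "immo", "irà", "irai", "iranno", "ire", "irebbe",
        "irebbero", "irei", "iremmo", "iremo", "ireste", "iresti",
        "irete", "irò", "irono", "isca", "iscano", "isce", "isci",
        "isco", "iscono", "issero", "ita", "ite", "iti", "ito", "iva",
        "ivamo", "ivano", "ivate", "ivi", "ivo", "ono", "uta", "ute",
        "uti", "uto", "ar", "ir",
    ],
    key=len,
    reverse=True,
)


def _is_vowel(ch: str) -> bool:
    # upper-case I/U are the "marked" non-vowel forms
    return ch in _VOWELS


def _mark_vowels(word: str) -> str:
    """Upper-case u after q, and u/i between vowels, so they act as consonants."""
    chars = list(word)
    for i in range(1, len(chars)):
        if chars[i] == "u" and chars[i - 1] == "q":
            chars[i] = "U"
    for i in range(1, len(chars) - 1):
        if chars[i] in "iu" and _is_vowel(chars[i - 1]) and _is_vowel(chars[i + 1]):
            chars[i] = chars[i].upper()
    return "".join(chars)


def _region_after_vowel_consonant(word: str, start: int) -> int:
    """Index after the first non-vowel following a vowel, scanning from start."""
    n = len(word)
    i = start
    while i < n and not _is_vowel(word[i]):
        i += 1
    while i < n and _is_vowel(word[i]):
        i += 1
    return i + 1 if i < n else n


def _compute_regions(word: str) -> tuple[int, int, int]:
    """Return (rv, r1, r2) start indices for a marked word."""
    n = len(word)
    r1 = _region_after_vowel_consonant(word, 0)
    r2 = _region_after_vowel_consonant(word, r1)

    if n < 2:
        return n, r1, r2
    if _is_vowel(word[0]) and _is_vowel(word[1]):
        # two initial vowels: region after the next consonant
        i = 2
        while i < n and _is_vowel(word[i]):
            i += 1
        rv = i + 1 if i < n else n
    elif not _is_vowel(word[1]):
        # second letter a consonant: region after the next following vowel
        i = 2
        while i < n and not _is_vowel(word[i]):
            i += 1
        rv = i + 1 if i < n else n
    else:
        # consonant-vowel: region after the third letter
        rv = 3 if n > 3 else n
    return rv, r1, r2


def _in_region(word: str, suffix_len: int, region_start: int) -> bool:
    return len(word) - suffix_len >= region_start


def _step0(word: str, rv: int) -> str:
    for suf in _STEP0_SUFFIXES:
        if not word.endswith(suf) or not _in_region(word, len(suf), rv):
            continue
        head = word[: -len(suf)]
        for lead in ("ando", "endo"):
            if head.endswith(lead) and _in_region(word, len(suf) + len(lead), rv):
                return head
        for lead in ("ar", "er", "ir"):
            if head.endswith(lead) and _in_region(word, len(suf) + len(lead), rv):
                return head + "e"
        return word
    return word


def _step1(word: str, rv: int, r1: int, r2: int) -> tuple[str, bool]:
    for suf in _STEP1_ALL:
        if not word.endswith(suf):
            continue
        m = len(suf)
        if suf == "amente":
            if not _in_region(word, m, r1):
                return word, False
            stem = word[:-m]
            if stem.endswith("iv") and _in_region(stem, 2, r2):
                stem = stem[:-2]
                if stem.endswith("at") and _in_region(stem, 2, r2):
                    stem = stem[:-2]
            else:
                for extra in ("os", "ic", "abil"):
                    if stem.endswith(extra) and _in_region(stem, len(extra), r2):
                        stem = stem[: -len(extra)]
                        break
            return stem, True
        if suf in _STEP1_AMENTO:
            if _in_region(word, m, rv):
                return word[:-m], True
            return word, False
        # every remaining group requires the suffix to lie in R2
        if not _in_region(word, m, r2):
            return word, False
        if suf in _STEP1_AZIONE:
            stem = word[:-m]
            if stem.endswith("ic") and _in_region(stem, 2, r2):
                stem = stem[:-2]
            return stem, True
        if suf in _STEP1_LOGIA:
            return word[:-m] + "log", True
        if suf in _STEP1_UZIONE:
            return word[:-m] + "u", True
        if suf in _STEP1_ENZA:
            return word[:-m] + "ente", True
        if suf in _STEP1_ITA:
            stem = word[:-m]
            for extra in ("abil", "ic", "iv"):
                if stem.endswith(extra) and _in_region(stem, len(extra), r2):
                    stem = stem[: -len(extra)]
                    break
            return stem, True
        if suf in _STEP1_IVO:
            stem = word[:-m]
            if stem.endswith("at") and _in_region(stem, 2, r2):
                stem = stem[:-2]
                if stem.endswith("ic") and _in_region(stem, 2, r2):
                    stem = stem[:-2]
            return stem, True
        return word[:-m], True
    return word, False


def _step2(word: str, rv: int) -> str:
    for suf in _STEP2_SUFFIXES:
        if word.endswith(suf):
            if _in_region(word, len(suf), rv):
                return word[: -len(suf)]
            return word
    return word


def _step3(word: str, rv: int) -> str:
    if word and word[-1] in "aeioàèìò" and _in_region(word, 1, rv):
        word = word[:-1]
        if word and word[-1] == "i" and _in_region(word, 1, rv):
            word = word[:-1]
    if (word.endswith("ch") or word.endswith("gh")) and _in_region(word, 2, rv):
        word = word[:-1]
    return word


@lru_cache(maxsize=262144)
def italian_stem(word: str) -> str:
    """Stem a single lower-case Italian token.

    Tokens that contain no alphabetic material (e.g. pure digit strings from
    blood-pressure readings) pass through unchanged apart from accent
    normalisation.
    """
    word = word.lower().translate(_ACUTE_TO_GRAVE)
    if len(word) <= 2:
        return word
    marked = _mark_vowels(word)
    rv, r1, r2 = _compute_regions(marked)
    marked = _step0(marked, rv)
    marked, removed = _step1(marked, rv, r1, r2)
    if not removed:
        marked = _step2(marked, rv)
    marked = _step3(marked, rv)
    return marked.lower()
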