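"""Word lists and lexical distances between languages.

A language is represented by its list of transcribed words for a shared
inventory of basic meanings (a Swadesh-style list). Dissimilarity between
two words a, b is the length-normalized Levenshtein distance

    LDN(a, b) = LD(a, b) / max(|a|, |b|)

which weighs short and long words equally. Two language-level distances are
built from it:

* **LDN** between languages: the mean of LDN(a_i, b_i) over all meanings i
  attested in both lexicons;
* **LDND**: LDN divided by the mean of LDN(a_i, b_j) over all ordered pairs
  of *different* meanings i != j drawn from the same shared-meaning set.
  The cross-meaning normalizer estimates how similar the two orthographies
  look by chance, so LDND corrects for accidental similarity and can exceed
  1 for unrelated languages.

Completeness diagnostics follow the same binary-attestation view of the
data: ``f_i`` is the fraction of languages attesting meaning i, ``g_i`` the
fraction of language pairs sharing it, ``N_eff`` the sum of the f_i of the
retained meanings, and the coverage the mean number of co-attested meanings
over all language pairs.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd

from .errors import (
    DataFormatError,
    DegenerateNormalizerError,
    EmptyInputError,
    NoOverlapError,
)
from .matrix import DistanceMatrix

__all__ = [
    "Lexicon",
    "LanguageInfo",
    "LexicalDataset",
    "read_wordlists",
    "write_wordlists",
    "levenshtein",
    "ldn_word",
    "ldn_language",
    "ldnd_normalizer",
    "ldnd_language",
    "build_distance_matrix",
    "meaning_statistics",
    "select_top_meanings",
    "effective_size",
    "coverage",
]

SYNONYM_RULES = ("first", "min")
METHODS = ("ldn", "ldnd")


# -- data model ---------------------------------------------------------


@dataclass(frozen=True)
class Lexicon:
    """One language's mapping meaning -> ordered tuple of transcriptions.

    Multiple transcriptions for one meaning are synonyms, kept in source
    order; empty synonym lists are not allowed (an unattested meaning is
    simply absent from ``entries``).
    """

    language_id: str
    entries: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for meaning, words in self.entries.items():
            if isinstance(words, str):
                words = (words,)
            words = tuple(str(w).strip() for w in words)
            if not words or any(not w for w in words):
                raise ValueError(
                    f"{self.language_id!r}: empty transcription for {meaning!r}"
                )
            clean[str(meaning)] = words
        object.__setattr__(self, "entries", clean)

    @property
    def meanings(self) -> frozenset[str]:
        return frozenset(self.entries)

    def words(self, meaning: str) -> tuple[str, ...]:
        return self.entries[meaning]


@dataclass(frozen=True)
class LanguageInfo:
    """Optional per-language metadata: classification path and group label."""

    classification: tuple[str, ...] | None = None
    group: str | None = None


@dataclass(frozen=True)
class LexicalDataset:
    """A family of lexicons over a shared, ordered meaning inventory."""

    meanings: tuple[str, ...]
    lexicons: tuple[Lexicon, ...]
    metadata: Mapping[str, LanguageInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "meanings", tuple(str(m) for m in self.meanings))
        object.__setattr__(self, "lexicons", tuple(self.lexicons))
        object.__setattr__(self, "metadata", dict(self.metadata))
        if len(set(self.meanings)) != len(self.meanings):
            raise ValueError("duplicate meaning ids in inventory")
        ids = [lx.language_id for lx in self.lexicons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate language ids")
        inventory = set(self.meanings)
        for lx in self.lexicons:
            extra = lx.meanings - inventory
            if extra:
                raise ValueError(
                    f"{lx.language_id!r} uses meanings outside the inventory: "
                    f"{sorted(extra)}"
                )

    @property
    def n_languages(self) -> int:
        return len(self.lexicons)

    @property
    def n_meanings(self) -> int:
        return len(self.meanings)

    @property
    def languages(self) -> tuple[str, ...]:
        return tuple(lx.language_id for lx in self.lexicons)

    def lexicon(self, language_id: str) -> Lexicon:
        for lx in self.lexicons:
            if lx.language_id == language_id:
                return lx
        raise KeyError(language_id)


# -- word-list I/O ------------------------------------------------------

_TSV_REQUIRED = ("language", "meaning", "word")


def read_wordlists(path, dialect: str = "tsv") -> LexicalDataset:
    """Read a word-list file into a :class:`LexicalDataset`.

    ``dialect="tsv"`` is the canonical format: UTF-8, header columns
    ``language``, ``meaning``, ``word`` and optionally ``classification``
    (a ``>``-separated path string) and ``group``. Rows with an empty
    ``word`` mark the meaning as missing for that language; repeated
    (language, meaning) rows accumulate synonyms in file order.

    ``dialect="asjp-txt"`` is a best-effort reader for ASJP-style flat
    files; see :func:`_read_asjp_txt`.
    """
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "asjp-txt":
        return _read_asjp_txt(path)
    raise ValueError(f"unknown word-list dialect: {dialect!r}")


def _read_tsv(path) -> LexicalDataset:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"word-list TSV is missing required columns: {missing}"
        )
    meanings: list[str] = []
    entries: dict[str, dict[str, list[str]]] = {}
    metadata: dict[str, LanguageInfo] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        lang = str(getattr(row, "language")).strip()
        meaning = str(getattr(row, "meaning")).strip()
        word = str(getattr(row, "word")).strip()
        if not lang or not meaning:
            raise DataFormatError("rows must carry a language and a meaning")
        if lang not in entries:
            entries[lang] = {}
            order.append(lang)
            cls = str(getattr(row, "classification", "")).strip()
            grp = str(getattr(row, "group", "")).strip()
            metadata[lang] = LanguageInfo(
                classification=tuple(
                    p.strip() for p in cls.split(">")
                ) if cls else None,
                group=grp or None,
            )
        if meaning not in meanings:
            meanings.append(meaning)
        if word:  # empty word = attested-missing
            entries[lang].setdefault(meaning, []).append(word)
    if not order:
        raise EmptyInputError("word-list file contains no languages")
    lexicons = tuple(
        Lexicon(lang, {m: tuple(ws) for m, ws in entries[lang].items()})
        for lang in order
    )
    return LexicalDataset(tuple(meanings), lexicons, metadata)


def _read_asjp_txt(path, keep_loans: bool = True) -> LexicalDataset:
    """Best-effort ASJP-style flat-file reader.

    Expected shape: one block per language, the block header being any line
    that does not start with a digit (a language name, optionally followed
    by ``{...}`` metadata that is discarded); each entry line is
    ``<meaning-number> <gloss>\t<forms>`` or ``<meaning-number>\t<forms>``,
    with comma-separated synonym forms. Forms equal to placeholders
    (``XXX``, ``?``, ``0``) are skipped; a leading ``%`` marks a loanword
    and is stripped (entries kept unless ``keep_loans`` is false).
    """
    with open(path, encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    meanings: list[str] = []
    entries: dict[str, dict[str, tuple[str, ...]]] = {}
    order: list[str] = []
    current: str | None = None
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not line[0].isdigit():
            name = line.split("{")[0].strip()
            if name:
                current = name
                if current not in entries:
                    entries[current] = {}
                    order.append(current)
            continue
        if current is None:
            raise DataFormatError("entry line before any language header")
        head, _, forms_part = line.partition("\t")
        if not forms_part:
            parts = line.split(None, 1)
            head, forms_part = parts[0], parts[1] if len(parts) > 1 else ""
        meaning = head.split()[0]
        forms: list[str] = []
        for form in forms_part.split(","):
            form = form.strip()
            loan = form.startswith("%")
            form = form.lstrip("%").strip()
            if not form or form in {"XXX", "?", "0"}:
                continue
            if loan and not keep_loans:
                continue
            forms.append(form)
        if not forms:
            continue
        if meaning not in meanings:
            meanings.append(meaning)
        entries[current][meaning] = tuple(forms)
    if not order:
        raise EmptyInputError("ASJP-style file contains no languages")
    lexicons = tuple(Lexicon(lang, entries[lang]) for lang in order)
    return LexicalDataset(tuple(meanings), lexicons, {})


def write_wordlists(ds: LexicalDataset, path) -> None:
    """Write the canonical word-list TSV (inverse of the ``tsv`` dialect).

    An unattested (language, meaning) pair is written as an explicit
    empty-word row, so both the language order and the meaning-inventory
    order survive the first-appearance reconstruction on re-read.
    """
    rows = []
    for lx in ds.lexicons:
        info = ds.metadata.get(lx.language_id, LanguageInfo())
        cls = " > ".join(info.classification) if info.classification else ""
        grp = info.group or ""
        for meaning in ds.meanings:
            words = lx.entries.get(meaning, ())
            if not words:
                rows.append((lx.language_id, meaning, "", cls, grp))
            for word in words:
                rows.append((lx.language_id, meaning, word, cls, grp))
    df = pd.DataFrame(
        rows, columns=["language", "meaning", "word", "classification", "group"]
    )
    df.to_csv(path, sep="\t", index=False)


# -- word distances -----------------------------------------------------


@lru_cache(maxsize=1 << 18)
def _edit_distance(a: str, b: str) -> int:
    # two-row dynamic programme over code points, unit costs
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions turning one string into the other (code-point units)."""
    return _edit_distance(str(a), str(b))


def ldn_word(a: str, b: str) -> float:
    """Length-normalized Levenshtein distance between two words, in [0, 1]."""
    a, b = str(a), str(b)
    longest = max(len(a), len(b))
    if longest == 0:
        raise ValueError("LDN undefined for two empty strings")
    return _edit_distance(a, b) / longest


def _check_synonym_rule(synonym_rule: str) -> None:
    if synonym_rule not in SYNONYM_RULES:
        raise ValueError(
            f"synonym_rule must be one of {SYNONYM_RULES}, got {synonym_rule!r}"
        )


def _entry_distance(
    words_a: Sequence[str], words_b: Sequence[str], synonym_rule: str
) -> float:
    if synonym_rule == "first":
        return ldn_word(words_a[0], words_b[0])
    return min(ldn_word(wa, wb) for wa in words_a for wb in words_b)


def _shared_meanings(a: Lexicon, b: Lexicon) -> list[str]:
    return [m for m in a.entries if m in b.entries]


def ldn_language(a: Lexicon, b: Lexicon, synonym_rule: str = "first") -> float:
    """Mean LDN over all meanings attested in both lexicons."""
    _check_synonym_rule(synonym_rule)
    shared = _shared_meanings(a, b)
    if not shared:
        raise NoOverlapError(
            f"{a.language_id!r} and {b.language_id!r} share no attested meaning"
        )
    return float(
        np.mean([
            _entry_distance(a.words(m), b.words(m), synonym_rule)
            for m in shared
        ])
    )


def ldnd_normalizer(
    a: Lexicon, b: Lexicon, synonym_rule: str = "first"
) -> float:
    """Mean LDN over ordered cross pairs of *different* shared meanings.

    Estimates the distance two historically unrelated lexicons would show
    by chance, given these orthographies and word-length profiles.
    """
    _check_synonym_rule(synonym_rule)
    shared = _shared_meanings(a, b)
    if len(shared) < 2:
        raise DegenerateNormalizerError(
            f"{a.language_id!r} and {b.language_id!r} share fewer than 2 "
            "meanings; the cross-meaning normalizer is undefined"
        )
    total = 0.0
    count = 0
    for mi, mj in itertools.permutations(shared, 2):
        total += _entry_distance(a.words(mi), b.words(mj), synonym_rule)
        count += 1
    return total / count


def ldnd_language(a: Lexicon, b: Lexicon, synonym_rule: str = "first") -> float:
    """LDND: the language-level LDN divided by the cross-meaning normalizer."""
    numerator = ldn_language(a, b, synonym_rule)
    denominator = ldnd_normalizer(a, b, synonym_rule)
    if denominator == 0.0:
        raise DegenerateNormalizerError(
            f"{a.language_id!r} and {b.language_id!r}: zero cross-meaning "
            "normalizer (all shared words identical)"
        )
    return numerator / denominator


def build_distance_matrix(
    ds: LexicalDataset, method: str = "ldnd", synonym_rule: str = "first"
) -> DistanceMatrix:
    """All pairwise language distances by the chosen method.

    LDN entries lie in [0, 1]; LDND entries are non-negative and hover
    around 1 for unrelated languages.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if ds.n_languages < 3:
        raise EmptyInputError("need at least 3 languages for a distance matrix")
    fn = ldn_language if method == "ldn" else ldnd_language
    n = ds.n_languages
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ds.lexicons[i], ds.lexicons[j]
            try:
                values[i, j] = values[j, i] = fn(a, b, synonym_rule)
            except (NoOverlapError, DegenerateNormalizerError) as exc:
                raise type(exc)(
                    f"cannot compute {method.upper()} for pair "
                    f"({a.language_id!r}, {b.language_id!r}): {exc}"
                ) from exc
    return DistanceMatrix(ds.languages, values)


# -- completeness and coverage ------------------------------------------


def _attestation_counts(ds: LexicalDataset) -> np.ndarray:
    return np.array([
        sum(1 for lx in ds.lexicons if m in lx.entries) for m in ds.meanings
    ])


def meaning_statistics(ds: LexicalDataset) -> pd.DataFrame:
    """Per-meaning attestation fractions, ranked.

    ``f``: fraction of languages attesting the meaning; ``g``: fraction of
    language pairs in which both attest it. Rows are sorted by ``f``
    descending; ties keep inventory order.
    """
    if ds.n_languages < 2:
        raise EmptyInputError("meaning statistics need at least 2 languages")
    counts = _attestation_counts(ds)
    n_pairs = comb(ds.n_languages, 2)
    df = pd.DataFrame({
        "meaning": ds.meanings,
        "f": counts / ds.n_languages,
        "g": [comb(int(k), 2) / n_pairs for k in counts],
    })
    return (
        df.sort_values("f", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def select_top_meanings(ds: LexicalDataset, n: int) -> LexicalDataset:
    """Restrict the dataset to the n most widely attested meanings.

    Ranking is by ``f`` descending with ties broken by inventory order; the
    retained meanings keep their original inventory order.
    """
    if not 1 <= n <= ds.n_meanings:
        raise ValueError(
            f"n must be in [1, {ds.n_meanings}], got {n}"
        )
    ranked = meaning_statistics(ds)["meaning"].tolist()
    keep = set(ranked[:n])
    meanings = tuple(m for m in ds.meanings if m in keep)
    lexicons = tuple(
        Lexicon(
            lx.language_id,
            {m: ws for m, ws in lx.entries.items() if m in keep},
        )
        for lx in ds.lexicons
    )
    return LexicalDataset(meanings, lexicons, ds.metadata)


def effective_size(ds: LexicalDataset) -> float:
    """N_eff: sum of the attestation fractions f over the inventory.

    Equals the inventory size M exactly when every language attests every
    meaning; smaller otherwise.
    """
    if ds.n_meanings == 0 or ds.n_languages == 0:
        return 0.0
    return float((_attestation_counts(ds) / ds.n_languages).sum())


def coverage(ds: LexicalDataset) -> float:
    """Mean number of co-attested meanings over all unordered language pairs.

    Each language is encoded as a 0/1 attestation vector over the
    inventory; the coverage is the average dot product between pairs, with
    theoretical maximum M (complete attestation).
    """
    if ds.n_languages < 2:
        raise EmptyInputError("coverage needs at least 2 languages")
    vectors = np.array([
        [1 if m in lx.entries else 0 for m in ds.meanings]
        for lx in ds.lexicons
    ])
    overlaps = [
        int(vectors[i] @ vectors[j])
        for i in range(len(vectors))
        for j in range(i + 1, len(vectors))
    ]
    return float(np.mean(overlaps))
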