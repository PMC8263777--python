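"""System organ class vocabulary and the two-level adverse-event term hierarchy.

Adverse events in spontaneous-report databases are coded with MedDRA-style
terms at two levels: preferred terms (PTs) and lowest level terms (LLTs),
where each LLT rolls up to exactly one PT and each PT carries one *primary*
system organ class (SOC). The analysis universe is the fixed set of 27 SOCs;
its ordering defines the column order of every downstream count matrix and
Z-score vector.

The real dictionary is licensed, so this module reads a plain tab-separated
dialect (``term_text, level, parent_pt, primary_soc``) that any fixture or
in-house export can produce.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import (
    DictionaryError,
    DuplicateEntryError,
    EmptyTermError,
    FormatError,
    VocabularySizeError,
)

N_SOC = 27

#: Marker returned for reaction terms absent from the dictionary. Callers
#: drop and count these; an unmapped term is a value, never an error.
UNMAPPED = None

_WS = re.compile(r"\s+")
_STRIP_CHARS = string.punctuation + string.whitespace


def normalize_term(raw: str) -> str:
    """Normalize free text to a dictionary key.

    Case-folds, collapses internal whitespace, and strips surrounding
    punctuation. Idempotent: ``normalize_term(normalize_term(x)) ==
    normalize_term(x)``.

    Raises
    ------
    EmptyTermError
        If the input is empty, or empty after normalization.
    """
    if raw is None or not raw.strip():
        raise EmptyTermError("cannot normalize an empty term")
    out = _WS.sub(" ", raw.casefold()).strip(_STRIP_CHARS)
    if not out:
        raise EmptyTermError(f"term {raw!r} is empty after normalization")
    return out


@dataclass(frozen=True)
class SOCEntry:
    soc_code: str
    soc_name: str
    abbreviation: str


@dataclass(frozen=True)
class SOCVocabulary:
    """Ordered universe of the 27 system organ classes.

    The order of ``entries`` is fixed at load time and indexes every count
    vector and Z-score vector in the pipeline.
    """

    entries: tuple[SOCEntry, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.entries) != N_SOC:
            raise VocabularySizeError(
                f"SOC vocabulary must have exactly {N_SOC} entries, "
                f"got {len(self.entries)}"
            )
        codes = [e.soc_code for e in self.entries]
        abbrs = [e.abbreviation for e in self.entries]
        for name, values in (("soc_code", codes), ("abbreviation", abbrs)):
            seen: set[str] = set()
            for v in values:
                if v in seen:
                    raise DuplicateEntryError(f"duplicate {name}: {v!r}")
                seen.add(v)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(codes)})

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.soc_code for e in self.entries)

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(e.abbreviation for e in self.entries)

    def index(self, soc_code: str) -> int:
        return self._index[soc_code]

    def __contains__(self, soc_code: object) -> bool:
        return soc_code in self._index

    def __len__(self) -> int:
        return N_SOC


def load_soc_vocabulary(path: str | Path | None = None) -> SOCVocabulary:
    """Load the 27-SOC vocabulary from a TSV, defaulting to the packaged table.

    The file must carry columns ``soc_code, soc_name, abbreviation``.
    """
    if path is None:
        src = resources.files("socsafety.data").joinpath("soc27.tsv")
        with resources.as_file(src) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"soc_code", "soc_name", "abbreviation"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"SOC table must have columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    entries = tuple(
        SOCEntry(r.soc_code, r.soc_name, r.abbreviation)
        for r in frame.itertuples(index=False)
    )
    return SOCVocabulary(entries)


@dataclass(frozen=True)
class MedDRATerm:
    """One dictionary term: a PT with a primary SOC, or an LLT with a parent PT."""

    term_text: str  # normalized key
    level: str  # "LLT" or "PT"
    parent_pt: Optional[str]  # normalized PT key; None iff level == "PT"
    primary_soc: Optional[str]  # SOC code; None for LLTs (resolved via parent)


class MedDRADictionary:
    """Two-level LLT→PT→primary-SOC hierarchy, closed under parent lookup."""

    def __init__(
        self,
        terms: Iterable[MedDRATerm],
        version_label: str = "fixture",
        vocab: SOCVocabulary | None = None,
    ) -> None:
        self.version_label = version_label
        self.terms: dict[str, MedDRATerm] = {}
        for t in terms:
            if t.term_text in self.terms:
                raise DuplicateEntryError(
                    f"duplicate dictionary term: {t.term_text!r}"
                )
            self.terms[t.term_text] = t
        self._validate(vocab)

    def _validate(self, vocab: SOCVocabulary | None) -> None:
        for t in self.terms.values():
            if t.level == "PT":
                if t.primary_soc is None:
                    raise DictionaryError(f"PT {t.term_text!r} lacks a primary SOC")
                if t.parent_pt is not None:
                    raise DictionaryError(f"PT {t.term_text!r} has a parent")
                if vocab is not None and t.primary_soc not in vocab:
                    raise DictionaryError(
                        f"PT {t.term_text!r} maps to unknown SOC {t.primary_soc!r}"
                    )
            elif t.level == "LLT":
                if t.parent_pt is None:
                    raise DictionaryError(f"LLT {t.term_text!r} lacks a parent PT")
                parent = self.terms.get(t.parent_pt)
                if parent is None or parent.level != "PT":
                    raise DictionaryError(
                        f"LLT {t.term_text!r} parent {t.parent_pt!r} "
                        "does not resolve to a PT"
                    )
            else:
                raise DictionaryError(
                    f"term {t.term_text!r} has unknown level {t.level!r}"
                )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, normalized_term: object) -> bool:
        return normalized_term in self.terms

    @classmethod
    def load(
        cls,
        path: str | Path,
        vocab: SOCVocabulary | None = None,
        version_label: str | None = None,
    ) -> "MedDRADictionary":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"term_text", "level", "parent_pt", "primary_soc"}
        if not required.issubset(frame.columns):
            raise FormatError(
                f"dictionary must have columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        terms = [
            MedDRATerm(
                term_text=normalize_term(r.term_text),
                level=r.level,
                parent_pt=normalize_term(r.parent_pt) if r.parent_pt else None,
                primary_soc=r.primary_soc or None,
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(terms, version_label or str(path), vocab)

    def write(self, path: str | Path) -> None:
        rows = [
            {
                "term_text": t.term_text,
                "level": t.level,
                "parent_pt": t.parent_pt or "",
                "primary_soc": t.primary_soc or "",
            }
            for t in self.terms.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def map_term_to_soc(term: str, dictionary: MedDRADictionary) -> Optional[str]:
    """Resolve a verbatim reaction term to its primary SOC code.

    A PT resolves directly to its primary SOC; an LLT resolves through its
    parent PT. Terms absent from the dictionary return :data:`UNMAPPED`
    (``None``) — the caller discards and counts them.
    """
    try:
        key = normalize_term(term)
    except EmptyTermError:
        return UNMAPPED
    t = dictionary.terms.get(key)
    if t is None:
        return UNMAPPED
    if t.level == "LLT":
        t = dictionary.terms[t.parent_pt]  # validated at load: always a PT
    return t.primary_soc
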