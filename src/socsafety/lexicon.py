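"""Drug lexicon: canonical drugs, synonym matching, and ATC classes.

Drug names in trial registries and spontaneous reports are free text — trade
names, active ingredients, abbreviations, with dose and form tacked on.
Matching is whole-token: a synonym fires only when its token sequence occurs
contiguously in the tokenized text, so "chloroquine" never fires inside
"hydroxychloroquine".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import AtcFormatError, EmptyTermError, FormatError, SynonymCollisionError
from .vocab import normalize_term

_TOKEN = re.compile(r"[a-z0-9]+")

# Valid ATC shapes: 1-letter anatomical group and the standard prefixes up to
# the full 7-character code (letter, 2 digits, 2 letters, 2 digits).
_ATC = re.compile(
    r"^[a-z]$|^[a-z]\d{2}$|^[a-z]\d{2}[a-z]$|^[a-z]\d{2}[a-z]{2}$|^[a-z]\d{2}[a-z]{2}\d{2}$",
    re.IGNORECASE,
)


def tokenize(text: str) -> tuple[str, ...]:
    """Normalize and split text into lowercase alphanumeric tokens."""
    try:
        norm = normalize_term(text)
    except EmptyTermError:
        return ()
    return tuple(_TOKEN.findall(norm))


def atc_class_of(atc_code: str) -> str:
    """Return the single-letter anatomical main group of an ATC code.

    Partial codes that are valid prefixes of the 7-character pattern are
    accepted ("J01", "J01FA"); anything else raises :class:`AtcFormatError`.
    """
    code = (atc_code or "").strip()
    if not _ATC.match(code):
        raise AtcFormatError(f"not a valid ATC code or prefix: {atc_code!r}")
    return code[0].upper()


@dataclass(frozen=True)
class DrugEntry:
    drug_id: str
    preferred_name: str
    synonyms: frozenset[str]  # normalized; always contains preferred_name
    atc_codes: frozenset[str]  # 1- to 7-character validated codes; may be empty

    def atc_classes(self) -> frozenset[str]:
        """Distinct first-letter classes; duplicates collapse to one membership."""
        return frozenset(atc_class_of(c) for c in self.atc_codes)


class DrugLexicon:
    """Collection of drugs with an inverted synonym-token index.

    A synonym mapping to two different drugs is a load-time error: a wrong
    drug assignment would corrupt every downstream count.
    """

    def __init__(self, entries: list[DrugEntry], version_tag: str = "fixture") -> None:
        self.version_tag = version_tag
        self.entries: dict[str, DrugEntry] = {}
        # synonym token-tuple -> drug_id, plus a first-token index for scanning
        self._syn_owner: dict[tuple[str, ...], str] = {}
        self._by_first: dict[str, list[tuple[tuple[str, ...], str]]] = {}
        for e in entries:
            if e.drug_id in self.entries:
                raise SynonymCollisionError(f"duplicate drug_id {e.drug_id!r}")
            if not e.synonyms:
                raise FormatError(f"drug {e.drug_id!r} has no synonyms")
            self.entries[e.drug_id] = e
            for syn in e.synonyms:
                toks = tuple(_TOKEN.findall(syn))
                if not toks:
                    continue
                owner = self._syn_owner.get(toks)
                if owner is not None and owner != e.drug_id:
                    raise SynonymCollisionError(
                        f"synonym {syn!r} maps to both {owner!r} and {e.drug_id!r}"
                    )
                self._syn_owner[toks] = e.drug_id
                self._by_first.setdefault(toks[0], []).append((toks, e.drug_id))
        # longest synonym first so span attribution is stable when synonyms of
        # the same drug overlap
        for lst in self._by_first.values():
            lst.sort(key=lambda p: len(p[0]), reverse=True)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, drug_id: str) -> DrugEntry:
        return self.entries[drug_id]

    def __iter__(self):
        return iter(self.entries.values())

    @classmethod
    def load(cls, path: str | Path, version_tag: str | None = None) -> "DrugLexicon":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"drug_id", "preferred_name", "synonyms", "atc_codes"}
        if not required.issubset(frame.columns):
            raise FormatError(
                f"lexicon must have columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        entries = []
        for r in frame.itertuples(index=False):
            syns = {normalize_term(s) for s in r.synonyms.split("|") if s.strip()}
            syns.add(normalize_term(r.preferred_name))
            codes = {c.strip() for c in r.atc_codes.split("|") if c.strip()}
            for c in codes:
                atc_class_of(c)  # validates; raises AtcFormatError
            entries.append(
                DrugEntry(
                    drug_id=r.drug_id,
                    preferred_name=r.preferred_name,
                    synonyms=frozenset(syns),
                    atc_codes=frozenset(codes),
                )
            )
        return cls(entries, version_tag or str(path))

    def write(self, path: str | Path) -> None:
        rows = [
            {
                "drug_id": e.drug_id,
                "preferred_name": e.preferred_name,
                "synonyms": "|".join(sorted(e.synonyms)),
                "atc_codes": "|".join(sorted(e.atc_codes)),
            }
            for e in self.entries.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def match_drug(free_text: str, lexicon: DrugLexicon) -> set[str]:
    """Return drug_ids whose synonyms occur as whole-token runs in the text.

    "Hydroxychloroquine Sulfate 200 mg" matches a lexicon synonym
    "hydroxychloroquine sulfate"; "chloroquine" does not fire inside
    "hydroxychloroquine" because matching is on whole tokens. Returns the
    empty set when nothing matches.
    """
    toks = tokenize(free_text)
    hits: set[str] = set()
    for i, tok in enumerate(toks):
        for syn_toks, drug_id in lexicon._by_first.get(tok, ()):
            if toks[i : i + len(syn_toks)] == syn_toks:
                hits.add(drug_id)
    return hits
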