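"""Spontaneous-report ingest: join, completeness filter, dedup, suspect filter.

Quarterly FAERS-style releases split each case across three delimited ASCII
tables — demographics, drug mentions, reactions — joined on (case id, case
version). Spontaneous reporting being what it is, the stream contains
duplicate submissions of the same case and incomplete reports; both are
removed before counting. Only drugs the reporter flagged as primary (PS) or
secondary (SS) suspect enter the analysis, and each retained report
contributes one record per (suspect drug, mapped reaction) pair — the
drug-event combination is the unit of counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .lexicon import DrugLexicon, match_drug
from .vocab import (
    UNMAPPED,
    EmptyTermError,
    MedDRADictionary,
    SOCVocabulary,
    map_term_to_soc,
    normalize_term,
)
from .errors import FormatError

logger = logging.getLogger(__name__)

ROLES = frozenset({"PS", "SS", "C", "I"})
SUSPECT_ROLES = frozenset({"PS", "SS"})

FEMALE = "female"
MALE = "male"
SEX_EXCLUDED = "excluded"  # missing/unknown/other sex codes: kept overall,
# excluded from the per-sex tables

DEMO_COLUMNS = ("caseid", "caseversion", "sex")
DRUG_COLUMNS = ("caseid", "caseversion", "role_cod", "drugname")
REAC_COLUMNS = ("caseid", "caseversion", "pt")


@dataclass(frozen=True)
class DrugMention:
    verbatim_name: str
    role: str  # PS | SS | C | I


@dataclass
class CaseReport:
    case_id: Optional[str]
    case_version: int
    sex_code: Optional[str]
    drug_mentions: list[DrugMention]
    reactions: list[str]

    @property
    def is_complete(self) -> bool:
        """Complete ⇔ case id present AND ≥1 drug mention AND ≥1 reaction."""
        return bool(self.case_id) and bool(self.drug_mentions) and bool(self.reactions)


@dataclass(frozen=True)
class DrugEventRecord:
    drug_id: str
    soc_code: str
    sex_stratum: str  # female | male | excluded
    case_id: Optional[str]


@dataclass
class ReadResult:
    reports: list[CaseReport]
    n_malformed_rows: int = 0


@dataclass
class ExplodeCounters:
    n_unmapped_reactions: int = 0
    n_unmatched_drug_names: int = 0


def _read_table(path: str | Path, columns: tuple[str, ...], delimiter: str):
    """Yield rows of a $-delimited (or TSV) table; malformed rows are counted.

    The dialect has no quoting and fields never contain the delimiter, so a
    plain split is the whole parser.
    """
    n_malformed = 0
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        if tuple(header) != columns:
            raise FormatError(
                f"{path}: expected header {columns}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) != len(columns):
                n_malformed += 1
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                continue
            rows.append(fields)
    return rows, n_malformed


def read_reports(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    delimiter: str = "$",
) -> ReadResult:
    """Join the three report tables on (case id, case version) into CaseReports.

    A key present in one table but not another yields an incomplete report,
    not an error; rows with a non-integer version, an unknown role code, or
    the wrong field count are skipped and counted.
    """
    demo_rows, bad_d = _read_table(demo_path, DEMO_COLUMNS, delimiter)
    drug_rows, bad_g = _read_table(drug_path, DRUG_COLUMNS, delimiter)
    reac_rows, bad_r = _read_table(reac_path, REAC_COLUMNS, delimiter)
    n_malformed = bad_d + bad_g + bad_r

    def key_of(caseid: str, caseversion: str):
        try:
            return caseid, int(caseversion)
        except ValueError:
            return None

    sex: dict[tuple, str] = {}
    mentions: dict[tuple, list[DrugMention]] = {}
    reactions: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    seen: set[tuple] = set()

    def note(key: tuple) -> None:
        if key not in seen:
            seen.add(key)
            order.append(key)

    for caseid, caseversion, sx in demo_rows:
        key = key_of(caseid, caseversion)
        if key is None:
            n_malformed += 1
            continue
        note(key)
        sex.setdefault(key, sx)
    for caseid, caseversion, role, name in drug_rows:
        key = key_of(caseid, caseversion)
        if key is None or role not in ROLES:
            n_malformed += 1
            continue
        note(key)
        mentions.setdefault(key, []).append(DrugMention(name, role))
    for caseid, caseversion, pt in reac_rows:
        key = key_of(caseid, caseversion)
        if key is None:
            n_malformed += 1
            continue
        note(key)
        if pt:
            reactions.setdefault(key, []).append(pt)

    reports = [
        CaseReport(
            case_id=key[0] or None,
            case_version=key[1],
            sex_code=sex.get(key) or None,
            drug_mentions=mentions.get(key, []),
            reactions=reactions.get(key, []),
        )
        for key in order
    ]
    return ReadResult(reports=reports, n_malformed_rows=n_malformed)


def drop_incomplete(reports: Iterable[CaseReport]) -> tuple[list[CaseReport], int]:
    """Remove reports lacking a case id, a drug name, or any adverse event."""
    reports = list(reports)
    kept = [r for r in reports if r.is_complete]
    return kept, len(reports) - len(kept)


def _dedup_key(report: CaseReport):
    drugs = frozenset(normalize_term(m.verbatim_name) for m in report.drug_mentions)
    reacs = frozenset(normalize_term(t) for t in report.reactions)
    return report.case_id, drugs, reacs


def deduplicate(reports: Iterable[CaseReport]) -> tuple[list[CaseReport], int]:
    """Keep only the latest version of duplicate submissions.

    Reports are grouped by (case id, normalized drug-name set, normalized
    reaction set); within a group only the highest case version survives.
    Ties on version keep the report appearing last in input order, with a
    warning. Idempotent.
    """
    reports = list(reports)
    best: dict[tuple, tuple[int, int]] = {}  # key -> (version, input position)
    for pos, r in enumerate(reports):
        key = _dedup_key(r)
        cur = best.get(key)
        if cur is None or r.case_version > cur[0]:
            best[key] = (r.case_version, pos)
        elif r.case_version == cur[0]:
            logger.warning(
                "tied case_version %d for case %s; keeping last occurrence",
                r.case_version,
                r.case_id,
            )
            best[key] = (r.case_version, pos)
    keep_pos = sorted(pos for _, pos in best.values())
    kept = [reports[pos] for pos in keep_pos]
    return kept, len(reports) - len(kept)


def explode_suspect_events(
    reports: Iterable[CaseReport],
    lexicon: DrugLexicon,
    dictionary: MedDRADictionary,
    vocab: SOCVocabulary,
) -> tuple[list[DrugEventRecord], ExplodeCounters]:
    """Expand cleaned reports into (drug, SOC) event records.

    For each report: every suspect-role (PS/SS) drug mention is resolved via
    the lexicon, every reaction via the dictionary to its primary SOC, and one
    record is emitted per (matched drug × mapped reaction). A drug mentioned
    as both PS and SS counts once; identical reactions within one report
    collapse to one. Unmapped reactions and unmatched suspect names are
    dropped and counted. Sex stratum is female/male for the F/M codes; all
    other codes are kept in the overall stream but excluded from sex tables.
    """
    counters = ExplodeCounters()
    records: list[DrugEventRecord] = []
    for report in reports:
        drug_ids: set[str] = set()
        for m in report.drug_mentions:
            if m.role not in SUSPECT_ROLES:
                continue
            hits = match_drug(m.verbatim_name, lexicon)
            if not hits:
                counters.n_unmatched_drug_names += 1
            drug_ids |= hits
        # unique normalized reactions, input order preserved
        unique_reactions: dict[str, None] = {}
        for raw in report.reactions:
            try:
                unique_reactions.setdefault(normalize_term(raw))
            except EmptyTermError:
                counters.n_unmapped_reactions += 1
        socs: list[str] = []
        for term in unique_reactions:
            soc = map_term_to_soc(term, dictionary)
            if soc is UNMAPPED:
                counters.n_unmapped_reactions += 1
            elif soc not in vocab:
                raise FormatError(f"dictionary SOC {soc!r} not in vocabulary")
            else:
                socs.append(soc)
        if report.sex_code == "F":
            stratum = FEMALE
        elif report.sex_code == "M":
            stratum = MALE
        else:
            stratum = SEX_EXCLUDED
        for drug_id in sorted(drug_ids):
            for soc in socs:
                records.append(
                    DrugEventRecord(drug_id, soc, stratum, report.case_id)
                )
    return records, counters
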