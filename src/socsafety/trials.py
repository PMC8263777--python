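"""Clinical-trials registry ingest: status filtering and drug resolution.

The registry export is a CSV with one row per trial; the "Interventions"
cell packs entries of the form ``Type: description`` separated by ``|``.
Trials marked withdrawn, suspended or terminated are excluded, then only
trials listing at least one Drug intervention are kept, and each Drug
description is resolved against the lexicon. A trial counts once per matched
drug no matter how many of its interventions mention it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError
from .lexicon import DrugLexicon, match_drug

EXCLUDED_STATUS_PREFIXES = ("withdrawn", "suspended", "terminated")


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    recruitment_status: str
    interventions: tuple[tuple[str, str], ...]  # (type, description)


@dataclass
class DrugTrialAssignment:
    drug_id: str
    trial_ids: set[str] = field(default_factory=set)

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)


def parse_interventions(cell: str) -> tuple[tuple[str, str], ...]:
    """Split an Interventions cell into (type, description) pairs.

    Entries lacking a ``Type:`` prefix are kept with type ``""`` (unknown);
    they never satisfy the Drug filter.
    """
    out = []
    for part in (cell or "").split("|"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            typ, _, desc = part.partition(":")
            out.append((typ.strip(), desc.strip()))
        else:
            out.append(("", part))
    return tuple(out)


def read_trials(
    path: str | Path,
    id_column: str = "trial_id",
    status_column: str = "status",
    interventions_column: str = "interventions",
) -> list[TrialRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (id_column, status_column, interventions_column):
        if col not in frame.columns:
            raise FormatError(f"trials CSV lacks column {col!r}")
    return [
        TrialRecord(
            trial_id=row[id_column],
            recruitment_status=row[status_column],
            interventions=parse_interventions(row[interventions_column]),
        )
        for _, row in frame.iterrows()
    ]


def is_status_excluded(status: str) -> bool:
    """True for withdrawn/suspended/terminated statuses (leading-word match)."""
    return status.strip().casefold().startswith(EXCLUDED_STATUS_PREFIXES)


_status_excluded = is_status_excluded


def filter_trials(records: Iterable[TrialRecord]) -> list[TrialRecord]:
    """Drop withdrawn/suspended/terminated trials, then non-drug trials.

    Status matching is case-insensitive on the leading word, so composite
    statuses like "Terminated (halted)" are excluded too; any other status
    passes through. Idempotent.
    """
    kept = [r for r in records if not _status_excluded(r.recruitment_status)]
    return [
        r
        for r in kept
        if any(typ.casefold() == "drug" for typ, _ in r.interventions)
    ]


def assign_drugs(
    records: Sequence[TrialRecord],
    lexicon: DrugLexicon,
) -> tuple[list[DrugTrialAssignment], int]:
    """Resolve Drug interventions to lexicon drugs.

    Returns assignments sorted by drug_id plus the number of trials whose
    Drug interventions matched nothing in the lexicon (excluded from
    assignments but reported — e.g. agents outside the lexicon's coverage).
    Output is independent of input record order.
    """
    by_drug: dict[str, set[str]] = {}
    n_unmatched_trials = 0
    for rec in records:
        matched: set[str] = set()
        for typ, desc in rec.interventions:
            if typ.casefold() != "drug":
                continue
            matched |= match_drug(desc, lexicon)
        if matched:
            for drug_id in matched:
                by_drug.setdefault(drug_id, set()).add(rec.trial_id)
        else:
            n_unmatched_trials += 1
    assignments = [
        DrugTrialAssignment(drug_id, by_drug[drug_id]) for drug_id in sorted(by_drug)
    ]
    return assignments, n_unmatched_trials


def trial_count_histogram(
    assignments: Iterable[DrugTrialAssignment],
) -> tuple[int, int, int, int]:
    """Bin drugs by trial count: tested in 1, 2, 3, and >3 trials."""
    bins = [0, 0, 0, 0]
    for a in assignments:
        n = a.n_trials
        if n == 1:
            bins[0] += 1
        elif n == 2:
            bins[1] += 1
        elif n == 3:
            bins[2] += 1
        elif n > 3:
            bins[3] += 1
    return tuple(bins)  # type: ignore[return-value]


def assignments_frame(assignments: Iterable[DrugTrialAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug_id": a.drug_id,
                "n_trials": a.n_trials,
                "trial_ids": "|".join(sorted(a.trial_ids)),
            }
            for a in assignments
        ],
        columns=["drug_id", "n_trials", "trial_ids"],
    )
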