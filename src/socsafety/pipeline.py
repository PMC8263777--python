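"""End-to-end orchestration: ingest → clean → map → profile → Z tables.

Every stage's in/out counts are collected into a run summary so the
cleaning/matching funnel is machine-checkable on any input (input reports =
surviving + incomplete-dropped + duplicates-removed, records = female + male
+ sex-excluded, and so on).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import faers, trials, zscore
from .errors import ConfigError
from .lexicon import DrugLexicon
from .simulate import SimulationConfig
from .vocab import MedDRADictionary, SOCVocabulary, load_soc_vocabulary

STRATA = ("overall", "female", "male")


class InputPaths(BaseModel):
    trials: Optional[str] = None
    demo: str
    drug: str
    reac: str
    dictionary: str
    lexicon: str
    soc_vocab: Optional[str] = None  # None -> packaged 27-SOC table


class PipelineConfig(BaseModel):
    """Single structured config for the CLI subcommands."""

    inputs: Optional[InputPaths] = None
    delimiter: str = "$"
    trial_id_column: str = "trial_id"
    trial_status_column: str = "status"
    trial_interventions_column: str = "interventions"
    sd_ddof: int = Field(default=0, ge=0, le=1)  # 0: divisor 27; 1: divisor 26
    stratify: bool = True
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)


@dataclass
class PipelineResult:
    vocab: SOCVocabulary
    lexicon: DrugLexicon
    dictionary: MedDRADictionary
    reports: list  # cleaned CaseReports
    records: list  # DrugEventRecords
    profiles: dict[str, list]  # stratum -> [SOCProfile]
    trial_assignments: list = field(default_factory=list)
    trial_histogram: tuple = (0, 0, 0, 0)
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    vocab: SOCVocabulary | None = None,
) -> PipelineResult:
    """Run every stage on the configured inputs and account for every record."""
    if config.inputs is None:
        raise ConfigError("pipeline config has no inputs section")
    paths = config.inputs
    vocab = vocab or load_soc_vocabulary(paths.soc_vocab)
    lexicon = DrugLexicon.load(paths.lexicon)
    dictionary = MedDRADictionary.load(paths.dictionary, vocab=vocab)
    summary: dict = {}

    # --- clinical trials ----------------------------------------------------
    assignments: list = []
    histogram: tuple = (0, 0, 0, 0)
    if paths.trials:
        trial_records = trials.read_trials(
            paths.trials,
            id_column=config.trial_id_column,
            status_column=config.trial_status_column,
            interventions_column=config.trial_interventions_column,
        )
        n_read = len(trial_records)
        status_kept = [
            r for r in trial_records if not trials.is_status_excluded(r.recruitment_status)
        ]
        filtered = trials.filter_trials(trial_records)
        assignments, n_unmatched = trials.assign_drugs(filtered, lexicon)
        histogram = trials.trial_count_histogram(assignments)
        summary["trials"] = {
            "n_read": n_read,
            "n_excluded_status": n_read - len(status_kept),
            "n_excluded_no_drug_intervention": len(status_kept) - len(filtered),
            "n_unmatched_trials": n_unmatched,
            "n_trials_assigned": len(filtered) - n_unmatched,
            "n_drugs_assigned": len(assignments),
            "histogram_1_2_3_gt3": list(histogram),
        }

    # --- spontaneous reports ------------------------------------------------
    read = faers.read_reports(paths.demo, paths.drug, paths.reac, config.delimiter)
    complete, n_incomplete = faers.drop_incomplete(read.reports)
    deduped, n_dups = faers.deduplicate(complete)
    records, counters = faers.explode_suspect_events(deduped, lexicon, dictionary, vocab)
    by_stratum = {
        faers.FEMALE: 0,
        faers.MALE: 0,
        faers.SEX_EXCLUDED: 0,
    }
    for rec in records:
        by_stratum[rec.sex_stratum] += 1
    summary["reports"] = {
        "n_reports_read": len(read.reports),
        "n_malformed_rows": read.n_malformed_rows,
        "n_incomplete_dropped": n_incomplete,
        "n_duplicates_removed": n_dups,
        "n_reports_kept": len(deduped),
        "n_unmapped_reactions": counters.n_unmapped_reactions,
        "n_unmatched_drug_names": counters.n_unmatched_drug_names,
        "n_records": len(records),
        "n_records_female": by_stratum[faers.FEMALE],
        "n_records_male": by_stratum[faers.MALE],
        "n_records_sex_excluded": by_stratum[faers.SEX_EXCLUDED],
    }

    # --- profiles -----------------------------------------------------------
    profiles = {"overall": zscore.aggregate_profiles(records, vocab)}
    if config.stratify:
        profiles["female"] = zscore.aggregate_profiles(records, vocab, faers.FEMALE)
        profiles["male"] = zscore.aggregate_profiles(records, vocab, faers.MALE)
    summary["profiles"] = {
        f"n_drugs_{stratum}": len(plist) for stratum, plist in profiles.items()
    }
    summary["profiles"]["n_drugs_zero_dispersion"] = sum(
        1 for p in profiles["overall"] if len(set(p.counts)) == 1
    )
    return PipelineResult(
        vocab=vocab,
        lexicon=lexicon,
        dictionary=dictionary,
        reports=deduped,
        records=records,
        profiles=profiles,
        trial_assignments=assignments,
        trial_histogram=histogram,
        summary=summary,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path, ddof: int = 0) -> dict[str, Path]:
    """Write every output table (CSV) plus the machine-readable run summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        p = out_dir / name
        frame.to_csv(p, index=index, lineterminator="\n")
        paths[name] = p

    if result.trial_assignments:
        save("trial_assignments.csv", trials.assignments_frame(result.trial_assignments))
    records_frame = pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "soc_code": r.soc_code,
                "sex_stratum": r.sex_stratum,
                "case_id": r.case_id,
            }
            for r in result.records
        ],
        columns=["drug_id", "soc_code", "sex_stratum", "case_id"],
    )
    save("records.csv", records_frame)

    for stratum, plist in result.profiles.items():
        nonempty = [p for p in plist if p.total > 0]
        if nonempty:
            zmat, bands = zscore.z_matrix(nonempty, result.vocab, ddof)
            save(f"z_{stratum}.csv", zmat, index=True)
            save(f"bands_{stratum}.csv", bands, index=True)
            save(f"long_{stratum}.csv", zscore.long_table(nonempty, result.vocab, ddof, stratum))
    overall = [p for p in result.profiles["overall"] if p.total > 0]
    save("atc_summary.csv", zscore.atc_class_summary(overall, result.lexicon, result.vocab, ddof))

    p = out_dir / "run_summary.json"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["run_summary.json"] = p
    return paths
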