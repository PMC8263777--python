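"""Synthetic corpus generator with planted SOC safety signals.

Generates the four inputs the pipeline consumes — a trials CSV, the three
FAERS-dialect report tables, a term dictionary, and a drug lexicon — plus a
ground-truth manifest, so every downstream stage is testable without any
external download.

The statistical model mirrors what the analysis assumes: each drug draws its
reactions from a 27-way categorical distribution over SOCs. A planted signal
(drug d, SOC s, factor lambda >= 1) multiplies that drug's weight for s by
lambda before renormalization, so with a uniform baseline the planted SOC
probability is lambda / (26 + lambda). Realism knobs cover duplicate report
versions, incomplete reports (missing case id, drug, or reactions), suspect
role codes over {PS, SS, C}, sex codes including an unknown-like code, and a
mixture of LLT and PT reaction spellings.

Determinism contract: a single numpy Generator seeded from the config drives
every draw in a fixed, documented order (lexicon ATC codes → trials → per-drug
reports → duplicate selection → incomplete reports), so identical configs
yield byte-identical output files. Within one report, reaction terms are
drawn without replacement, so the cleaner's within-report duplicate-reaction
collapse never changes a count relative to the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError
from .vocab import N_SOC, MedDRADictionary, MedDRATerm, SOCVocabulary, load_soc_vocabulary
from .lexicon import DrugEntry, DrugLexicon

ATC_LETTERS = "ABCDGHJLMNPRSV"  # the 14 anatomical main groups

_STATUSES = [
    "Completed",
    "Recruiting",
    "Active, not recruiting",
    "Not yet recruiting",
    "Withdrawn",
    "Suspended",
    "Terminated",
]
_STATUS_PROBS = [0.30, 0.28, 0.15, 0.07, 0.06, 0.06, 0.08]
_DOSES = [10, 25, 50, 100, 200, 400]


class Enrichment(BaseModel):
    drug_id: str
    soc_code: str
    factor: float = Field(ge=1.0)


class SimulationConfig(BaseModel):
    """Knobs of the synthetic corpus; defaults are the package's study conditions."""

    n_drugs: int = Field(default=20, ge=1)
    n_reports_per_drug: int = Field(default=200, ge=1)
    baseline_soc_probs: Optional[list[float]] = None  # None -> uniform over 27
    enrichments: list[Enrichment] = Field(default_factory=list)
    duplicate_rate: float = Field(default=0.05, ge=0.0, lt=1.0)
    incomplete_rate: float = Field(default=0.05, ge=0.0, lt=1.0)
    sex_probs: dict[str, float] = Field(
        default_factory=lambda: {"F": 0.45, "M": 0.45, "UNK": 0.10}
    )
    role_probs: dict[str, float] = Field(
        default_factory=lambda: {"PS": 0.60, "SS": 0.25, "C": 0.15}
    )
    extra_reactions_mean: float = Field(default=0.5, ge=0.0)
    llt_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    atc_assign_prob: float = Field(default=0.7, ge=0.0, le=1.0)
    trials_per_drug_mean: float = Field(default=1.5, ge=0.0)
    seed: int = 0

    @field_validator("baseline_soc_probs")
    @classmethod
    def _check_baseline(cls, v):
        if v is None:
            return v
        if len(v) != N_SOC:
            raise ValueError(f"baseline_soc_probs must have {N_SOC} entries")
        arr = np.asarray(v, dtype=float)
        if (arr < 0).any() or not np.isclose(arr.sum(), 1.0, atol=1e-9):
            raise ValueError("baseline_soc_probs must be non-negative and sum to 1")
        return v

    @model_validator(mode="after")
    def _check_probs(self):
        for name, probs in (("sex_probs", self.sex_probs), ("role_probs", self.role_probs)):
            vals = np.asarray(list(probs.values()), dtype=float)
            if (vals < 0).any() or not np.isclose(vals.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if not set(self.role_probs) <= {"PS", "SS", "C", "I"}:
            raise ValueError("role_probs keys must be FAERS role codes")
        return self


@dataclass
class SimulatedCorpus:
    out_dir: Path
    paths: dict[str, Path]
    manifest: dict


def build_fixture_dictionary(
    vocab: SOCVocabulary,
    n_pts_per_soc: int = 4,
    n_llts_per_pt: int = 2,
) -> MedDRADictionary:
    """Deterministic synthetic term hierarchy covering every SOC.

    Term texts are schematic ("card reaction 01", "card reaction 01 variant 2")
    rather than clinical vocabulary; what matters downstream is only the
    LLT→PT→SOC structure.
    """
    terms: list[MedDRATerm] = []
    for code in vocab.codes:
        for k in range(1, n_pts_per_soc + 1):
            pt = f"{code.lower()} reaction {k:02d}"
            terms.append(MedDRATerm(pt, "PT", None, code))
            for m in range(1, n_llts_per_pt + 1):
                terms.append(
                    MedDRATerm(f"{pt} variant {m}", "LLT", pt, None)
                )
    return MedDRADictionary(terms, version_label="synthetic-fixture", vocab=vocab)


def _build_lexicon(config: SimulationConfig, rng: np.random.Generator) -> DrugLexicon:
    entries = []
    for i in range(config.n_drugs):
        drug_id = f"D{i:03d}"
        preferred = f"drugname{i:03d}"
        synonyms = frozenset(
            {preferred, f"{preferred} hydrochloride", f"dz{i:03d}"}
        )
        codes: set[str] = set()
        if rng.random() < config.atc_assign_prob:
            for _ in range(int(rng.integers(1, 3))):
                letter = ATC_LETTERS[int(rng.integers(len(ATC_LETTERS)))]
                l2 = int(rng.integers(1, 17))
                l34 = "".join(
                    ATC_LETTERS[int(rng.integers(len(ATC_LETTERS)))] for _ in range(2)
                )
                l5 = int(rng.integers(1, 100))
                codes.add(f"{letter}{l2:02d}{l34}{l5:02d}")
        entries.append(DrugEntry(drug_id, preferred, synonyms, frozenset(codes)))
    return DrugLexicon(entries, version_tag="synthetic-fixture")


def _soc_probs_for(
    config: SimulationConfig, drug_id: str, vocab: SOCVocabulary
) -> np.ndarray:
    if config.baseline_soc_probs is None:
        probs = np.full(N_SOC, 1.0 / N_SOC)
    else:
        probs = np.asarray(config.baseline_soc_probs, dtype=float).copy()
    for e in config.enrichments:
        if e.drug_id == drug_id:
            if e.soc_code not in vocab:
                raise ConfigError(f"enrichment SOC {e.soc_code!r} not in vocabulary")
            probs[vocab.index(e.soc_code)] *= e.factor
    return probs / probs.sum()


def _terms_by_soc(dictionary: MedDRADictionary) -> dict[str, tuple[list[str], list[str]]]:
    """Per SOC: (sorted PT texts, sorted LLT texts)."""
    pts: dict[str, list[str]] = {}
    llts: dict[str, list[str]] = {}
    for t in dictionary.terms.values():
        if t.level == "PT":
            pts.setdefault(t.primary_soc, []).append(t.term_text)
        else:
            soc = dictionary.terms[t.parent_pt].primary_soc
            llts.setdefault(soc, []).append(t.term_text)
    return {
        soc: (sorted(pts.get(soc, [])), sorted(llts.get(soc, [])))
        for soc in set(pts) | set(llts)
    }


def simulate_corpus(
    config: SimulationConfig,
    out_dir: str | Path,
    delimiter: str = "$",
) -> SimulatedCorpus:
    """Generate the full synthetic corpus and write it under ``out_dir``.

    Returns the file paths and the ground-truth manifest (also written as
    ``manifest.json``). See the module docstring for the data model and the
    determinism contract.
    """
    try:
        config = SimulationConfig.model_validate(config)
    except Exception as exc:  # pydantic ValidationError -> package error
        raise ConfigError(str(exc)) from exc

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    vocab = load_soc_vocabulary()
    dictionary = build_fixture_dictionary(vocab)
    lexicon = _build_lexicon(config, rng)
    term_pool = _terms_by_soc(dictionary)

    sex_codes = sorted(config.sex_probs)
    sex_p = np.array([config.sex_probs[c] for c in sex_codes])
    role_codes = sorted(config.role_probs)
    role_p = np.array([config.role_probs[c] for c in role_codes])

    # --- trials ------------------------------------------------------------
    trial_rows: list[tuple[str, str, str]] = []
    expected_trial_counts: dict[str, int] = {}
    trial_no = 0
    for entry in lexicon:
        n_trials = 1 + int(rng.poisson(config.trials_per_drug_mean))
        kept = 0
        syns = sorted(entry.synonyms)
        for _ in range(n_trials):
            trial_no += 1
            status = _STATUSES[int(rng.choice(len(_STATUSES), p=_STATUS_PROBS))]
            syn = syns[int(rng.integers(len(syns)))]
            dose = _DOSES[int(rng.integers(len(_DOSES)))]
            interventions = f"Drug: {syn} {dose} mg"
            trial_rows.append((f"NCT{trial_no:08d}", status, interventions))
            if not status.casefold().startswith(("withdrawn", "suspended", "terminated")):
                kept += 1
        expected_trial_counts[entry.drug_id] = kept
    # a few trials the drug filter / lexicon should reject
    for i in range(max(1, config.n_drugs // 10)):
        trial_no += 1
        trial_rows.append(
            (f"NCT{trial_no:08d}", "Recruiting", "Behavioral: supportive care")
        )
        trial_no += 1
        trial_rows.append(
            (f"NCT{trial_no:08d}", "Completed", f"Drug: herbal decoction {i + 1}")
        )

    # --- reports -----------------------------------------------------------
    demo_rows: list[tuple[str, str, str]] = []
    drug_rows: list[tuple[str, str, str, str]] = []
    reac_rows: list[tuple[str, str, str]] = []
    base_reports: list[dict] = []  # for duplicate re-emission
    base_counts: dict[str, dict[str, int]] = {}
    suspect_counts: dict[str, dict[str, int]] = {}
    suspect_counts_by_sex: dict[str, dict[str, dict[str, int]]] = {}

    case_no = 0
    for entry in lexicon:
        drug_id = entry.drug_id
        probs = _soc_probs_for(config, drug_id, vocab)
        n = config.n_reports_per_drug
        sexes = [sex_codes[i] for i in rng.choice(len(sex_codes), size=n, p=sex_p)]
        roles = [role_codes[i] for i in rng.choice(len(role_codes), size=n, p=role_p)]
        n_reacts = 1 + rng.poisson(config.extra_reactions_mean, size=n)
        syns = sorted(entry.synonyms)
        base_counts[drug_id] = {}
        suspect_counts[drug_id] = {}
        suspect_counts_by_sex[drug_id] = {}
        for r in range(n):
            case_no += 1
            case_id = f"C{case_no:07d}"
            verbatim = syns[int(rng.integers(len(syns)))]
            if rng.random() < 0.3:
                verbatim = verbatim.upper()
            soc_idx = rng.choice(N_SOC, size=int(n_reacts[r]), p=probs)
            used: set[str] = set()
            terms: list[str] = []
            socs: list[str] = []
            for idx in soc_idx:
                soc = vocab.codes[int(idx)]
                pts, llts = term_pool[soc]
                pool = llts if rng.random() < config.llt_fraction else pts
                term = pool[int(rng.integers(len(pool)))]
                if term in used:  # draw without replacement within a report
                    for cand in pts + llts:
                        if cand not in used:
                            term = cand
                            break
                    else:
                        continue  # SOC's whole pool already used; drop the draw
                used.add(term)
                terms.append(term)
                socs.append(soc)
            stratum = (
                "female" if sexes[r] == "F" else "male" if sexes[r] == "M" else "excluded"
            )
            suspect = roles[r] in ("PS", "SS")
            for soc in socs:
                base_counts[drug_id][soc] = base_counts[drug_id].get(soc, 0) + 1
                if suspect:
                    suspect_counts[drug_id][soc] = (
                        suspect_counts[drug_id].get(soc, 0) + 1
                    )
                    by_sex = suspect_counts_by_sex[drug_id].setdefault(stratum, {})
                    by_sex[soc] = by_sex.get(soc, 0) + 1
            report = {
                "case_id": case_id,
                "version": 1,
                "sex": sexes[r],
                "role": roles[r],
                "verbatim": verbatim,
                "terms": terms,
                "drug_id": drug_id,
            }
            base_reports.append(report)
            demo_rows.append((case_id, "1", sexes[r]))
            drug_rows.append((case_id, "1", roles[r], verbatim))
            for term in terms:
                reac_rows.append((case_id, "1", term))

    # --- injected duplicates ----------------------------------------------
    n_base = len(base_reports)
    n_dup = int(round(config.duplicate_rate * n_base))
    dup_manifest = []
    if n_dup:
        for pos in sorted(rng.choice(n_base, size=n_dup, replace=False).tolist()):
            rep = base_reports[pos]
            demo_rows.append((rep["case_id"], "2", rep["sex"]))
            drug_rows.append((rep["case_id"], "2", rep["role"], rep["verbatim"]))
            for term in rep["terms"]:
                reac_rows.append((rep["case_id"], "2", term))
            dup_manifest.append(
                {
                    "case_id": rep["case_id"],
                    "base_version": 1,
                    "dup_version": 2,
                    "drug_id": rep["drug_id"],
                }
            )

    # --- injected incomplete reports ---------------------------------------
    n_inc = int(round(config.incomplete_rate * n_base))
    inc_manifest = []
    kinds = ["no_case_id", "no_drug", "no_reactions"]
    for i in range(n_inc):
        kind = kinds[int(rng.integers(len(kinds)))]
        entry = lexicon[f"D{int(rng.integers(config.n_drugs)):03d}"]
        sex = sex_codes[int(rng.choice(len(sex_codes), p=sex_p))]
        role = role_codes[int(rng.choice(len(role_codes), p=role_p))]
        syn = sorted(entry.synonyms)[0]
        soc = vocab.codes[int(rng.integers(N_SOC))]
        term = term_pool[soc][0][0]
        if kind == "no_case_id":
            version = str(900000 + i)  # unique grouping for blank case ids
            demo_rows.append(("", version, sex))
            drug_rows.append(("", version, role, syn))
            reac_rows.append(("", version, term))
            inc_manifest.append({"kind": kind, "case_id": "", "version": int(version)})
        else:
            case_no += 1
            case_id = f"C{case_no:07d}"
            demo_rows.append((case_id, "1", sex))
            if kind == "no_drug":
                reac_rows.append((case_id, "1", term))
            else:  # no_reactions
                drug_rows.append((case_id, "1", role, syn))
            inc_manifest.append({"kind": kind, "case_id": case_id, "version": 1})

    # --- write everything ---------------------------------------------------
    paths = {
        "trials": out_dir / "trials.csv",
        "demo": out_dir / "demo.txt",
        "drug": out_dir / "drug.txt",
        "reac": out_dir / "reac.txt",
        "dictionary": out_dir / "dictionary.tsv",
        "lexicon": out_dir / "lexicon.tsv",
        "manifest": out_dir / "manifest.json",
    }
    with open(paths["trials"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("trial_id,status,interventions\n")
        for tid, status, interventions in trial_rows:
            fh.write(f'{tid},"{status}","{interventions}"\n')
    _write_delimited(paths["demo"], ("caseid", "caseversion", "sex"), demo_rows, delimiter)
    _write_delimited(
        paths["drug"], ("caseid", "caseversion", "role_cod", "drugname"), drug_rows, delimiter
    )
    _write_delimited(paths["reac"], ("caseid", "caseversion", "pt"), reac_rows, delimiter)
    dictionary.write(paths["dictionary"])
    lexicon.write(paths["lexicon"])

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "planted": [e.model_dump() for e in config.enrichments],
        "drugs": {
            drug_id: {
                "base_soc_counts": dict(sorted(base_counts[drug_id].items())),
                "suspect_soc_counts": dict(sorted(suspect_counts[drug_id].items())),
                "suspect_soc_counts_by_sex": {
                    s: dict(sorted(d.items()))
                    for s, d in sorted(suspect_counts_by_sex[drug_id].items())
                },
                "expected_trial_count": expected_trial_counts[drug_id],
            }
            for drug_id in sorted(base_counts)
        },
        "duplicates": dup_manifest,
        "incomplete": inc_manifest,
        "totals": {
            "n_base_reports": n_base,
            "n_duplicates": n_dup,
            "n_incomplete": n_inc,
        },
    }
    with open(paths["manifest"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SimulatedCorpus(out_dir=out_dir, paths=paths, manifest=manifest)


def _write_delimited(path: Path, columns, rows, delimiter: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(columns) + "\n")
        for row in rows:
            fh.write(delimiter.join(row) + "\n")
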