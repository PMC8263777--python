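"""A hand-checkable micro-corpus with its expected pipeline output frozen.

Sixteen report groups over three antimalarial/antibiotic drugs and five of
the 27 SOCs, exercising every cleaning rule once: a duplicate case version
(twice), an incomplete report missing its drug and reactions, a report
missing its case id, a concomitant-only mention, an unmapped reaction term,
and a drug name outside the lexicon. The expected per-(drug, SOC) counts
below were tallied by hand from the report listing and are frozen; the
corpus is written from string constants, so regeneration is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

_TRIALS_CSV = """\
trial_id,status,interventions
NCT0000001,Completed,"Drug: Hydroxychloroquine 200 mg"
NCT0000002,Recruiting,"Drug: Hydroxychloroquine Sulfate|Drug: Azithromycin 500 mg"
NCT0000003,Withdrawn,"Drug: Chloroquine"
NCT0000004,Completed,"Behavioral: exercise"
NCT0000005,Completed,"Drug: Traditional Chinese Medicine decoction"
NCT0000006,Terminated (COVID-19),"Drug: Azithromycin"
NCT0000007,Completed,"Drug: Chloroquine Phosphate"
"""

_LEXICON_TSV = """\
drug_id	preferred_name	synonyms	atc_codes
D001	hydroxychloroquine	hydroxychloroquine|hydroxychloroquine sulfate|plaquenil	P01BA02
D002	azithromycin	azithromycin|zithromax	J01FA10
D003	chloroquine	chloroquine|chloroquine phosphate	P01BA01
"""

_DICTIONARY_TSV = """\
term_text	level	parent_pt	primary_soc
cardiac arrest	PT		CARD
nausea	PT		GASTR
diarrhoea	PT		GASTR
headache	PT		NERV
rash	PT		SKIN
fatigue	PT		GENRL
feeling tired	LLT	fatigue
stomach upset	LLT	nausea
"""

_DEMO = """\
caseid$caseversion$sex
C001$1$F
C001$2$F
C002$1$M
C003$1$F
C004$1$UNK
C005$1$M
C006$1$F
C007$1$M
C008$1$F
C009$1$F
C010$1$M
C011$1$F
C012$2$F
C012$3$F
C013$1$M
$999$F
"""

_DRUG = """\
caseid$caseversion$role_cod$drugname
C001$1$PS$Hydroxychloroquine Sulfate
C001$2$PS$Hydroxychloroquine Sulfate
C002$1$PS$Plaquenil
C003$1$PS$Azithromycin
C004$1$SS$Zithromax
C005$1$PS$Chloroquine Phosphate
C006$1$C$Chloroquine
C007$1$PS$Hydroxychloroquine
C007$1$SS$Azithromycin
C008$1$PS$Azithromycin
C009$1$PS$Traditional Chinese Medicine
C010$1$PS$Chloroquine
C011$1$PS$Hydroxychloroquine
C012$2$PS$Azithromycin
C012$3$PS$Azithromycin
$999$PS$Hydroxychloroquine
"""

_REAC = """\
caseid$caseversion$pt
C001$1$Cardiac Arrest
C001$1$Nausea
C001$2$Cardiac Arrest
C001$2$Nausea
C002$1$Rash
C003$1$Nausea
C003$1$Headache
C004$1$Fatigue
C005$1$Cardiac Arrest
C006$1$Nausea
C007$1$Headache
C007$1$Feeling Tired
C008$1$Totally Made Up Term
C009$1$Nausea
C010$1$Diarrhoea
C010$1$Rash
C011$1$Stomach Upset
C012$2$Rash
C012$3$Rash
$999$Nausea
"""

#: Hand-tallied per-(drug, SOC) counts after full cleaning and mapping.
EXPECTED_COUNTS: dict[tuple[str, str], int] = {
    ("D001", "CARD"): 1,   # C001 cardiac arrest
    ("D001", "GASTR"): 2,  # C001 nausea, C011 stomach upset (LLT -> nausea)
    ("D001", "NERV"): 1,   # C007 headache
    ("D001", "GENRL"): 1,  # C007 feeling tired (LLT -> fatigue)
    ("D001", "SKIN"): 1,   # C002 rash
    ("D002", "GASTR"): 1,  # C003 nausea
    ("D002", "NERV"): 2,   # C003 headache, C007 headache
    ("D002", "GENRL"): 2,  # C004 fatigue, C007 feeling tired
    ("D002", "SKIN"): 1,   # C012 rash (latest version)
    ("D003", "CARD"): 1,   # C005 cardiac arrest
    ("D003", "GASTR"): 1,  # C010 diarrhoea
    ("D003", "SKIN"): 1,   # C010 rash
}

#: female / male / sex-excluded record totals; they sum to the overall 15.
EXPECTED_STRATUM_TOTALS = {"female": 6, "male": 8, "excluded": 1}

EXPECTED_CLEANING = {
    "n_reports_read": 16,
    "n_incomplete_dropped": 2,  # C013 (no drug/reactions) and the blank-id report
    "n_duplicates_removed": 2,  # C001 v1, C012 v2
    "n_reports_kept": 12,
    "n_unmapped_reactions": 1,   # C008 "Totally Made Up Term"
    "n_unmatched_drug_names": 1,  # C009 "Traditional Chinese Medicine"
}

#: trial funnel: 7 read -> 5 after status filter -> 4 with Drug interventions
#: -> 3 trials matched to lexicon drugs (the TCM trial matches nothing).
EXPECTED_TRIAL_ASSIGNMENTS = {"D001": 2, "D002": 1, "D003": 1}
EXPECTED_TRIAL_HISTOGRAM = (2, 1, 0, 0)


def write_fixture_small(out_dir: str | Path) -> dict[str, Path]:
    """Write the micro-corpus; returns the file paths.

    Deterministic: the files are emitted from string constants, so two calls
    produce byte-identical output. The expected post-pipeline counts are
    stored alongside as ``expected_counts.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contents = {
        "trials": ("trials.csv", _TRIALS_CSV),
        "lexicon": ("lexicon.tsv", _LEXICON_TSV),
        "dictionary": ("dictionary.tsv", _DICTIONARY_TSV),
        "demo": ("demo.txt", _DEMO),
        "drug": ("drug.txt", _DRUG),
        "reac": ("reac.txt", _REAC),
    }
    paths: dict[str, Path] = {}
    for key, (name, text) in contents.items():
        p = out_dir / name
        p.write_text(text, encoding="utf-8", newline="\n")
        paths[key] = p
    expected = out_dir / "expected_counts.tsv"
    with open(expected, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug_id\tsoc_code\tcount\n")
        for (drug_id, soc), count in sorted(EXPECTED_COUNTS.items()):
            fh.write(f"{drug_id}\t{soc}\t{count}\n")
    paths["expected_counts"] = expected
    return paths
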