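"""Report joining, completeness filtering, deduplication, suspect expansion."""

from collections import Counter

import pytest

from socsafety.errors import FormatError
from socsafety.faers import (
    SEX_EXCLUDED,
    CaseReport,
    DrugMention,
    deduplicate,
    drop_incomplete,
    explode_suspect_events,
    read_reports,
)
from socsafety.lexicon import DrugEntry, DrugLexicon
from socsafety.vocab import MedDRADictionary, MedDRATerm

from oracle import brute_force_counts


def write_files(tmp_path, demo, drug, reac, delim="$"):
    paths = {}
    for name, header, rows in (
        ("demo", "caseid$caseversion$sex", demo),
        ("drug", "caseid$caseversion$role_cod$drugname", drug),
        ("reac", "caseid$caseversion$pt", reac),
    ):
        p = tmp_path / f"{name}.txt"
        p.write_text("\n".join([header.replace("$", delim)] + rows) + "\n")
        paths[name] = p
    return paths


@pytest.fixture()
def tiny_lexicon():
    return DrugLexicon(
        [DrugEntry("DX", "examplinib", frozenset({"examplinib"}), frozenset())]
    )


@pytest.fixture()
def tiny_dictionary():
    return MedDRADictionary(
        [
            MedDRATerm("nausea", "PT", None, "GASTR"),
            MedDRATerm("cardiac arrest", "PT", None, "CARD"),
        ]
    )


class TestReadReports:
    def test_clean_join(self, tmp_path):
        paths = write_files(
            tmp_path,
            ["C1$1$F", "C2$1$M"],
            ["C1$1$PS$examplinib", "C2$1$PS$examplinib"],
            ["C1$1$nausea", "C2$1$nausea"],
        )
        result = read_reports(paths["demo"], paths["drug"], paths["reac"])
        assert len(result.reports) == 2
        assert all(r.is_complete for r in result.reports)

    def test_drug_row_without_demo_row_still_complete(self, tmp_path):
        paths = write_files(
            tmp_path, [], ["C1$1$PS$examplinib"], ["C1$1$nausea"]
        )
        (report,) = read_reports(paths["demo"], paths["drug"], paths["reac"]).reports
        assert report.sex_code is None
        assert report.is_complete

    def test_empty_reaction_file_makes_all_incomplete(self, tmp_path):
        paths = write_files(tmp_path, ["C1$1$F"], ["C1$1$PS$examplinib"], [])
        reports = read_reports(paths["demo"], paths["drug"], paths["reac"]).reports
        assert all(not r.is_complete for r in reports)

    def test_malformed_header_is_format_error(self, tmp_path):
        paths = write_files(tmp_path, ["C1$1$F"], ["C1$1$PS$examplinib"], ["C1$1$nausea"])
        paths["demo"].write_text("wrong$header\nC1$1$F\n")
        with pytest.raises(FormatError):
            read_reports(paths["demo"], paths["drug"], paths["reac"])

    def test_malformed_rows_skipped_and_counted(self, tmp_path):
        paths = write_files(
            tmp_path,
            ["C1$1$F", "garbage row"],
            ["C1$1$PS$examplinib", "C2$notanumber$PS$x"],
            ["C1$1$nausea"],
        )
        result = read_reports(paths["demo"], paths["drug"], paths["reac"])
        assert result.n_malformed_rows == 2
        assert len(result.reports) == 1


def report(case_id, version, sex, mentions, reactions):
    return CaseReport(case_id, version, sex, list(mentions), list(reactions))


class TestDropIncomplete:
    @pytest.mark.parametrize(
        "rep,complete",
        [
            (report(None, 1, "F", [DrugMention("x", "PS")], ["nausea"]), False),
            (report("C1", 1, "F", [], ["nausea"]), False),
            (report("C1", 1, "F", [DrugMention("x", "PS")], []), False),
            (report("C1", 1, "F", [DrugMention("x", "PS")], ["nausea"]), True),
        ],
    )
    def test_completeness_rule(self, rep, complete):
        kept, n_dropped = drop_incomplete([rep])
        assert (len(kept), n_dropped) == ((1, 0) if complete else (0, 1))


class TestDeduplicate:
    def test_latest_version_survives(self):
        reps = [
            report("C1", v, "F", [DrugMention("x", "PS")], ["nausea"]) for v in (1, 2, 3)
        ]
        kept, n_removed = deduplicate(reps)
        assert n_removed == 2
        assert kept[0].case_version == 3

    def test_same_case_different_reactions_both_kept(self):
        reps = [
            report("C1", 1, "F", [DrugMention("x", "PS")], ["nausea"]),
            report("C1", 2, "F", [DrugMention("x", "PS")], ["rash"]),
        ]
        kept, n_removed = deduplicate(reps)
        assert n_removed == 0 and len(kept) == 2

    def test_single_report_identity(self):
        reps = [report("C1", 1, "F", [DrugMention("x", "PS")], ["nausea"])]
        assert deduplicate(reps) == (reps, 0)

    def test_idempotent_and_shrinking(self, sim_result):
        once, n1 = deduplicate(sim_result.reports)
        twice, n2 = deduplicate(once)
        assert n2 == 0 and twice == once
        assert len(once) <= len(sim_result.reports)

    def test_version_tie_keeps_last_in_input_order(self):
        a = report("C1", 1, "F", [DrugMention("x", "PS")], ["nausea"])
        b = report("C1", 1, "M", [DrugMention("x", "PS")], ["nausea"])
        kept, n_removed = deduplicate([a, b])
        assert n_removed == 1 and kept[0] is b

    def test_normalized_key_ignores_case_and_order(self):
        a = report("C1", 1, "F",
                   [DrugMention("Examplinib", "PS"), DrugMention("other", "C")],
                   ["Nausea", "RASH"])
        b = report("C1", 2, "F",
                   [DrugMention("other", "C"), DrugMention("EXAMPLINIB", "PS")],
                   ["rash", "nausea"])
        kept, n_removed = deduplicate([a, b])
        assert n_removed == 1 and kept[0].case_version == 2


class TestExplodeSuspectEvents:
    def test_cross_product_of_suspect_drugs_and_mapped_reactions(
        self, vocab, tiny_lexicon, tiny_dictionary
    ):
        reps = [report("C1", 1, "F", [DrugMention("examplinib", "PS")],
                       ["nausea", "cardiac arrest"])]
        records, counters = explode_suspect_events(reps, tiny_lexicon, tiny_dictionary, vocab)
        assert Counter((r.drug_id, r.soc_code) for r in records) == Counter(
            {("DX", "GASTR"): 1, ("DX", "CARD"): 1}
        )
        assert counters.n_unmapped_reactions == 0

    def test_concomitant_only_report_yields_nothing(self, vocab, tiny_lexicon, tiny_dictionary):
        reps = [report("C1", 1, "F", [DrugMention("examplinib", "C")], ["nausea"])]
        records, _ = explode_suspect_events(reps, tiny_lexicon, tiny_dictionary, vocab)
        assert records == []

    def test_unknown_sex_is_excluded_stratum_but_counted_overall(
        self, vocab, tiny_lexicon, tiny_dictionary
    ):
        reps = [report("C1", 1, "UNK", [DrugMention("examplinib", "PS")], ["nausea"])]
        records, _ = explode_suspect_events(reps, tiny_lexicon, tiny_dictionary, vocab)
        assert len(records) == 1 and records[0].sex_stratum == SEX_EXCLUDED

    def test_ps_and_ss_mentions_of_same_drug_count_once(
        self, vocab, tiny_lexicon, tiny_dictionary
    ):
        reps = [report("C1", 1, "F",
                       [DrugMention("examplinib", "PS"), DrugMention("examplinib", "SS")],
                       ["nausea"])]
        records, _ = explode_suspect_events(reps, tiny_lexicon, tiny_dictionary, vocab)
        assert len(records) == 1

    def test_repeated_reaction_in_one_report_collapses(
        self, vocab, tiny_lexicon, tiny_dictionary
    ):
        reps = [report("C1", 1, "F", [DrugMention("examplinib", "PS")],
                       ["nausea", "Nausea", "NAUSEA."])]
        records, _ = explode_suspect_events(reps, tiny_lexicon, tiny_dictionary, vocab)
        assert len(records) == 1

    def test_unmapped_and_unmatched_are_counted(self, vocab, tiny_lexicon, tiny_dictionary):
        reps = [
            report("C1", 1, "F", [DrugMention("examplinib", "PS")], ["made up term"]),
            report("C2", 1, "F", [DrugMention("unknown agent", "PS")], ["nausea"]),
        ]
        records, counters = explode_suspect_events(reps, tiny_lexicon, tiny_dictionary, vocab)
        assert records == []
        assert counters.n_unmapped_reactions == 1
        assert counters.n_unmatched_drug_names == 1


class TestSyntheticCorpusEquivalence:
    def test_stratum_counts_conserve_total(self, sim_result):
        s = sim_result.summary["reports"]
        assert (
            s["n_records_female"] + s["n_records_male"] + s["n_records_sex_excluded"]
            == s["n_records"]
        )

    def test_cleaning_removes_exactly_injected_corruption(self, sim_corpus, sim_result):
        s = sim_result.summary["reports"]
        assert s["n_duplicates_removed"] == sim_corpus.manifest["totals"]["n_duplicates"]
        assert s["n_incomplete_dropped"] == sim_corpus.manifest["totals"]["n_incomplete"]
        assert (
            s["n_reports_kept"] + s["n_incomplete_dropped"] + s["n_duplicates_removed"]
            == s["n_reports_read"]
        )

    def test_pipeline_counts_equal_brute_force_recount_exactly(self, sim_corpus, sim_result):
        paths = sim_corpus.paths
        oracle_overall, oracle_strat = brute_force_counts(
            paths["demo"], paths["drug"], paths["reac"],
            paths["lexicon"], paths["dictionary"],
        )
        got_overall = Counter((r.drug_id, r.soc_code) for r in sim_result.records)
        got_strat = Counter(
            (r.drug_id, r.soc_code, r.sex_stratum) for r in sim_result.records
        )
        assert got_overall == oracle_overall
        assert got_strat == oracle_strat

    def test_pipeline_counts_equal_manifest_ground_truth(self, sim_corpus, sim_result):
        got = Counter((r.drug_id, r.soc_code) for r in sim_result.records)
        want = {
            (drug, soc): n
            for drug, info in sim_corpus.manifest["drugs"].items()
            for soc, n in info["suspect_soc_counts"].items()
        }
        assert dict(got) == want
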