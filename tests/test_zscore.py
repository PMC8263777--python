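"""The Z-score metric: closed forms, invariants, banding, and summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socsafety.errors import EmptyProfileError
from socsafety.faers import DrugEventRecord
from socsafety.lexicon import DrugEntry, DrugLexicon
from socsafety.zscore import (
    Band,
    SOCProfile,
    aggregate_profiles,
    atc_class_summary,
    categorize,
    compute_zscores,
    significant_socs,
)

SQRT26 = math.sqrt(26)


def profile(counts, drug_id="D"):
    return SOCProfile(drug_id, tuple(counts))


def zvector(counts, vocab, ddof=0):
    return [r.z for r in compute_zscores(profile(counts), vocab, ddof)]


class TestClosedForms:
    def test_one_hot_profile(self, vocab):
        zs = zvector([100] + [0] * 26, vocab)
        assert zs[0] == pytest.approx(SQRT26, abs=1e-9)
        for z in zs[1:]:
            assert z == pytest.approx(-1 / SQRT26, abs=1e-9)

    def test_location_scale_invariance_shifted_profile(self, vocab):
        # (3, 1 x 26) is (100, 0 x 26) rescaled: identical Z vector
        a = zvector([100] + [0] * 26, vocab)
        b = zvector([3] + [1] * 26, vocab)
        assert np.allclose(a, b, atol=1e-9)

    def test_constant_profile_is_undefined(self, vocab):
        recs = compute_zscores(profile([7] * 27), vocab)
        assert all(r.z is None and r.band is Band.UNDEFINED for r in recs)

    def test_empty_profile_is_an_error(self, vocab):
        with pytest.raises(EmptyProfileError):
            compute_zscores(profile([0] * 27), vocab)

    def test_sample_sd_option_shrinks_z(self, vocab):
        z0 = zvector([100] + [0] * 26, vocab, ddof=0)[0]
        z1 = zvector([100] + [0] * 26, vocab, ddof=1)[0]
        assert z1 < z0


counts_strategy = st.lists(st.integers(0, 500), min_size=27, max_size=27).filter(
    lambda c: len(set(c)) > 1
)


class TestInvariants:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(counts_strategy)
    def test_standardization_identities(self, vocab, counts):
        zs = np.array(zvector(counts, vocab))
        assert abs(zs.sum()) < 1e-9
        assert abs((zs**2).sum() - 27) < 1e-9
        assert np.abs(zs).max() <= SQRT26 + 1e-9
        assert (zs > 2).sum() <= 6

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        counts_strategy,
        st.integers(1, 9),
        st.integers(0, 50),
    )
    def test_location_scale_invariance(self, vocab, counts, a, b):
        base = zvector(counts, vocab)
        transformed = zvector([a * c + b for c in counts], vocab)
        assert np.allclose(base, transformed, atol=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(counts_strategy, st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, vocab, counts, rnd):
        perm = list(range(27))
        rnd.shuffle(perm)
        base = zvector(counts, vocab)
        permuted = zvector([counts[p] for p in perm], vocab)
        assert np.allclose([base[p] for p in perm], permuted, atol=1e-9)


class TestCategorize:
    @pytest.mark.parametrize(
        "z,band",
        [
            (3.7, Band.SIGNIFICANTLY_FREQUENT),
            (2.4, Band.SIGNIFICANTLY_FREQUENT),
            (2.0, Band.FREQUENT),  # strict "> 2" rule: 2 itself is not significant
            (1.5, Band.FREQUENT),
            (1.0, Band.SLIGHTLY_FREQUENT),
            (0.5, Band.SLIGHTLY_FREQUENT),
            (0.0, Band.LIKELY_INFREQUENT),
            (-0.03, Band.LIKELY_INFREQUENT),
            (-1.0, Band.INFREQUENT),
            (-2.5, Band.INFREQUENT),
            (None, Band.UNDEFINED),
        ],
    )
    def test_band_boundaries(self, z, band):
        assert categorize(z) is band


class TestSignificantSOCs:
    def test_single_significant(self, vocab):
        recs = compute_zscores(profile([50] + [1] * 26), vocab)
        sig = significant_socs(recs)
        assert sig == {vocab.codes[0]}

    def test_none_significant(self, vocab):
        recs = compute_zscores(profile(list(range(27))), vocab)
        assert significant_socs(recs) == set()

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(counts_strategy)
    def test_at_most_six(self, vocab, counts):
        assert len(significant_socs(compute_zscores(profile(counts), vocab))) <= 6


class TestAggregateProfiles:
    def test_tally(self, vocab):
        records = [DrugEventRecord("X", "CARD", "female", f"C{i}") for i in range(5)]
        (prof,) = aggregate_profiles(records, vocab)
        assert prof.counts[vocab.index("CARD")] == 5
        assert prof.total == 5

    def test_empty(self, vocab):
        assert aggregate_profiles([], vocab) == []

    def test_stratum_selection(self, vocab):
        records = [
            DrugEventRecord("X", "CARD", "female", "C1"),
            DrugEventRecord("X", "CARD", "male", "C2"),
            DrugEventRecord("X", "CARD", "excluded", "C3"),
        ]
        assert aggregate_profiles(records, vocab)[0].total == 3
        assert aggregate_profiles(records, vocab, "female")[0].total == 1
        assert aggregate_profiles(records, vocab, "male")[0].total == 1


class TestAtcClassSummary:
    def lexicon(self):
        return DrugLexicon(
            [
                DrugEntry("D1", "a", frozenset({"a"}), frozenset({"J01FA10"})),
                DrugEntry("D2", "b", frozenset({"b"}), frozenset({"J05AE03"})),
                DrugEntry("D3", "c", frozenset({"c"}), frozenset({"A02BC01", "N05BA01"})),
                DrugEntry("D4", "d", frozenset({"d"}), frozenset()),  # no ATC: excluded
            ]
        )

    def test_class_averages(self, vocab):
        profiles = [
            profile([10] + [0] * 26, "D1"),
            profile([30] + [0] * 26, "D2"),
        ]
        frame = atc_class_summary(profiles, self.lexicon(), vocab)
        row = frame.set_index("atc_class").loc["J"]
        assert row["n_drugs"] == 2
        assert row["total_events"] == 40
        assert row["mean_events_per_drug"] == 20

    def test_multi_class_drug_contributes_full_totals_to_each(self, vocab):
        frame = atc_class_summary(
            [profile([8] + [0] * 26, "D3")], self.lexicon(), vocab
        )
        idx = frame.set_index("atc_class")
        assert idx.loc["A", "total_events"] == 8
        assert idx.loc["N", "total_events"] == 8

    def test_drugs_without_atc_are_excluded(self, vocab):
        frame = atc_class_summary(
            [profile([8] + [0] * 26, "D4")], self.lexicon(), vocab
        )
        assert frame.empty
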