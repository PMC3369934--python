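import numpy as np
import pandas as pd
import pytest

from conftest import make_bin_reads
from drisee.binning import PrefixBin
from drisee.consensus import build_bin_alignment
from drisee.profile import (
    EVENT_COLUMNS,
    ErrorProfile,
    aggregate_profiles,
    compare_profiles,
    normalize_profile,
    phred_profile,
    summarize,
    tally_bin,
    total_error_by_position,
)
from drisee.seqio import SequenceRead

PREFIX = "CACG"
L = len(PREFIX)


def tally_suffixes(suffixes, prefix=PREFIX):
    bin_ = PrefixBin(prefix=prefix, members=make_bin_reads(prefix, suffixes))
    return tally_bin(build_bin_alignment(bin_, len(prefix)))


def random_profile(rng, n_positions=8, prefix_length=2):
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(n_positions, len(EVENT_COLUMNS))),
        index=pd.RangeIndex(1, n_positions + 1),
        columns=EVENT_COLUMNS,
        dtype=np.int64,
    )
    return ErrorProfile(counts=counts, prefix_length=prefix_length)


class TestTallyBin:
    def test_exact_duplicates_are_pure_match(self):
        prof = tally_suffixes(["ACGTACGT"] * 20)
        err = prof.counts[["subst_A", "subst_T", "subst_C", "subst_G",
                           "insertion", "deletion"]]
        assert int(err.to_numpy().sum()) == 0
        # prefix positions carry abundance-weighted matches of the prefix base
        assert prof.counts.loc[1, "match_C"] == 20
        assert prof.counts.loc[2, "match_A"] == 20
        assert int(prof.coverage().sum()) == 20 * (L + 8)

    def test_substitution_keyed_by_consensus_base(self):
        prof = tally_suffixes(["ACGT", "ACGT", "ACTT"])
        pos = L + 3  # consensus G, variant read T
        assert prof.counts.loc[pos, "match_G"] == 2
        assert prof.counts.loc[pos, "subst_G"] == 1

    def test_deletion_counted_at_deleted_position(self):
        prof = tally_suffixes(["ACGTACGT"] * 19 + ["ACGACGT"])
        assert int(prof.counts["deletion"].sum()) == 1
        assert prof.counts.loc[L + 4, "deletion"] == 1

    def test_insertion_anchored_left(self):
        prof = tally_suffixes(["ACGTACGT"] * 19 + ["ACGTTACGT"])
        assert int(prof.counts["insertion"].sum()) == 1
        assert prof.counts.loc[L + 4, "insertion"] == 1

    def test_terminal_gaps_are_not_deletions(self):
        prof = tally_suffixes(["ACGTACGT"] * 19 + ["ACGTAC"])
        assert int(prof.counts["deletion"].sum()) == 0
        assert prof.coverage().loc[L + 8] == 19
        assert prof.coverage().loc[L + 6] == 20


class TestAggregateProfiles:
    def test_linearity(self):
        prof = tally_suffixes(["ACGT", "ACGT", "ACTT"])
        double = aggregate_profiles([prof, prof])
        assert (double.counts == 2 * prof.counts).all().all()

    def test_empty_collection(self):
        assert aggregate_profiles([]).counts.empty

    def test_mixed_prefix_length_rejected(self):
        a = tally_suffixes(["ACGT", "ACTT"])
        b = tally_suffixes(["ACGT", "ACTT"], prefix="CACGT")
        with pytest.raises(ValueError):
            aggregate_profiles([a, b])

    def test_matches_brute_force_cell_addition(self):
        rng = np.random.default_rng(0)
        profiles = [random_profile(rng, n_positions=rng.integers(3, 10)) for _ in range(10)]
        agg = aggregate_profiles(profiles)
        for pos in agg.counts.index:
            for col in EVENT_COLUMNS:
                expected = sum(
                    p.counts.loc[pos, col]
                    for p in profiles
                    if pos in p.counts.index
                )
                assert agg.counts.loc[pos, col] == expected


class TestNormalizeProfile:
    def test_hand_normalization(self):
        prof = tally_suffixes(["ACGT", "ACGT", "ACGT", "ACTT"])
        pct = normalize_profile(prof)
        pos = L + 3
        assert pct.loc[pos, "match_G"] == pytest.approx(75.0)
        assert pct.loc[pos, "subst_G"] == pytest.approx(25.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(1)
        prof = random_profile(rng)
        pct = normalize_profile(prof)
        np.testing.assert_allclose(pct.sum(axis=1).to_numpy(), 100.0, atol=1e-9)

    def test_zero_coverage_rows_are_blank(self):
        prof = tally_suffixes(["ACGT", "ACGT"])
        prof.counts.loc[L + 2] = 0
        pct = normalize_profile(prof)
        assert pct.loc[L + 2].isna().all()

    def test_reweighting_recovers_counts(self):
        rng = np.random.default_rng(2)
        prof = random_profile(rng)
        pct = normalize_profile(prof)
        cov = prof.coverage()
        back = pct.mul(cov, axis=0) / 100.0
        np.testing.assert_allclose(back.to_numpy(), prof.counts.to_numpy(), atol=1e-9)


class TestSummarize:
    def test_all_match_profile_is_zero(self):
        prof = tally_suffixes(["ACGTACGT"] * 20)
        s = summarize(prof)
        assert s.weighted["Total"] == 0.0
        assert s.averaged["Total"] == 0.0

    def test_total_is_sum_of_components(self):
        rng = np.random.default_rng(3)
        prof = random_profile(rng)
        s = summarize(prof)
        for form in (s.weighted, s.averaged):
            comps = [form[k] for k in ("A_subst", "T_subst", "C_subst", "G_subst", "InDel")]
            assert form["Total"] == pytest.approx(sum(comps), abs=1e-9)
            assert 0.0 <= form["Total"] <= 100.0

    def test_prefix_positions_excluded_from_summary(self):
        prof = tally_suffixes(["ACGT", "ACGT", "ACTT"])
        # corrupting a prefix row must not change the summary
        before = summarize(prof).weighted["Total"]
        prof.counts.loc[1, "subst_A"] = 999
        assert summarize(prof).weighted["Total"] == pytest.approx(before)

    def test_uncovered_profile_rejected(self):
        counts = pd.DataFrame(
            0, index=pd.RangeIndex(1, 5), columns=EVENT_COLUMNS, dtype=np.int64
        )
        with pytest.raises(ValueError):
            summarize(ErrorProfile(counts=counts, prefix_length=2))

    def test_weighted_form_on_known_counts(self):
        # 3 reads x 1 non-prefix position: 2 matches + 1 substitution -> 33.3%
        prof = tally_suffixes(["A", "A", "C"])
        s = summarize(prof)
        assert s.weighted["Total"] == pytest.approx(100.0 / 3.0)
        assert s.weighted["A_subst"] == pytest.approx(100.0 / 3.0)


class TestPhredProfile:
    def test_flat_q20_gives_one_percent(self):
        reads = [SequenceRead(f"r{i}", "ACGT", quals=[20] * 4) for i in range(5)]
        prof = phred_profile(reads)
        np.testing.assert_allclose(prof.to_numpy(), 1.0)

    def test_mean_of_mixed_qualities(self):
        reads = [
            SequenceRead("a", "A", quals=[10]),
            SequenceRead("b", "A", quals=[30]),
        ]
        assert phred_profile(reads).loc[1] == pytest.approx(5.05)

    def test_ragged_lengths_use_covering_reads(self):
        reads = [
            SequenceRead("a", "AA", quals=[10, 10]),
            SequenceRead("b", "A", quals=[30]),
        ]
        prof = phred_profile(reads)
        assert prof.loc[1] == pytest.approx(5.05)
        assert prof.loc[2] == pytest.approx(10.0)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            phred_profile([])

    def test_missing_quals_rejected(self):
        with pytest.raises(ValueError):
            phred_profile([SequenceRead("a", "A")])


class TestCompareProfiles:
    def test_identical_inputs_zero_difference(self):
        s = pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3])
        out = compare_profiles(s, s.copy())
        np.testing.assert_allclose(out["difference"].to_numpy(), 0.0)

    def test_flat_difference(self):
        idx = range(1, 11)
        d = pd.Series(2.0, index=idx)
        p = pd.Series(1.0, index=idx)
        out = compare_profiles(d, p)
        np.testing.assert_allclose(out["difference"].to_numpy(), 1.0)

    def test_overlap_rule(self):
        d = pd.Series(1.0, index=range(1, 101))
        p = pd.Series(1.0, index=range(1, 81))
        assert len(compare_profiles(d, p)) == 80

    def test_empty_overlap_rejected(self):
        d = pd.Series(1.0, index=[1, 2])
        p = pd.Series(1.0, index=[5, 6])
        with pytest.raises(ValueError):
            compare_profiles(d, p)

    def test_total_error_by_position_matches_normalized_rows(self):
        prof = tally_suffixes(["ACGT", "ACGT", "ACGT", "ACTT"])
        per_pos = total_error_by_position(prof)
        assert per_pos.loc[L + 3] == pytest.approx(25.0)
        assert per_pos.loc[L + 1] == pytest.approx(0.0)
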