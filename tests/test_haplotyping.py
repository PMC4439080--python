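"""Haplotype collapsing, grouping, temporal cohorts and count tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paleocattle.haplotyping import (
    ContingencyTable,
    HaplotypeTable,
    assign_groups,
    assign_period,
    build_counts,
    collapse_haplotypes,
    most_common_haplotype,
)
from paleocattle.seqio import SampleRecord

from conftest import make_alignment


def test_collapse_direct_enumeration(aln_factory):
    table = collapse_haplotypes(aln_factory({"a": "AAT", "b": "AAT", "c": "ACT"}))
    assert len(table) == 2
    assert table.counts == [2, 1]
    assert table.labels == ["H01", "H02"]
    assert table.members[0] == ["a", "b"]


def test_collapse_identical_sequences(aln_factory):
    table = collapse_haplotypes(aln_factory({f"s{i}": "ACGT" for i in range(6)}))
    assert len(table) == 1 and table.counts == [6]


def test_collapse_complete_deletion_removes_missing_columns(aln_factory):
    # column 2 has a gap, column 4 an N: both removed, so a and b merge
    table = collapse_haplotypes(aln_factory({"a": "A-GT", "b": "ACGN"}))
    assert len(table) == 1
    assert table.columns == (1, 3)


def test_collapse_all_columns_missing_errors(aln_factory):
    with pytest.raises(ValueError, match="no informative sites"):
        collapse_haplotypes(aln_factory({"a": "-N", "b": "AN"}))


def test_collapse_pairwise_mode_merges_compatible(aln_factory):
    table = collapse_haplotypes(aln_factory({"a": "ACGT", "b": "ACGN"}), "pairwise")
    assert len(table) == 1 and table.counts == [2]


@given(st.permutations(["AAT", "AAT", "ACT", "GGT", "GGT", "GGT"]))
def test_collapse_invariant_under_input_order(seqs):
    aln = make_alignment({f"s{i}": s for i, s in enumerate(seqs)})
    table = collapse_haplotypes(aln)
    # canonical labelling: count-desc then lexicographic sequence
    assert table.sequences == ["GGT", "AAT", "ACT"]
    assert table.counts == [3, 2, 1]
    assert table.n_samples == 6


def test_most_common_haplotype_and_tie_break(aln_factory):
    table = collapse_haplotypes(aln_factory({"a": "CT", "b": "CT", "c": "AT"}))
    assert most_common_haplotype(table) == "H01"
    tied = collapse_haplotypes(aln_factory({"a": "CT", "b": "AT"}))
    # tie broken by lexicographically smaller sequence
    assert tied.sequence_of(most_common_haplotype(tied)) == "AT"


def test_assign_groups_partition(aln_factory):
    aln = aln_factory(
        {"anc1": "AA", "anc2": "CC", "mod1": "AA", "mod2": "GG", "mod3": "AA"}
    )
    table = collapse_haplotypes(aln)
    scheme = assign_groups(table, ancient_ids={"anc1", "anc2"}, modern_ids={"mod1", "mod2", "mod3"})
    by_seq = {table.sequence_of(lab): g for lab, g in scheme.group_of.items()}
    assert by_seq == {
        "AA": "common",
        "CC": "unique_ancient",
        "GG": "not_found_in_ancient",
    }
    # partition: every haplotype in exactly one group
    assert set(scheme.group_of) == set(table.labels)


def test_assign_groups_shared_non_common(aln_factory):
    aln = aln_factory(
        {"anc1": "AA", "mod1": "AA", "mod2": "GG", "mod3": "GG", "mod4": "GG"}
    )
    table = collapse_haplotypes(aln)
    scheme = assign_groups(table, {"anc1"}, {"mod1", "mod2", "mod3", "mod4"})
    by_seq = {table.sequence_of(lab): g for lab, g in scheme.group_of.items()}
    assert by_seq["GG"] == "common"
    assert by_seq["AA"] == "ancient_shared"


def test_assign_groups_overlap_rejected(aln_factory):
    table = collapse_haplotypes(aln_factory({"a": "AA", "b": "CC"}))
    with pytest.raises(ValueError, match="overlap"):
        assign_groups(table, {"a"}, {"a", "b"})


@pytest.mark.parametrize(
    "date, period",
    [
        (1300, "Medieval"),
        (1550, "Post-Medieval"),  # half-open boundary
        (1200, "Medieval"),
        (1199, "Prehistoric"),
        (-700, "Prehistoric"),
        (1850, "Modern"),
    ],
)
def test_assign_period_bins(date, period):
    assert assign_period(SampleRecord(id="s", date_early=date, date_late=date)) == period


def test_assign_period_range_binned_by_midpoint():
    rec = SampleRecord(id="s", date_early=1500, date_late=1600)  # midpoint 1550
    assert assign_period(rec) == "Post-Medieval"


def test_assign_period_out_of_range():
    with pytest.raises(ValueError, match="out of covered range"):
        assign_period(SampleRecord(id="s", date_early=-800, date_late=-800))


def _cohort_samples():
    recs = []
    for i in range(5):
        recs.append(SampleRecord(id=f"p{i}", date_early=900, date_late=900, region="FI"))
    for i in range(14):
        recs.append(SampleRecord(id=f"m{i}", date_early=1300, date_late=1300, region="FI"))
    return recs


def test_build_counts_pooled_cohort_size():
    # Prehistoric + Medieval pooled: n = 5 + 14 = 19
    def pooled(rec):
        p = assign_period(rec)
        return "Prehistoric and Medieval" if p in ("Prehistoric", "Medieval") else p

    table = build_counts(_cohort_samples(), row_by=pooled, col_by="region")
    assert table.total == 19
    assert table.row_totals.tolist() == [19]


def test_build_counts_single_sample():
    table = build_counts([SampleRecord(id="s", period="Medieval", region="FI")],
                         row_by="period", col_by="region")
    assert table.shape == (1, 1) and table.total == 1


def test_build_counts_empty_errors():
    with pytest.raises(ValueError, match="no samples"):
        build_counts([], row_by="period", col_by="region")


def test_contingency_invariants():
    t = ContingencyTable(["r1", "r2"], ["c1", "c2"], [[1, 2], [3, 4]])
    assert t.total == 10
    assert t.row_totals.tolist() == [3, 7]
    assert t.col_totals.tolist() == [4, 6]
    with pytest.raises(ValueError, match="negative"):
        ContingencyTable(["r"], ["c"], [[-1]])


def test_haplotype_table_count_member_consistency():
    with pytest.raises(ValueError, match="count"):
        HaplotypeTable(["H01"], ["AA"], [2], [["only-one"]])
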