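"""Circular coordinates, FASTA/metadata I/O and age resolution."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paleocattle.seqio import (
    BOVINE_MT,
    CircularReference,
    DLOOP_REGION,
    ND5_REGION,
    Q_FRAGMENT_REGION,
    AlignedSeqSet,
    FormatError,
    RegionSpec,
    SampleRecord,
    concat_regions,
    read_alignment,
    read_metadata,
    region_length,
    sample_age,
    write_alignment,
)


@pytest.mark.parametrize(
    "region, expected",
    [
        (DLOOP_REGION, 486),          # wraps through the origin: 16031..178
        (ND5_REGION, 181),
        (Q_FRAGMENT_REGION, 77),
        (RegionSpec(9, 2, CircularReference("toy", 10)), 4),  # 9,10,1,2
        (RegionSpec(1, 10, CircularReference("toy", 10)), 10),
    ],
)
def test_region_length(region, expected):
    assert region_length(region) == expected
    assert len(region.positions()) == expected


def test_dloop_positions_wrap_in_circular_order():
    pos = DLOOP_REGION.positions()
    assert pos[0] == 16031 and pos[-1] == 178
    assert 16338 in pos and 1 in pos


@given(
    length=st.integers(2, 500),
    start=st.integers(1, 500),
    end=st.integers(1, 500),
    shift=st.integers(0, 500),
)
def test_region_length_invariant_under_origin_rotation(length, start, end, shift):
    start, end = (start - 1) % length + 1, (end - 1) % length + 1
    ref = CircularReference("toy", length)
    rotated = RegionSpec(
        (start - 1 + shift) % length + 1, (end - 1 + shift) % length + 1, ref
    )
    assert region_length(RegionSpec(start, end, ref)) == region_length(rotated)


def test_position_outside_reference_rejected():
    with pytest.raises(ValueError, match="outside"):
        RegionSpec(0, 5, CircularReference("toy", 10))
    with pytest.raises(ValueError, match="outside"):
        RegionSpec(1, 11, CircularReference("toy", 10))


def test_read_alignment_roundtrip(tmp_path):
    region = RegionSpec(9, 2, CircularReference("toy", 10))
    aln = AlignedSeqSet(["s1", "s2"], region.positions(), ["ACGT", "AC-T"])
    path = tmp_path / "x.fasta"
    write_alignment(aln, path)
    back = read_alignment(path, region)
    assert back.ids == aln.ids and back.rows == aln.rows and back.columns == aln.columns


def test_read_alignment_uppercases_and_maps_unknown(tmp_path):
    path = tmp_path / "x.fasta"
    path.write_text(">s1\nacgt\n>s2\nac?t\n")
    region = RegionSpec(1, 4, CircularReference("toy", 10))
    aln = read_alignment(path, region)
    assert aln.row("s1") == "ACGT"
    assert aln.row("s2") == "ACNT"


def test_read_alignment_length_mismatch_names_record(tmp_path):
    path = tmp_path / "x.fasta"
    path.write_text(">good\nACGT\n>bad\nACG\n")
    with pytest.raises(FormatError, match="bad"):
        read_alignment(path, RegionSpec(1, 4, CircularReference("toy", 10)))


def test_read_alignment_empty_file(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    with pytest.raises(FormatError, match="no FASTA"):
        read_alignment(path, RegionSpec(1, 4, CircularReference("toy", 10)))


def test_concat_regions_builds_667bp_haplotype_region(tmp_path):
    ids = [f"a{i}" for i in range(3)]
    dloop = AlignedSeqSet(ids, DLOOP_REGION.positions(), ["A" * 486] * 3)
    nd5 = AlignedSeqSet(ids, ND5_REGION.positions(), ["C" * 181] * 3)
    combined = concat_regions([dloop, nd5])
    assert combined.n_columns == 667
    assert combined.row("a0") == "A" * 486 + "C" * 181


def test_concat_regions_single_set_unchanged(aln_factory):
    aln = aln_factory({"s": "ACGT"})
    assert concat_regions([aln]) is aln


def test_concat_regions_id_mismatch(aln_factory):
    a = aln_factory({"s1": "AC"})
    b = aln_factory({"s2": "GT"}, start=10)
    with pytest.raises(FormatError, match="s1|s2"):
        concat_regions([a, b])


def test_duplicate_ids_rejected():
    with pytest.raises(FormatError, match="duplicate"):
        AlignedSeqSet(["s", "s"], (1, 2), ["AC", "GT"])


METADATA = """id\tsite\tregion\tperiod\tdate_early\tdate_late\tage_bp\tsex
c1\tTurku\tFinland\tMedieval\t1200\t1550\t\tmale
c2\tTurku\tFinland\t\t\t\t900\t
"""


def test_read_metadata_parses_and_defaults(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text(METADATA)
    records = read_metadata(path)
    assert records[0].period == "Medieval"
    assert records[0].date_early == 1200 and records[0].date_late == 1550
    assert records[1].sex == "unknown"
    assert records[1].age_bp == 900


def test_read_metadata_duplicate_id(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text("id\tsex\nc1\tmale\nc1\tmale\n")
    with pytest.raises(FormatError, match=":3.*duplicate|duplicate"):
        read_metadata(path)


def test_read_metadata_bad_date_reports_row(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text("id\tdate_early\nc1\tmedieval-ish\n")
    with pytest.raises(FormatError, match=":2"):
        read_metadata(path)


def test_sample_age_point_age_passthrough():
    rec = SampleRecord(id="c", age_bp=900)
    assert sample_age(rec, seed=0) == 900


def test_sample_age_uniform_draw_reproducible():
    rec = SampleRecord(id="c", date_early=1200, date_late=1550)
    ages = [sample_age(rec, seed=7) for _ in range(3)]
    assert ages[0] == ages[1] == ages[2]
    # within the BP range implied by the calendar range (datum 1950)
    assert 1950 - 1550 <= ages[0] <= 1950 - 1200
    assert sample_age(rec, seed=8) != ages[0]


def test_sample_age_degenerate_range():
    rec = SampleRecord(id="c", date_early=1500, date_late=1500)
    assert sample_age(rec, seed=0) == 450


def test_sample_age_requires_information():
    with pytest.raises(ValueError, match="no age"):
        sample_age(SampleRecord(id="c"), seed=0)
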