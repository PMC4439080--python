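"""Alignment and metadata I/O on circular mitochondrial coordinates.

The bovine mitochondrial genome is circular, and the amplified fragments are
addressed in 1-based inclusive coordinates of the reference sequence
(GenBank-style), so a fragment may wrap through the origin — the D-loop
fragment runs from position 16031 through the origin to position 178.
This module reads pre-aligned FASTA fragments into :class:`AlignedSeqSet`
objects whose columns carry those reference positions, reads per-sample
metadata tables, and resolves context-dated samples to point ages.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: canonical nucleotide symbols kept as-is; everything else becomes N
IUPAC_SYMBOLS = frozenset("ACGTRYSWKMBDHVN-")

#: years-before-present datum used to convert calendar dates (radiocarbon convention)
BP_REFERENCE_YEAR = 1950


class FormatError(ValueError):
    """Malformed input file (wrong record length, duplicate ids, bad dates)."""


@dataclass(frozen=True)
class CircularReference:
    """A circular reference sequence addressed in 1-based coordinates."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"reference length must be >= 1, got {self.length}")


#: the bovine mitochondrial reference (V00654), 16338 sites
BOVINE_MT = CircularReference("V00654", 16338)


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive region on a circular reference.

    ``start`` may exceed ``end``, in which case the region wraps once through
    the origin (positions start..length, 1..end).
    """

    start: int
    end: int
    reference: CircularReference = BOVINE_MT

    def __post_init__(self) -> None:
        L = self.reference.length
        for pos in (self.start, self.end):
            if not 1 <= pos <= L:
                raise ValueError(f"position {pos} outside [1, {L}] on {self.reference.name}")

    @property
    def length(self) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return self.reference.length - self.start + 1 + self.end

    def positions(self) -> tuple[int, ...]:
        """Reference positions walked from start to end inclusive (wrapping once)."""
        L = self.reference.length
        if self.start <= self.end:
            return tuple(range(self.start, self.end + 1))
        return tuple(range(self.start, L + 1)) + tuple(range(1, self.end + 1))


# fragment definitions used throughout the analysis
DLOOP_REGION = RegionSpec(16031, 178)          # 486 bp control region
ND5_REGION = RegionSpec(12911, 13091)          # 181 bp ND5 fragment
Q_FRAGMENT_REGION = RegionSpec(15936, 16012)   # 77 bp fragment carrying the Q diagnostic


def region_length(region: RegionSpec) -> int:
    """Number of positions walking the circle from start to end inclusive."""
    return region.length


Regions = RegionSpec | Sequence[RegionSpec]


def region_positions(region: Regions) -> tuple[int, ...]:
    """Column positions of one region or of several disjoint fragments in order."""
    if isinstance(region, RegionSpec):
        return region.positions()
    positions: tuple[int, ...] = ()
    for frag in region:
        if set(positions) & set(frag.positions()):
            raise ValueError("fragments share positions")
        positions += frag.positions()
    return positions


@dataclass
class AlignedSeqSet:
    """An alignment whose columns are reference positions of a region.

    Rows are per-sample symbol strings over {A,C,G,T,-,N, IUPAC ambiguity};
    all rows have the same length and ids are unique.
    """

    ids: list[str]
    columns: tuple[int, ...]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes}")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != len(self.columns):
                raise FormatError(
                    f"record {sid!r}: length {len(row)} != {len(self.columns)} columns"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def row(self, sample_id: str) -> str:
        return self.rows[self.ids.index(sample_id)]

    def site(self, sample_id: str, position: int) -> str:
        """Symbol of one sample at a reference position."""
        return self.row(sample_id)[self.columns.index(position)]

    def position_map(self, sample_id: str) -> dict[int, str]:
        """Reference position -> symbol for one sample."""
        return dict(zip(self.columns, self.row(sample_id)))

    def subset(self, ids: Iterable[str]) -> "AlignedSeqSet":
        keep = [i for i in self.ids if i in set(ids)]
        return AlignedSeqSet(keep, self.columns, [self.row(i) for i in keep])

    def matrix(self) -> np.ndarray:
        """Alignment as an (n_samples, n_columns) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="<U1")


def _clean_symbols(seq: str, record_id: str) -> str:
    seq = seq.upper()
    bad = sorted(set(seq) - IUPAC_SYMBOLS)
    if bad:
        logger.warning("record %s: unknown symbols %s mapped to N", record_id, bad)
        seq = "".join(c if c in IUPAC_SYMBOLS else "N" for c in seq)
    return seq


def read_alignment(path: str | Path, region: Regions) -> AlignedSeqSet:
    """Read a pre-aligned FASTA whose records span ``region``.

    ``region`` may be a single :class:`RegionSpec` or a sequence of disjoint
    fragments whose columns are concatenated in order.  Record length must
    equal the total region length; symbols are upper-cased and anything
    outside the nucleotide/IUPAC alphabet is mapped to N with a logged
    warning.
    """
    positions = region_positions(region)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    ids, rows = [], []
    for rec in records:
        seq = _clean_symbols(str(rec.seq), rec.id)
        if len(seq) != len(positions):
            raise FormatError(
                f"record {rec.id!r}: length {len(seq)} does not match the "
                f"{len(positions)} bp region"
            )
        ids.append(rec.id)
        rows.append(seq)
    return AlignedSeqSet(ids, positions, rows)


def write_alignment(aln: AlignedSeqSet, path: str | Path) -> None:
    """Write an alignment back to FASTA (one record per sample)."""
    records = [
        SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def concat_regions(sets: Sequence[AlignedSeqSet]) -> AlignedSeqSet:
    """Concatenate alignments of disjoint regions over the same samples.

    The sets must have identical id ordering (e.g. the 486 bp D-loop and the
    181 bp ND5 fragments combine into the 667 bp haplotype region).
    """
    if not sets:
        raise ValueError("no alignments to concatenate")
    if len(sets) == 1:
        return sets[0]
    first = sets[0]
    for other in sets[1:]:
        if other.ids != first.ids:
            missing = sorted(set(first.ids) ^ set(other.ids))
            raise FormatError(f"id mismatch between alignments: {missing or 'order differs'}")
    columns: tuple[int, ...] = ()
    for s in sets:
        if set(columns) & set(s.columns):
            raise FormatError("regions to concatenate share columns")
        columns += s.columns
    rows = ["".join(s.rows[i] for s in sets) for i in range(len(first.ids))]
    return AlignedSeqSet(list(first.ids), columns, rows)


SEXES = ("male", "female", "indeterminate", "unknown")


@dataclass
class SampleRecord:
    """Per-sample archaeological metadata.

    Calendar dates are in calendar years with negative values for BC; ``age_bp``
    is a point age in years before present (datum 1950) when available.
    """

    id: str
    site: str = ""
    region: str = ""
    period: str = ""
    date_early: float | None = None  # earliest calendar year of the context
    date_late: float | None = None   # latest calendar year of the context
    age_bp: float | None = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sample {self.id}: sex {self.sex!r} not in {SEXES}")
        if (
            self.date_early is not None
            and self.date_late is not None
            and self.date_early > self.date_late
        ):
            raise ValueError(f"sample {self.id}: date_early > date_late")

    @property
    def date_midpoint(self) -> float | None:
        if self.date_early is None or self.date_late is None:
            return None
        return (self.date_early + self.date_late) / 2.0


METADATA_COLUMNS = ("id", "site", "region", "period", "date_early", "date_late", "age_bp", "sex")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the per-sample TSV metadata table.

    Required column: ``id``; missing optional fields become empty/None/unknown.
    Duplicate ids and unparseable dates raise :class:`FormatError` with the
    offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'id'")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 2  # header is line 1
        sid = row["id"].strip()
        if not sid:
            raise FormatError(f"{path}:{rownum}: empty sample id")
        if sid in seen:
            raise FormatError(f"{path}:{rownum}: duplicate sample id {sid!r}")
        seen.add(sid)

        def num(col: str) -> float | None:
            val = str(row.get(col, "")).strip()
            if val == "":
                return None
            try:
                return float(val)
            except ValueError:
                raise FormatError(f"{path}:{rownum}: cannot parse {col}={val!r}") from None

        try:
            records.append(
                SampleRecord(
                    id=sid,
                    site=str(row.get("site", "")).strip(),
                    region=str(row.get("region", "")).strip(),
                    period=str(row.get("period", "")).strip(),
                    date_early=num("date_early"),
                    date_late=num("date_late"),
                    age_bp=num("age_bp"),
                    sex=str(row.get("sex", "")).strip() or "unknown",
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{rownum}: {exc}") from None
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "site": r.site,
                "region": r.region,
                "period": r.period,
                "date_early": r.date_early,
                "date_late": r.date_late,
                "age_bp": r.age_bp,
                "sex": r.sex,
            }
            for r in records
        ],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def sample_age(record: SampleRecord, seed: int) -> float:
    """Resolve a sample to a point age in years BP.

    A radiocarbon point age is returned as-is.  Context-dated samples carry
    only a calendar date range; their date is drawn uniformly over the range
    (the minimal assumption for a context interval) and converted to years
    before 1950.  The draw is a pure function of (record id, seed).
    """
    if record.age_bp is not None:
        return float(record.age_bp)
    if record.date_early is None or record.date_late is None:
        raise ValueError(f"sample {record.id}: no age or date-range information")
    if record.date_early == record.date_late:
        date = float(record.date_early)
    else:
        # per-record stream (stable CRC, not Python's salted hash) so the
        # draw depends on neither call order nor interpreter session
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32(record.id.encode())])
        )
        date = rng.uniform(record.date_early, record.date_late)
    return max(0.0, BP_REFERENCE_YEAR - date)
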