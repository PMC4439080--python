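"""Haplotype collapsing, grouping schemes, temporal cohorts and count tables.

Aligned sequences are collapsed into distinct haplotypes (after a missing-data
policy), labelled canonically H01, H02, ... by descending carrier count and
then lexicographic sequence, so labels do not depend on input order.  The
grouping scheme follows the comparison of ancient against modern panels:
the single most frequent haplotype of the combined dataset ("common"), other
haplotypes shared between ancient and modern samples ("ancient_shared"),
haplotypes seen only in ancient samples ("unique_ancient") and haplotypes
absent from the ancient panel ("not_found_in_ancient").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import AlignedSeqSet, SampleRecord

logger = logging.getLogger(__name__)

GROUPS = ("common", "ancient_shared", "unique_ancient", "not_found_in_ancient", "other")

#: temporal cohort edges in calendar years (negative = BC); half-open bins
PERIOD_BINS = (
    ("Prehistoric", -700.0, 1200.0),
    ("Medieval", 1200.0, 1550.0),
    ("Post-Medieval", 1550.0, 1800.0),
    ("Modern", 1800.0, float("inf")),
)


@dataclass
class HaplotypeTable:
    """Distinct haplotype sequences with counts, member ids and labels."""

    labels: list[str]
    sequences: list[str]
    counts: list[int]
    members: list[list[str]]
    columns: tuple[int, ...] = ()  # reference positions retained after the missing-data policy

    def __post_init__(self) -> None:
        if len({*self.labels}) != len(self.labels):
            raise ValueError("haplotype labels must be unique")
        for c, m in zip(self.counts, self.members):
            if c != len(m):
                raise ValueError("count does not match member list")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return sum(self.counts)

    def label_of(self, sample_id: str) -> str:
        for lab, mem in zip(self.labels, self.members):
            if sample_id in mem:
                return lab
        raise KeyError(sample_id)

    def sequence_of(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": self.labels,
                "count": self.counts,
                "members": [",".join(m) for m in self.members],
                "sequence": self.sequences,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _complete_deletion_columns(aln: AlignedSeqSet) -> list[int]:
    """Indices of columns free of '-' and 'N' in every sample."""
    mat = aln.matrix()
    keep = ~np.any((mat == "-") | (mat == "N"), axis=0)
    return list(np.flatnonzero(keep))


def collapse_haplotypes(
    aln: AlignedSeqSet, missing_policy: str = "complete_deletion"
) -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes.

    Under ``complete_deletion`` (the default, mirroring the usual behaviour of
    haplotype software on alignments with missing data) every column carrying
    a gap or an N in any sample is removed before comparison.  Under
    ``pairwise`` all columns are kept and a sequence joins the first existing
    haplotype it is compatible with (N matching anything); this greedy merge
    is order-canonicalised and intended for sensitivity checks only.
    """
    if len(aln) == 0:
        raise ValueError("empty alignment")
    if missing_policy == "complete_deletion":
        keep = _complete_deletion_columns(aln)
        if not keep:
            raise ValueError("no informative sites: every column has missing data")
        columns = tuple(aln.columns[i] for i in keep)
        reduced = {sid: "".join(aln.row(sid)[i] for i in keep) for sid in aln.ids}
        groups: dict[str, list[str]] = {}
        for sid in sorted(aln.ids):
            groups.setdefault(reduced[sid], []).append(sid)
    elif missing_policy == "pairwise":
        columns = aln.columns
        seqs: list[str] = []
        groups = {}
        for sid in sorted(aln.ids):
            row = aln.row(sid)
            for s in seqs:
                if all(a == b or "N" in (a, b) for a, b in zip(row, s)):
                    groups[s].append(sid)
                    break
            else:
                seqs.append(row)
                groups[row] = [sid]
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    # canonical labelling: count-desc, then lexicographic sequence
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    labels = [f"H{i + 1:02d}" for i in range(len(ordered))]
    return HaplotypeTable(
        labels=labels,
        sequences=[seq for seq, _ in ordered],
        counts=[len(mem) for _, mem in ordered],
        members=[sorted(mem) for _, mem in ordered],
        columns=columns,
    )


def most_common_haplotype(table: HaplotypeTable) -> str:
    """Label of the haplotype with the highest carrier count.

    Ties are broken by lexicographically smallest sequence, deterministically.
    """
    if len(table) == 0:
        raise ValueError("empty haplotype table")
    best = min(range(len(table)), key=lambda i: (-table.counts[i], table.sequences[i]))
    return table.labels[best]


@dataclass
class GroupingScheme:
    """Assignment of each haplotype to exactly one comparison group."""

    name: str
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.group_of.values()} - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}")

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.group_of.items()), columns=["haplotype", "group"]
        ).to_csv(path, sep="\t", index=False)


def assign_groups(
    table: HaplotypeTable, ancient_ids: Iterable[str], modern_ids: Iterable[str]
) -> GroupingScheme:
    """Group haplotypes by their occurrence in ancient vs modern panels.

    The most frequent haplotype overall is "common"; the remaining haplotypes
    are "ancient_shared" (carried by both panels), "unique_ancient" (ancient
    only) or "not_found_in_ancient" (modern only).
    """
    ancient, modern = set(ancient_ids), set(modern_ids)
    if ancient & modern:
        raise ValueError(f"ancient/modern id sets overlap: {sorted(ancient & modern)}")
    all_members = {m for mem in table.members for m in mem}
    uncovered = all_members - ancient - modern
    if uncovered:
        raise ValueError(f"samples in neither panel: {sorted(uncovered)}")
    common = most_common_haplotype(table)
    group_of: dict[str, str] = {}
    for lab, mem in zip(table.labels, table.members):
        n_anc = sum(1 for m in mem if m in ancient)
        n_mod = len(mem) - n_anc
        if lab == common:
            group_of[lab] = "common"
        elif n_anc and n_mod:
            group_of[lab] = "ancient_shared"
        elif n_anc:
            group_of[lab] = "unique_ancient"
        else:
            group_of[lab] = "not_found_in_ancient"
    return GroupingScheme("ancient_vs_modern", group_of)


def assign_period(record: SampleRecord) -> str:
    """Temporal cohort of a sample from its calendar date.

    Bins are half-open: [700 BC, 1200), [1200, 1550), [1550, 1800) and
    [1800, inf) = Modern; date ranges are binned by their midpoint.
    """
    date = record.date_midpoint
    if date is None:
        if record.date_early is not None:
            date = float(record.date_early)
        elif record.date_late is not None:
            date = float(record.date_late)
        else:
            raise ValueError(f"sample {record.id}: no date information")
    for name, lo, hi in PERIOD_BINS:
        if lo <= date < hi:
            return name
    raise ValueError(f"sample {record.id}: date {date} out of covered range (before 700 BC)")


@dataclass
class ContingencyTable:
    """A labelled non-negative integer cross-tabulation."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContingencyTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())


def build_counts(
    samples: Sequence[SampleRecord],
    row_by: str | Callable[[SampleRecord], str],
    col_by: str | Callable[[SampleRecord], str],
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate samples by two fields (or callables) into a count table."""
    if not samples:
        raise ValueError("no samples to tabulate")

    def getter(spec: str | Callable[[SampleRecord], str]) -> Callable[[SampleRecord], str]:
        if callable(spec):
            return spec
        return lambda rec: str(getattr(rec, spec))

    rget, cget = getter(row_by), getter(col_by)
    rows = [rget(s) for s in samples]
    cols = [cget(s) for s in samples]
    row_labels = list(row_order) if row_order else sorted(set(rows))
    col_labels = list(col_order) if col_order else sorted(set(cols))
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for r, c in zip(rows, cols):
        counts[row_labels.index(r), col_labels.index(c)] += 1
    return ContingencyTable(row_labels, col_labels, counts)
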