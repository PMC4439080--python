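"""Diagnostic-site haplogroup classification for taurine mtDNA, and Y1/Y2 calls.

Taurine mitochondrial haplogroups (the T family, Q, P, R and sub-groups such
as T3b or T1f) are defined by diagnostic substitutions at known reference
positions; classification walks a rule tree and returns the deepest rule whose
required alleles all match.  The rule set is data, not code: a default bovine
configuration ships with the package but any site list can be loaded.

Paternal lineages are called from a single diagnostic transversion in intron
19 of the Y-chromosomal UTY gene, which separates haplotypes Y1 and Y2; which
allele maps to which label is configuration, not an assertion of ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .seqio import AlignedSeqSet

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: IUPAC ambiguity expansions (ambiguity covering the required base is
#: "not contradicted" but does not advance classification depth)
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class RuleSetError(ValueError):
    """Invalid haplogroup rule configuration."""


@dataclass(frozen=True)
class DiagnosticRule:
    """One haplogroup rule: required alleles at reference positions."""

    label: str
    parent: str | None
    required: Mapping[int, str]


@dataclass
class HaplogroupRuleSet:
    """A tree of diagnostic rules rooted at the macro-haplogroups."""

    rules: list[DiagnosticRule]
    default_label: str = "T3"

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise RuleSetError("duplicate rule labels")
        self._by_label = {r.label: r for r in self.rules}
        for rule in self.rules:
            if rule.parent is not None and rule.parent not in self._by_label:
                raise RuleSetError(f"rule {rule.label}: unknown parent {rule.parent}")
        # acyclicity + parent consistency
        for rule in self.rules:
            seen = {rule.label}
            inherited: dict[int, str] = dict(rule.required)
            node = rule
            while node.parent is not None:
                node = self._by_label[node.parent]
                if node.label in seen:
                    raise RuleSetError(f"cycle through rule {node.label}")
                seen.add(node.label)
                for pos, allele in node.required.items():
                    if inherited.setdefault(pos, allele) != allele:
                        raise RuleSetError(
                            f"rule {rule.label} contradicts ancestor {node.label} "
                            f"at position {pos}"
                        )

    def rule(self, label: str) -> DiagnosticRule:
        return self._by_label[label]

    def children(self, label: str | None) -> list[DiagnosticRule]:
        return [r for r in self.rules if r.parent == label]

    def depth(self, label: str) -> int:
        d, node = 0, self._by_label[label]
        while node.parent is not None:
            node = self._by_label[node.parent]
            d += 1
        return d

    def path_profile(self, label: str) -> dict[int, str]:
        """All required alleles accumulated from the root down to ``label``."""
        profile: dict[int, str] = {}
        node: DiagnosticRule | None = self._by_label[label]
        while node is not None:
            for pos, allele in node.required.items():
                profile.setdefault(pos, allele)
            node = self._by_label[node.parent] if node.parent else None
        return profile

    @property
    def diagnostic_positions(self) -> frozenset[int]:
        return frozenset(p for r in self.rules for p in r.required)


def _parse_sites(text: str) -> dict[int, str]:
    text = text.strip()
    if text in ("", "-"):
        return {}
    out: dict[int, str] = {}
    for item in text.split(","):
        pos, _, allele = item.partition("=")
        allele = allele.strip().upper()
        if allele not in "ACGT" or not allele:
            raise RuleSetError(f"bad allele in {item!r}")
        out[int(pos)] = allele
    return out


def load_ruleset(path: str | Path, reference_length: int | None = 16338) -> HaplogroupRuleSet:
    """Load a diagnostic rule set from its TSV configuration.

    Lines are ``label<TAB>parent<TAB>pos=allele[,pos=allele...]`` with ``-``
    for "no parent" / "no extra sites"; ``# default_label:`` comments set the
    label of the all-reference profile.
    """
    rules: list[DiagnosticRule] = []
    default_label = "T3"
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "default_label:" in line:
                default_label = line.split("default_label:")[1].strip()
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise RuleSetError(f"bad rule line: {line!r}")
        label, parent, sites = parts
        required = _parse_sites(sites)
        if reference_length is not None:
            for pos in required:
                if not 1 <= pos <= reference_length:
                    raise RuleSetError(f"rule {label}: position {pos} outside reference")
        rules.append(
            DiagnosticRule(label.strip(), None if parent.strip() in ("", "-") else parent.strip(), required)
        )
    if not rules:
        raise RuleSetError(f"{path}: no rules")
    return HaplogroupRuleSet(rules, default_label=default_label)


def default_ruleset() -> HaplogroupRuleSet:
    """The bovine rule set shipped with the package (user-replaceable data)."""
    with resources.as_file(
        resources.files("paleocattle.data").joinpath("bovine_mt_rules.tsv")
    ) as p:
        return load_ruleset(p)


_MATCH, _COMPATIBLE, _SKIP, _CONTRADICT = range(4)


def _site_status(symbol: str | None, allele: str) -> int:
    if symbol is None or symbol in ("N", "-"):
        return _SKIP
    expanded = _IUPAC.get(symbol, "")
    if symbol == allele:
        return _MATCH
    if allele in expanded:
        return _COMPATIBLE
    return _CONTRADICT


def classify_mt(profile: Mapping[int, str], rules: HaplogroupRuleSet) -> str:
    """Classify one sequence, given as reference position -> symbol.

    Returns the deepest rule whose required alleles all match exactly.  A rule
    with any required site missing or N is skipped (together with its
    subtree); an IUPAC ambiguity covering the required base does not
    contradict the rule but does not advance depth either.  If no diagnostic
    position of the rule set is covered, returns ``"unassigned"``.
    """
    covered = [p for p in rules.diagnostic_positions if profile.get(p, "N") not in ("N", "-", None)]
    if not covered:
        return UNASSIGNED

    best_label, best_depth = UNASSIGNED, -1

    def walk(rule, depth: int) -> None:
        nonlocal best_label, best_depth
        statuses = [_site_status(profile.get(p), a) for p, a in rule.required.items()]
        if any(s == _CONTRADICT for s in statuses) or any(s == _SKIP for s in statuses):
            return  # rule (and subtree) excluded / skipped
        exact = all(s == _MATCH for s in statuses)
        if exact and depth > best_depth:
            best_label, best_depth = rule.label, depth
        if exact:  # ambiguity does not advance depth, so descend only on exact match
            for child in rules.children(rule.label):
                walk(child, depth + 1)

    for root in rules.children(None):
        walk(root, 0)
    return best_label


def batch_classify(aln: AlignedSeqSet, rules: HaplogroupRuleSet) -> pd.DataFrame:
    """Classify every sample of an alignment; returns a (id, label) table."""
    out = [
        {"id": sid, "label": classify_mt(aln.position_map(sid), rules)} for sid in aln.ids
    ]
    return pd.DataFrame(out, columns=["id", "label"])


def label_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Summary counts per haplogroup label from a batch_classify table."""
    return calls["label"].value_counts().to_dict()


# --- Y chromosome -----------------------------------------------------------

#: reference position of the diagnostic UTY intron-19 transversion (AY936543)
UTY19_SITE = 423

#: shipped default allele->label mapping; configuration, not ground truth
DEFAULT_Y_MAPPING = {"G": "Y2", "T": "Y1"}

NO_AMPLIFICATION = "no_amplification"


@dataclass(frozen=True)
class YHaplotypeCall:
    sample_id: str
    allele: str
    label: str


def classify_y(
    sample_id: str,
    fragment: str,
    *,
    columns: Iterable[int] | None = None,
    site: int = UTY19_SITE,
    offset: int | None = None,
    mapping: Mapping[str, str] = DEFAULT_Y_MAPPING,
) -> YHaplotypeCall:
    """Call Y1/Y2 from a UTY intron-19 fragment.

    The diagnostic base is located either by reference coordinate (``site``
    plus per-base ``columns``) or by a 0-based ``offset`` into the fragment.
    Alleles outside the configured mapping (including N) yield
    ``no_amplification``.
    """
    if offset is None:
        if columns is None:
            raise ValueError("provide either columns+site or an explicit offset")
        cols = list(columns)
        if site not in cols:
            raise ValueError(f"fragment does not cover diagnostic site {site}")
        offset = cols.index(site)
    if not 0 <= offset < len(fragment):
        raise ValueError(f"fragment too short for offset {offset}")
    allele = fragment[offset].upper()
    return YHaplotypeCall(sample_id, allele, mapping.get(allele, NO_AMPLIFICATION))


def batch_classify_y(
    aln: AlignedSeqSet,
    *,
    site: int = UTY19_SITE,
    mapping: Mapping[str, str] = DEFAULT_Y_MAPPING,
) -> list[YHaplotypeCall]:
    return [
        classify_y(sid, aln.row(sid), columns=aln.columns, site=site, mapping=mapping)
        for sid in aln.ids
    ]
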