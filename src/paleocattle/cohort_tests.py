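"""Frequency tests on cohort count tables.

Pearson's chi-square (uncorrected, as in the classic SPSS output) for r x c
tables, and the two-tailed Fisher exact test (sum of hypergeometric
probabilities no larger than the observed table's) for 2 x 2 tables, with the
standard automatic selection rule: when 20% or more of the cells have
expected counts below 5 and the table is 2 x 2, the exact test is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .haplotyping import ContingencyTable

logger = logging.getLogger(__name__)

PEARSON, FISHER = "pearson_chisq", "fisher_exact"


@dataclass
class TestResult:
    method: str
    statistic: float | None
    df: int | None
    p_value: float
    expected: np.ndarray
    selection_reason: str = ""

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": None if self.statistic is None else round(float(self.statistic), 6),
            "df": self.df,
            "p_value": float(self.p_value),
            "selection_reason": self.selection_reason,
        }


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected counts E_ij = row_i * col_j / total under independence."""
    if min(table.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    rows, cols = table.row_totals, table.col_totals
    if table.total <= 0 or (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in contingency table")
    return np.outer(rows, cols) / table.total


def pearson_chisq(table: ContingencyTable) -> TestResult:
    """Uncorrected Pearson chi-square with df = (r-1)(c-1)."""
    expected = expected_counts(table)
    if (expected == 0).any():
        raise ValueError("zero expected count")
    chi2, p, df, _ = stats.chi2_contingency(table.counts, correction=False)
    return TestResult(PEARSON, float(chi2), int(df), float(p), expected)


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-tailed Fisher exact test on a 2x2 table.

    Two-tailed p is the sum over all tables with the observed margins whose
    hypergeometric probability does not exceed the observed one (the SPSS/R
    convention).
    """
    if table.shape != (2, 2):
        raise ValueError(
            "Fisher exact implemented for 2x2 tables; use pearson_chisq "
            "or a Monte-Carlo approximation for larger tables"
        )
    expected = expected_counts(table)
    _, p = stats.fisher_exact(table.counts, alternative="two-sided")
    return TestResult(FISHER, None, None, float(p), expected)


def select_test(table: ContingencyTable, small_expected_frac: float = 0.20) -> TestResult:
    """Automatic test selection.

    Fisher's exact test when >= ``small_expected_frac`` of the cells have
    expected counts < 5 and the table is 2x2; Pearson chi-square otherwise
    (with a logged caveat for small-expected tables larger than 2x2).
    """
    expected = expected_counts(table)
    frac_small = float(np.mean(expected < 5))
    if frac_small >= small_expected_frac:
        if table.shape == (2, 2):
            res = fisher_exact_2x2(table)
            res.selection_reason = (
                f"{frac_small:.0%} of cells with expected < 5; 2x2 -> Fisher exact"
            )
            return res
        logger.warning(
            "%.0f%% of cells have expected < 5 but table is %sx%s; "
            "chi-square may be unreliable",
            100 * frac_small, *table.shape,
        )
        res = pearson_chisq(table)
        res.selection_reason = (
            f"{frac_small:.0%} of cells with expected < 5 but table not 2x2 -> chi-square (caveat)"
        )
        return res
    res = pearson_chisq(table)
    res.selection_reason = f"{frac_small:.0%} of cells with expected < 5 -> chi-square"
    return res


def write_result(result: TestResult, path: str | Path) -> None:
    import json

    Path(path).write_text(
        json.dumps(
            {**result.as_dict(), "expected": result.expected.round(4).tolist()}, indent=2
        )
    )
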