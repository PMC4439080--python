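"""Sequence diversity statistics with a heterochrony correction.

Implements the classic summary suite for a cohort of aligned sequences —
segregating sites S, haplotype count h, haplotype diversity Hd, mean pairwise
differences K, nucleotide diversity pi = K/L, Watterson's theta_W = S/a1 and
Tajima's D with its beta-approximation significance — plus a correction for
heterochronous (serially sampled) data.

Ancient-DNA cohorts pool samples of different ages t_i (years BP).  A lineage
sampled t years ago has accumulated t years less mutation than a modern one,
so pairwise differences are inflated by mu_year * |t_i - t_j| relative to an
isochronous sample and pi over-estimates the population-scaled diversity.
The corrected estimate subtracts the mean pairwise-age term:

    pi_hmu = pi - rate * mean_{i<j} |t_i - t_j|

with the rate in substitutions per site per year.  The relative bias
(pi - pi_hmu) / pi_hmu is reported in percent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .haplotyping import HaplotypeTable, collapse_haplotypes
from .seqio import AlignedSeqSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TajimaComponents:
    """The a1..e2 constants of Tajima's D for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_components(n: int) -> TajimaComponents:
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaComponents(n, a1, a2, b1, b2, c1, c2, e1, e2)


def _retained_columns(aln: AlignedSeqSet) -> np.ndarray:
    """Column matrix with indel-bearing columns removed (indels excluded)."""
    mat = aln.matrix()
    keep = ~np.any(mat == "-", axis=0)
    return mat[:, keep]


def segregating_sites(aln: AlignedSeqSet) -> int:
    """Number of segregating sites, excluding indel columns; N symbols ignored."""
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    mat = _retained_columns(aln)
    S = 0
    for j in range(mat.shape[1]):
        symbols = {s for s in mat[:, j] if s != "N"}
        if len(symbols) >= 2:
            S += 1
    return S


def pairwise_k(aln: AlignedSeqSet) -> float:
    """Mean number of pairwise differences K over all C(n,2) pairs.

    Computed on indel-free columns; positions where either sequence is N are
    skipped for that pair.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    mat = _retained_columns(aln)
    n = len(aln)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            ok = (a != "N") & (b != "N")
            total += int(np.sum((a != b) & ok))
    return total / (n * (n - 1) / 2)


def analysed_length(aln: AlignedSeqSet) -> int:
    """Number of columns retained for K/pi (indel-free columns)."""
    return _retained_columns(aln).shape[1]


def haplotype_diversity(counts: Sequence[int], n: int | None = None) -> float:
    """Hd = n/(n-1) * (1 - sum p_i^2) from haplotype carrier counts."""
    counts = list(counts)
    if n is None:
        n = sum(counts)
    if n < 2:
        raise ValueError("need n >= 2")
    if sum(counts) != n:
        raise ValueError("counts do not sum to n")
    p = np.asarray(counts, dtype=float) / n
    return (n / (n - 1.0)) * (1.0 - float(np.sum(p**2)))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator theta_W = S / a1 (per sequence)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if S < 0:
        raise ValueError("S must be non-negative")
    return S / tajima_components(n).a1


def tajimas_d(n: int, S: int, K: float) -> float:
    """Tajima's D from sample size, segregating sites and mean differences.

    D = (K - S/a1) / sqrt(e1*S + e2*S*(S-1)); undefined (NaN) at S = 0.
    """
    if n < 4:
        raise ValueError("need n >= 4 for Tajima's D")
    if S == 0:
        logger.warning("Tajima's D undefined at S=0")
        return float("nan")
    c = tajima_components(n)
    return (K - S / c.a1) / math.sqrt(c.e1 * S + c.e2 * S * (S - 1))


def tajima_significance(D: float, n: int, alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided p for Tajima's D under the scaled-beta null approximation.

    D is assumed to follow a beta distribution rescaled to its theoretical
    range [Dmin, Dmax] with mean 0 and variance 1 (the approximation used by
    the classic implementations); returns (p, significant at ``alpha``).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if math.isnan(D):
        return float("nan"), False
    c = tajima_components(n)
    dmin = (2.0 / n - 1.0 / c.a1) / math.sqrt(c.e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / c.a1) / math.sqrt(c.e2)
    alpha_shape = -(1 + dmin * dmax) * dmax / (dmax - dmin)
    beta_shape = (1 + dmin * dmax) * dmin / (dmax - dmin)
    x = (D - dmin) / (dmax - dmin)
    cdf = float(stats.beta.cdf(np.clip(x, 0.0, 1.0), beta_shape, alpha_shape))
    p = 2.0 * min(cdf, 1.0 - cdf)
    return p, p < alpha


@dataclass(frozen=True)
class HeterochronyParams:
    """Parameters of the heterochrony correction.

    rate
        Substitution rate; by default per site per million years (e.g. 0.43
        for 43%/Myr), interpretation switched by ``rate_unit``:
        ``per_site_per_myr`` (default), ``per_site_per_year`` or
        ``per_site_per_generation`` (converted via ``generation_length``).
    generation_length
        Years per generation (used only under the per-generation rate unit
        and for reporting in generation time).
    ages
        Sample ages in years BP, one per sequence.
    """

    rate: float
    ages: tuple[float, ...]
    generation_length: float = 5.0
    rate_unit: str = "per_site_per_myr"

    def rate_per_site_per_year(self) -> float:
        if self.rate <= 0 or self.generation_length <= 0:
            raise ValueError("rate and generation_length must be positive")
        if self.rate_unit == "per_site_per_myr":
            return self.rate / 1.0e6
        if self.rate_unit == "per_site_per_year":
            return self.rate
        if self.rate_unit == "per_site_per_generation":
            return self.rate / self.generation_length
        raise ValueError(f"unknown rate_unit {self.rate_unit!r}")


def mean_pairwise_age_difference(ages: Sequence[float]) -> float:
    """Mean |t_i - t_j| over all pairs, in the units of ``ages``."""
    t = np.asarray(ages, dtype=float)
    n = len(t)
    if n < 2:
        raise ValueError("need at least 2 ages")
    return float(np.abs(t[:, None] - t[None, :]).sum() / (n * (n - 1)))


def heterochrony_correction(pi: float, params: HeterochronyParams) -> tuple[float, float]:
    """Corrected nucleotide diversity pi_hmu and relative bias in percent.

    pi_hmu = pi - rate_per_year * mean pairwise age difference; a negative
    corrected value is clamped to 0 with a warning.  Returns
    (pi_hmu, bias_pct) with bias_pct = (pi - pi_hmu)/pi_hmu * 100.
    """
    if pi < 0:
        raise ValueError("pi must be non-negative")
    c = params.rate_per_site_per_year() * mean_pairwise_age_difference(params.ages)
    pi_hmu = pi - c
    if pi_hmu < 0:
        logger.warning("corrected pi negative (%.3g); clamped to 0", pi_hmu)
        pi_hmu = 0.0
    bias = (pi - pi_hmu) / pi_hmu * 100.0 if pi_hmu > 0 else float("inf")
    return pi_hmu, bias


@dataclass
class DiversityEstimates:
    """The per-cohort summary row: N, S, h, Hd, K, theta_W, D, pi, pi_hmu, bias."""

    N: int
    S: int
    h: int
    Hd: float
    K: float
    theta_w: float
    D: float
    D_p: float
    D_significant: bool
    pi: float
    L: int
    pi_hmu: float | None = None
    bias_pct: float | None = None

    def as_dict(self) -> dict:
        return {
            "N": self.N, "S": self.S, "h": self.h,
            "Hd": round(self.Hd, 3), "K": round(self.K, 3),
            "theta_s": round(self.theta_w, 3),
            "D": round(self.D, 3), "D_p": round(self.D_p, 4),
            "D_significant": self.D_significant,
            "pi": self.pi, "L": self.L,
            "pi_hmu": self.pi_hmu, "bias_pct": self.bias_pct,
        }


def cohort_summary(
    aln: AlignedSeqSet,
    heterochrony: HeterochronyParams | None = None,
) -> DiversityEstimates:
    """Full diversity summary of one cohort alignment.

    pi = K/L on the indel-free columns; when heterochrony parameters are
    given, pi_hmu and the bias percentage are included.
    """
    n = len(aln)
    S = segregating_sites(aln)
    K = pairwise_k(aln)
    L = analysed_length(aln)
    table: HaplotypeTable = collapse_haplotypes(aln)
    pi = K / L
    D = tajimas_d(n, S, K) if (n >= 4 and S > 0) else float("nan")
    p, sig = tajima_significance(D, n) if not math.isnan(D) else (float("nan"), False)
    est = DiversityEstimates(
        N=n, S=S, h=len(table),
        Hd=haplotype_diversity(table.counts, n),
        K=K, theta_w=watterson_theta(S, n),
        D=D, D_p=p, D_significant=sig, pi=pi, L=L,
    )
    if heterochrony is not None:
        est.pi_hmu, est.bias_pct = heterochrony_correction(pi, heterochrony)
    return est
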