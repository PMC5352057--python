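"""Case-control genotype association for a biallelic SNP.

Implements the frequency summaries and the Pearson chi-squared test used
to compare rs2305089 (T gene, Gly177Asp) genotype distributions between a
chordoma group and a control group.  The chi-squared statistic is the
classic sum of (O-E)^2/E over the group x genotype grid with expectations
from the margins; no continuity correction is applied (Yates applies to
2x2 tables only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .models import GenotypeCohortTable

#: below this expected cell count the asymptotic chi-square reference is
#: conventionally considered questionable
SMALL_EXPECTED_COUNT = 5.0


def carrier_frequency(table: GenotypeCohortTable, group: str) -> float:
    """Fraction of individuals in ``group`` carrying >= 1 risk allele,
    i.e. (het + homalt) / n."""
    row = table.row(group)
    n = row.sum()
    if n == 0:
        raise ValueError(f"group {group!r} is empty")
    return float((row[1] + row[2]) / n)


def allele_frequency(table: GenotypeCohortTable, group: str) -> float:
    """Fraction of chromosomes in ``group`` bearing the risk allele,
    i.e. (het + 2 * homalt) / 2n.  Distinct from the carrier frequency:
    a mostly-heterozygous group has a high carrier but moderate allele
    frequency."""
    row = table.row(group)
    n = row.sum()
    if n == 0:
        raise ValueError(f"group {group!r} is empty")
    return float((row[1] + 2 * row[2]) / (2 * n))


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    min_expected: float
    small_expected_warning: bool
    p_monte_carlo: Optional[float] = None

    def p_rounded(self, sig: int = 2) -> float:
        """p to ``sig`` significant figures by rounding."""
        if self.p_value == 0:
            return 0.0
        from math import floor, log10

        digits = -int(floor(log10(abs(self.p_value)))) + (sig - 1)
        return round(self.p_value, digits)

    def p_truncated(self, sig: int = 2) -> float:
        """p to ``sig`` significant figures by truncation (a printed
        '0.0038' can arise from truncating 0.00387)."""
        if self.p_value == 0:
            return 0.0
        from math import floor, log10

        digits = -int(floor(log10(abs(self.p_value)))) + (sig - 1)
        scale = 10.0**digits
        return np.trunc(self.p_value * scale) / scale


def pearson_chisq(
    table: GenotypeCohortTable,
    monte_carlo: bool = False,
    n_monte_carlo: int = 10_000,
    mc_seed: int = 2305089,
) -> ChiSquareResult:
    """Pearson chi-squared test of genotype-by-group independence.

    Zero-margin rows/columns are dropped with a warning; a table left
    with fewer than 2 rows or columns is degenerate and raises.  The
    headline p-value is the asymptotic upper-tail chi-square probability
    with df = (r-1)(c-1); when any expected count is small an optional
    fixed-seed Monte-Carlo p (sampling tables with the observed margins)
    is computed alongside.
    """
    counts = np.asarray(table.counts, dtype=float)
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        warnings.warn("dropping zero-margin rows/columns from the table")
        counts = counts[row_keep][:, col_keep]
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValueError("degenerate table: need >= 2 groups and genotypes")
    row_m = counts.sum(axis=1, keepdims=True)
    col_m = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    expected = row_m @ col_m / total
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(statistic, df))
    min_expected = float(expected.min())
    small = min_expected < SMALL_EXPECTED_COUNT
    p_mc = None
    if monte_carlo:
        p_mc = _monte_carlo_p(counts, statistic, n_monte_carlo, mc_seed)
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=p,
        expected=expected,
        min_expected=min_expected,
        small_expected_warning=small,
        p_monte_carlo=p_mc,
    )


def _monte_carlo_p(
    counts: np.ndarray, observed: float, n_sim: int, seed: int
) -> float:
    """Monte-Carlo p: chi-square statistics of random tables with the
    observed margins (rows drawn sequentially by multivariate
    hypergeometric sampling), with the +1 correction."""
    rng = np.random.default_rng(seed)
    col_m = counts.sum(axis=0).astype(int)
    row_m = counts.sum(axis=1).astype(int)
    total = counts.sum()
    expected = np.outer(row_m, col_m) / total
    exceed = 0
    if counts.shape[0] == 2:
        rows1 = rng.multivariate_hypergeometric(col_m, int(row_m[0]),
                                                size=n_sim)
        rows2 = col_m[None, :] - rows1
        sim = np.stack([rows1, rows2], axis=1).astype(float)
        stat = ((sim - expected[None]) ** 2 / expected[None]).sum(axis=(1, 2))
        exceed = int((stat >= observed - 1e-12).sum())
    else:
        for _ in range(n_sim):
            remaining = col_m.copy()
            sim = np.empty_like(counts)
            for i, nrow in enumerate(row_m[:-1]):
                draw = rng.multivariate_hypergeometric(remaining, int(nrow))
                sim[i] = draw
                remaining = remaining - draw
            sim[-1] = remaining
            stat = ((sim - expected) ** 2 / expected).sum()
            if stat >= observed - 1e-12:
                exceed += 1
    return (exceed + 1) / (n_sim + 1)
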