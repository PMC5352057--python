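"""RPKM quantification and group-wise expression comparison.

RPKM = 10^9 * C / (N * L) for C reads on a gene of L exonic bases in a
library of N mapped reads.  Group comparisons use the Wilcoxon rank-sum
test on log2-transformed values: rank-based, hence invariant under any
monotone transform and robust at the 4-or-5-samples-per-group scale of a
small tumor cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix


def rpkm(count: float, gene_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp < 1:
        raise ValueError("gene length must be >= 1 bp")
    if library_size < 1:
        raise ValueError("library size must be >= 1 read")
    return 1e9 * count / (library_size * gene_length_bp)


def rpkm_matrix(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, float],
    library_sizes: Optional[Mapping[str, float]] = None,
    group_labels: Optional[Mapping[str, str]] = None,
) -> ExpressionMatrix:
    """RPKM for a gene x sample count table.

    Library sizes default to the column sums; gene length is the union of
    exon intervals, supplied per gene.
    """
    genes = list(counts.index)
    samples = list(counts.columns)
    missing = [g for g in genes if g not in gene_lengths]
    if missing:
        raise KeyError(f"no length for genes {missing}")
    lib = np.array(
        [
            library_sizes[s] if library_sizes is not None else counts[s].sum()
            for s in samples
        ],
        dtype=float,
    )
    if (lib < 1).any():
        raise ValueError("zero-read library")
    lengths = np.array([gene_lengths[g] for g in genes], dtype=float)
    values = 1e9 * counts.to_numpy(dtype=float) / (lib[None, :] * lengths[:, None])
    return ExpressionMatrix(
        genes=genes,
        samples=samples,
        values=values,
        group_labels=dict(group_labels or {}),
    )


def log2_matrix(
    matrix: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Elementwise log2(x + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return ExpressionMatrix(
        genes=list(matrix.genes),
        samples=list(matrix.samples),
        values=np.log2(matrix.values + pseudocount),
        group_labels=dict(matrix.group_labels),
    )


@dataclass
class GroupComparison:
    gene: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    direction: str  # 'a>b', 'b>a' or 'equal'
    statistic: float
    p_value: float


def compare_groups(
    matrix: ExpressionMatrix,
    gene: str,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> GroupComparison:
    """Two-sided rank-sum comparison of one gene between two groups.

    Values are log2(x + pseudocount)-transformed first (which cannot
    change the ranks, but matches how the comparison is reported).  Exact
    null enumeration is used for small tie-free samples, the tie-corrected
    normal approximation otherwise; fully tied data give p = 1 under the
    midrank convention.
    """
    a = np.log2(
        [
            matrix.gene_values(gene)[matrix.samples.index(s)] + pseudocount
            for s in matrix.samples_in_group(group_a)
        ]
    )
    b = np.log2(
        [
            matrix.gene_values(gene)[matrix.samples.index(s)] + pseudocount
            for s in matrix.samples_in_group(group_b)
        ]
    )
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupComparison(
            gene, group_a, group_b, len(a), len(b), mean_a, mean_b,
            "equal", float(len(a) * len(b) / 2), 1.0,
        )
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 10 and not has_ties) else \
        "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    if mean_a > mean_b:
        direction = "a>b"
    elif mean_b > mean_a:
        direction = "b>a"
    else:
        direction = "equal"
    return GroupComparison(
        gene, group_a, group_b, len(a), len(b), mean_a, mean_b,
        direction, float(res.statistic), float(res.pvalue),
    )


@dataclass
class FusionExpressionReport:
    """Expression of the fusion target gene in fusion-harbouring vs other
    samples.  ``descriptive_only`` is set when a partition has a single
    sample, as in a 4-versus-1 cohort, where no test is attempted."""

    gene: str
    n_fusion: int
    n_other: int
    mean_fusion: float
    mean_other: float
    fold: float
    descriptive_only: bool
    comparison: Optional[GroupComparison] = None


def fusion_expression_check(
    matrix: ExpressionMatrix,
    gene: str,
    fusion_samples: Sequence[str],
) -> FusionExpressionReport:
    """Compare a gene's expression between fusion and non-fusion samples."""
    fusion_samples = list(fusion_samples)
    others = [s for s in matrix.samples if s not in fusion_samples]
    if not fusion_samples or not others:
        raise ValueError("both partitions must be non-empty")
    values = matrix.gene_values(gene)
    v_f = np.array([values[matrix.samples.index(s)] for s in fusion_samples])
    v_o = np.array([values[matrix.samples.index(s)] for s in others])
    mean_f, mean_o = float(v_f.mean()), float(v_o.mean())
    fold = mean_f / mean_o if mean_o > 0 else float("inf")
    descriptive = min(len(v_f), len(v_o)) < 2
    comparison = None
    if not descriptive:
        labelled = ExpressionMatrix(
            genes=list(matrix.genes),
            samples=list(matrix.samples),
            values=matrix.values,
            group_labels={
                s: ("fusion" if s in fusion_samples else "other")
                for s in matrix.samples
            },
        )
        comparison = compare_groups(labelled, gene, "fusion", "other")
    return FusionExpressionReport(
        gene=gene,
        n_fusion=len(v_f),
        n_other=len(v_o),
        mean_fusion=mean_f,
        mean_other=mean_o,
        fold=fold,
        descriptive_only=descriptive,
        comparison=comparison,
    )
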