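"""Somatic mutation burden, substitution spectra and recurrence tallies.

Substitutions are collapsed onto the pyrimidine strand into six classes
(C>A, C>G, C>T, T>A, T>C, T>G) and stratified by their trinucleotide
context into the standard 96-channel spectrum: per class, a 4x4 grid with
the 5' flanking base on the vertical axis and the 3' base on the
horizontal axis.  Indels count toward the mutation burden (mut/Mb) but
carry no trinucleotide context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    NUCLEOTIDES,
    SomaticVariant,
    SUBSTITUTION_CLASSES,
    VariantKind,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_CLASS_INDEX = {c: i for i, c in enumerate(SUBSTITUTION_CLASSES)}

HYPERMUTATION_THRESHOLD = 10.0  # mut/Mb


def substitution_class(ref: str, alt: str) -> str:
    """Collapse a substitution onto the pyrimidine strand.

    Purine references are complemented: G>A becomes C>T, A>G becomes T>C,
    and so on, yielding one of the six canonical classes.
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in ("C", "T"):
        return f"{ref}>{alt}"
    return f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"


def trinucleotide_context(
    genome: Mapping[str, str], variant: SomaticVariant
) -> Optional[tuple[str, str, str]]:
    """(class, 5' base, 3' base) for an SNV, on the pyrimidine strand.

    When the reference base is a purine, the flanks are complemented and
    swapped so the context is reported on the pyrimidine strand.  Returns
    None — excluded, with a log record — for variants at a chromosome
    boundary or with an N anywhere in the trinucleotide.
    """
    if variant.kind is not VariantKind.SNV:
        raise ValueError("context is defined for SNVs only")
    seq = genome[variant.chrom]
    pos0 = variant.pos - 1
    if pos0 < 1 or pos0 >= len(seq) - 1:
        logger.warning(
            "variant at %s:%d has no flanking context; excluded",
            variant.chrom, variant.pos,
        )
        return None
    five, ref, three = seq[pos0 - 1], seq[pos0], seq[pos0 + 1]
    if any(b not in _COMPLEMENT for b in (five, ref, three)):
        logger.warning(
            "ambiguous base in context at %s:%d; excluded",
            variant.chrom, variant.pos,
        )
        return None
    if ref != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"genome has {ref}, variant says {variant.ref}"
        )
    cls = substitution_class(variant.ref, variant.alt)
    if variant.ref in ("C", "T"):
        return cls, five, three
    return cls, _COMPLEMENT[three], _COMPLEMENT[five]


@dataclass
class SpectrumMatrix:
    """Per-sample substitution spectrum: 6 classes x 4x4 contexts.

    ``context96[k, i, j]`` counts class k events with 5' base
    NUCLEOTIDES[i] and 3' base NUCLEOTIDES[j].  Conservation holds by
    construction: summing context96 over everything equals the number of
    context-resolvable SNVs, and the six-class totals include every SNV.
    """

    sample_id: str
    six_class: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SUBSTITUTION_CLASSES}
    )
    context96: np.ndarray = field(
        default_factory=lambda: np.zeros((6, 4, 4), dtype=np.int64)
    )
    n_snvs: int = 0
    n_indels: int = 0
    n_excluded: int = 0
    mut_per_mb: float = 0.0
    hypermutated: bool = False

    def class_total(self, cls: str) -> int:
        return self.six_class[cls]

    def context_frame(self) -> pd.DataFrame:
        """96-row tidy frame: class, five_prime, three_prime, count —
        ordering matches a 5'-vertical / 3'-horizontal heatmap layout."""
        rows = []
        for k, cls in enumerate(SUBSTITUTION_CLASSES):
            for i, five in enumerate(NUCLEOTIDES):
                for j, three in enumerate(NUCLEOTIDES):
                    rows.append((cls, five, three, int(self.context96[k, i, j])))
        return pd.DataFrame(
            rows, columns=["class", "five_prime", "three_prime", "count"]
        )


def build_spectrum(
    variants: Iterable[SomaticVariant],
    genome: Mapping[str, str],
    capture_mb: float,
    hyper_thresh: float = HYPERMUTATION_THRESHOLD,
    sample_id: Optional[str] = None,
) -> SpectrumMatrix:
    """Aggregate one sample's variants into a spectrum.

    ``capture_mb`` is the sequenced target size in megabases; the burden
    is (SNVs + indels) / capture_mb and the sample is flagged
    hypermutated above ``hyper_thresh``.
    """
    if capture_mb <= 0:
        raise ValueError("capture_mb must be > 0")
    variants = list(variants)
    sid = sample_id or (variants[0].sample_id if variants else "NA")
    spec = SpectrumMatrix(sample_id=sid)
    for v in variants:
        if v.kind is not VariantKind.SNV:
            spec.n_indels += 1
            continue
        spec.n_snvs += 1
        spec.six_class[substitution_class(v.ref, v.alt)] += 1
        ctx = trinucleotide_context(genome, v)
        if ctx is None:
            spec.n_excluded += 1
            continue
        cls, five, three = ctx
        spec.context96[
            _CLASS_INDEX[cls], _BASE_INDEX[five], _BASE_INDEX[three]
        ] += 1
    spec.mut_per_mb = (spec.n_snvs + spec.n_indels) / capture_mb
    spec.hypermutated = spec.mut_per_mb > hyper_thresh
    return spec


@dataclass
class NpCpGResult:
    """NpCpG C>T prominence of one spectrum.

    ``score`` is the fraction of context-resolved C>T events whose 3'
    base is G; ``flagged`` is None when the sample has too few SNVs for
    the fraction to mean anything (indeterminate, not an error).
    """

    score: Optional[float]
    flagged: Optional[bool]
    n_ct: int


def npcpg_prominence(
    spectrum: SpectrumMatrix,
    prominence_thresh: float = 0.5,
    min_snvs: int = 10,
) -> NpCpGResult:
    """Flag the deamination-style signature: C>T concentrated at NpCpG."""
    k = _CLASS_INDEX["C>T"]
    n_ct = int(spectrum.context96[k].sum())
    if spectrum.n_snvs < min_snvs or n_ct == 0:
        return NpCpGResult(score=None, flagged=None, n_ct=n_ct)
    at_g = int(spectrum.context96[k, :, _BASE_INDEX["G"]].sum())
    score = at_g / n_ct
    return NpCpGResult(
        score=score, flagged=score > prominence_thresh, n_ct=n_ct
    )


def recurrent_genes(
    mutated_genes_per_sample: Mapping[str, Iterable[str]],
    min_cases: int = 3,
    protein_changes_per_sample: Optional[
        Mapping[str, Iterable[tuple[str, str]]]
    ] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes mutated in at least ``min_cases`` distinct samples.

    Returns (gene recurrence, identical-protein-change recurrence); the
    second tracks the stricter pattern of the very same amino-acid change
    appearing in several cases and is empty when no protein-change data
    are supplied.  Both are sorted by case count (descending) then name.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    gene_cases: dict[str, set[str]] = {}
    for sample, genes in mutated_genes_per_sample.items():
        for gene in set(genes):
            gene_cases.setdefault(gene, set()).add(sample)
    rows = [
        (gene, len(samples))
        for gene, samples in gene_cases.items()
        if len(samples) >= min_cases
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    genes_df = pd.DataFrame(rows, columns=["gene", "n_cases"])

    change_rows: list[tuple[str, str, int]] = []
    if protein_changes_per_sample:
        change_cases: dict[tuple[str, str], set[str]] = {}
        for sample, changes in protein_changes_per_sample.items():
            for gene, change in set(changes):
                change_cases.setdefault((gene, change), set()).add(sample)
        change_rows = [
            (gene, change, len(samples))
            for (gene, change), samples in change_cases.items()
            if len(samples) >= min_cases
        ]
        change_rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    changes_df = pd.DataFrame(
        change_rows, columns=["gene", "protein_change", "n_cases"]
    )
    return genes_df, changes_df
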