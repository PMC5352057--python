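"""Domain types shared across the pipeline stages.

All genomic coordinates at these interfaces are 1-based inclusive, matching
how positions are reported in SAM/GTF and in the clinical genomics
literature.  Conversion to 0-based half-open happens only inside functions
that index into sequences or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

NUCLEOTIDES = ("A", "C", "G", "T")

#: The six pyrimidine-strand substitution classes, in conventional order.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True)
class GeneModel:
    """A gene: chromosome, strand, ordered exons and per-exon CDS phase.

    ``exons`` are (start, end) 1-based inclusive intervals stored in
    transcription order: ascending for '+' genes, descending genomic
    coordinates for '-' genes.  ``cds_phase_per_exon`` gives, for each
    coding exon, the number of bases at its transcript 5' edge that
    complete a codon begun in the previous exon (GTF frame convention);
    it is defined iff ``is_coding``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    is_coding: bool = True
    cds_phase_per_exon: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        exs = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exs)
        for s, e in exs:
            if s < 1 or e < s:
                raise ValueError(f"gene {self.gene_id}: bad exon interval ({s},{e})")
        genomic = sorted(exs)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if exs != tuple(expected):
            raise ValueError(
                f"gene {self.gene_id}: exons not in transcription order"
            )
        if self.is_coding:
            if self.cds_phase_per_exon is None:
                object.__setattr__(
                    self, "cds_phase_per_exon", self._default_phases()
                )
            elif len(self.cds_phase_per_exon) != len(exs):
                raise ValueError(
                    f"gene {self.gene_id}: need one phase per exon"
                )
            elif any(p not in (0, 1, 2) for p in self.cds_phase_per_exon):
                raise ValueError(f"gene {self.gene_id}: phases must be 0-2")
        elif self.cds_phase_per_exon is not None:
            raise ValueError(
                f"gene {self.gene_id}: phase defined for noncoding gene"
            )

    def _default_phases(self) -> tuple[int, ...]:
        phases, total = [], 0
        for s, e in self.exons:
            phases.append((-total) % 3)
            total += e - s + 1
        return tuple(phases)

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the gene span."""
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate of the gene span."""
        return max(e for _, e in self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def exon_index_at(self, pos: int) -> Optional[int]:
        """Transcript-order index of the exon containing ``pos``, or None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return i
        return None

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in genomic (ascending) order, 1-based inclusive."""
        genomic = sorted(self.exons)
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(genomic, genomic[1:])
        ]

    def cds_length_up_to(self, pos: int) -> int:
        """Exonic bases from the transcript 5' end through genomic ``pos``.

        For '+' genes this counts exon bases at coordinates <= pos; for '-'
        genes, exon bases at coordinates >= pos.
        """
        if not (self.start <= pos <= self.end):
            raise ValueError(
                f"position {pos} outside gene {self.gene_id} span"
            )
        total = 0
        for s, e in self.exons:
            if self.strand == "+":
                if e <= pos:
                    total += e - s + 1
                elif s <= pos:
                    total += pos - s + 1
            else:
                if s >= pos:
                    total += e - s + 1
                elif e >= pos:
                    total += e - pos + 1
        return total


@dataclass(frozen=True)
class MateAlignment:
    """One mate of a paired-end fragment: where and how long it aligned."""

    chrom: str
    start: int  # 1-based leftmost aligned position
    strand: str
    aligned_length: int

    def __post_init__(self) -> None:
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if self.start < 1:
            raise ValueError("start must be >= 1 (1-based)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned position."""
        return self.start + self.aligned_length - 1


@dataclass(frozen=True)
class ReadPairAlignment:
    pair_id: str
    mate1: MateAlignment
    mate2: MateAlignment
    mapping_ok: bool = True


class VariantKind(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic substitution or indel in one sample."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("variant position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.kind is VariantKind.SNV:
            if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
                raise ValueError(
                    f"SNV bases must be A/C/G/T, got {self.ref}>{self.alt}"
                )

    @property
    def kind(self) -> VariantKind:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantKind.SNV
        if len(self.ref) > len(self.alt):
            return VariantKind.DELETION
        return VariantKind.INSERTION


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient row of the clinical table."""

    patient_no: int
    age: float
    gender: str  # M / F
    subtype: str  # chondroid / typical / unknown
    location: str
    extent: str  # GTR / STR
    status: str  # primary / recurrence
    radiation: str  # Y / N / ND
    survival: str

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.extent not in ("GTR", "STR"):
            raise ValueError(f"extent must be GTR or STR, got {self.extent!r}")


@dataclass
class CoverageTrack:
    """Per-base read depth over one genomic region."""

    chrom: str
    start: int  # 1-based position of depth[0]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        return self.start + len(self.depth) - 1


class FrameStatus(str, Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    NONCODING = "noncoding"


@dataclass
class FusionCandidate:
    """A candidate gene fusion supported by discordant read pairs."""

    gene5: str
    gene3: str
    chrom5: str
    breakpoint5: int
    chrom3: str
    breakpoint3: int
    n_discordant_pairs: int
    n_junction_reads: int = 0
    frame_status: FrameStatus = FrameStatus.NONCODING

    def __post_init__(self) -> None:
        if self.gene5 == self.gene3:
            raise ValueError("fusion partners must be distinct genes")

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom5 == self.chrom3

    @property
    def breakpoint_distance(self) -> Optional[int]:
        if not self.intrachromosomal:
            return None
        return abs(self.breakpoint3 - self.breakpoint5)


@dataclass
class Segment:
    """A constant-copy-number run of consecutive windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    mean_log2: float
    call: str = "neutral"  # gain / loss / neutral


@dataclass
class GenotypeCohortTable:
    """Genotype counts per group for a biallelic SNP (e.g. rs2305089).

    ``counts[i, j]`` is the number of individuals in ``groups[i]`` with
    ``genotypes[j]``.  Genotype order is homref, het, homalt.
    """

    groups: tuple[str, ...]
    genotypes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        self.genotypes = tuple(self.genotypes)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.groups), len(self.genotypes)):
            raise ValueError("counts grid does not match group/genotype lists")
        if (self.counts < 0).any():
            raise ValueError("genotype counts must be non-negative")

    def row(self, group: str) -> np.ndarray:
        try:
            i = self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}") from None
        return self.counts[i]

    def group_size(self, group: str) -> int:
        return int(self.row(group).sum())

    @classmethod
    def from_individuals(
        cls,
        records: Sequence[tuple[str, str]],
        genotypes: Sequence[str] = ("G/G", "G/A", "A/A"),
    ) -> "GenotypeCohortTable":
        """Build the table from (group, genotype) per-individual records."""
        groups = tuple(dict.fromkeys(g for g, _ in records))
        gt = tuple(genotypes)
        counts = np.zeros((len(groups), len(gt)), dtype=np.int64)
        for group, genotype in records:
            if genotype not in gt:
                raise ValueError(f"unknown genotype {genotype!r}")
            counts[groups.index(group), gt.index(genotype)] += 1
        return cls(groups, gt, counts)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a sample-to-group labelling."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix dimensions do not match gene/sample lists")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    def gene_values(self, gene: str) -> np.ndarray:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_labels.get(s) == group]
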