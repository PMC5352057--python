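"""Readers and writers for every external format the pipeline touches.

Formats are deliberately plain-text: FASTA for sequence, a SAM text dialect
("SAM-lite") for paired-end alignments, and tab-separated tables for
variants, gene models, count matrices, genotype tables and the clinical
table.  Every TSV writer emits a leading comment line beginning '#';
readers skip '#' lines.  All coordinates in these files are 1-based
inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .models import (
    ClinicalRecord,
    GeneModel,
    MateAlignment,
    ReadPairAlignment,
    SomaticVariant,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# SAM flag bits actually consumed by the SAM-lite reader
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_FIRST_IN_PAIR = 0x40


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into a chrom -> uppercase sequence mapping.

    Record names are taken from the header up to the first whitespace.
    Duplicate names and empty files are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM-lite

def _aligned_length_from_cigar(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string (M/D/N/=/X ops)."""
    length = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            if ch in "MDN=X":
                length += int(num)
            elif ch not in "ISHP":
                raise ValueError(f"unknown CIGAR op {ch!r} in {cigar!r}")
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return length


def read_sam_lite(path: PathLike) -> list[ReadPairAlignment]:
    """Parse paired-end alignments from SAM text.

    Two dialects are accepted per line: standard >= 11-column SAM (only
    QNAME, FLAG, RNAME, POS and the CIGAR-derived aligned length are
    consumed, so real BAM-derived SAM text parses) and a minimal 5-column
    form QNAME FLAG RNAME POS LENGTH.  Records are paired by QNAME;
    QNAMEs without exactly two records are dropped with a logged count.
    """
    records: dict[str, list[tuple[int, MateAlignment, bool]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: too few columns")
            qname = fields[0]
            try:
                flag = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed FLAG {fields[1]!r}"
                ) from None
            rname = fields[2]
            pos = int(fields[3])
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: POS must be >= 1")
            if len(fields) >= 11:
                cigar = fields[5]
                if cigar != "*":
                    length = _aligned_length_from_cigar(cigar)
                elif fields[9] != "*":
                    length = len(fields[9])
                else:
                    raise ValueError(
                        f"{path}:{lineno}: no CIGAR and no sequence"
                    )
            else:
                length = int(fields[4])
            mate = MateAlignment(
                chrom=rname,
                start=pos,
                strand="-" if flag & _FLAG_REVERSE else "+",
                aligned_length=length,
            )
            mapped = not flag & _FLAG_UNMAPPED
            records.setdefault(qname, []).append((flag, mate, mapped))

    pairs: list[ReadPairAlignment] = []
    n_dropped = 0
    for qname, recs in records.items():
        if len(recs) != 2:
            n_dropped += len(recs)
            continue
        # put the first-in-pair mate first when the flag says so
        if (recs[1][0] & _FLAG_FIRST_IN_PAIR) and not (
            recs[0][0] & _FLAG_FIRST_IN_PAIR
        ):
            recs = [recs[1], recs[0]]
        pairs.append(
            ReadPairAlignment(
                pair_id=qname,
                mate1=recs[0][1],
                mate2=recs[1][1],
                mapping_ok=recs[0][2] and recs[1][2],
            )
        )
    if n_dropped:
        logger.warning(
            "read_sam_lite: dropped %d unpaired record(s) from %s",
            n_dropped,
            path,
        )
    return pairs


def write_sam_lite(pairs: Iterable[ReadPairAlignment], path: PathLike) -> None:
    """Write pairs as minimal standard SAM (CIGAR = <len>M, no sequence)."""
    with open(path, "w") as fh:
        fh.write("@CO\tchordax SAM-lite paired-end alignments\n")
        for pair in pairs:
            for idx, mate in ((1, pair.mate1), (2, pair.mate2)):
                flag = 0x1 | (_FLAG_FIRST_IN_PAIR if idx == 1 else 0x80)
                if mate.strand == "-":
                    flag |= _FLAG_REVERSE
                if not pair.mapping_ok:
                    flag |= _FLAG_UNMAPPED
                fh.write(
                    "\t".join(
                        [
                            pair.pair_id,
                            str(flag),
                            mate.chrom,
                            str(mate.start),
                            "60",
                            f"{mate.aligned_length}M",
                            "*",
                            "0",
                            "0",
                            "*",
                            "*",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Variant table (VCF-like TSV)

_VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]


def read_variant_table(
    path: PathLike, chrom_lengths: Mapping[str, int] | None = None
) -> list[SomaticVariant]:
    """Read a VCF-like TSV (sample_id, chrom, pos, ref, alt).

    If ``chrom_lengths`` is given, unknown chromosomes and out-of-bounds
    coordinates are errors.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_VARIANT_COLUMNS,
        dtype={"sample_id": str, "chrom": str, "ref": str, "alt": str},
    )
    variants = []
    for row in df.itertuples(index=False):
        pos = int(row.pos)
        if pos < 1:
            raise ValueError(f"coordinate < 1 in {path}: {row}")
        if chrom_lengths is not None:
            if row.chrom not in chrom_lengths:
                raise ValueError(f"unknown chromosome {row.chrom!r} in {path}")
            if pos > chrom_lengths[row.chrom]:
                raise ValueError(
                    f"position {pos} beyond {row.chrom} in {path}"
                )
        variants.append(
            SomaticVariant(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                pos=pos,
                ref=str(row.ref),
                alt=str(row.alt),
            )
        )
    return variants


def write_variant_table(
    variants: Iterable[SomaticVariant], path: PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(f"{v.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF-like TSV)

_GTF_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "phases",
    "coding",
]


def read_gtf_lite(path: PathLike) -> list[GeneModel]:
    """Read gene models from a GTF-like TSV (one gene per row).

    Exon starts/ends are comma-separated 1-based inclusive coordinates in
    transcription order; ``phases`` is '.' for noncoding genes.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GTF_COLUMNS,
        dtype=str,
    )
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in row.exon_starts.split(",")]
        ends = [int(x) for x in row.exon_ends.split(",")]
        if len(starts) != len(ends):
            raise ValueError(f"{path}: exon start/end count mismatch")
        coding = str(row.coding).lower() in ("1", "true", "yes")
        phases = None
        if coding and row.phases != ".":
            phases = tuple(int(x) for x in row.phases.split(","))
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                exons=tuple(zip(starts, ends)),
                is_coding=coding,
                cds_phase_per_exon=phases,
            )
        )
    return genes


def write_gtf_lite(genes: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_GTF_COLUMNS) + "\n")
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            phases = (
                ",".join(str(p) for p in g.cds_phase_per_exon)
                if g.is_coding
                else "."
            )
            coding = "1" if g.is_coding else "0"
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{starts}\t{ends}"
                f"\t{phases}\t{coding}\n"
            )


# ---------------------------------------------------------------------------
# Matrices and tables

def read_tsv_matrix(path: PathLike) -> pd.DataFrame:
    """Read a gene x sample (or window x sample) matrix with a '#' banner."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df


def write_tsv_matrix(
    df: pd.DataFrame, path: PathLike, banner: str = "chordax matrix"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {banner}\n")
        df.to_csv(fh, sep="\t")


_CLINICAL_COLUMNS = [
    "patient_no",
    "age",
    "gender",
    "subtype",
    "location",
    "extent",
    "status",
    "radiation",
    "survival",
]


def read_clinical_table(path: PathLike) -> list[ClinicalRecord]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_CLINICAL_COLUMNS,
        dtype=str,
    )
    return [
        ClinicalRecord(
            patient_no=int(r.patient_no),
            age=float(r.age),
            gender=str(r.gender),
            subtype=str(r.subtype),
            location=str(r.location),
            extent=str(r.extent),
            status=str(r.status),
            radiation=str(r.radiation),
            survival=str(r.survival),
        )
        for r in df.itertuples(index=False)
    ]


def write_clinical_table(
    records: Sequence[ClinicalRecord], path: PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_CLINICAL_COLUMNS) + "\n")
        for r in records:
            age = int(r.age) if float(r.age).is_integer() else r.age
            fh.write(
                f"{r.patient_no}\t{age}\t{r.gender}\t{r.subtype}\t"
                f"{r.location}\t{r.extent}\t{r.status}\t{r.radiation}\t"
                f"{r.survival}\n"
            )


def read_genotype_table(path: PathLike):
    """Read per-individual genotypes (sample_id, group, genotype) into a
    :class:`~chordax.models.GenotypeCohortTable`."""
    from .models import GenotypeCohortTable

    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["sample_id", "group", "genotype"], dtype=str,
    )
    return GenotypeCohortTable.from_individuals(
        [(r.group, r.genotype) for r in df.itertuples(index=False)]
    )


def write_genotype_table(records, path: PathLike) -> None:
    """Write (sample_id, group, genotype) rows."""
    with open(path, "w") as fh:
        fh.write("#sample_id\tgroup\tgenotype\n")
        for sample_id, group, genotype in records:
            fh.write(f"{sample_id}\t{group}\t{genotype}\n")
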