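"""Coverage-based gene-fusion discovery from paired-end RNA alignments.

The procedure filters read pairs by two criteria — (1) the two mates align
to different genes; (2) a mate aligns wholly within an intron of a gene
that already has criterion-1 support — then infers each partner's
breakpoint from the per-nucleotide coverage profile as a single mean-shift
changepoint restricted to intron/exon-flank candidate positions, and
finally classifies the reading frame of the joined coding regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .models import (
    CoverageTrack,
    FrameStatus,
    FusionCandidate,
    GeneModel,
    MateAlignment,
    ReadPairAlignment,
)

logger = logging.getLogger(__name__)


class PairClass(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT_GENE_PAIR = "discordant_gene_pair"
    INTRONIC_BREAKPOINT_SUPPORT = "intronic_breakpoint_support"
    UNASSIGNED = "unassigned"


class GeneIndex:
    """Interval lookup from a gene set: which genes does a mate overlap?"""

    def __init__(self, genes: Sequence[GeneModel],
                 chrom_lengths: Optional[Mapping[str, int]] = None) -> None:
        self.genes = list(genes)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)

    def known_chrom(self, chrom: str) -> bool:
        if self.chrom_lengths is not None:
            return chrom in self.chrom_lengths
        return chrom in self.by_chrom

    def overlapping(self, mate: MateAlignment) -> list[GeneModel]:
        """Genes whose span overlaps the mate's aligned interval.

        A mate inside two (nested/overlapping) genes counts for both; the
        ambiguity is logged at debug level.
        """
        hits = [
            g
            for g in self.by_chrom.get(mate.chrom, [])
            if mate.start <= g.end and mate.end >= g.start
        ]
        if len(hits) > 1:
            logger.debug(
                "mate at %s:%d overlaps %d genes", mate.chrom, mate.start,
                len(hits),
            )
        return hits

    def wholly_intronic(self, mate: MateAlignment) -> list[GeneModel]:
        """Genes with an intron fully containing the mate."""
        out = []
        for g in self.overlapping(mate):
            for s, e in g.introns():
                if s <= mate.start and mate.end <= e:
                    out.append(g)
                    break
        return out


def classify_read_pair(
    pair: ReadPairAlignment,
    index: GeneIndex,
    supported_genes: Optional[set[str]] = None,
) -> PairClass:
    """Label one pair against the two fusion-filter criteria.

    ``supported_genes`` is the set of gene ids already linked by a
    criterion-1 pair; mates wholly inside an intron of such a gene give
    ``INTRONIC_BREAKPOINT_SUPPORT`` (criterion 2).  Mates on chromosomes
    absent from the index raise.
    """
    for mate in (pair.mate1, pair.mate2):
        if not index.known_chrom(mate.chrom):
            raise ValueError(
                f"pair {pair.pair_id}: unknown chromosome {mate.chrom!r}"
            )
    g1 = index.overlapping(pair.mate1)
    g2 = index.overlapping(pair.mate2)
    ids1 = {g.gene_id for g in g1}
    ids2 = {g.gene_id for g in g2}
    if g1 and g2 and not (ids1 & ids2):
        return PairClass.DISCORDANT_GENE_PAIR
    if supported_genes:
        for mate in (pair.mate1, pair.mate2):
            if any(
                g.gene_id in supported_genes
                for g in index.wholly_intronic(mate)
            ):
                return PairClass.INTRONIC_BREAKPOINT_SUPPORT
    if ids1 & ids2:
        return PairClass.CONCORDANT
    return PairClass.UNASSIGNED


# ---------------------------------------------------------------------------
# Coverage and breakpoints

def build_coverage(
    alignments: Iterable[ReadPairAlignment] | Iterable[MateAlignment],
    chrom: str,
    start: int,
    end: int,
) -> CoverageTrack:
    """Per-base depth over [start, end] (1-based inclusive).

    ``depth[i]`` counts aligned bases covering position start+i; the sum
    over the track equals the total aligned bases intersecting the region.
    """
    if end < start:
        raise ValueError("empty region")
    depth = np.zeros(end - start + 1, dtype=np.int64)
    for item in alignments:
        mates = (
            (item.mate1, item.mate2)
            if isinstance(item, ReadPairAlignment)
            else (item,)
        )
        for mate in mates:
            if mate.chrom != chrom:
                continue
            lo = max(mate.start, start) - start
            hi = min(mate.end, end) - start
            if hi >= lo:
                depth[lo : hi + 1] += 1
    return CoverageTrack(chrom=chrom, start=start, depth=depth)


@dataclass
class BreakpointCall:
    """A single mean-shift changepoint in a coverage track.

    ``boundary`` is the 1-based position of the first base of the right-
    hand side of the split; ``direction`` is 'drop' when the left side is
    the high-coverage side.  For a drop, the boundary is therefore the
    first base of the low side.
    """

    boundary: int
    direction: str  # 'drop' or 'rise'
    delta: float


def candidate_boundaries(gene: GeneModel, flank: int = 10) -> np.ndarray:
    """Positions eligible as changepoint boundaries: intron bases plus a
    ``flank``-base margin into each adjacent exon."""
    positions: set[int] = set()
    for s, e in gene.introns():
        positions.update(range(s - flank, e + flank + 2))
    return np.array(sorted(positions), dtype=int)


def infer_breakpoint(
    track: CoverageTrack,
    gene: Optional[GeneModel] = None,
    min_delta: Optional[float] = None,
    flank: int = 10,
) -> Optional[BreakpointCall]:
    """Locate the single changepoint maximizing |mean(left) - mean(right)|.

    Candidate boundaries are restricted to the gene's introns and exon
    flanks when a gene model is supplied; ties break to the leftmost
    position.  Returns None (no-breakpoint, distinct from an error) when
    the best shift is below ``min_delta`` (default: 5x the track's median
    depth, floored at 1).
    """
    depth = track.depth.astype(float)
    n = len(depth)
    if n < 2:
        return None
    if min_delta is None:
        min_delta = max(1.0, 5.0 * float(np.median(depth)))
    csum = np.concatenate([[0.0], np.cumsum(depth)])
    # split index i: left = depth[:i], right = depth[i:], i in 1..n-1
    i = np.arange(1, n)
    mean_left = csum[i] / i
    mean_right = (csum[n] - csum[i]) / (n - i)
    diff = mean_left - mean_right
    if gene is not None:
        bounds = candidate_boundaries(gene, flank=flank)
        positions = bounds[(bounds > track.start) & (bounds <= track.end)]
        if len(positions) == 0:
            return None
        mask = np.zeros(n - 1, dtype=bool)
        mask[positions - track.start - 1] = True
        diff = np.where(mask, diff, 0.0)
    absdiff = np.abs(diff)
    top = float(absdiff.max())
    # leftmost maximum, tolerant of float noise so exact ties break left
    best = int(np.flatnonzero(absdiff >= top - 1e-9 * (1.0 + top))[0])
    if absdiff[best] < min_delta:
        return None
    return BreakpointCall(
        boundary=track.start + best + 1,
        direction="drop" if diff[best] > 0 else "rise",
        delta=float(absdiff[best]),
    )


# ---------------------------------------------------------------------------
# Fusion calling

def classify_frame(
    gene5: GeneModel, breakpoint5: int, gene3: GeneModel, breakpoint3: int
) -> FrameStatus:
    """Reading-frame status of the junction.

    In frame iff the donor's CDS length up to its breakpoint leaves a
    codon remainder equal to the acceptor exon's phase (the bases that
    exon expects from upstream); noncoding if either partner lacks a CDS.
    """
    if not gene5.is_coding or not gene3.is_coding:
        return FrameStatus.NONCODING
    idx3 = gene3.exon_index_at(breakpoint3)
    if idx3 is None:
        return FrameStatus.NONCODING  # acceptor joins inside an intron
    cds_len = gene5.cds_length_up_to(breakpoint5)
    phase = gene3.cds_phase_per_exon[idx3]
    return (
        FrameStatus.IN_FRAME
        if cds_len % 3 == phase
        else FrameStatus.OUT_OF_FRAME
    )


def reconstruct_junction(
    candidate: FusionCandidate,
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    k: int,
) -> str:
    """Junction sequence: k donor bases + k acceptor bases in transcript
    orientation (minus-strand sides reverse-complemented)."""
    from .synth import _gene_by_id, _transcript_side, _donor_prefix_coords, \
        _acceptor_suffix_coords

    g5 = _gene_by_id(genes, candidate.gene5)
    g3 = _gene_by_id(genes, candidate.gene3)
    if not g5.contains(candidate.chrom5, candidate.breakpoint5):
        raise ValueError("breakpoint5 outside donor gene")
    if not g3.contains(candidate.chrom3, candidate.breakpoint3):
        raise ValueError("breakpoint3 outside acceptor gene")
    if k > _donor_prefix_coords(g5, candidate.breakpoint5):
        raise ValueError("k exceeds donor-side sequence available")
    if k > _acceptor_suffix_coords(g3, candidate.breakpoint3):
        raise ValueError("k exceeds acceptor-side sequence available")
    donor = _transcript_side(genome, g5, candidate.breakpoint5, "donor", k)
    acceptor = _transcript_side(
        genome, g3, candidate.breakpoint3, "acceptor", k
    )
    return donor + acceptor


def _mean_transcript_offset(
    gene: GeneModel, mates: Sequence[MateAlignment]
) -> float:
    """Mean fractional position of mate midpoints along the gene span,
    measured from the transcript 5' end."""
    span = gene.end - gene.start + 1
    offs = []
    for m in mates:
        mid = (m.start + m.end) / 2.0
        frac = (mid - gene.start) / span
        offs.append(frac if gene.strand == "+" else 1.0 - frac)
    return float(np.mean(offs)) if offs else 0.5


def call_fusions(
    pairs: Sequence[ReadPairAlignment],
    genes: Sequence[GeneModel],
    min_support: int = 2,
    genome: Optional[Mapping[str, str]] = None,
    junction_reads: Optional[Sequence[str]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    flank: int = 10,
    min_delta: Optional[float] = None,
) -> list[FusionCandidate]:
    """Call fusion candidates from paired-end alignments.

    One candidate is emitted per unordered gene pair linked by at least
    ``min_support`` criterion-1 (discordant) pairs — a gene pair never
    linked by a discordant pair is never called, whatever the coverage
    looks like.  The donor (5') partner is the gene whose supporting mates
    sit closest to its transcript start.  Breakpoints come from the
    coverage changepoint (donor: last base of the high side before the
    drop; acceptor: first base of the high side at the rise), falling back
    to the extreme supporting-mate coordinate when no changepoint clears
    ``min_delta``.  When the genome and junction-read sequences are given,
    reads matching the reconstructed junction end-to-end are counted as
    ``n_junction_reads``.  Candidates are sorted by support, descending.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    index = GeneIndex(genes, chrom_lengths)
    support: dict[tuple[str, str], list[ReadPairAlignment]] = {}
    for pair in pairs:
        if classify_read_pair(pair, index) is not PairClass.DISCORDANT_GENE_PAIR:
            continue
        for ga in index.overlapping(pair.mate1):
            for gb in index.overlapping(pair.mate2):
                if ga.gene_id == gb.gene_id:
                    continue
                key = tuple(sorted((ga.gene_id, gb.gene_id)))
                support.setdefault(key, []).append(pair)

    gene_map = {g.gene_id: g for g in genes}
    candidates: list[FusionCandidate] = []
    for (id_a, id_b), sup_pairs in support.items():
        if len(sup_pairs) < min_support:
            continue
        ga, gb = gene_map[id_a], gene_map[id_b]
        mates_a = _mates_in_gene(sup_pairs, ga)
        mates_b = _mates_in_gene(sup_pairs, gb)
        # donor = partner whose support clusters nearest its 5' end
        if _mean_transcript_offset(ga, mates_a) <= _mean_transcript_offset(
            gb, mates_b
        ):
            g5, g3, mates5, mates3 = ga, gb, mates_a, mates_b
        else:
            g5, g3, mates5, mates3 = gb, ga, mates_b, mates_a

        bp5 = _locate_breakpoint(pairs, g5, "donor", mates5, flank, min_delta)
        bp3 = _locate_breakpoint(pairs, g3, "acceptor", mates3, flank,
                                 min_delta)
        cand = FusionCandidate(
            gene5=g5.gene_id,
            gene3=g3.gene_id,
            chrom5=g5.chrom,
            breakpoint5=bp5,
            chrom3=g3.chrom,
            breakpoint3=bp3,
            n_discordant_pairs=len(sup_pairs),
            frame_status=_safe_frame(g5, bp5, g3, bp3),
        )
        if genome is not None and junction_reads:
            cand.n_junction_reads = _count_junction_reads(
                cand, genome, genes, junction_reads
            )
        candidates.append(cand)
    candidates.sort(key=lambda c: (-c.n_discordant_pairs, c.gene5, c.gene3))
    return candidates


def _mates_in_gene(
    pairs: Sequence[ReadPairAlignment], gene: GeneModel
) -> list[MateAlignment]:
    out = []
    for p in pairs:
        for m in (p.mate1, p.mate2):
            if m.chrom == gene.chrom and m.start <= gene.end and m.end >= gene.start:
                out.append(m)
    return out


def _locate_breakpoint(
    all_pairs: Sequence[ReadPairAlignment],
    gene: GeneModel,
    side: str,
    support_mates: Sequence[MateAlignment],
    flank: int,
    min_delta: Optional[float],
) -> int:
    """Breakpoint for one fusion partner.

    The coverage changepoint localizes the breakpoint region; the exact
    coordinate is then taken from the supporting mates themselves — the
    identified paired ends reveal the fusion point — as the extreme
    aligned base (donor: last transcribed base, acceptor: first) among
    support mates near the changepoint.  Without a changepoint above
    ``min_delta`` the global extreme support-mate coordinate is used.
    """
    margin = 200
    start = max(1, gene.start - margin)
    track = build_coverage(all_pairs, gene.chrom, start, gene.end + margin)
    call = infer_breakpoint(track, gene, min_delta=min_delta, flank=flank)
    read_len = max(m.aligned_length for m in support_mates)
    # which mate edge is the junction-proximal one, in genome coordinates
    want_max_end = (side == "donor") == (gene.strand == "+")
    edges = [m.end if want_max_end else m.start for m in support_mates]
    if call is not None:
        lo, hi = call.boundary - 2 * read_len, call.boundary + 2 * read_len
        near = [e for e in edges if lo <= e <= hi]
        if near:
            return max(near) if want_max_end else min(near)
    return max(edges) if want_max_end else min(edges)


def _safe_frame(
    g5: GeneModel, bp5: int, g3: GeneModel, bp3: int
) -> FrameStatus:
    try:
        return classify_frame(g5, bp5, g3, bp3)
    except ValueError:
        return FrameStatus.NONCODING


def _count_junction_reads(
    candidate: FusionCandidate,
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    reads: Sequence[str],
) -> int:
    if not reads:
        return 0
    k = max(len(r) for r in reads) - 1
    from .synth import _gene_by_id, _donor_prefix_coords, \
        _acceptor_suffix_coords

    g5 = _gene_by_id(genes, candidate.gene5)
    g3 = _gene_by_id(genes, candidate.gene3)
    k = min(
        k,
        _donor_prefix_coords(g5, candidate.breakpoint5),
        _acceptor_suffix_coords(g3, candidate.breakpoint3),
    )
    if k < 1:
        return 0
    junction = reconstruct_junction(candidate, genome, genes, k)
    return sum(1 for r in reads if r in junction)
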