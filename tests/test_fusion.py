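"""Fusion filter, coverage, breakpoint inference and candidate calling."""

import numpy as np
import pytest

from chordax import fusion, synth
from chordax.fusion import (
    GeneIndex,
    PairClass,
    build_coverage,
    call_fusions,
    classify_frame,
    classify_read_pair,
    infer_breakpoint,
    reconstruct_junction,
)
from chordax.models import (
    CoverageTrack,
    FrameStatus,
    FusionCandidate,
    GeneModel,
    MateAlignment,
    ReadPairAlignment,
)


def _pair(c1, s1, c2, s2, length=50, pid="p"):
    return ReadPairAlignment(
        pid,
        MateAlignment(c1, s1, "+", length),
        MateAlignment(c2, s2, "-", length),
    )


TOY_GENES = [
    GeneModel("gA", "chr1", "+", ((100, 200), (300, 400))),
    GeneModel("gB", "chr1", "+", ((700, 800), (900, 1000))),
    GeneModel("gC", "chr2", "+", ((100, 250),)),
]


class TestClassifyReadPair:
    idx = GeneIndex(TOY_GENES, chrom_lengths={"chr1": 2000, "chr2": 2000})

    def test_mates_in_two_genes_discordant(self):
        p = _pair("chr1", 150, "chr1", 750)
        assert classify_read_pair(p, self.idx) is PairClass.DISCORDANT_GENE_PAIR

    def test_both_mates_one_gene_concordant(self):
        p = _pair("chr1", 120, "chr1", 320)
        assert classify_read_pair(p, self.idx) is PairClass.CONCORDANT

    def test_intronic_mate_of_supported_gene(self):
        p = _pair("chr1", 220, "chr1", 1500, length=30)
        label = classify_read_pair(p, self.idx, supported_genes={"gA"})
        assert label is PairClass.INTRONIC_BREAKPOINT_SUPPORT
        # without criterion-1 support the same pair is not evidence
        assert classify_read_pair(p, self.idx) is PairClass.UNASSIGNED

    def test_unknown_chromosome_raises(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            classify_read_pair(_pair("chrX", 5, "chr1", 150), self.idx)

    def test_agrees_with_interval_containment_oracle(self):
        """Exhaustive mate placements vs a brute-force interval scan."""

        def oracle(p, genes, supported):
            def hits(m):
                return {
                    g.gene_id
                    for g in genes
                    if g.chrom == m.chrom
                    and m.start <= g.end
                    and m.end >= g.start
                }

            def intronic(m):
                out = set()
                for g in genes:
                    if g.chrom != m.chrom:
                        continue
                    exs = sorted(g.exons)
                    for (_, e1), (s2, _) in zip(exs, exs[1:]):
                        if e1 + 1 <= m.start and m.end <= s2 - 1:
                            out.add(g.gene_id)
                return out

            h1, h2 = hits(p.mate1), hits(p.mate2)
            if h1 and h2 and not (h1 & h2):
                return PairClass.DISCORDANT_GENE_PAIR
            if supported and (
                (intronic(p.mate1) | intronic(p.mate2)) & supported
            ):
                return PairClass.INTRONIC_BREAKPOINT_SUPPORT
            if h1 & h2:
                return PairClass.CONCORDANT
            return PairClass.UNASSIGNED

        rng = np.random.default_rng(42)
        genes = TOY_GENES + [
            GeneModel("gD", "chr1", "+", ((1100, 1300), (1400, 1600))),
            GeneModel("gE", "chr2", "-", ((900, 1100), (400, 600))),
            GeneModel("gF", "chr2", "+", ((1500, 1900),)),
        ]
        idx = GeneIndex(genes, chrom_lengths={"chr1": 2000, "chr2": 2000})
        for _ in range(400):
            p = _pair(
                rng.choice(["chr1", "chr2"]),
                int(rng.integers(1, 1900)),
                rng.choice(["chr1", "chr2"]),
                int(rng.integers(1, 1900)),
                length=int(rng.integers(1, 120)),
            )
            supported = set(
                rng.choice(
                    [g.gene_id for g in genes],
                    size=int(rng.integers(0, 3)),
                    replace=False,
                )
            )
            assert classify_read_pair(p, idx, supported) == oracle(
                p, genes, supported
            )


class TestBuildCoverage:
    def test_single_read(self):
        t = build_coverage(
            [MateAlignment("chr1", 1, "+", 10)], "chr1", 1, 20
        )
        assert t.depth[:10].tolist() == [1] * 10
        assert t.depth[10:].sum() == 0

    def test_linearity_two_identical_reads(self):
        reads = [MateAlignment("chr1", 5, "+", 10)] * 2
        t = build_coverage(reads, "chr1", 1, 20)
        single = build_coverage(reads[:1], "chr1", 1, 20)
        assert np.array_equal(t.depth, 2 * single.depth)

    def test_matches_per_read_accumulation_oracle(self):
        rng = np.random.default_rng(7)
        reads = [
            MateAlignment("chr1", int(rng.integers(1, 500)), "+",
                          int(rng.integers(1, 80)))
            for _ in range(200)
        ]
        region = ("chr1", 50, 450)
        t = build_coverage(reads, *region)
        expected = np.zeros(401, dtype=int)
        for r in reads:
            for pos in range(r.start, r.end + 1):
                if 50 <= pos <= 450:
                    expected[pos - 50] += 1
        assert np.array_equal(t.depth, expected)
        assert t.depth.sum() == expected.sum()


class TestInferBreakpoint:
    def _oracle(self, depth, start):
        """Exhaustive changepoint scan: leftmost maximizer of the
        two-sided mean difference (exact ties break left)."""
        n = len(depth)
        diffs = np.array(
            [abs(np.mean(depth[:i]) - np.mean(depth[i:])) for i in range(1, n)]
        )
        top = diffs.max()
        best = int(np.flatnonzero(diffs >= top - 1e-9 * (1.0 + top))[0])
        return start + best + 1, float(diffs[best])

    def test_step_track_found_at_step(self):
        depth = np.array([100] * 50 + [0] * 50)
        call = infer_breakpoint(
            CoverageTrack("chr1", 1, depth), min_delta=1.0
        )
        oracle_pos, _ = self._oracle(depth, 1)
        assert call.boundary == oracle_pos == 51
        assert call.direction == "drop"

    def test_flat_track_no_breakpoint(self):
        call = infer_breakpoint(
            CoverageTrack("chr1", 1, np.full(100, 7)), min_delta=1.0
        )
        assert call is None

    def test_two_equal_steps_leftmost_wins(self):
        depth = np.array([10] * 20 + [0] * 20 + [10] * 20 + [0] * 20)
        call = infer_breakpoint(
            CoverageTrack("chr1", 1, depth), min_delta=0.1
        )
        oracle_pos, _ = self._oracle(depth, 1)
        assert call.boundary == oracle_pos

    def test_random_tracks_match_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            depth = rng.integers(0, 40, size=int(rng.integers(10, 120)))
            call = infer_breakpoint(
                CoverageTrack("chr1", 11, depth), min_delta=0.0
            )
            oracle_pos, oracle_d = self._oracle(depth, 11)
            assert call.boundary == oracle_pos
            assert call.delta == pytest.approx(oracle_d)

    def test_candidate_restriction_to_introns(self):
        gene = GeneModel("g", "chr1", "+", ((1, 40), (81, 120)))
        # big step at 21 (exonic, not a candidate); small step at intron
        depth = np.array([100] * 20 + [50] * 25 + [0] * 75)
        call = infer_breakpoint(
            CoverageTrack("chr1", 1, depth), gene, min_delta=1.0, flank=5
        )
        assert 36 <= call.boundary <= 86  # within intron +/- flank


class TestCallFusions:
    def test_injected_fusion_recovered_exactly(self, genome, genes,
                                               cohort_spec, chrom_lengths):
        fus = cohort_spec.fusion
        pairs, _, junc = synth.simulate_fusion_read_pairs(
            genome, genes, fus, n_pairs=50, seed=2, placement="tiled"
        )
        calls = call_fusions(
            pairs, genes, min_support=2, genome=genome,
            junction_reads=junc, chrom_lengths=chrom_lengths,
        )
        assert len(calls) == 1
        c = calls[0]
        assert (c.gene5, c.gene3) == (fus.gene5, fus.gene3)
        assert c.breakpoint5 == fus.breakpoint5
        assert c.breakpoint3 == fus.breakpoint3
        assert c.frame_status is FrameStatus.IN_FRAME
        assert c.intrachromosomal
        assert c.n_junction_reads > 0

    def test_min_support_above_injection_empty(self, genome, genes,
                                               cohort_spec, chrom_lengths):
        pairs, counts, _ = synth.simulate_fusion_read_pairs(
            genome, genes, cohort_spec.fusion, n_pairs=10, seed=2
        )
        calls = call_fusions(
            pairs, genes, min_support=counts["discordant"] + 1,
            chrom_lengths=chrom_lengths,
        )
        assert calls == []

    def test_two_fusions_ordered_by_support(self, genome, genes,
                                            chrom_lengths, cohort_spec):
        f1 = cohort_spec.fusion
        g_bg1 = next(g for g in genes if g.gene_id == "BG1")
        g_bg2 = next(g for g in genes if g.gene_id == "BG2")
        f2 = synth.FusionSpec(
            gene5="BG1", gene3="BG2",
            breakpoint5=g_bg1.exons[0][1], breakpoint3=g_bg2.exons[1][0],
        )
        p1, _, _ = synth.simulate_fusion_read_pairs(
            genome, genes, f1, n_pairs=60, seed=4, pair_id_prefix="a"
        )
        p2, _, _ = synth.simulate_fusion_read_pairs(
            genome, genes, f2, n_pairs=20, seed=5, pair_id_prefix="b"
        )
        calls = call_fusions(p1 + p2, genes, min_support=2,
                             chrom_lengths=chrom_lengths)
        assert [(c.gene5, c.gene3) for c in calls] == [
            ("SAMD5L", "SASH1L"), ("BG1", "BG2")
        ]
        assert calls[0].n_discordant_pairs > calls[1].n_discordant_pairs

    def test_no_coverage_only_calls(self, genome, genes, chrom_lengths):
        """Genes never linked by a discordant pair are never called, even
        with deep concordant coverage."""
        g = next(g for g in genes if g.gene_id == "BG1")
        reads = [
            ReadPairAlignment(
                f"c{i}",
                MateAlignment(g.chrom, g.start + i, "+", 80),
                MateAlignment(g.chrom, g.start + i + 120, "-", 80),
            )
            for i in range(50)
        ]
        assert call_fusions(reads, genes, chrom_lengths=chrom_lengths) == []


class TestClassifyFrame:
    donor = GeneModel("d", "chr1", "+", ((1, 300), (401, 700)))
    acceptor = GeneModel(
        "a", "chr1", "+", ((1001, 1501), (1601, 2000)),
    )  # exon1 is 501 bases -> exon2 phase 0

    def test_donor_cds_multiple_of_three_in_frame(self):
        assert (
            classify_frame(self.donor, 300, self.acceptor, 1601)
            is FrameStatus.IN_FRAME
        )

    def test_one_extra_base_out_of_frame(self):
        donor = GeneModel("d", "chr1", "+", ((1, 301), (401, 700)))
        assert (
            classify_frame(donor, 301, self.acceptor, 1601)
            is FrameStatus.OUT_OF_FRAME
        )

    def test_noncoding_donor(self):
        nc = GeneModel("n", "chr1", "+", ((1, 300),), is_coding=False)
        assert (
            classify_frame(nc, 200, self.acceptor, 1601)
            is FrameStatus.NONCODING
        )

    def test_breakpoint_outside_gene_raises(self):
        with pytest.raises(ValueError, match="outside"):
            classify_frame(self.donor, 900, self.acceptor, 1601)


class TestReconstructJunction:
    def _candidate(self, g5, g3, bp5, bp3):
        return FusionCandidate(
            gene5=g5.gene_id, gene3=g3.gene_id,
            chrom5=g5.chrom, breakpoint5=bp5,
            chrom3=g3.chrom, breakpoint3=bp3,
            n_discordant_pairs=3,
        )

    def test_k5_equals_manual_concatenation(self):
        genome = {"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGT"}
        g5 = GeneModel("d", "chr1", "+", ((1, 10),))
        g3 = GeneModel("a", "chr1", "+", ((21, 30),))
        junction = reconstruct_junction(
            self._candidate(g5, g3, 10, 21), genome, [g5, g3], k=5
        )
        assert junction == genome["chr1"][5:10] + genome["chr1"][20:25]
        assert len(junction) == 10

    def test_minus_strand_donor_reverse_complemented(self):
        genome = {"chr1": "AACCGGTTAACCGGTTAACCGGTT"}
        g5 = GeneModel("d", "chr1", "-", ((5, 14),))
        g3 = GeneModel("a", "chr1", "+", ((17, 24),))
        junction = reconstruct_junction(
            self._candidate(g5, g3, 8, 17), genome, [g5, g3], k=4
        )
        # donor transcript runs right-to-left: bases 8..11 reverse-complemented
        manual = "".join(
            {"A": "T", "C": "G", "G": "C", "T": "A"}[b]
            for b in reversed(genome["chr1"][7:11])
        )
        assert junction[:4] == manual

    def test_simulated_junction_reads_match(self, genome, genes,
                                            cohort_spec):
        fus = cohort_spec.fusion
        _, _, junc = synth.simulate_fusion_read_pairs(
            genome, genes, fus, n_pairs=40, seed=6
        )
        cand = self._candidate(
            next(g for g in genes if g.gene_id == fus.gene5),
            next(g for g in genes if g.gene_id == fus.gene3),
            fus.breakpoint5,
            fus.breakpoint3,
        )
        junction = reconstruct_junction(cand, genome, genes, k=100)
        assert junc and all(read in junction for read in junc)

    def test_k_too_large_raises(self):
        genome = {"chr1": "ACGTACGTAC" * 10}
        g5 = GeneModel("d", "chr1", "+", ((1, 10),))
        g3 = GeneModel("a", "chr1", "+", ((21, 30),))
        with pytest.raises(ValueError, match="exceeds"):
            reconstruct_junction(
                self._candidate(g5, g3, 10, 21), genome, [g5, g3], k=15
            )
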