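"""Synthetic chordoma-like cohort generator.

Every downstream stage of the pipeline is exercised against data produced
here: a small multi-chromosome genome; an expressed in-frame fusion between
two neighbouring same-chromosome genes (the SAMD5-SASH1 pattern); arm-scale
copy-number gains and losses; somatic SNVs at a few mutations per megabase
with a C>T/T>C/C>A-dominated spectrum and an optional NpCpG C>T-enriched
subset of samples; per-gene expression counts with a target gene elevated
in one group; and a two-group genotype cohort.

All generators are fully deterministic given their seed: the same seed
yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    ClinicalRecord,
    GeneModel,
    GenotypeCohortTable,
    MateAlignment,
    ReadPairAlignment,
    SomaticVariant,
    SUBSTITUTION_CLASSES,
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default 6-class substitution weights: C>T, T>C and C>A dominate, the
#: pattern observed in skull base chordoma exomes.
DEFAULT_SIGNATURE_MIX = {
    "C>A": 0.15,
    "C>G": 0.05,
    "C>T": 0.40,
    "T>A": 0.05,
    "T>C": 0.25,
    "T>G": 0.10,
}


@dataclass(frozen=True)
class FusionSpec:
    """An injected gene fusion: donor gene/breakpoint joined to acceptor.

    ``breakpoint5`` is the last transcribed donor base, ``breakpoint3`` the
    first transcribed acceptor base (both genomic, 1-based).
    """

    gene5: str
    gene3: str
    breakpoint5: int
    breakpoint3: int
    expression_level: float = 1.0

    def __post_init__(self) -> None:
        if self.expression_level < 0:
            raise ValueError("expression_level must be >= 0")


@dataclass
class CohortSpec:
    """Declarative description of a synthetic cohort's genome and signals.

    The default universe is a scaled-down genome of 5 chromosomes x 2 Mb;
    the default gene pair sits on chr1 with its transcription starts an
    inter-gene distance apart that mirrors the 772 kb separation of the
    fusion partners at 1:10 scale.
    """

    seed: int = 0
    n_chrom: int = 5
    chrom_length: int = 2_000_000
    genes: list[GeneModel] = field(default_factory=list)
    fusion: Optional[FusionSpec] = None
    #: chrom -> (p-arm state, q-arm state), states in {gain, loss, neutral}
    cna_arms: dict[str, tuple[str, str]] = field(default_factory=dict)
    mut_rate: float = 2.1  # mutations per Mb per sample
    signature_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_MIX)
    )
    npcpg_fraction: float = 0.4
    genotype_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "chordoma": (0.125, 0.375, 0.5),
            "control": (0.48, 0.4267, 0.0933),
        }
    )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The standard test universe: fusion pair on chr1, background genes on
    the other chromosomes, arm events mirroring the loss-1p/10/13,
    gain-7/17q pattern."""
    intergene = 77_200  # 772 kb at 1:10 scale
    gene5 = GeneModel(
        gene_id="SAMD5L",
        chrom="chr1",
        strand="+",
        exons=((10_000, 10_599), (12_000, 12_500), (14_000, 14_800)),
    )
    gene3 = GeneModel(
        gene_id="SASH1L",
        chrom="chr1",
        strand="+",
        exons=(
            (10_000 + intergene, 10_500 + intergene),
            (12_000 + intergene, 12_650 + intergene),
            (14_500 + intergene, 15_400 + intergene),
        ),
    )
    background = [
        GeneModel(
            gene_id=f"BG{i}",
            chrom=f"chr{i + 1}",
            strand="+",
            exons=(
                (50_000, 50_900),
                (52_000, 52_950),
                (54_000, 55_000),
            ),
        )
        for i in range(1, 5)
    ]
    fusion = FusionSpec(
        gene5="SAMD5L",
        gene3="SASH1L",
        breakpoint5=10_599,  # end of donor exon 1
        breakpoint3=12_000 + intergene,  # start of acceptor exon 2
        expression_level=1.0,
    )
    cna_arms = {
        "chr1": ("loss", "neutral"),  # 1p loss analogue
        "chr2": ("gain", "gain"),  # chromosome 7 gain analogue
        "chr3": ("loss", "loss"),  # chromosome 10 loss analogue
        "chr4": ("loss", "loss"),  # chromosome 13 loss analogue
        "chr5": ("neutral", "gain"),  # 17q gain analogue
    }
    return CohortSpec(
        seed=seed,
        genes=[gene5, gene3] + background,
        fusion=fusion,
        cna_arms=cna_arms,
    )


# ---------------------------------------------------------------------------
# Genome

def make_genome(spec: CohortSpec) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate random chromosome sequences and return them with the gene
    models, after validating that genes fit and do not overlap."""
    rng = np.random.default_rng(spec.seed)
    names = spec.chrom_names()
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in spec.genes:
        if gene.chrom not in names:
            raise ValueError(f"gene {gene.gene_id} on unknown {gene.chrom}")
        if gene.end > spec.chrom_length:
            raise ValueError(
                f"gene {gene.gene_id} extends past chromosome end"
            )
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for chrom, genes in by_chrom.items():
        spans = sorted((g.start, g.end, g.gene_id) for g in genes)
        for (s1, e1, g1), (s2, e2, g2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"genes {g1} and {g2} overlap on {chrom}")
    if spec.fusion is not None:
        _validate_fusion(spec.fusion, spec.genes)
    bases = np.array(list("ACGT"))
    seqs = {
        name: "".join(bases[rng.integers(0, 4, size=spec.chrom_length)])
        for name in names
    }
    return seqs, list(spec.genes)


def _gene_by_id(genes: Sequence[GeneModel], gene_id: str) -> GeneModel:
    for g in genes:
        if g.gene_id == gene_id:
            return g
    raise KeyError(f"no gene {gene_id!r}")


def _validate_fusion(fusion: FusionSpec, genes: Sequence[GeneModel]) -> None:
    g5 = _gene_by_id(genes, fusion.gene5)
    g3 = _gene_by_id(genes, fusion.gene3)
    if not g5.start <= fusion.breakpoint5 <= g5.end:
        raise ValueError("breakpoint5 outside donor gene span")
    if not g3.start <= fusion.breakpoint3 <= g3.end:
        raise ValueError("breakpoint3 outside acceptor gene span")


# ---------------------------------------------------------------------------
# Fusion read pairs

def _donor_prefix_coords(gene: GeneModel, breakpoint5: int) -> int:
    """Contiguous genomic bases available immediately 5' of the junction
    within the breakpoint exon (or intron, for an intronic breakpoint)."""
    idx = gene.exon_index_at(breakpoint5)
    if idx is not None:
        s, e = gene.exons[idx]
        return breakpoint5 - s + 1 if gene.strand == "+" else e - breakpoint5 + 1
    return 0


def simulate_fusion_read_pairs(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    fusion: Optional[FusionSpec],
    n_pairs: int,
    insert_size_mean: int = 250,
    insert_size_sd: int = 30,
    read_length: int = 101,
    seed: int = 0,
    background_pairs_per_gene: int = 0,
    junction_read_fraction: float = 0.2,
    placement: str = "random",
    pair_id_prefix: str = "frag",
) -> tuple[list[ReadPairAlignment], dict[str, int], list[str]]:
    """Simulate paired-end RNA fragments around an injected fusion.

    Emits three classes: (a) concordant background pairs drawn from within
    each gene's span, (b) discordant pairs whose mates flank the fusion
    junction (mate1 entirely in the donor ending at or before
    ``breakpoint5``, mate2 entirely in the acceptor starting at or after
    ``breakpoint3``), and (c) junction-spanning reads, returned as raw
    sequences because a contiguous-alignment record cannot represent a
    split read.

    ``placement="tiled"`` spaces discordant fragments evenly over the
    admissible junction offsets (noise-free coverage with reads ending
    exactly at the donor breakpoint and starting exactly at the acceptor
    breakpoint); ``"random"`` draws offsets and insert sizes randomly.

    Returns ``(pairs, class_counts, junction_read_sequences)``.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPairAlignment] = []
    junction_seqs: list[str] = []
    counts = {"concordant": 0, "discordant": 0, "junction": 0}
    serial = 0

    if background_pairs_per_gene:
        for gene in genes:
            span = gene.end - gene.start + 1
            if insert_size_mean > span:
                raise ValueError(
                    f"insert size {insert_size_mean} exceeds span of "
                    f"{gene.gene_id}"
                )
            hi = gene.end - insert_size_mean + 1
            starts = rng.integers(gene.start, hi + 1,
                                  size=background_pairs_per_gene)
            for u in starts:
                u = int(u)
                pairs.append(
                    ReadPairAlignment(
                        pair_id=f"{pair_id_prefix}_bg_{serial}",
                        mate1=MateAlignment(gene.chrom, u, "+", read_length),
                        mate2=MateAlignment(
                            gene.chrom,
                            u + insert_size_mean - read_length,
                            "-",
                            read_length,
                        ),
                    )
                )
                serial += 1
                counts["concordant"] += 1

    if fusion is None or n_pairs == 0 or fusion.expression_level == 0:
        return pairs, counts, junction_seqs

    g5 = _gene_by_id(genes, fusion.gene5)
    g3 = _gene_by_id(genes, fusion.gene3)
    bp5, bp3 = fusion.breakpoint5, fusion.breakpoint3
    donor_avail = _donor_prefix_coords(g5, bp5)
    idx3 = g3.exon_index_at(bp3)
    if idx3 is None:
        raise ValueError("acceptor breakpoint must lie in an exon")
    s3, e3 = g3.exons[idx3]
    acceptor_avail = e3 - bp3 + 1 if g3.strand == "+" else bp3 - s3 + 1

    n_fusion = int(round(n_pairs * min(fusion.expression_level, 1.0)))
    n_junction = int(round(n_fusion * junction_read_fraction))
    n_discordant = n_fusion - n_junction

    lo_d = read_length
    hi_d = insert_size_mean - read_length
    hi_d = min(hi_d, donor_avail)
    if hi_d < lo_d:
        raise ValueError(
            "insert size leaves no room for a discordant mate on the donor "
            "side; shorten the reads or enlarge the donor exon"
        )
    if placement == "tiled":
        donor_parts = np.unique(
            np.round(np.linspace(lo_d, hi_d, max(n_discordant, 2)))
        ).astype(int)
        donor_parts = np.resize(donor_parts, n_discordant)
        inserts = np.full(n_discordant, insert_size_mean, dtype=int)
    else:
        donor_parts = rng.integers(lo_d, hi_d + 1, size=n_discordant)
        inserts = np.clip(
            np.round(rng.normal(insert_size_mean, insert_size_sd,
                                size=n_discordant)),
            2 * read_length,
            None,
        ).astype(int)
    for d, ins in zip(donor_parts, inserts):
        d = int(d)
        a = int(ins) - d  # acceptor portion of the fragment
        a = max(read_length, min(a, acceptor_avail))
        if g5.strand == "+":
            m1 = MateAlignment(g5.chrom, bp5 - d + 1, "+", read_length)
        else:
            m1 = MateAlignment(g5.chrom, bp5 + d - read_length, "-",
                               read_length)
        if g3.strand == "+":
            m2 = MateAlignment(g3.chrom, bp3 + a - read_length, "-",
                               read_length)
        else:
            m2 = MateAlignment(g3.chrom, bp3 - a + 1, "+", read_length)
        pairs.append(
            ReadPairAlignment(
                pair_id=f"{pair_id_prefix}_fus_{serial}", mate1=m1, mate2=m2
            )
        )
        serial += 1
        counts["discordant"] += 1

    # junction-spanning reads: donor suffix + acceptor prefix
    donor_seq = _transcript_side(genome, g5, bp5, side="donor",
                                 k=read_length - 1)
    acceptor_seq = _transcript_side(genome, g3, bp3, side="acceptor",
                                    k=read_length - 1)
    max_off = min(len(donor_seq), read_length - 1)
    min_off = read_length - min(len(acceptor_seq), read_length - 1)
    if placement == "tiled":
        offsets = np.round(
            np.linspace(min_off, max_off, max(n_junction, 1))
        ).astype(int)[:n_junction]
    else:
        offsets = rng.integers(min_off, max_off + 1, size=n_junction)
    for o in offsets:
        o = int(o)
        junction_seqs.append(
            donor_seq[len(donor_seq) - o:] + acceptor_seq[: read_length - o]
        )
        counts["junction"] += 1
    return pairs, counts, junction_seqs


def _transcript_side(
    genome: Mapping[str, str],
    gene: GeneModel,
    breakpoint: int,
    side: str,
    k: int,
) -> str:
    """Up to ``k`` transcript-orientation bases ending at (donor) or
    starting at (acceptor) the breakpoint, reverse-complemented for minus-
    strand genes.  Does not cross exon boundaries."""
    seq = genome[gene.chrom]
    avail = (
        _donor_prefix_coords(gene, breakpoint)
        if side == "donor"
        else _acceptor_suffix_coords(gene, breakpoint)
    )
    k = min(k, avail)
    if side == "donor":
        if gene.strand == "+":
            frag = seq[breakpoint - k : breakpoint]
        else:
            frag = _revcomp(seq[breakpoint - 1 : breakpoint - 1 + k])
    else:
        if gene.strand == "+":
            frag = seq[breakpoint - 1 : breakpoint - 1 + k]
        else:
            frag = _revcomp(seq[breakpoint - k : breakpoint])
    return frag


def _acceptor_suffix_coords(gene: GeneModel, breakpoint: int) -> int:
    idx = gene.exon_index_at(breakpoint)
    if idx is None:
        return 0
    s, e = gene.exons[idx]
    return e - breakpoint + 1 if gene.strand == "+" else breakpoint - s + 1


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


# ---------------------------------------------------------------------------
# Exome depth profiles

_CNA_FACTORS = {"gain": None, "loss": None, "neutral": 1.0}


def simulate_depth_profiles(
    cna_arms: Mapping[str, tuple[str, str]],
    n_windows: int,
    mean_depth: float = 200.0,
    noise: float = 0.05,
    seed: int = 0,
    gain_factor: float = 1.5,
    loss_factor: float = 0.5,
    tumor_library_factor: float = 1.0,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Simulate matched tumor/normal per-window read counts.

    Each chromosome gets ``n_windows`` windows; the first half belong to
    the p arm, the rest to the q arm.  Tumor window means are the normal
    mean scaled by the arm's copy state (gain 1.5x, loss 0.5x, neutral 1x
    by default) and a library-size factor.  Counts are negative-binomial
    with dispersion ``noise`` (variance m + noise*m^2); ``noise=0`` yields
    the exact means, so ratios are noise-free.
    """
    if n_windows <= 0:
        raise ValueError("n_windows must be > 0")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)
    factors = {"gain": gain_factor, "loss": loss_factor, "neutral": 1.0}
    rows = []
    for chrom, (p_state, q_state) in cna_arms.items():
        for state in (p_state, q_state):
            if state not in factors:
                raise ValueError(f"unknown arm state {state!r}")
        half = n_windows // 2
        for w in range(n_windows):
            arm = "p" if w < half else "q"
            state = p_state if arm == "p" else q_state
            rows.append(
                (chrom, w * window_bp + 1, (w + 1) * window_bp, arm, state)
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "arm", "state"])
    normal_mean = np.full(len(df), mean_depth)
    tumor_mean = (
        normal_mean
        * df["state"].map(factors).to_numpy()
        * tumor_library_factor
    )
    if noise == 0:
        df["normal"] = normal_mean
        df["tumor"] = tumor_mean
    else:
        df["normal"] = _nb_draw(rng, normal_mean, noise)
        df["tumor"] = _nb_draw(rng, tumor_mean, noise)
    return df


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative-binomial counts with var = m + dispersion * m^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# Somatic variants

class GenomeSites:
    """Cached per-chromosome site indices for variant placement.

    Positions are 0-based indices into the chromosome string, excluding
    the first and last base so a trinucleotide context always exists.
    """

    def __init__(self, genome: Mapping[str, str]) -> None:
        self.genome = genome
        self.chroms = list(genome)
        self.lengths = {c: len(genome[c]) for c in self.chroms}
        self.pyr_sites: dict[str, dict[str, np.ndarray]] = {}
        self.npcpg_sites: dict[str, np.ndarray] = {}
        for chrom, seq in genome.items():
            arr = np.frombuffer(seq.encode(), dtype="S1")
            interior = slice(1, len(seq) - 1)
            is_c = arr == b"C"
            is_g = arr == b"G"
            is_t = arr == b"T"
            is_a = arr == b"A"
            idx = np.arange(len(seq))
            self.pyr_sites[chrom] = {
                "C": idx[interior][(is_c | is_g)[interior]],
                "T": idx[interior][(is_t | is_a)[interior]],
            }
            # NpCpG on either strand: C followed by G, or G preceded by C
            cpg = np.zeros(len(seq), dtype=bool)
            cpg[:-1] |= is_c[:-1] & is_g[1:]  # the C of a CpG
            cpg[1:] |= is_g[1:] & is_c[:-1]  # the G of a CpG
            self.npcpg_sites[chrom] = idx[interior][cpg[interior]]
        self.total_mb = sum(self.lengths.values()) / 1e6


def simulate_variants(
    genome: Mapping[str, str],
    mut_rate: float,
    signature_mix: Mapping[str, float] | None = None,
    npcpg_enriched: bool = False,
    npcpg_fraction: float = 0.4,
    indel_fraction: float = 0.05,
    seed: int = 0,
    sample_id: str = "S1",
    sites: Optional[GenomeSites] = None,
) -> list[SomaticVariant]:
    """Draw somatic variants at ``mut_rate`` mutations/Mb.

    The total count is Poisson with mean rate x genome megabases; a fixed
    fraction (default 5%) become 1-bp indels, the rest SNVs whose
    substitution class follows ``signature_mix``.  When ``npcpg_enriched``,
    each C>T event is placed at an NpCpG site with probability
    ``npcpg_fraction`` (deamination-of-methyl-cytosine mimicry); otherwise
    all events land at uniformly chosen sites with the matching reference
    base on either strand.
    """
    if mut_rate < 0:
        raise ValueError("mut_rate must be >= 0")
    mix = dict(signature_mix or DEFAULT_SIGNATURE_MIX)
    weights = np.array([mix.get(c, 0.0) for c in SUBSTITUTION_CLASSES])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("signature weights must sum to 1")
    rng = np.random.default_rng(seed)
    if sites is None:
        sites = GenomeSites(genome)
    n_total = rng.poisson(mut_rate * sites.total_mb)
    if n_total == 0:
        return []
    n_indel = rng.binomial(n_total, indel_fraction)
    n_snv = n_total - n_indel

    chrom_lens = np.array([sites.lengths[c] for c in sites.chroms], float)
    chrom_p = chrom_lens / chrom_lens.sum()
    variants: list[SomaticVariant] = []

    class_ids = rng.choice(len(SUBSTITUTION_CLASSES), size=n_snv, p=weights)
    chrom_ids = rng.choice(len(sites.chroms), size=n_snv, p=chrom_p)
    at_cpg = (
        rng.random(n_snv) < npcpg_fraction
        if npcpg_enriched
        else np.zeros(n_snv, dtype=bool)
    )
    for ci, ki, cpg in zip(chrom_ids, class_ids, at_cpg):
        chrom = sites.chroms[int(ci)]
        cls = SUBSTITUTION_CLASSES[int(ki)]
        pyr_ref, pyr_alt = cls[0], cls[2]
        if cpg and cls == "C>T":
            pool = sites.npcpg_sites[chrom]
        else:
            pool = sites.pyr_sites[chrom][pyr_ref]
        if len(pool) == 0:
            continue
        pos0 = int(pool[rng.integers(len(pool))])
        ref = genome[chrom][pos0]
        if ref == pyr_ref:
            alt = pyr_alt
        else:  # purine strand: complement the class
            alt = _COMPLEMENT[pyr_alt]
        variants.append(
            SomaticVariant(sample_id, chrom, pos0 + 1, ref, alt)
        )

    for _ in range(n_indel):
        chrom = sites.chroms[int(rng.choice(len(sites.chroms), p=chrom_p))]
        seq = genome[chrom]
        pos0 = int(rng.integers(1, len(seq) - 2))
        base = seq[pos0]
        if rng.random() < 0.5:  # insertion
            ins = "ACGT"[rng.integers(4)]
            variants.append(
                SomaticVariant(sample_id, chrom, pos0 + 1, base, base + ins)
            )
        else:  # 1-bp deletion
            variants.append(
                SomaticVariant(
                    sample_id, chrom, pos0 + 1, base + seq[pos0 + 1], base
                )
            )
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


# ---------------------------------------------------------------------------
# Expression counts

def simulate_expression_counts(
    gene_lengths: Mapping[str, int],
    sample_groups: Mapping[str, str],
    base_mean: float = 500.0,
    overexpression: Mapping[str, Mapping[str, float] | tuple[str, float]]
    | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene read counts for a grouped cohort.

    ``overexpression`` maps gene -> {group: fold} (a single (group, fold)
    pair is also accepted): samples in a listed group get a fold-elevated
    mean for that gene — the pattern of the fusion target gene being
    over-expressed in fusion-harbouring samples.
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_lengths)
    samples = list(sample_groups)
    over: dict[str, dict[str, float]] = {}
    for g, spec in (overexpression or {}).items():
        over[g] = dict([spec]) if isinstance(spec, tuple) else dict(spec)
    means = np.empty((len(genes), len(samples)))
    for i, g in enumerate(genes):
        scale = gene_lengths[g] / 1000.0  # longer genes catch more reads
        for j, s in enumerate(samples):
            fold = over.get(g, {}).get(sample_groups[s], 1.0)
            means[i, j] = base_mean * scale * fold
    counts = _nb_draw(rng, means.ravel(), dispersion).reshape(means.shape)
    return pd.DataFrame(counts, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# Genotype cohort

def simulate_genotype_cohort(
    group_sizes: Mapping[str, int] | Sequence[int],
    genotype_probs: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    seed: int = 0,
    genotypes: Sequence[str] = ("G/G", "G/A", "A/A"),
) -> GenotypeCohortTable:
    """Draw genotype counts per group from multinomial distributions."""
    if not isinstance(group_sizes, Mapping):
        group_sizes = {f"group{i + 1}": n for i, n in enumerate(group_sizes)}
        genotype_probs = {
            g: p for g, p in zip(group_sizes, genotype_probs)
        }
    rng = np.random.default_rng(seed)
    counts = []
    for group, n in group_sizes.items():
        if n < 0:
            raise ValueError("group sizes must be >= 0")
        p = np.asarray(genotype_probs[group], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"genotype probabilities for {group} must sum to 1")
        counts.append(rng.multinomial(n, p))
    return GenotypeCohortTable(
        groups=tuple(group_sizes),
        genotypes=tuple(genotypes),
        counts=np.array(counts),
    )


def rs2305089_study_counts() -> GenotypeCohortTable:
    """The observed rs2305089 genotype table: 8 skull base chordoma cases
    (G/G 1, G/A 3, A/A 4) against 75 glioma controls (G/G 36, G/A 32,
    A/A 7)."""
    return GenotypeCohortTable(
        groups=("chordoma", "control"),
        genotypes=("G/G", "G/A", "A/A"),
        counts=np.array([[1, 3, 4], [36, 32, 7]]),
    )


def study_clinical_records() -> list[ClinicalRecord]:
    """The ten-patient skull base chordoma clinical table."""
    rows = [
        (1, 56, "M", "chondroid", "Clivus", "GTR", "recurrence", "Y", "alive"),
        (2, 67, "M", "chondroid", "Clivus", "GTR", "primary", "N", "alive"),
        (3, 49, "M", "chondroid", "Clivus", "STR", "primary", "N", "alive"),
        (4, 63, "F", "chondroid", "Clivus", "GTR", "primary", "N", "alive"),
        (5, 62, "M", "typical", "Clivus", "GTR", "primary", "Y", "alive"),
        (6, 64, "F", "typical", "Clivus", "GTR", "primary", "N", "alive"),
        (7, 72, "M", "typical", "Clivus", "GTR", "recurrence", "N", "alive"),
        (8, 60, "M", "chondroid", "Clivus", "GTR", "recurrence", "Y", "alive"),
        (9, 58, "M", "unknown", "Clivus", "GTR", "primary", "ND", "alive"),
        (10, 48, "M", "unknown", "Clivus", "STR", "recurrence", "ND", "alive"),
    ]
    return [ClinicalRecord(*row) for row in rows]
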