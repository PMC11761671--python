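"""Microsynteny scoring around homologs and tandem vs dispersed duplicate
classification.

For a pair of homologous genes, the region spanning each gene plus
``flank_bp`` (default 50 kb) on both sides is extracted with the focal gene's
own span hard-masked with N, the two regions are locally aligned, alignments
shorter than ``min_aln_len`` (default 100 bp) or below the score cutoff are
discarded, and the flanking-homology fraction is the merged aligned flank
bases divided by the available flank bases (the homolog's positions excluded
from both numerator and denominator). Genes sharing less than 5% flanking
homology are classified non-syntenic.

Duplicate pairs are classified tandem when on the same scaffold and either
close in genomic distance or separated by few annotated genes; otherwise
dispersed (retro-style relocation). The cutoffs are explicit config defaults
because visual dotplot judgment is not reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import AlignParams, local_align, merged_covered_length
from .io_core import GeneRecord, Genome

SYNTENY_CUTOFF = 0.05  # below this flanking-homology fraction: non-syntenic
DEFAULT_FLANK_BP = 50_000
MIN_ALN_LEN = 100


@dataclass
class SyntenyRecord:
    gene_a: str
    gene_b: str
    flank_bp: int
    aligned_bp_excl_homolog: int
    flank_total_bp: int
    flanking_homology: float
    syntenic: bool


@dataclass
class DuplicateClassification:
    paralog_pair: tuple[str, str]
    mode: str  # tandem | dispersed
    same_scaffold: bool
    genomic_gap_bp: int | None = None
    intervening_genes: int | None = None


def extract_flanks(
    gene: GeneRecord, genome: Genome, flank_bp: int = DEFAULT_FLANK_BP
) -> tuple[str, str, tuple[int, int]]:
    """Return (left flank, right flank, homolog span) for a gene, with flanks
    clipped at scaffold ends."""
    if gene.scaffold not in genome:
        raise ValueError(f"gene {gene.gene_id}: scaffold {gene.scaffold!r} not in genome")
    seq = genome[gene.scaffold].sequence
    s, e = gene.span
    left = seq[max(0, s - flank_bp) : s]
    right = seq[e : e + flank_bp]
    return left, right, (s, e)


def _masked_region(gene: GeneRecord, genome: Genome, flank_bp: int) -> tuple[str, int, int]:
    """The gene's neighbourhood with the homolog span hard-masked with N.

    Returns (sequence, masked span start within the region, masked length).
    """
    left, right, (s, e) = extract_flanks(gene, genome, flank_bp)
    homolog_len = e - s
    region = left + "N" * homolog_len + right
    return region, len(left), homolog_len


def flanking_homology(
    rec_a: GeneRecord,
    rec_b: GeneRecord,
    genome_a: Genome,
    genome_b: Genome,
    flank_bp: int = DEFAULT_FLANK_BP,
    params: AlignParams | None = None,
    min_aln_len: int = MIN_ALN_LEN,
    cutoff: float = SYNTENY_CUTOFF,
) -> SyntenyRecord:
    """Score flanking homology between the neighbourhoods of two genes.

    Both flanks are pooled into a single ratio. At scaffold edges the
    denominator is the flank sequence actually present, so genes near contig
    ends are not penalized.
    """
    region_a, mask_off, mask_len = _masked_region(rec_a, genome_a, flank_bp)
    region_b, _, _ = _masked_region(rec_b, genome_b, flank_bp)
    flank_total = len(region_a) - mask_len
    if flank_total == 0 or len(region_b) == 0:
        raise ValueError(f"no flanking sequence for pair ({rec_a.gene_id}, {rec_b.gene_id})")

    p = params or AlignParams.nucleotide()
    hsps = [
        h
        for h in local_align(region_a, region_b, p, rec_a.gene_id, rec_b.gene_id)
        if h.aln_len >= min_aln_len
    ]
    # merged aligned query bases, excluding any residual overlap with the mask
    intervals = []
    for h in hsps:
        s, e = h.q_interval
        if s < mask_off + mask_len and e > mask_off:  # clip out the masked span
            if s < mask_off:
                intervals.append((s, min(e, mask_off)))
            if e > mask_off + mask_len:
                intervals.append((max(s, mask_off + mask_len), e))
        else:
            intervals.append((s, e))
    aligned = merged_covered_length(intervals)
    frac = min(aligned / flank_total, 1.0)
    return SyntenyRecord(
        gene_a=rec_a.gene_id,
        gene_b=rec_b.gene_id,
        flank_bp=flank_bp,
        aligned_bp_excl_homolog=aligned,
        flank_total_bp=flank_total,
        flanking_homology=frac,
        syntenic=frac >= cutoff,
    )


def classify_duplicate(
    paralog_pair: tuple[GeneRecord, GeneRecord],
    gene_records: list[GeneRecord] | None = None,
    tandem_max_gap: int = 100_000,
    tandem_max_genes: int = 10,
) -> DuplicateClassification:
    """Classify a paralog pair as tandem or dispersed.

    Tandem iff on the same scaffold AND (genomic gap <= ``tandem_max_gap`` OR
    number of annotated genes between them <= ``tandem_max_genes``).
    ``gene_records`` supplies the annotation used to count intervening genes;
    without it only the distance rule applies.
    """
    a, b = paralog_pair
    ids = (a.gene_id, b.gene_id)
    if a.scaffold != b.scaffold:
        return DuplicateClassification(ids, "dispersed", same_scaffold=False)
    (as_, ae), (bs, be) = a.span, b.span
    gap = max(bs - ae, as_ - be, 0)
    intervening = None
    if gene_records is not None:
        lo, hi = min(ae, be), max(as_, bs)
        intervening = sum(
            1
            for g in gene_records
            if g.scaffold == a.scaffold
            and g.gene_id not in ids
            and g.span[0] >= lo
            and g.span[1] <= hi
        )
    tandem = gap <= tandem_max_gap or (intervening is not None and intervening <= tandem_max_genes)
    return DuplicateClassification(
        ids,
        "tandem" if tandem else "dispersed",
        same_scaffold=True,
        genomic_gap_bp=gap,
        intervening_genes=intervening,
    )
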