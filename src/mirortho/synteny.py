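"""Microsynteny: classify a reference miRNA's genomic context and locate the
shared syntenic region in a core species via protein-coding anchor genes.

An intergenic miRNA is anchored by its flanking protein-coding genes; a
region in the core genome is shared syntenic when the orthologs of an
anchor pair lie on the same chromosome with at most ``k`` genes between
them.  Up to ``n`` additional genes per side serve as alternative anchors
(gene loss / annotation-artefact tolerance).  Anchor pairs are tried
nearest-first; orientation is ignored, so inversions are tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .alignment_search import (
    SearchEngineParams,
    best_hit,
    confirm_by_reverse_search,
    local_search,
)
from .genomics_io import (
    GeneAnnotation,
    GenomeSequence,
    GenomicInterval,
    MirnaRecord,
    OrthologTable,
    extract_sequence,
)

__all__ = [
    "SyntenyParams",
    "MirnaContext",
    "CoreBundle",
    "classify_context",
    "shared_syntenic_region",
    "collect_positional_ortholog",
]


@dataclass(frozen=True)
class SyntenyParams:
    """k: max intervening genes between anchor orthologs; n: max alternative
    anchors per side."""

    k: int = 3
    n: int = 1
    flank: int = 100  # nt added around the syntenic span

    def __post_init__(self) -> None:
        if self.k < 0 or self.n < 0 or self.flank < 0:
            raise ValueError("SyntenyParams fields must be >= 0")


@dataclass(frozen=True)
class MirnaContext:
    """Genomic context of a reference miRNA.

    ``up_anchors``/``down_anchors`` are nearest-first gene ids; they are
    populated for intragenic miRNAs too, to support the fallback when the
    host gene has no ortholog.
    """

    kind: str  # "intergenic" | "intragenic"
    host_gene: str | None = None
    up_anchors: tuple[str, ...] = ()
    down_anchors: tuple[str, ...] = ()


@dataclass
class CoreBundle:
    """Everything needed to query one core species."""

    species: str
    genome: GenomeSequence
    annotation: GeneAnnotation
    orthologs: OrthologTable


def classify_context(
    mirna: MirnaRecord, annotation: GeneAnnotation, params: SyntenyParams | None = None
) -> MirnaContext:
    """Intragenic iff a protein-coding gene contains the full pre-miRNA
    interval; otherwise intergenic with up to n+1 anchors per side,
    nearest-first.  Genes only partially overlapping the miRNA are not used
    as anchors."""
    params = params or SyntenyParams()
    iv = mirna.interval
    genes = annotation.genes_on(iv.chrom)
    host = None
    for g in genes:
        gi = g.interval
        if gi.start <= iv.start and iv.end <= gi.end:
            host = g.gene_id
            break
    upstream = [g.gene_id for g in genes if g.interval.end <= iv.start]
    downstream = [g.gene_id for g in genes if g.interval.start >= iv.end]
    n_take = params.n + 1
    up = tuple(reversed(upstream[-n_take:]))  # nearest first
    down = tuple(downstream[:n_take])
    if host is not None:
        return MirnaContext("intragenic", host_gene=host, up_anchors=up, down_anchors=down)
    return MirnaContext("intergenic", up_anchors=up, down_anchors=down)


def _span_of(core: GeneAnnotation, gene_a: str, gene_b: str) -> GenomicInterval:
    ia, ib = core.gene(gene_a).interval, core.gene(gene_b).interval
    return GenomicInterval(ia.chrom, min(ia.start, ib.start), max(ia.end, ib.end), "+")


def _intervening_genes(core: GeneAnnotation, gene_a: str, gene_b: str) -> int | None:
    """Number of genes strictly between the two genes in core gene order, or
    None when they are on different chromosomes."""
    ia, ib = core.gene(gene_a).interval, core.gene(gene_b).interval
    if ia.chrom != ib.chrom:
        return None
    order = [g.gene_id for g in core.genes_on(ia.chrom)]
    pa, pb = order.index(gene_a), order.index(gene_b)
    if pa > pb:
        pa, pb = pb, pa
    return pb - pa - 1


def _clip(
    iv: GenomicInterval, flank: int, chrom_lengths: Mapping[str, int] | None
) -> GenomicInterval:
    start = max(0, iv.start - flank)
    end = iv.end + flank
    if chrom_lengths is not None and iv.chrom in chrom_lengths:
        end = min(end, chrom_lengths[iv.chrom])
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def shared_syntenic_region(
    context: MirnaContext,
    core_annotation: GeneAnnotation,
    orthologs: OrthologTable,
    params: SyntenyParams | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> GenomicInterval | None:
    """Locate the shared syntenic region in the core species, or None.

    Intragenic: the host gene ortholog's locus (falling back to intergenic
    logic when the host is unmapped).  Intergenic: the first qualifying
    anchor pair, pairs ordered nearest-first by (up rank + down rank, up
    rank); a pair qualifies when both orthologs share a chromosome with at
    most k genes between them.  The returned span includes the anchor genes
    and is extended by ``flank`` nt each side.
    """
    params = params or SyntenyParams()
    if context.kind == "intragenic":
        host_ortholog = orthologs.get(context.host_gene) if context.host_gene else None
        if host_ortholog is not None and host_ortholog in core_annotation:
            iv = core_annotation.gene(host_ortholog).interval
            return _clip(
                GenomicInterval(iv.chrom, iv.start, iv.end, "+"), params.flank, chrom_lengths
            )
        # host unmapped: proceed as if intergenic
    pairs = [
        (i + j, i, up, down)
        for i, up in enumerate(context.up_anchors)
        for j, down in enumerate(context.down_anchors)
    ]
    pairs.sort(key=lambda t: (t[0], t[1]))
    for _, _, up, down in pairs:
        up_o, down_o = orthologs.get(up), orthologs.get(down)
        if up_o is None or down_o is None:
            continue
        if up_o not in core_annotation or down_o not in core_annotation:
            continue
        between = _intervening_genes(core_annotation, up_o, down_o)
        if between is None or between > params.k:
            continue
        return _clip(_span_of(core_annotation, up_o, down_o), params.flank, chrom_lengths)
    return None


def collect_positional_ortholog(
    mirna: MirnaRecord,
    reference_annotation: GeneAnnotation,
    reference_genome: GenomeSequence,
    core: CoreBundle,
    params: SyntenyParams | None = None,
    search_params: SearchEngineParams | None = None,
) -> str | None:
    """Positional miRNA ortholog sequence in one core species, or None.

    Extracts the shared syntenic region, searches it with the reference
    pre-miRNA, and accepts the best hit only if its reverse search in the
    reference genome identifies the reference miRNA locus (reciprocal best
    hit).  The returned sequence is the hit extended/trimmed to the
    reference pre-miRNA length (clipped at region bounds).
    """
    params = params or SyntenyParams()
    search_params = search_params or SearchEngineParams()
    context = classify_context(mirna, reference_annotation, params)
    chrom_lengths = {c: core.genome.length(c) for c in core.genome}
    region = shared_syntenic_region(
        context, core.annotation, core.orthologs, params, chrom_lengths
    )
    if region is None:
        return None
    region_seq = extract_sequence(core.genome, region)
    region_genome = GenomeSequence({"region": region_seq})
    hit = best_hit(local_search(mirna.sequence, region_genome, search_params))
    if hit is None:
        return None
    # extend the aligned subject interval by the unaligned query lengths on
    # each end so the candidate covers the whole pre-miRNA, then trim any
    # indel-driven surplus from the right
    qlen = len(mirna.sequence)
    iv = hit.interval
    lo = max(0, iv.start - hit.query_start)
    hi = min(len(region_seq), iv.end + (qlen - hit.query_end))
    if hi - lo > qlen:
        hi = lo + qlen
    candidate = extract_sequence(
        region_genome, GenomicInterval("region", lo, hi, iv.strand)
    )
    if not confirm_by_reverse_search(candidate, reference_genome, mirna, search_params):
        return None
    return candidate
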