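import numpy as np
import pytest

from mirortho.genomics_io import (
    GeneAnnotation,
    GeneRecord,
    GenomeSequence,
    GenomicInterval,
    MirnaRecord,
    OrthologTable,
    decode_sequence,
)
from mirortho.synteny import (
    CoreBundle,
    MirnaContext,
    SyntenyParams,
    classify_context,
    collect_positional_ortholog,
    shared_syntenic_region,
)


def annotation(order, chrom="c1", start=0, gene_len=10, gap=5):
    """Helper: genes laid out left to right in the given id order."""
    genes = []
    pos = start
    for gid in order:
        genes.append(GeneRecord(gid, GenomicInterval(chrom, pos, pos + gene_len)))
        pos += gene_len + gap
    return GeneAnnotation(genes)


def mirna_between(ann, left_gid, right_gid, chrom="c1"):
    li = ann.gene(left_gid).interval
    ri = ann.gene(right_gid).interval
    start = li.end + 1
    end = ri.start - 1
    return MirnaRecord(
        "mir", "fam", GenomicInterval(chrom, start, end, "+"), "A" * (end - start)
    )


class TestClassifyContext:
    def test_intragenic_containment(self):
        ann = annotation(["A", "B", "C"], gene_len=100, gap=20)
        host = ann.gene("B").interval
        m = MirnaRecord(
            "mir", "fam", GenomicInterval("c1", host.start + 10, host.start + 72, "+"), "A" * 62
        )
        ctx = classify_context(m, ann)
        assert ctx.kind == "intragenic" and ctx.host_gene == "B"

    def test_intergenic_nearest_first_anchors(self):
        ann = annotation(["A", "B", "C", "D"])
        m = mirna_between(ann, "B", "C")
        ctx = classify_context(m, ann, SyntenyParams(n=1))
        assert ctx.kind == "intergenic"
        assert ctx.up_anchors == ("B", "A")
        assert ctx.down_anchors == ("C", "D")

    def test_mirna_before_first_gene(self):
        ann = annotation(["A", "B"], start=100)
        m = MirnaRecord("mir", "fam", GenomicInterval("c1", 10, 72, "+"), "A" * 62)
        ctx = classify_context(m, ann)
        assert ctx.kind == "intergenic"
        assert ctx.up_anchors == ()
        assert ctx.down_anchors == ("A", "B")

    def test_no_genes_yields_empty_anchor_context(self):
        ann = GeneAnnotation([])
        m = MirnaRecord("mir", "fam", GenomicInterval("c1", 10, 72, "+"), "A" * 62)
        ctx = classify_context(m, ann)
        assert ctx.up_anchors == () and ctx.down_anchors == ()


class TestSharedSyntenicRegion:
    def setup_method(self):
        self.ctx = MirnaContext("intergenic", up_anchors=("B",), down_anchors=("C",))

    def test_one_intervening_gene_qualifies(self):
        core = annotation(["Bp", "x", "Cp"])
        table = OrthologTable({"B": "Bp", "C": "Cp"})
        region = shared_syntenic_region(self.ctx, core, table, SyntenyParams(k=3, flank=0))
        assert region == GenomicInterval(
            "c1", core.gene("Bp").interval.start, core.gene("Cp").interval.end, "+"
        )

    def test_too_many_intervening_genes(self):
        core = annotation(["Bp", "x1", "x2", "x3", "x4", "Cp"])
        table = OrthologTable({"B": "Bp", "C": "Cp"})
        assert (
            shared_syntenic_region(self.ctx, core, table, SyntenyParams(k=3, n=0))
            is None
        )

    def test_anchors_on_different_chromosomes(self):
        genes = list(annotation(["Bp"]).all_genes()) + [
            GeneRecord("Cp", GenomicInterval("c2", 0, 10))
        ]
        core = GeneAnnotation(genes)
        table = OrthologTable({"B": "Bp", "C": "Cp"})
        assert (
            shared_syntenic_region(self.ctx, core, table, SyntenyParams(n=0)) is None
        )

    def test_inverted_anchor_order_tolerated(self):
        core = annotation(["Cp", "x", "Bp"])
        table = OrthologTable({"B": "Bp", "C": "Cp"})
        region = shared_syntenic_region(self.ctx, core, table, SyntenyParams(flank=0))
        assert region is not None
        assert region.start == core.gene("Cp").interval.start
        assert region.end == core.gene("Bp").interval.end

    def test_intragenic_host_ortholog(self):
        ctx = MirnaContext("intragenic", host_gene="G")
        core = annotation(["Gp"])
        table = OrthologTable({"G": "Gp"})
        region = shared_syntenic_region(ctx, core, table, SyntenyParams(flank=7))
        iv = core.gene("Gp").interval
        assert region == GenomicInterval("c1", max(0, iv.start - 7), iv.end + 7, "+")

    def test_intragenic_unmapped_host_falls_back_to_anchors(self):
        ctx = MirnaContext(
            "intragenic", host_gene="G", up_anchors=("B",), down_anchors=("C",)
        )
        core = annotation(["Bp", "Cp"])
        table = OrthologTable({"B": "Bp", "C": "Cp"})
        region = shared_syntenic_region(ctx, core, table, SyntenyParams(flank=0))
        assert region is not None


def _oracle_shared_region(ctx, core, table, params):
    """Independent brute-force enumeration of anchor pairs, nearest-first."""
    pairs = sorted(
        (
            (i + j, i, up, down)
            for i, up in enumerate(ctx.up_anchors)
            for j, down in enumerate(ctx.down_anchors)
        ),
        key=lambda t: (t[0], t[1]),
    )
    for _, _, up, down in pairs:
        uo, do = table.get(up), table.get(down)
        if uo is None or do is None or uo not in core or do not in core:
            continue
        iu, id_ = core.gene(uo).interval, core.gene(do).interval
        if iu.chrom != id_.chrom:
            continue
        between = sum(
            1
            for g in core.genes_on(iu.chrom)
            if g.gene_id not in (uo, do)
            and min(iu.start, id_.start) < g.interval.start < max(iu.start, id_.start)
        )
        if between > params.k:
            continue
        lo = min(iu.start, id_.start)
        hi = max(iu.end, id_.end)
        return GenomicInterval(iu.chrom, max(0, lo - params.flank), hi + params.flank, "+")
    return None


def random_instance(rng, n_genes=None):
    """A random core gene order (subset, shuffled, possibly 2 chromosomes)."""
    n = int(rng.integers(4, 31)) if n_genes is None else n_genes
    ref_ids = [f"g{i}" for i in range(n)]
    mid = n // 2
    ctx = MirnaContext(
        "intergenic",
        up_anchors=tuple(reversed(ref_ids[max(0, mid - 3) : mid])),
        down_anchors=tuple(ref_ids[mid : mid + 3]),
    )
    keep = [g for g in ref_ids if rng.random() > 0.15]
    rng.shuffle(keep)
    split = len(keep) if rng.random() < 0.5 else int(rng.integers(0, len(keep) + 1))
    genes = []
    for chrom, ids in (("c1", keep[:split]), ("c2", keep[split:])):
        pos = 0
        for gid in ids:
            genes.append(GeneRecord(gid + "p", GenomicInterval(chrom, pos, pos + 10)))
            pos += 15
    core = GeneAnnotation(genes)
    table = OrthologTable({gid: gid + "p" for gid in keep})
    params = SyntenyParams(
        k=int(rng.integers(0, 5)), n=int(rng.integers(0, 3)), flank=int(rng.integers(0, 101))
    )
    # context honours n: trim anchor lists
    ctx = MirnaContext(
        "intergenic",
        up_anchors=ctx.up_anchors[: params.n + 1],
        down_anchors=ctx.down_anchors[: params.n + 1],
    )
    return ctx, core, table, params


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_gene_orders(self, rng):
        for _ in range(250):
            ctx, core, table, params = random_instance(rng)
            assert shared_syntenic_region(ctx, core, table, params) == _oracle_shared_region(
                ctx, core, table, params
            )

    def test_monotone_in_k_and_n(self, rng):
        for _ in range(100):
            ctx, core, table, params = random_instance(rng)
            found = shared_syntenic_region(ctx, core, table, params)
            if found is None:
                continue
            bigger = SyntenyParams(k=params.k + 2, n=params.n, flank=params.flank)
            assert shared_syntenic_region(ctx, core, table, bigger) is not None


class TestCollectPositionalOrtholog:
    def _bundle(self, rng, plant=True, scramble=False):
        gene_len, gap = 60, 80
        order = [f"g{i}" for i in range(6)]
        genes, pos = [], 0
        seq = rng.integers(0, 4, 6 * (gene_len + gap) + gap).astype(np.uint8)
        for gid in order:
            genes.append(GeneRecord(gid, GenomicInterval("c1", pos + gap, pos + gap + gene_len)))
            pos += gene_len + gap
        ann = GeneAnnotation(genes)
        mirna_seq = decode_sequence(rng.integers(0, 4, 62).astype(np.uint8))
        mid = (ann.gene("g2").interval.end + ann.gene("g3").interval.start) // 2 - 31
        from mirortho.genomics_io import encode_sequence

        seq_ref = seq.copy()
        seq_ref[mid : mid + 62] = encode_sequence(mirna_seq)
        ref_genome = GenomeSequence({"c1": seq_ref})
        mirna = MirnaRecord(
            "mir", "fam", GenomicInterval("c1", mid, mid + 62, "+"), mirna_seq
        )
        core_seq = seq_ref.copy() if plant else seq.copy()
        core_genome = GenomeSequence({"c1": core_seq})
        table = OrthologTable({g: g for g in order})
        core = CoreBundle("core", core_genome, ann, table)
        return mirna, ann, ref_genome, core

    def test_planted_ortholog_recovered(self, rng):
        mirna, ann, ref_genome, core = self._bundle(rng, plant=True)
        seq = collect_positional_ortholog(mirna, ann, ref_genome, core)
        assert seq == mirna.sequence

    def test_no_hit_in_syntenic_region(self, rng):
        mirna, ann, ref_genome, core = self._bundle(rng, plant=False)
        assert collect_positional_ortholog(mirna, ann, ref_genome, core) is None
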