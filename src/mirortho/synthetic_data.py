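"""Seeded generator of complete synthetic test fixtures.

The generator emulates the study design of a targeted miRNA ortholog search:
a clade of species with conserved protein-coding gene order, hairpin miRNAs
planted intergenically and intragenically in the root genome, and evolution
along the species tree with per-site substitutions (slower in the mature arm
than in star, loop and flanks), whole-locus losses, tandem duplications,
whole-genome duplications and gene-order inversions.  Ground truth is
recorded at every event, so downstream modules can be scored against it.

Substitutions are Jukes-Cantor-style uniform; indels occur only through
whole-locus events, which keeps truth checking alignment-free and exact.
The same seed always yields a byte-identical fixture set.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genomics_io import (
    GeneAnnotation,
    GeneRecord,
    GenomeSequence,
    GenomicInterval,
    MirnaRecord,
    OrthologTable,
    VariantRecord,
    decode_sequence,
    encode_sequence,
    reverse_complement,
    write_fasta,
    write_gff3,
    write_mirna_table,
    write_ortholog_table,
    write_variants,
)
from .synteny import CoreBundle

__all__ = [
    "SimulationConfig",
    "CladeBundle",
    "generate_hairpin",
    "evolve_clade",
    "emit_variants",
    "write_bundle",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulated evolutionary regime.

    Defaults describe a small vertebrate-like clade: 1% substitutions per
    site per branch, 5% chance per branch that a miRNA locus is deleted, and
    hairpin sub-regions under increasing constraint towards the mature arm
    (multipliers mature <= star <= loop <= flank).
    """

    seed: int = 0
    n_species: int = 20
    tree_shape: str = "balanced"  # "balanced" | "caterpillar" | newick string
    n_genes: int = 3000
    n_families: int = 50
    substitution_rate: float = 0.01  # per site per branch
    loss_probability: float = 0.05  # per miRNA copy per branch
    duplication_probability: float = 0.0  # tandem duplication, per copy/branch
    wgd_branches: tuple[str, ...] = ()
    inversion_rate: float = 0.0  # expected gene-block inversions per branch
    mature_multiplier: float = 0.2
    star_multiplier: float = 0.5
    loop_multiplier: float = 0.8
    flank_multiplier: float = 1.0
    n_chromosomes: int = 2
    gene_length: int = 300
    spacer_length: int = 200
    intragenic_fraction: float = 0.3
    stem_length: int = 25
    loop_length: int = 12
    n_core_species: int = 4
    n_decoys: int = 0
    decoy_divergence: float = 0.08
    gain_nodes: tuple[tuple[str, str], ...] = ()  # (family_id, node label)

    def validate(self) -> None:
        errors = []
        for name in (
            "substitution_rate",
            "loss_probability",
            "duplication_probability",
            "intragenic_fraction",
            "decoy_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must be in [0, 1], got {v}")
        mults = [
            self.mature_multiplier,
            self.star_multiplier,
            self.loop_multiplier,
            self.flank_multiplier,
        ]
        if any(m < 0 for m in mults):
            errors.append("region multipliers must be >= 0")
        if not (
            self.mature_multiplier
            <= self.star_multiplier
            <= self.loop_multiplier
            <= self.flank_multiplier
        ):
            errors.append("multipliers must be ordered mature <= star <= loop <= flank")
        if self.n_species < 2:
            errors.append("n_species must be >= 2")
        if self.n_core_species >= self.n_species:
            errors.append("n_core_species must be < n_species")
        if self.n_genes < 4 * self.n_chromosomes:
            errors.append("n_genes too small for the chromosome count")
        if self.n_families > self.n_genes // 3:
            errors.append("too many miRNA families for the gene count")
        total = 2 * self.stem_length + self.loop_length
        if not 55 <= total <= 70:
            errors.append(f"pre-miRNA length 2*stem+loop = {total} outside 55..70")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str, children: list | None = None):
        self.label = label
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _build_tree(config: SimulationConfig) -> _Node:
    shape = config.tree_shape
    if shape not in ("balanced", "caterpillar"):
        return _parse_newick(shape)
    leaves = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    counter = [0]

    def next_label() -> str:
        counter[0] += 1
        return f"n{counter[0]:02d}"

    if shape == "balanced":

        def build(names: list[str]) -> _Node:
            if len(names) == 1:
                return _Node(names[0])
            node = _Node(next_label())
            half = len(names) // 2
            node.children = [build(names[:half]), build(names[half:])]
            return node

        return build(leaves)
    # caterpillar
    node = _Node(leaves[-1])
    for name in reversed(leaves[:-1]):
        parent = _Node(next_label())
        parent.children = [_Node(name), node]
        node = parent
    return node


def _parse_newick(text: str) -> _Node:
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def conv(dn) -> _Node:
        label = dn.taxon.label if dn.taxon else (dn.label or "")
        return _Node(label, [conv(c) for c in dn.child_nodes()])

    root = conv(tree.seed_node)
    # label unnamed internals deterministically
    counter = [0]

    def fix(n: _Node) -> None:
        if not n.is_leaf and not n.label:
            counter[0] += 1
            n.label = f"n{counter[0]:02d}"
        for c in n.children:
            fix(c)

    fix(root)
    return root


def _to_newick(node: _Node) -> str:
    if node.is_leaf:
        return node.label
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}){node.label}"


def _subtree_labels(node: _Node) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}

    def walk(n: _Node) -> set[str]:
        s = {n.label}
        for c in n.children:
            s |= walk(c)
        out[n.label] = s
        return s

    walk(node)
    return out


def _leaves(node: _Node) -> list[str]:
    if node.is_leaf:
        return [node.label]
    return [l for c in node.children for l in _leaves(c)]


def _path_to(node: _Node, target: str) -> list[str] | None:
    if node.label == target:
        return [node.label]
    for c in node.children:
        sub = _path_to(c, target)
        if sub is not None:
            return [node.label] + sub
    return None


# ---------------------------------------------------------------------------
# hairpin
# ---------------------------------------------------------------------------

_WOBBLE = {2: 3, 3: 2}  # G->T means partner T instead of C; T->G partner


def generate_hairpin(
    stem_length: int, loop_length: int, rng: np.random.Generator
) -> tuple[str, dict[str, tuple[int, int]]]:
    """A pre-miRNA hairpin and its sub-region offsets.

    The 3' arm is the reverse complement of the 5' arm with ~10% GU wobble.
    Sub-regions (relative to the hairpin 5' end): mature = arm positions
    1..22, star = the complementary span at the 3' end, loop = the unpaired
    centre.  Flanks (30 nt each) are taken from the surrounding genome at
    planting time.
    """
    total = 2 * stem_length + loop_length
    if not 55 <= total <= 70:
        raise ValueError(f"pre-miRNA length {total} outside the 55..70 nt range")
    if stem_length < 22:
        raise ValueError("stem must be >= 22 nt to hold a 22-nt mature arm")
    arm5 = rng.integers(0, 4, stem_length).astype(np.uint8)
    loop = rng.integers(0, 4, loop_length).astype(np.uint8)
    arm3 = reverse_complement(arm5).copy()
    # GU wobble: flip ~10% of eligible complementary positions
    for k in range(stem_length):
        partner5 = arm5[stem_length - 1 - k]
        if partner5 in (2, 3) and rng.random() < 0.10:
            arm3[k] = _WOBBLE[int(partner5)]
    seq = np.concatenate([arm5, loop, arm3])
    sub = {
        "mature": (0, 22),
        "loop": (stem_length, stem_length + loop_length),
        "star": (total - 22, total),
    }
    return decode_sequence(seq), sub


# ---------------------------------------------------------------------------
# genome state and events
# ---------------------------------------------------------------------------


@dataclass
class _Locus:
    mirna_id: str
    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    copy: int


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class _State:
    chroms: dict[str, np.ndarray]
    genes: list[_Gene]
    loci: list[_Locus]
    decoys: list[tuple[str, str, int, int]]  # family, chrom, start, end
    next_copy: dict[str, int]


def _copy_state(state: _State) -> _State:
    return _State(
        chroms={k: v.copy() for k, v in state.chroms.items()},
        genes=[replace(g) for g in state.genes],
        loci=[replace(l) for l in state.loci],
        decoys=list(state.decoys),
        next_copy=dict(state.next_copy),
    )


def _shift_features(state: _State, chrom: str, pos: int, delta: int) -> None:
    """Shift coordinates after an insertion (delta > 0 at pos) or deletion
    (delta < 0 of segment [pos, pos - delta))."""
    for coll in (state.genes, state.loci):
        for f in coll:
            if f.chrom != chrom:
                continue
            if f.start >= pos:
                f.start += delta
                f.end += delta
            elif f.end > pos:
                f.end += delta
    shifted = []
    for fam, c, s, e in state.decoys:
        if c == chrom and s >= pos:
            s, e = s + delta, e + delta
        elif c == chrom and e > pos:
            e += delta
        shifted.append((fam, c, s, e))
    state.decoys = shifted


def _delete_segment(state: _State, chrom: str, s: int, e: int) -> None:
    arr = state.chroms[chrom]
    state.chroms[chrom] = np.concatenate([arr[:s], arr[e:]])
    _shift_features(state, chrom, s, -(e - s))


def _insert_segment(state: _State, chrom: str, pos: int, segment: np.ndarray) -> None:
    arr = state.chroms[chrom]
    state.chroms[chrom] = np.concatenate([arr[:pos], segment, arr[pos:]])
    _shift_features(state, chrom, pos, len(segment))


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _invert_block(state: _State, chrom: str, s: int, e: int) -> None:
    arr = state.chroms[chrom]
    arr[s:e] = reverse_complement(arr[s:e])
    for coll in (state.genes, state.loci):
        for f in coll:
            if f.chrom == chrom and f.start >= s and f.end <= e:
                f.start, f.end = s + (e - f.end), s + (e - f.start)
                f.strand = _flip(f.strand)
    state.decoys = [
        (fam, c, s + (e - de), s + (e - ds)) if c == chrom and ds >= s and de <= e else (fam, c, ds, de)
        for fam, c, ds, de in state.decoys
    ]


# ---------------------------------------------------------------------------
# root genome
# ---------------------------------------------------------------------------


def _build_root(config: SimulationConfig, rng: np.random.Generator) -> _State:
    genes_per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if c < config.n_genes % config.n_chromosomes else 0)
        for c in range(config.n_chromosomes)
    ]
    chroms: dict[str, np.ndarray] = {}
    genes: list[_Gene] = []
    spacers: list[tuple[str, int, int]] = []  # chrom, spacer index, spacer start
    gid = 0
    for c, n_genes in enumerate(genes_per_chrom):
        name = f"chr{c + 1}"
        length = (n_genes + 1) * config.spacer_length + n_genes * config.gene_length
        chroms[name] = rng.integers(0, 4, length).astype(np.uint8)
        pos = config.spacer_length
        for k in range(n_genes):
            gid += 1
            genes.append(
                _Gene(
                    gene_id=f"g{gid:05d}",
                    chrom=name,
                    start=pos,
                    end=pos + config.gene_length,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            if 1 <= k:  # spacer between gene k-1 and gene k (interior only)
                spacers.append((name, k, pos - config.spacer_length))
            pos += config.gene_length + config.spacer_length
    # plant miRNAs
    loci: list[_Locus] = []
    pre_len = 2 * config.stem_length + config.loop_length
    rng.shuffle(spacers)
    spacer_iter = iter(spacers)
    gene_pool = [g for g in genes if g.end - g.start >= pre_len + 60]
    rng.shuffle(gene_pool)
    gene_iter = iter(gene_pool)
    hairpins: dict[str, tuple[str, dict[str, tuple[int, int]]]] = {}
    for f in range(config.n_families):
        fam = f"fam{f + 1:02d}"
        mid = f"mir{f + 1:02d}"
        seq, sub = generate_hairpin(config.stem_length, config.loop_length, rng)
        hairpins[fam] = (seq, sub)
        intragenic = rng.random() < config.intragenic_fraction
        if intragenic:
            g = next(gene_iter)
            offset = int(
                rng.integers(30, g.end - g.start - pre_len - 30)
            )
            start = g.start + offset
            chrom = g.chrom
        else:
            chrom, _k, sp_start = next(spacer_iter)
            start = sp_start + (config.spacer_length - pre_len) // 2
        codes = encode_sequence(seq)
        state_arr = chroms[chrom]
        state_arr[start : start + pre_len] = codes
        loci.append(
            _Locus(
                mirna_id=mid,
                family_id=fam,
                chrom=chrom,
                start=start,
                end=start + pre_len,
                strand="+",
                copy=1,
            )
        )
    # plant decoys (diverged pseudogene copies, present in every species)
    decoys: list[tuple[str, str, int, int]] = []
    for f in range(min(config.n_decoys, config.n_families)):
        fam = f"fam{f + 1:02d}"
        seq, _sub = hairpins[fam]
        codes = encode_sequence(seq).copy()
        n_sub = max(1, int(round(config.decoy_divergence * len(codes))))
        # evenly spaced substitutions keep seed words intact, so similarity
        # searches (incl. the naive baseline) can still find the decoy
        pos_sub = np.array(
            [int((k + 0.5) * len(codes) / n_sub) for k in range(n_sub)], dtype=np.int64
        )
        codes[pos_sub] = (codes[pos_sub] + rng.integers(1, 4, n_sub).astype(np.uint8)) % 4
        chrom, _k, sp_start = next(spacer_iter)
        start = sp_start + (config.spacer_length - pre_len) // 2
        chroms[chrom][start : start + pre_len] = codes
        decoys.append((fam, chrom, start, start + pre_len))
    return _State(
        chroms=chroms,
        genes=genes,
        loci=loci,
        decoys=decoys,
        next_copy={l.mirna_id: 2 for l in loci},
    )


# ---------------------------------------------------------------------------
# branch evolution
# ---------------------------------------------------------------------------


def _sub_multipliers(config: SimulationConfig, state: _State, chrom: str) -> np.ndarray:
    mult = np.ones(len(state.chroms[chrom]), dtype=np.float32)
    pre_regions = {
        "mature": config.mature_multiplier,
        "star": config.star_multiplier,
        "loop": config.loop_multiplier,
    }
    stem, loop = None, None
    for l in state.loci:
        if l.chrom != chrom:
            continue
        length = l.end - l.start
        sub = _relative_subregions(config, length)
        # everything inside the hairpin defaults to the loop multiplier
        mult[l.start : l.end] = config.loop_multiplier
        for name, (lo, hi) in sub.items():
            g_lo, g_hi = _to_genomic(l, lo, hi)
            mult[g_lo:g_hi] = pre_regions[name]
        f_lo = max(0, l.start - 30)
        f_hi = min(len(mult), l.end + 30)
        mult[f_lo : l.start] = config.flank_multiplier
        mult[l.end : f_hi] = config.flank_multiplier
    return mult


def _relative_subregions(config: SimulationConfig, length: int) -> dict[str, tuple[int, int]]:
    stem, loop = config.stem_length, config.loop_length
    return {
        "mature": (0, 22),
        "loop": (stem, stem + loop),
        "star": (length - 22, length),
    }


def _to_genomic(locus: _Locus, lo: int, hi: int) -> tuple[int, int]:
    if locus.strand == "+":
        return locus.start + lo, locus.start + hi
    return locus.end - hi, locus.end - lo


def _apply_branch(
    state: _State,
    config: SimulationConfig,
    child: _Node,
    rng: np.random.Generator,
    carried: set[str],
    lost_rows: list[dict],
    reference_safe: bool,
) -> None:
    """Mutate ``state`` in place along the branch leading into ``child``."""
    # 1. families not carried into this subtree are removed silently
    for l in [l for l in state.loci if l.family_id not in carried]:
        _delete_segment(state, l.chrom, l.start, l.end)
        state.loci.remove(l)
    # 2. whole-genome duplication
    if child.label in config.wgd_branches:
        for name in list(state.chroms):
            new_name = f"{name}w{child.label}"
            state.chroms[new_name] = state.chroms[name].copy()
            for g in [g for g in state.genes if g.chrom == name]:
                state.genes.append(
                    _Gene(f"{g.gene_id}_w", new_name, g.start, g.end, g.strand)
                )
            for l in [l for l in state.loci if l.chrom == name]:
                nc = state.next_copy[l.mirna_id]
                state.next_copy[l.mirna_id] = nc + 1
                state.loci.append(
                    _Locus(l.mirna_id, l.family_id, new_name, l.start, l.end, l.strand, nc)
                )
            state.decoys.extend(
                [(fam, new_name, s, e) for fam, c, s, e in state.decoys if c == name]
            )
    # 3. gene-block inversions
    if config.inversion_rate > 0:
        n_inv = rng.poisson(config.inversion_rate)
        for _ in range(n_inv):
            chrom = str(rng.choice(sorted(state.chroms)))
            chrom_genes = sorted(
                [g for g in state.genes if g.chrom == chrom], key=lambda g: g.start
            )
            if len(chrom_genes) < 6:
                continue
            size = int(rng.integers(2, 6))
            i0 = int(rng.integers(0, len(chrom_genes) - size))
            s = chrom_genes[i0].start
            e = chrom_genes[i0 + size - 1].end
            # skip if a miRNA locus straddles the block boundary
            if any(
                l.chrom == chrom and (l.start < s <= l.end or l.start < e <= l.end)
                for l in state.loci
            ):
                continue
            _invert_block(state, chrom, s, e)
    # 4. losses (skipped on the reference lineage so the reference keeps its
    # full miRNA complement, as a curated reference annotation would)
    if config.loss_probability > 0 and not reference_safe:
        for l in list(state.loci):
            if rng.random() < config.loss_probability:
                _delete_segment(state, l.chrom, l.start, l.end)
                state.loci.remove(l)
                lost_rows.append(
                    {
                        "branch": child.label,
                        "family_id": l.family_id,
                        "mirna_id": l.mirna_id,
                        "copy": l.copy,
                    }
                )
    # 5. tandem duplications
    if config.duplication_probability > 0:
        for l in list(state.loci):
            if rng.random() < config.duplication_probability:
                segment = state.chroms[l.chrom][l.start : l.end].copy()
                _insert_segment(state, l.chrom, l.end, segment)
                nc = state.next_copy[l.mirna_id]
                state.next_copy[l.mirna_id] = nc + 1
                state.loci.append(
                    _Locus(
                        l.mirna_id,
                        l.family_id,
                        l.chrom,
                        l.end,
                        l.end + len(segment),
                        l.strand,
                        nc,
                    )
                )
    # 6. substitutions
    if config.substitution_rate > 0:
        for chrom in sorted(state.chroms):
            arr = state.chroms[chrom]
            mult = _sub_multipliers(config, state, chrom)
            hit = np.flatnonzero(
                rng.random(len(arr)) < config.substitution_rate * mult
            )
            if hit.size:
                arr[hit] = (arr[hit] + rng.integers(1, 4, hit.size).astype(np.uint8)) % 4


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------


@dataclass
class CladeBundle:
    """Everything a downstream analysis needs, in memory."""

    config: SimulationConfig
    tree_newick: str
    species: list[str]
    reference_species: str
    core_species: list[str]
    genomes: dict[str, GenomeSequence]
    annotations: dict[str, GeneAnnotation]
    ortholog_tables: dict[str, OrthologTable]
    mirnas: list[MirnaRecord]
    truth: pd.DataFrame
    losses: pd.DataFrame
    decoys: pd.DataFrame
    gain_node_of: dict[str, str]

    @property
    def target_species(self) -> list[str]:
        return list(self.species)

    @property
    def families(self) -> list[str]:
        return sorted({m.family_id for m in self.mirnas})

    def core_bundle(self, species: str) -> CoreBundle:
        return CoreBundle(
            species=species,
            genome=self.genomes[species],
            annotation=self.annotations[species],
            orthologs=self.ortholog_tables[species],
        )

    def gold_table(self) -> pd.DataFrame:
        """Truth loci in the benchmark gold-standard layout."""
        return self.truth.rename(columns={"species": "species"})[
            ["species", "family_id", "mirna_id", "chrom", "start", "end", "strand"]
        ].copy()


def _mirna_record(config: SimulationConfig, locus: _Locus, genome: GenomeSequence) -> MirnaRecord:
    iv = GenomicInterval(locus.chrom, locus.start, locus.end, locus.strand)
    seq_codes = genome.codes(locus.chrom)[locus.start : locus.end]
    if locus.strand == "-":
        seq_codes = reverse_complement(seq_codes)
    sub = _relative_subregions(config, locus.end - locus.start)
    ivs = {}
    for name, (lo, hi) in sub.items():
        g_lo, g_hi = _to_genomic(locus, lo, hi)
        ivs[name] = GenomicInterval(locus.chrom, g_lo, g_hi, locus.strand)
    n = genome.length(locus.chrom)
    if locus.strand == "+":
        f5 = (max(0, locus.start - 30), locus.start)
        f3 = (locus.end, min(n, locus.end + 30))
    else:
        f5 = (locus.end, min(n, locus.end + 30))
        f3 = (max(0, locus.start - 30), locus.start)
    mirna_id = locus.mirna_id if locus.copy == 1 else f"{locus.mirna_id}.{locus.copy}"
    return MirnaRecord(
        mirna_id=mirna_id,
        family_id=locus.family_id,
        interval=iv,
        sequence=decode_sequence(seq_codes),
        mature=ivs["mature"],
        star=ivs["star"],
        loop=ivs["loop"],
        flank5=GenomicInterval(locus.chrom, f5[0], f5[1], locus.strand)
        if f5[1] > f5[0]
        else None,
        flank3=GenomicInterval(locus.chrom, f3[0], f3[1], locus.strand)
        if f3[1] > f3[0]
        else None,
    )


def evolve_clade(config: SimulationConfig) -> CladeBundle:
    """Simulate the clade and return all fixtures plus the truth table."""
    config.validate()
    tree = _build_tree(config)
    leaves = _leaves(tree)
    subtree = _subtree_labels(tree)
    reference = leaves[0]
    cores = leaves[1 : 1 + config.n_core_species]
    ref_path = set(_path_to(tree, reference) or [])
    gain_of = {f"fam{k + 1:02d}": tree.label for k in range(config.n_families)}
    for fam, node in config.gain_nodes:
        if node not in subtree:
            raise ValueError(f"gain node {node!r} not in the tree")
        if reference not in subtree[node] and node != reference:
            raise ValueError(
                f"gain node {node!r} for {fam} is not ancestral to the reference"
            )
        gain_of[fam] = node

    rng_root = np.random.default_rng([config.seed, 0])
    root_state = _build_root(config, rng_root)

    states: dict[str, _State] = {}
    lost_rows: list[dict] = []
    branch_counter = [0]

    def carried_into(child: _Node) -> set[str]:
        out = set()
        for fam, g in gain_of.items():
            if g in subtree[child.label] or child.label in subtree[g]:
                out.add(fam)
        return out

    def recurse(node: _Node, state: _State) -> None:
        if node.is_leaf:
            states[node.label] = state
            return
        for child in node.children:
            branch_counter[0] += 1
            rng = np.random.default_rng([config.seed, branch_counter[0]])
            child_state = _copy_state(state)
            _apply_branch(
                child_state,
                config,
                child,
                rng,
                carried_into(child),
                lost_rows,
                reference_safe=child.label in ref_path,
            )
            recurse(child, child_state)

    recurse(tree, root_state)

    genomes = {
        sp: GenomeSequence(
            {name: arr for name, arr in states[sp].chroms.items()}, label=sp
        )
        for sp in leaves
    }
    annotations = {
        sp: GeneAnnotation(
            GeneRecord(
                g.gene_id, GenomicInterval(g.chrom, g.start, g.end, g.strand)
            )
            for g in states[sp].genes
        )
        for sp in leaves
    }
    ref_gene_ids = {g.gene_id for g in states[reference].genes}
    ortholog_tables = {
        sp: OrthologTable(
            {
                g.gene_id: g.gene_id
                for g in states[sp].genes
                if g.gene_id in ref_gene_ids
            }
        )
        for sp in cores
    }
    mirnas = [
        _mirna_record(config, l, genomes[reference])
        for l in sorted(states[reference].loci, key=lambda l: (l.mirna_id, l.copy))
    ]
    # truth table and seed-identity flags relative to the reference hairpins
    ref_seq_of = {}
    for l in states[reference].loci:
        if l.copy == 1:
            codes = genomes[reference].codes(l.chrom)[l.start : l.end]
            if l.strand == "-":
                codes = reverse_complement(codes)
            ref_seq_of[l.family_id] = decode_sequence(codes)
    truth_rows = []
    for sp in leaves:
        genome = genomes[sp]
        for l in sorted(states[sp].loci, key=lambda l: (l.mirna_id, l.copy)):
            codes = genome.codes(l.chrom)[l.start : l.end]
            if l.strand == "-":
                codes = reverse_complement(codes)
            seq = decode_sequence(codes)
            ref_seq = ref_seq_of.get(l.family_id)
            if ref_seq is not None and len(ref_seq) == len(seq):
                seed_ok = seq[1:8] == ref_seq[1:8]  # mature positions 2..8
            else:
                seed_ok = False
            truth_rows.append(
                {
                    "species": sp,
                    "mirna_id": l.mirna_id,
                    "family_id": l.family_id,
                    "copy": l.copy,
                    "chrom": l.chrom,
                    "start": l.start,
                    "end": l.end,
                    "strand": l.strand,
                    "sequence": seq,
                    "seed_identical": seed_ok,
                    "gain_node": gain_of[l.family_id],
                }
            )
    decoy_rows = []
    for sp in leaves:
        for fam, chrom, s, e in states[sp].decoys:
            decoy_rows.append(
                {"species": sp, "family_id": fam, "chrom": chrom, "start": s, "end": e}
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "species",
            "mirna_id",
            "family_id",
            "copy",
            "chrom",
            "start",
            "end",
            "strand",
            "sequence",
            "seed_identical",
            "gain_node",
        ],
    )
    return CladeBundle(
        config=config,
        tree_newick=_to_newick(tree) + ";",
        species=leaves,
        reference_species=reference,
        core_species=cores,
        genomes=genomes,
        annotations=annotations,
        ortholog_tables=ortholog_tables,
        mirnas=mirnas,
        truth=truth,
        losses=pd.DataFrame(lost_rows, columns=["branch", "family_id", "mirna_id", "copy"]),
        decoys=pd.DataFrame(decoy_rows, columns=["species", "family_id", "chrom", "start", "end"]),
        gain_node_of=gain_of,
    )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_MAF_REPRESENTATIVES = (5e-05, 0.005, 0.1)  # rare, uncommon, common


def emit_variants(
    classes: Mapping[str, "RegionClass"],
    densities_per_kb: Mapping[str, float],
    maf_weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
) -> tuple[list[VariantRecord], dict[str, float]]:
    """Deterministically place variants in each region class.

    Counts are ``round(density * length / 1000)`` per class, positions evenly
    spaced through the class's concatenated intervals, and MAF values drawn
    from the three bins with largest-remainder rounding of ``maf_weights`` —
    so the configured densities and bin fractions are recovered exactly.
    """
    variants: list[VariantRecord] = []
    expected: dict[str, float] = {}
    for label in sorted(classes):
        region = classes[label]
        total = region.total_length
        n = int(round(densities_per_kb.get(label, 0.0) * total / 1000.0))
        expected[label] = n / total * 1000.0
        if n == 0:
            continue
        # largest-remainder apportionment of the MAF bins
        quotas = [w * n for w in maf_weights]
        counts = [int(q) for q in quotas]
        rem = n - sum(counts)
        order = sorted(range(3), key=lambda k: -(quotas[k] - counts[k]))
        for k in order[:rem]:
            counts[k] += 1
        mafs = [
            _MAF_REPRESENTATIVES[k] for k in range(3) for _ in range(counts[k])
        ]
        # evenly spaced positions over the concatenated class
        offsets = [int((i + 0.5) * total / n) for i in range(n)]
        ivs = sorted(region.intervals, key=lambda iv: (iv.chrom, iv.start))
        bounds = []
        acc = 0
        for iv in ivs:
            bounds.append((acc, acc + len(iv), iv))
            acc += len(iv)
        for off, maf in zip(offsets, mafs):
            for lo, hi, iv in bounds:
                if lo <= off < hi:
                    pos = iv.start + (off - lo)
                    variants.append(
                        VariantRecord(
                            GenomicInterval(iv.chrom, pos, pos + 1, "+"), maf
                        )
                    )
                    break
    return variants, expected


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_bundle(bundle: CladeBundle, outdir: str | Path) -> None:
    """Write the full fixture set in the formats the readers consume."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "annotations").mkdir(exist_ok=True)
    (outdir / "orthologs").mkdir(exist_ok=True)
    (outdir / "tree.nwk").write_text(bundle.tree_newick + "\n")
    (outdir / "reference.txt").write_text(bundle.reference_species + "\n")
    (outdir / "core_species.txt").write_text("\n".join(bundle.core_species) + "\n")
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(bundle.config).items()
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    for sp in bundle.species:
        write_fasta(bundle.genomes[sp], outdir / "genomes" / f"{sp}.fa")
        write_gff3(bundle.annotations[sp], outdir / "annotations" / f"{sp}.gff3")
    for sp, table in bundle.ortholog_tables.items():
        write_ortholog_table(table, outdir / "orthologs" / f"{sp}.tsv")
    write_mirna_table(bundle.mirnas, outdir / "mirnas.tsv")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    bundle.losses.to_csv(outdir / "losses.tsv", sep="\t", index=False)
    bundle.decoys.to_csv(outdir / "decoys.tsv", sep="\t", index=False)
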