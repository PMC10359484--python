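"""Phylogenetic profiles, family dating, co-ortholog spectra and the
phylogenomic supermatrix.

A profile matrix holds, per miRNA (or family) and species, the co-ortholog
count (0 = absent) and a seed-conservation status.  Family origins are dated
to the last common ancestor of all carrier species together with the
reference; missing data is the fraction of absent cells among species that
diversified after a family's origin.  The supermatrix concatenates one
ortholog per species per miRNA and removes alignment columns with more than
50% gaps; maximum-likelihood tree inference itself is delegated to external
software via the emitted FASTA/relaxed-PHYLIP/partition files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .model_training import global_align, _star_merge
from .ortholog_search import OrthologPrediction

__all__ = [
    "ProfileMatrix",
    "TaxonomyTree",
    "build_profiles",
    "collapse_to_family",
    "date_family_origin",
    "missing_data_fraction",
    "co_ortholog_spectrum",
    "build_supermatrix",
    "write_supermatrix",
]


class TaxonomyTree:
    """Rooted species tree with labelled internal nodes (thin dendropy wrap)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        self.leaf_labels = labels

    @classmethod
    def from_newick(cls, newick: str | Path) -> "TaxonomyTree":
        text = Path(newick).read_text() if str(newick).endswith(".nwk") else str(newick)
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        return cls(tree)

    @staticmethod
    def node_label(node: dendropy.Node) -> str:
        return node.taxon.label if node.taxon is not None else (node.label or "")

    def mrca(self, labels: Sequence[str]) -> dendropy.Node:
        labels = list(dict.fromkeys(labels))
        unknown = set(labels) - set(self.leaf_labels)
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        if len(labels) == 1:
            return self._find_leaf(labels[0])
        return self._tree.mrca(taxa=[self._taxon(l) for l in labels])

    def _taxon(self, label: str):
        for t in self._tree.taxon_namespace:
            if t.label == label:
                return t
        raise KeyError(label)

    def _find_leaf(self, label: str) -> dendropy.Node:
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(label)

    def leaves_under(self, node: dendropy.Node) -> list[str]:
        return [l.taxon.label for l in node.leaf_iter()]

    def leaves_under_label(self, label: str) -> list[str]:
        for node in self._tree.preorder_node_iter():
            if self.node_label(node) == label:
                return self.leaves_under(node)
        raise KeyError(f"no node labelled {label!r}")


@dataclass
class ProfileMatrix:
    """counts: rows x species co-ortholog counts; seed: seed status strings
    ('identical', 'changed', 'unknown'; empty for absent cells)."""

    counts: pd.DataFrame
    seed: pd.DataFrame
    level: str = "gene"  # "gene" | "family"

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for rid in self.counts.index:
            for sp in self.counts.columns:
                rows.append(
                    {
                        "id": rid,
                        "species": sp,
                        "count": int(self.counts.loc[rid, sp]),
                        "seed": self.seed.loc[rid, sp],
                    }
                )
        return pd.DataFrame(rows)

    def to_phyloprofile(self, family_of: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Long-format table compatible with phylogenetic-profile viewers:
        geneID, ncbiID (species), orthoID per co-ortholog."""
        rows = []
        for rid in self.counts.index:
            for sp in self.counts.columns:
                n = int(self.counts.loc[rid, sp])
                for k in range(n):
                    rows.append(
                        {"geneID": rid, "ncbiID": sp, "orthoID": f"{rid}|{sp}|{k + 1}"}
                    )
        return pd.DataFrame(rows, columns=["geneID", "ncbiID", "orthoID"])


def _seed_status(flags: list[bool | None]) -> str:
    if any(f is True for f in flags):
        return "identical"
    if any(f is False for f in flags):
        return "changed"
    return "unknown"


def build_profiles(
    predictions: Sequence[OrthologPrediction],
    mirna_ids: Sequence[str],
    species: Sequence[str],
) -> ProfileMatrix:
    """Gene-level profile: co-ortholog counts per miRNA x species.  Rows for
    miRNAs never found anywhere are preserved as zero rows."""
    counts = pd.DataFrame(0, index=list(mirna_ids), columns=list(species), dtype=int)
    seed = pd.DataFrame("", index=list(mirna_ids), columns=list(species), dtype=object)
    flags: dict[tuple[str, str], list[bool | None]] = {}
    for p in predictions:
        if p.mirna_id not in counts.index or p.target_species not in counts.columns:
            continue
        counts.loc[p.mirna_id, p.target_species] += 1
        flags.setdefault((p.mirna_id, p.target_species), []).append(p.seed_identical)
    for (rid, sp), fl in flags.items():
        seed.loc[rid, sp] = _seed_status(fl)
    return ProfileMatrix(counts=counts, seed=seed, level="gene")


def collapse_to_family(
    matrix: ProfileMatrix, family_of: Mapping[str, str]
) -> ProfileMatrix:
    """Family-level profile: counts summed over members; seed 'identical' if
    any member is identical."""
    fams = list(dict.fromkeys(family_of[g] for g in matrix.counts.index))
    counts = pd.DataFrame(0, index=fams, columns=matrix.counts.columns, dtype=int)
    seed = pd.DataFrame("", index=fams, columns=matrix.counts.columns, dtype=object)
    for fam in fams:
        members = [g for g in matrix.counts.index if family_of[g] == fam]
        counts.loc[fam] = matrix.counts.loc[members].sum(axis=0)
        for sp in matrix.counts.columns:
            statuses = [matrix.seed.loc[g, sp] for g in members if matrix.counts.loc[g, sp] > 0]
            if statuses:
                if "identical" in statuses:
                    seed.loc[fam, sp] = "identical"
                elif "changed" in statuses:
                    seed.loc[fam, sp] = "changed"
                else:
                    seed.loc[fam, sp] = "unknown"
    return ProfileMatrix(counts=counts, seed=seed, level="family")


def date_family_origin(
    carrier_species: Sequence[str],
    tree: TaxonomyTree,
    reference_species: str,
) -> str:
    """Label of the last common ancestor of the reference and every carrier
    species (the family's minimal evolutionary age)."""
    carriers = [s for s in carrier_species]
    if not carriers and not reference_species:
        raise ValueError("family present in no species")
    labels = list(dict.fromkeys([reference_species] + carriers))
    if len(labels) == 1:
        return labels[0]
    node = tree.mrca(labels)
    return TaxonomyTree.node_label(node)


def missing_data_fraction(
    matrix: ProfileMatrix,
    tree: TaxonomyTree,
    origins: Mapping[str, str],
) -> float:
    """Fraction of zero cells among cells whose species diversified after the
    family's origin (species outside the origin clade are never counted)."""
    numer = denom = 0
    for rid in matrix.counts.index:
        origin = origins[rid]
        if origin in tree.leaf_labels:
            eligible = [origin]
        else:
            eligible = tree.leaves_under_label(origin)
        for sp in eligible:
            if sp not in matrix.counts.columns:
                continue
            denom += 1
            if matrix.counts.loc[rid, sp] == 0:
                numer += 1
    return numer / denom if denom else 0.0


def co_ortholog_spectrum(matrix: ProfileMatrix, species: str) -> np.ndarray:
    """Among miRNAs present in the species, the fractions represented by
    1, 2, 3 and >= 4 co-orthologs."""
    if species not in matrix.counts.columns:
        raise ValueError(f"species {species!r} absent from matrix")
    counts = matrix.counts[species].to_numpy()
    counts = counts[counts >= 1]
    if counts.size == 0:
        return np.zeros(4)
    bins = np.array(
        [
            np.sum(counts == 1),
            np.sum(counts == 2),
            np.sum(counts == 3),
            np.sum(counts >= 4),
        ],
        dtype=float,
    )
    return bins / counts.size


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------


def build_supermatrix(
    sequences: Mapping[str, Mapping[str, str]],
    species: Sequence[str],
    reference_species: str | None = None,
    min_representation: float = 0.2,
    max_gap_fraction: float = 0.5,
) -> tuple[dict[str, str], list[tuple[str, int, int]], list[str]]:
    """Concatenated MSA over per-miRNA ortholog sets.

    ``sequences[mirna_id][species]`` is the rank-1 ortholog sequence.
    Species represented in fewer than ``min_representation`` of the miRNAs
    are dropped (strict <); species missing an individual miRNA get all-gap
    rows; columns with gap fraction strictly above ``max_gap_fraction`` are
    removed.  Returns (alignment rows by species, partitions as
    (mirna_id, start, end) over surviving columns, retained species).
    """
    mirna_ids = sorted(sequences)
    if not mirna_ids:
        raise ValueError("no miRNA ortholog sets supplied")
    rep = {
        sp: sum(1 for m in mirna_ids if sp in sequences[m] and sequences[m][sp])
        for sp in species
    }
    retained = [sp for sp in species if rep[sp] / len(mirna_ids) >= min_representation]
    if len(retained) < 2:
        raise ValueError("fewer than 2 species after the representation filter")
    concat = {sp: [] for sp in retained}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for mid in mirna_ids:
        present = [sp for sp in retained if sequences[mid].get(sp)]
        if not present:
            continue
        if reference_species in present:
            center = reference_species
        else:
            center = present[0]
        center_seq = sequences[mid][center]
        others = [sp for sp in present if sp != center]
        aligned = [global_align(center_seq, sequences[mid][sp]) for sp in others]
        rows = _star_merge(center_seq, aligned)
        width = len(rows[0])
        msa = {center: rows[0]}
        for sp, row in zip(others, rows[1:]):
            msa[sp] = row
        # drop high-gap columns within this partition
        block = [msa.get(sp, "-" * width) for sp in retained]
        n_rows = len(block)
        keep_cols = [
            j
            for j in range(width)
            if sum(1 for r in block if r[j] == "-") / n_rows <= max_gap_fraction
        ]
        if not keep_cols:
            continue
        for sp, row in zip(retained, block):
            concat[sp].append("".join(row[j] for j in keep_cols))
        partitions.append((mid, offset, offset + len(keep_cols)))
        offset += len(keep_cols)
    return {sp: "".join(parts) for sp, parts in concat.items()}, partitions, retained


def write_supermatrix(
    alignment: Mapping[str, str],
    partitions: Sequence[tuple[str, int, int]],
    prefix: str | Path,
) -> None:
    """Write FASTA, relaxed PHYLIP and a partition table under a path prefix."""
    prefix = Path(prefix)
    species = list(alignment)
    width = len(next(iter(alignment.values()))) if alignment else 0
    with open(prefix.with_suffix(".fasta"), "w") as fh:
        for sp in species:
            fh.write(f">{sp}\n{alignment[sp]}\n")
    with open(prefix.with_suffix(".phy"), "w") as fh:
        fh.write(f"{len(species)} {width}\n")
        pad = max(len(s) for s in species) + 2
        for sp in species:
            fh.write(f"{sp.ljust(pad)}{alignment[sp]}\n")
    with open(prefix.with_suffix(".partitions.tsv"), "w") as fh:
        fh.write("partition\tstart\tend\n")
        for mid, start, end in partitions:
            fh.write(f"{mid}\t{start}\t{end}\n")
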