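"""Readers/writers for on-disk formats and the shared coordinate model.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
Conversion to/from 1-based inclusive coordinates happens only at the GFF3
boundary; BED output is natively 0-based half-open.  Sequences are stored
internally as ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4) so that the
alignment kernels can work on them directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "GeneRecord",
    "GeneAnnotation",
    "MirnaRecord",
    "OrthologTable",
    "VariantRecord",
    "FormatError",
    "reverse_complement",
    "encode_sequence",
    "decode_sequence",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_mirna_table",
    "write_mirna_table",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_variants",
    "write_variants",
    "read_bed",
    "write_bed",
    "interval_overlap",
    "extract_sequence",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# sequence encoding
# ---------------------------------------------------------------------------

_ALPHABET = "ACGTN"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord("U")] = 3  # RNA input is accepted and normalised to DNA
_CODE[ord("u")] = 3
# IUPAC ambiguity codes are accepted on input and collapsed to N
for _c in "RYSWKMBDHVryswkmbdhv":
    _CODE[ord(_c)] = 4

_DECODE = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)
# complement in code space: A<->T, C<->G, N->N
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array (A=0..N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise FormatError(f"illegal nucleotide character {bad!r}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def reverse_complement(seq: str | np.ndarray) -> str | np.ndarray:
    """Reverse complement of a string or code array (same type returned)."""
    if isinstance(seq, str):
        return decode_sequence(_COMPLEMENT[encode_sequence(seq)][::-1])
    return _COMPLEMENT[seq][::-1]


# ---------------------------------------------------------------------------
# core domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length in nt; 0 for different chromosomes.  Strand is ignored:
    the benchmark's true-positive criterion is purely positional."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class GenomeSequence:
    """Per-chromosome nucleotide sequences of one assembly."""

    def __init__(self, chroms: Mapping[str, str | np.ndarray], label: str = ""):
        self.label = label
        self._chroms: dict[str, np.ndarray] = {}
        for name, seq in chroms.items():
            codes = encode_sequence(seq) if isinstance(seq, str) else np.asarray(
                seq, dtype=np.uint8
            )
            self._chroms[name] = codes
        # per-(word size) seed index caches used by alignment_search
        self._word_index: dict = {}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def codes(self, chrom: str) -> np.ndarray:
        return self._chroms[chrom]

    def sequence(self, chrom: str) -> str:
        return decode_sequence(self._chroms[chrom])

    def invalidate_caches(self) -> None:
        self._word_index.clear()


def extract_sequence(genome: GenomeSequence, iv: GenomicInterval) -> str:
    """Sequence of an interval; minus strand returns the reverse complement."""
    if iv.chrom not in genome:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome {genome.label!r}")
    n = genome.length(iv.chrom)
    if iv.end > n:
        raise IndexError(
            f"interval [{iv.start}, {iv.end}) exceeds {iv.chrom} length {n}"
        )
    codes = genome.codes(iv.chrom)[iv.start : iv.end]
    if iv.strand == "-":
        codes = _COMPLEMENT[codes][::-1]
    return decode_sequence(codes)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"


class GeneAnnotation:
    """Protein-coding gene records, retrievable sorted by start per chromosome."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        self._by_id: dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in self._by_id:
                raise FormatError(f"duplicate gene id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
            self._by_chrom.setdefault(g.interval.chrom, []).append(g)
        for recs in self._by_chrom.values():
            recs.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def chrom_names(self) -> list[str]:
        return list(self._by_chrom)

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        return list(self._by_chrom.get(chrom, []))

    def all_genes(self) -> list[GeneRecord]:
        return [g for c in self._by_chrom.values() for g in c]


@dataclass(frozen=True)
class MirnaRecord:
    """A reference pre-miRNA with its hairpin sub-annotations.

    Sub-intervals (mature, star, loop) are nested in the pre-miRNA interval;
    the two 30-nt flanks are adjacent to it.  ``mature`` and ``star`` must not
    overlap.
    """

    mirna_id: str
    family_id: str
    interval: GenomicInterval
    sequence: str
    mature: GenomicInterval | None = None
    star: GenomicInterval | None = None
    loop: GenomicInterval | None = None
    flank5: GenomicInterval | None = None
    flank3: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"{self.mirna_id}: sequence length {len(self.sequence)} != "
                f"interval length {len(self.interval)}"
            )
        for name in ("mature", "star", "loop"):
            sub = getattr(self, name)
            if sub is not None and not (
                sub.chrom == self.interval.chrom
                and self.interval.start <= sub.start
                and sub.end <= self.interval.end
            ):
                raise ValueError(f"{self.mirna_id}: {name} not nested in pre-miRNA")
        if self.mature is not None and self.star is not None:
            if interval_overlap(self.mature, self.star) > 0:
                raise ValueError(f"{self.mirna_id}: mature and star overlap")

    def subregion_sequence(self, genome: GenomeSequence, name: str) -> str | None:
        sub = getattr(self, name)
        return None if sub is None else extract_sequence(genome, sub)


class OrthologTable:
    """One-to-one mapping reference gene id -> core-species gene id."""

    def __init__(self, pairs: Mapping[str, str]):
        self._map = dict(pairs)
        if len(set(self._map.values())) != len(self._map):
            raise FormatError("ortholog table is not one-to-one")

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, ref_gene: str) -> bool:
        return ref_gene in self._map

    def get(self, ref_gene: str) -> str | None:
        return self._map.get(ref_gene)

    def items(self):
        return self._map.items()

    def validate_against(self, annotation: GeneAnnotation) -> None:
        missing = [g for g in self._map.values() if g not in annotation]
        if missing:
            raise FormatError(
                f"ortholog table references unknown core genes: {missing[:5]}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant with its minor allele frequency."""

    interval: GenomicInterval
    maf: float

    def __post_init__(self) -> None:
        if len(self.interval) != 1:
            raise ValueError("variant interval must have length 1")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF must be in [0, 0.5], got {self.maf}")

    @property
    def position(self) -> int:
        return self.interval.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, label: str | None = None) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased and U is converted to T.  Duplicate record ids
    and characters outside the IUPAC set raise :class:`FormatError`.
    """
    path = Path(path)
    chroms: dict[str, np.ndarray] = {}
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FormatError(f"{path}: not a FASTA file (line 1)")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        try:
            chroms[rec.id] = encode_sequence(str(rec.seq))
        except FormatError as exc:
            raise FormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    return GenomeSequence(chroms, label=label or path.stem)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF3_GENE_TYPES = {"gene", "protein_coding_gene"}


def read_gff3(path: str | Path, gene_types: set[str] | None = None) -> GeneAnnotation:
    """Read gene features from a GFF3 file.

    1-based inclusive coordinates are converted to 0-based half-open.
    Features whose ``type`` is not a gene type are ignored.  ``start > end``
    in the input raises :class:`FormatError`.
    """
    path = Path(path)
    types = gene_types or _GFF3_GENE_TYPES
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in types:
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise FormatError(f"{path}:{lineno}: start > end")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: feature without ID attribute")
            biotype = attr_map.get("biotype", "protein_coding")
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand if strand in "+-" else "+")
            genes.append(GeneRecord(gene_id, iv, biotype))
    return GeneAnnotation(genes)


def write_gff3(annotation: GeneAnnotation, path: str | Path, source: str = "mirortho") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation.all_genes():
            iv = gene.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        source,
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={gene.gene_id};biotype={gene.biotype}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# miRNA tables (TSV, MirGeneDB-style columns; coordinates 0-based half-open)
# ---------------------------------------------------------------------------

#: Default column map for the miRNA TSV dialect.  Other dialects can be read
#: by passing a mapping from these canonical names to the file's own headers.
MIRNA_COLUMNS = [
    "mirna_id",
    "family_id",
    "chrom",
    "start",
    "end",
    "strand",
    "sequence",
    "mature_start",
    "mature_end",
    "star_start",
    "star_end",
    "loop_start",
    "loop_end",
    "flank5_start",
    "flank5_end",
    "flank3_start",
    "flank3_end",
]


def _opt_interval(row, chrom, strand, prefix) -> GenomicInterval | None:
    s, e = row.get(f"{prefix}_start"), row.get(f"{prefix}_end")
    if pd.isna(s) or pd.isna(e):
        return None
    return GenomicInterval(chrom, int(s), int(e), strand)


def read_mirna_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[MirnaRecord]:
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = {"mirna_id", "family_id", "chrom", "start", "end", "strand", "sequence"} - set(
        df.columns
    )
    if missing:
        raise FormatError(f"{path}: missing miRNA table columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        chrom, strand = str(row["chrom"]), str(row["strand"])
        iv = GenomicInterval(chrom, int(row["start"]), int(row["end"]), strand)
        records.append(
            MirnaRecord(
                mirna_id=str(row["mirna_id"]),
                family_id=str(row["family_id"]),
                interval=iv,
                sequence=str(row["sequence"]),
                mature=_opt_interval(row, chrom, strand, "mature"),
                star=_opt_interval(row, chrom, strand, "star"),
                loop=_opt_interval(row, chrom, strand, "loop"),
                flank5=_opt_interval(row, chrom, strand, "flank5"),
                flank3=_opt_interval(row, chrom, strand, "flank3"),
            )
        )
    return records


def write_mirna_table(records: Sequence[MirnaRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict = {
            "mirna_id": r.mirna_id,
            "family_id": r.family_id,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "strand": r.interval.strand,
            "sequence": r.sequence,
        }
        for name in ("mature", "star", "loop", "flank5", "flank3"):
            sub = getattr(r, name)
            row[f"{name}_start"] = "" if sub is None else sub.start
            row[f"{name}_end"] = "" if sub is None else sub.end
        rows.append(row)
    pd.DataFrame(rows, columns=MIRNA_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog tables / BED / variants
# ---------------------------------------------------------------------------


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Two-column TSV: reference gene id, core gene id (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    first = tuple(df.iloc[0, :2])
    if first == ("ref_gene", "core_gene"):
        df = df.iloc[1:]
    return OrthologTable(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_gene\tcore_gene\n")
        for ref, core in table.items():
            fh.write(f"{ref}\t{core}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(
    rows: Iterable[tuple[GenomicInterval, str, float]], path: str | Path
) -> None:
    """Write (interval, name, score) rows as BED6; scores capped at 1000."""
    with open(path, "w") as fh:
        for iv, name, score in rows:
            capped = int(min(max(score, 0), 1000))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{capped}\t{iv.strand}\n"
            )


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a VCF (subset: CHROM, POS, and the AF info field).

    Allele frequencies are folded to minor allele frequencies
    ``min(AF, 1 - AF)``.  Records without AF are skipped.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            af = rec.info.get("AF")
            if af is None:
                continue
            if isinstance(af, (tuple, list)):
                af = af[0]
            maf = min(float(af), 1.0 - float(af))
            iv = GenomicInterval(rec.chrom, rec.pos - 1, rec.pos, "+")
            out.append(VariantRecord(iv, maf))
    return out


def write_variants(variants: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        chroms = sorted({v.interval.chrom for v in variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.interval.chrom, v.position)):
            fh.write(
                f"{v.interval.chrom}\t{v.position + 1}\t.\tA\tG\t.\tPASS\tAF={v.maf:.6g}\n"
            )
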