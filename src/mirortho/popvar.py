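"""Population-variation analysis of miRNA sub-regions versus other genomic
region classes: SNP density per kb, minor-allele-frequency binning, and a
Welch two-sample contrast on per-gene density vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genomics_io import GenomicInterval, MirnaRecord, VariantRecord

__all__ = [
    "RegionClass",
    "MAF_RARE_CUTOFF",
    "MAF_COMMON_CUTOFF",
    "snp_density",
    "variants_in_region",
    "maf_fractions",
    "per_gene_densities",
    "compare_densities",
    "region_classes_from_mirnas",
]

# MAF bins: rare < 0.01%, uncommon < 1%, common >= 1%
MAF_RARE_CUTOFF = 0.0001
MAF_COMMON_CUTOFF = 0.01


@dataclass
class RegionClass:
    """A named class of non-overlapping genomic intervals."""

    label: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"{self.label}: overlapping intervals {a} / {b}"
                    )

    @property
    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def variants_in_region(
    region: RegionClass, variants: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Variants falling inside the class (position p in [start, end))."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in region.intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for v in variants:
        spans = by_chrom.get(v.interval.chrom)
        if spans and any(s <= v.position < e for s, e in spans):
            out.append(v)
    return out


def snp_density(region: RegionClass, variants: Sequence[VariantRecord]) -> float:
    """(#variants in class / total class length) * 1000 = SNPs per kb."""
    length = region.total_length
    if length == 0:
        raise ValueError(f"{region.label}: zero total length")
    return len(variants_in_region(region, variants)) / length * 1000.0


def maf_fractions(
    variants: Sequence[VariantRecord],
) -> tuple[float, float, float] | None:
    """Fractions of variants with rare (<0.01%), uncommon (<1%) and common
    (>=1%) minor allele frequencies; None for an empty variant set."""
    if not variants:
        return None
    n = len(variants)
    rare = sum(1 for v in variants if v.maf < MAF_RARE_CUTOFF)
    common = sum(1 for v in variants if v.maf >= MAF_COMMON_CUTOFF)
    uncommon = n - rare - common
    return rare / n, uncommon / n, common / n


def per_gene_densities(
    mirnas: Sequence[MirnaRecord],
    subregion: str,
    variants: Sequence[VariantRecord],
) -> np.ndarray:
    """Per-miRNA SNP density (per kb) of one hairpin sub-region
    ('mature', 'star', 'loop', 'flank5' or 'flank3')."""
    out = []
    for m in mirnas:
        iv = getattr(m, subregion)
        if iv is None:
            continue
        rc = RegionClass(f"{m.mirna_id}:{subregion}", [iv])
        out.append(snp_density(rc, variants))
    return np.array(out)


def compare_densities(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t statistic and p-value on per-gene density vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per class")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def region_classes_from_mirnas(
    mirnas: Sequence[MirnaRecord],
    cds: Sequence[GenomicInterval] = (),
    lncrna: Sequence[GenomicInterval] = (),
) -> dict[str, RegionClass]:
    """The seven region classes: miRNA mature/star/loop/5p-flank/3p-flank
    plus CDS and lncRNA interval sets."""
    classes: dict[str, list[GenomicInterval]] = {
        "mature": [],
        "star": [],
        "loop": [],
        "5p-flank": [],
        "3p-flank": [],
    }
    attr_of = {
        "mature": "mature",
        "star": "star",
        "loop": "loop",
        "5p-flank": "flank5",
        "3p-flank": "flank3",
    }
    for m in mirnas:
        for label, attr in attr_of.items():
            iv = getattr(m, attr)
            if iv is not None:
                classes[label].append(iv)
    out = {label: RegionClass(label, ivs) for label, ivs in classes.items() if ivs}
    if cds:
        out["CDS"] = RegionClass("CDS", list(cds))
    if lncrna:
        out["lncRNA"] = RegionClass("lncRNA", list(lncrna))
    return out
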