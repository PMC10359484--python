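"""Stage-2 targeted ortholog search.

Candidate regions in the target genome come either from a similarity
pre-search with the reference pre-miRNA, extended 1000 nt up- and downstream
("quick" mode), or from tiling the whole genome ("exhaustive" mode).  Each
region is scanned with the trained sequence+structure model; hits scoring at
least the configured fraction (default 50%) of the reference's own score
``S_ref`` are kept, deduplicated, and confirmed by a reverse search in the
reference genome.  All confirmed hits are reported as (co-)orthologs ranked
by score.

Region scanning uses a gap-free profile sweep over every window offset as a
prefilter, then rescans the best offsets with the full gapped scorer — the
same filter-then-refine layout real covariance-model search engines use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .alignment_search import (
    SearchEngineParams,
    best_hit,
    confirm_by_reverse_search,
    local_search,
)
from .genomics_io import (
    GenomeSequence,
    GenomicInterval,
    MirnaRecord,
    decode_sequence,
    interval_overlap,
    reverse_complement,
    write_bed,
)
from .model_training import StructureProfileModel, global_align

__all__ = [
    "SearchParams",
    "ScanHit",
    "OrthologPrediction",
    "candidate_regions",
    "scan_region",
    "scan_region_all",
    "search_orthologs",
    "seed_identical",
    "predictions_to_dataframe",
    "write_predictions",
]


@dataclass(frozen=True)
class SearchParams:
    """Parameters of the targeted search stage."""

    mode: str = "quick"  # "quick" | "exhaustive"
    extension: int = 1000
    threshold: float = 0.5  # fraction of S_ref a hit must reach
    max_rescore: int = 200  # cap on DP rescans per region and strand
    prefilter_margin: float = 5.0  # bits of slack below threshold in prefilter

    def __post_init__(self) -> None:
        if self.mode not in ("quick", "exhaustive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.extension < 0:
            raise ValueError("extension must be >= 0")


@dataclass(frozen=True)
class ScanHit:
    interval: GenomicInterval
    score: float


@dataclass(frozen=True)
class OrthologPrediction:
    """An accepted ortholog call."""

    mirna_id: str
    target_species: str
    interval: GenomicInterval
    sequence: str
    bit_score: float
    score_fraction: float
    seed_identical: bool | None  # None = unknown (no mature annotation)
    rank: int  # co-ortholog rank, 1 = best score
    family_id: str = ""

    @property
    def strand(self) -> str:
        return self.interval.strand


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------


def merge_intervals(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome (strand dropped)."""
    out: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in ivs}):
        spans = sorted(
            [(iv.start, iv.end) for iv in ivs if iv.chrom == chrom]
        )
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, "+"))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e, "+"))
    return out


def candidate_regions(
    mirna: MirnaRecord,
    target_genome: GenomeSequence,
    params: SearchParams | None = None,
    search_params: SearchEngineParams | None = None,
) -> list[GenomicInterval]:
    """Quick mode: similarity hits of the reference pre-miRNA extended by
    ``extension`` nt up- and downstream, clipped and merged.  Exhaustive
    mode: tiles of length 2*extension over every chromosome, overlapping by
    twice the pre-miRNA length so no hairpin is split."""
    params = params or SearchParams()
    if params.mode == "quick":
        hits = local_search(
            mirna.sequence, target_genome, search_params, query_id=mirna.mirna_id
        )
        regions = []
        for h in hits:
            iv = h.interval
            n = target_genome.length(iv.chrom)
            regions.append(
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - params.extension),
                    min(n, iv.end + params.extension),
                    "+",
                )
            )
        return merge_intervals(regions) if regions else []
    tile = max(2 * params.extension, 2 * len(mirna.sequence))
    overlap = 2 * len(mirna.sequence)
    step = max(1, tile - overlap)
    regions = []
    for chrom in target_genome:
        n = target_genome.length(chrom)
        pos = 0
        while pos < n:
            regions.append(GenomicInterval(chrom, pos, min(n, pos + tile), "+"))
            if pos + tile >= n:
                break
            pos += step
    return regions


# ---------------------------------------------------------------------------
# region scanning
# ---------------------------------------------------------------------------


def _gapfree_scores(model: StructureProfileModel, codes: np.ndarray) -> np.ndarray:
    """Gap-free profile score for every window offset.

    Windows have the ungapped reference length; columns are gathered at
    their reference positions, so models whose training alignment carries
    insertion columns stay correctly registered.
    """
    W = model.ref_length
    if codes.shape[0] < W:
        return np.empty(0)
    off = model.ref_offsets
    used = np.flatnonzero(off >= 0).astype(np.int64)
    used_pos = off[used]
    pi, pj = model.pairs[:, 0], model.pairs[:, 1]
    ok = (off[pi] >= 0) & (off[pj] >= 0) if pi.size else np.zeros(0, dtype=bool)
    pair_idx = np.flatnonzero(ok).astype(np.int64)
    return _kernels.gapfree_sweep(
        model.emissions,
        used,
        used_pos,
        pair_idx,
        off[pi[pair_idx]] if pair_idx.size else np.zeros(0, dtype=np.int64),
        off[pj[pair_idx]] if pair_idx.size else np.zeros(0, dtype=np.int64),
        model.pair_emissions,
        codes,
        W,
    )


def _scan_strand(
    model: StructureProfileModel,
    codes: np.ndarray,
    params: SearchParams,
    threshold: float,
    top_k: int,
) -> list[tuple[int, float]]:
    """Offsets (in the given orientation) and exact scores worth keeping."""
    L = model.ref_length
    n = codes.shape[0]
    if n < L:
        if n == 0:
            return []
        total, _ = _kernels.profile_score(
            model.emissions,
            model.gamma,
            model.pairs[:, 0],
            model.pairs[:, 1],
            model.pair_emissions,
            codes,
        )
        return [(0, float(total))]
    pre = _gapfree_scores(model, codes)
    cut = threshold - params.prefilter_margin
    sel = np.flatnonzero(pre >= cut)
    if sel.size > params.max_rescore:
        keep = np.argsort(pre[sel])[::-1][: params.max_rescore]
        sel = sel[keep]
    k = min(top_k, pre.shape[0])
    top = np.argpartition(pre, -k)[-k:]
    sel = np.union1d(sel, top).astype(np.int64)
    scores = _kernels.profile_score_batch(
        model.emissions,
        model.gamma,
        model.pairs[:, 0],
        model.pairs[:, 1],
        model.pair_emissions,
        codes,
        sel,
        L,
    )
    return [(int(o), float(s)) for o, s in zip(sel, scores)]


def scan_region_all(
    model: StructureProfileModel,
    genome: GenomeSequence,
    region: GenomicInterval,
    params: SearchParams | None = None,
    threshold: float = -np.inf,
) -> list[ScanHit]:
    """All window hits in a region with score >= threshold, overlapping hits
    deduplicated (best score kept); sorted by score desc, then start, then
    plus strand first."""
    params = params or SearchParams()
    L = model.ref_length
    fwd = genome.codes(region.chrom)[region.start : region.end]
    n = fwd.shape[0]
    raw_hits: list[tuple[float, GenomicInterval]] = []
    for strand in "+-":
        codes = fwd if strand == "+" else reverse_complement(fwd)
        for off, score in _scan_strand(model, codes, params, threshold, top_k=5):
            wlen = min(L, n)
            if strand == "+":
                s = region.start + off
            else:
                s = region.start + (n - off - wlen)
            raw_hits.append(
                (score, GenomicInterval(region.chrom, s, s + wlen, strand))
            )
    raw_hits.sort(key=lambda t: (-t[0], t[1].start, t[1].strand))
    kept: list[ScanHit] = []
    for score, iv in raw_hits:
        if any(interval_overlap(iv, k.interval) > 0 for k in kept):
            continue
        kept.append(ScanHit(iv, score))
    return [h for h in kept if h.score >= threshold]


def scan_region(
    model: StructureProfileModel,
    genome: GenomeSequence,
    region: GenomicInterval,
    params: SearchParams | None = None,
) -> ScanHit | None:
    """Best-scoring window in the region (ties: smaller start, plus strand)."""
    hits = scan_region_all(model, genome, region, params, threshold=-np.inf)
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# full search
# ---------------------------------------------------------------------------


def seed_identical(mirna: MirnaRecord, prediction_sequence: str) -> bool | None:
    """True iff the 7-nt seed (mature positions 2-8) of the prediction is
    identical and gap-free to the reference; None when the reference lacks a
    mature annotation."""
    if mirna.mature is None:
        return None
    iv = mirna.interval
    if iv.strand == "+":
        off = mirna.mature.start - iv.start
    else:
        off = iv.end - mirna.mature.end
    seed_lo, seed_hi = off + 1, off + 8  # mature positions 2..8, 1-based
    ref_row, pred_row = global_align(mirna.sequence, prediction_sequence)
    rpos = 0
    for rc, pc in zip(ref_row, pred_row):
        if rc == "-":
            continue
        if seed_lo <= rpos < seed_hi:
            if pc == "-" or pc != rc:
                return False
        rpos += 1
    return True


def search_orthologs(
    model: StructureProfileModel,
    mirna: MirnaRecord,
    target_genome: GenomeSequence,
    reference_genome: GenomeSequence,
    params: SearchParams | None = None,
    search_params: SearchEngineParams | None = None,
    target_species: str = "",
) -> list[OrthologPrediction]:
    """Search one target genome for (co-)orthologs of one reference miRNA.

    An empty list means the ortholog is absent.
    """
    params = params or SearchParams()
    search_params = search_params or SearchEngineParams()
    threshold = params.threshold * model.s_ref
    regions = candidate_regions(mirna, target_genome, params, search_params)
    if regions:
        # exhaustive tiles overlap; merging them lets the prefilter sweep
        # whole chromosomes in one pass
        regions = merge_intervals(regions)
    hits: list[ScanHit] = []
    for region in regions:
        hits.extend(scan_region_all(model, target_genome, region, params, threshold))
    # exhaustive tiles overlap; keep the best hit per locus
    hits.sort(key=lambda h: (-h.score, h.interval.chrom, h.interval.start, h.interval.strand))
    dedup: list[ScanHit] = []
    for h in hits:
        if any(interval_overlap(h.interval, k.interval) > 0 for k in dedup):
            continue
        dedup.append(h)
    predictions = []
    for h in dedup:
        seq = _hit_sequence(target_genome, h.interval)
        if not confirm_by_reverse_search(seq, reference_genome, mirna, search_params):
            continue
        predictions.append((h, seq))
    predictions.sort(
        key=lambda t: (-t[0].score, t[0].interval.chrom, t[0].interval.start)
    )
    out = []
    for rank, (h, seq) in enumerate(predictions, start=1):
        out.append(
            OrthologPrediction(
                mirna_id=mirna.mirna_id,
                family_id=mirna.family_id,
                target_species=target_species,
                interval=h.interval,
                sequence=seq,
                bit_score=h.score,
                score_fraction=h.score / model.s_ref,
                seed_identical=seed_identical(mirna, seq),
                rank=rank,
            )
        )
    return out


def _hit_sequence(genome: GenomeSequence, iv: GenomicInterval) -> str:
    codes = genome.codes(iv.chrom)[iv.start : iv.end]
    if iv.strand == "-":
        codes = reverse_complement(codes)
    return decode_sequence(codes)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def predictions_to_dataframe(predictions: Sequence[OrthologPrediction]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": p.mirna_id,
            "family_id": p.family_id,
            "target_species": p.target_species,
            "chrom": p.interval.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "strand": p.interval.strand,
            "bit_score": p.bit_score,
            "score_fraction": p.score_fraction,
            "seed_identical": (
                "unknown" if p.seed_identical is None else str(p.seed_identical).lower()
            ),
            "rank": p.rank,
            "sequence": p.sequence,
        }
        for p in predictions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "family_id",
            "target_species",
            "chrom",
            "start",
            "end",
            "strand",
            "bit_score",
            "score_fraction",
            "seed_identical",
            "rank",
            "sequence",
        ],
    )


def write_predictions(
    predictions: Sequence[OrthologPrediction], tsv_path: str | Path, bed_path: str | Path
) -> None:
    predictions_to_dataframe(predictions).to_csv(tsv_path, sep="\t", index=False)
    write_bed(
        (
            (p.interval, f"{p.mirna_id}|rank{p.rank}", p.score_fraction * 1000)
            for p in predictions
        ),
        bed_path,
    )
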