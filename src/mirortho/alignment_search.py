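"""Local sequence-similarity search (BLASTn-like) with reciprocal-best-hit
logic and the annotation liftover used for benchmarking.

The built-in engine seeds on exact word matches and runs an affine-gap
Smith-Waterman (Gotoh) restricted to a window around each seed cluster, so
that for subjects that fit inside a single window the reported score is the
exact optimal local alignment score.  Raw scores are converted to bit scores
with ``(lambda * S - ln K) / ln 2``.

An adapter for an external tabular-output search binary (e.g. NCBI blastn)
is provided for parity runs; the engine choice is a parameter.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from math import log
from pathlib import Path

import numpy as np

from . import _kernels
from .genomics_io import (
    GenomeSequence,
    GenomicInterval,
    MirnaRecord,
    decode_sequence,
    encode_sequence,
    extract_sequence,
    interval_overlap,
    reverse_complement,
)

__all__ = [
    "SearchEngineParams",
    "SearchHit",
    "LiftoverParams",
    "local_search",
    "best_hit",
    "confirm_by_reverse_search",
    "liftover_mirna",
    "parse_tabular_hits",
    "external_local_search",
]


@dataclass(frozen=True)
class SearchEngineParams:
    """Scoring constants of the built-in engine (BLASTn-like defaults)."""

    word_size: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5  # cost of the first gapped position
    gap_extend: int = 2  # cost of each further gapped position
    lambda_: float = 0.625
    k: float = 0.41
    min_bit_score: float = 30.0

    def bit_score(self, raw: int) -> float:
        return (self.lambda_ * raw - log(self.k)) / log(2.0)


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    interval: GenomicInterval  # subject interval, strand-aware
    bit_score: float
    identity: float  # percent in [0, 100]
    coverage: float  # percent of query covered, in [0, 100]
    subject_sequence: str  # ungapped subject segment on the hit strand
    raw_score: int = 0
    # aligned query span, 0-based half-open, in the orientation searched
    # (for minus-strand hits the query was reverse-complemented first)
    query_start: int = 0
    query_end: int = 0

    def __post_init__(self) -> None:
        if self.bit_score <= 0:
            raise ValueError("bit score must be > 0")
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity/coverage out of bounds")


@dataclass(frozen=True)
class LiftoverParams:
    min_identity: float = 90.0
    min_coverage: float = 80.0

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100 and 0 < self.min_coverage <= 100):
            raise ValueError("liftover cutoffs must be in (0, 100]")


# ---------------------------------------------------------------------------
# seed index
# ---------------------------------------------------------------------------


def _word_codes(codes: np.ndarray, w: int) -> np.ndarray:
    """Rolling w-mer codes (base 4); windows containing N get code -1."""
    n = codes.shape[0]
    if n < w:
        return np.empty(0, dtype=np.int64)
    m = n - w + 1
    words = np.zeros(m, dtype=np.int64)
    c = codes.astype(np.int64)
    for i in range(w):
        words = words * 4 + np.minimum(c[i : m + i], 3)
    bad = (codes >= 4).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    has_n = (cum[w:] - cum[:-w]) > 0
    words[has_n] = -1
    return words


def _genome_index(genome: GenomeSequence, w: int):
    """Sorted word index per chromosome, cached on the genome object."""
    cache = genome._word_index
    if w not in cache:
        idx = {}
        for chrom in genome:
            words = _word_codes(genome.codes(chrom), w)
            order = np.argsort(words, kind="stable").astype(np.int64)
            idx[chrom] = (words[order], order)
        cache[w] = idx
    return cache[w]


def _seed_positions(sorted_words, positions, word: int) -> np.ndarray:
    lo = np.searchsorted(sorted_words, word, side="left")
    hi = np.searchsorted(sorted_words, word, side="right")
    return positions[lo:hi]


# ---------------------------------------------------------------------------
# built-in engine
# ---------------------------------------------------------------------------


def _cluster_starts(starts: np.ndarray, qlen: int) -> list[tuple[int, int]]:
    """Group putative alignment start positions into clusters within qlen."""
    if starts.size == 0:
        return []
    starts = np.unique(starts)
    clusters = []
    lo = hi = int(starts[0])
    for s in starts[1:]:
        s = int(s)
        if s - hi <= qlen:
            hi = s
        else:
            clusters.append((lo, hi))
            lo = hi = s
    clusters.append((lo, hi))
    return clusters


def _search_one_strand(
    q_codes: np.ndarray,
    query_id: str,
    qlen_orig: int,
    genome: GenomeSequence,
    strand: str,
    params: SearchEngineParams,
) -> list[SearchHit]:
    w = params.word_size
    qlen = q_codes.shape[0]
    if qlen < w:
        return []
    q_words = _word_codes(q_codes, w)
    index = _genome_index(genome, w)
    pad = qlen + 50
    hits: list[SearchHit] = []
    for chrom in genome:
        sorted_words, positions = index[chrom]
        diag_starts = []
        for qi in range(q_words.shape[0]):
            word = q_words[qi]
            if word < 0:
                continue
            pos = _seed_positions(sorted_words, positions, int(word))
            if pos.size:
                diag_starts.append(pos - qi)
        if not diag_starts:
            continue
        starts = np.concatenate(diag_starts)
        g = genome.codes(chrom)
        n = g.shape[0]
        for lo, hi in _cluster_starts(starts, qlen):
            w_lo = max(0, lo - pad)
            w_hi = min(n, hi + qlen + pad)
            raw, q1, q2, s1, s2, n_match, alen = _kernels.gotoh_local(
                q_codes,
                g[w_lo:w_hi],
                params.match,
                params.mismatch,
                params.gap_open,
                params.gap_extend,
            )
            if raw <= 0 or alen == 0:
                continue
            bits = params.bit_score(raw)
            if bits < params.min_bit_score:
                continue
            sstart, send = w_lo + s1, w_lo + s2
            iv = GenomicInterval(chrom, sstart, send, strand)
            segment = g[sstart:send]
            if strand == "-":
                subject_seq = decode_sequence(reverse_complement(segment))
            else:
                subject_seq = decode_sequence(segment)
            hits.append(
                SearchHit(
                    query_id=query_id,
                    interval=iv,
                    bit_score=bits,
                    identity=100.0 * n_match / alen,
                    coverage=100.0 * (q2 - q1) / qlen_orig,
                    subject_sequence=subject_seq,
                    raw_score=raw,
                    query_start=q1,
                    query_end=q2,
                )
            )
    return hits


def _dedup_hits(hits: list[SearchHit]) -> list[SearchHit]:
    """Keep the best-scoring hit per overlapping subject locus (any strand)."""
    ordered = sorted(
        hits,
        key=lambda h: (-h.raw_score, h.interval.chrom, h.interval.start, h.interval.strand),
    )
    kept: list[SearchHit] = []
    for h in ordered:
        if any(interval_overlap(h.interval, k.interval) > 0 for k in kept):
            continue
        kept.append(h)
    return kept


def local_search(
    query: str,
    subject: GenomeSequence,
    params: SearchEngineParams | None = None,
    query_id: str = "query",
) -> list[SearchHit]:
    """Search ``query`` against both strands of ``subject``.

    Hits are sorted by bit score descending; ties break by smaller subject
    start, then plus strand.
    """
    if not query:
        raise ValueError("query must be non-empty")
    params = params or SearchEngineParams()
    if len(query) < params.word_size:
        raise ValueError(
            f"query length {len(query)} below seed word size {params.word_size}"
        )
    q_codes = encode_sequence(query)
    hits = _search_one_strand(q_codes, query_id, len(query), subject, "+", params)
    rc = reverse_complement(q_codes)
    hits += _search_one_strand(rc, query_id, len(query), subject, "-", params)
    hits = _dedup_hits(hits)
    hits.sort(
        key=lambda h: (
            -h.bit_score,
            h.interval.chrom,
            h.interval.start,
            h.interval.strand,
        )
    )
    return hits


def best_hit(hits: list[SearchHit]) -> SearchHit | None:
    """First hit of the documented sort order, or None."""
    return hits[0] if hits else None


def confirm_by_reverse_search(
    candidate_sequence: str,
    reference_genome: GenomeSequence,
    reference_mirna: MirnaRecord,
    params: SearchEngineParams | None = None,
) -> bool:
    """True iff the candidate's best hit in the reference genome overlaps the
    reference pre-miRNA locus (>= 1 nt)."""
    if not candidate_sequence:
        raise ValueError("candidate sequence must be non-empty")
    params = params or SearchEngineParams()
    if len(candidate_sequence) < params.word_size:
        return False
    hit = best_hit(local_search(candidate_sequence, reference_genome, params))
    if hit is None:
        return False
    return interval_overlap(hit.interval, reference_mirna.interval) > 0


def liftover_mirna(
    mirna: MirnaRecord,
    new_genome: GenomeSequence,
    liftover: LiftoverParams | None = None,
    params: SearchEngineParams | None = None,
) -> GenomicInterval | None:
    """Map a miRNA onto another assembly: best hit passing the identity and
    query-coverage cutoffs, or None."""
    liftover = liftover or LiftoverParams()
    hits = local_search(mirna.sequence, new_genome, params, query_id=mirna.mirna_id)
    passing = [
        h
        for h in hits
        if h.identity >= liftover.min_identity and h.coverage >= liftover.min_coverage
    ]
    hit = best_hit(passing)
    return hit.interval if hit else None


# ---------------------------------------------------------------------------
# external engine adapter
# ---------------------------------------------------------------------------

_TABULAR_FIELDS = "qseqid sseqid pident qcovs sstart send sstrand bitscore"


def parse_tabular_hits(text: str, genome: GenomeSequence | None = None) -> list[SearchHit]:
    """Parse tabular search output with the adapter's field contract:
    ``qseqid sseqid pident qcovs sstart send sstrand bitscore`` (1-based
    inclusive subject coordinates, sstart > send allowed on the minus
    strand)."""
    hits = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        qseqid, sseqid, pident, qcovs, sstart, send, sstrand, bits = f[:8]
        s1, s2 = int(sstart), int(send)
        if sstrand in ("minus", "-") or s1 > s2:
            strand = "-"
            s1, s2 = min(s1, s2), max(s1, s2)
        else:
            strand = "+"
        iv = GenomicInterval(sseqid, s1 - 1, s2, strand)
        subject_seq = ""
        if genome is not None and sseqid in genome:
            subject_seq = extract_sequence(genome, iv)
        hits.append(
            SearchHit(
                query_id=qseqid,
                interval=iv,
                bit_score=float(bits),
                identity=float(pident),
                coverage=float(qcovs),
                subject_sequence=subject_seq,
            )
        )
    hits.sort(
        key=lambda h: (-h.bit_score, h.interval.chrom, h.interval.start, h.interval.strand)
    )
    return hits


def external_local_search(
    query: str,
    subject_fasta: str | Path,
    executable: str = "blastn",
    query_id: str = "query",
    extra_args: tuple[str, ...] = ("-task", "blastn"),
) -> list[SearchHit]:
    """Run an external BLAST+-compatible binary and parse its tabular output."""
    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as qf:
        qf.write(f">{query_id}\n{query}\n")
        qpath = qf.name
    try:
        cmd = [
            executable,
            "-query",
            qpath,
            "-subject",
            str(subject_fasta),
            "-outfmt",
            f"6 {_TABULAR_FIELDS}",
            *extra_args,
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
        return parse_tabular_hits(proc.stdout)
    finally:
        Path(qpath).unlink(missing_ok=True)
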