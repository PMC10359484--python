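"""Evaluation of ortholog predictions against a gold-standard location table,
plus two reproducible baseline callers (naive best-hit search and whole-genome
-alignment block coverage).

Counting is per family x species cell: a prediction overlapping (>= 1 nt) a
gold interval of the same family is a true positive; a prediction without a
matching gold entry is a false positive; an unmatched gold entry is a false
negative; an empty cell on both sides is a true negative.  Multiple
predictions are matched greedily in score order, each consuming at most one
gold entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment_search import SearchEngineParams, SearchHit, best_hit, local_search
from .genomics_io import (
    GenomeSequence,
    GenomicInterval,
    MirnaRecord,
    interval_overlap,
)
from .ortholog_search import OrthologPrediction

__all__ = [
    "ConfusionCounts",
    "classify_cell",
    "metrics",
    "aggregate_confusion",
    "wga_block_call",
    "naive_blast_call",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classify_cell(
    predictions: Sequence[tuple[GenomicInterval, float]] | Sequence[OrthologPrediction],
    gold: Sequence[GenomicInterval],
) -> ConfusionCounts:
    """Confusion counts for one family x species cell.

    ``predictions`` may be (interval, score) tuples or OrthologPrediction
    objects; matching is greedy in descending score, one gold entry per
    prediction.
    """
    items: list[tuple[GenomicInterval, float]] = []
    for p in predictions:
        if isinstance(p, OrthologPrediction):
            items.append((p.interval, p.bit_score))
        else:
            items.append((p[0], p[1]))
    items.sort(key=lambda t: (-t[1], t[0].chrom, t[0].start))
    counts = ConfusionCounts()
    unmatched = list(gold)
    for iv, _score in items:
        match_idx = next(
            (k for k, g in enumerate(unmatched) if interval_overlap(iv, g) > 0), None
        )
        if match_idx is None:
            counts.fp += 1
        else:
            counts.tp += 1
            unmatched.pop(match_idx)
    counts.fn += len(unmatched)
    if not items and not gold:
        counts.tn = 1
    return counts


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
    (TP+TN)/total, F1 2TP/(2TP+FP+FN); None where the denominator is 0."""

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "accuracy": ratio(c.tp + c.tn, c.total),
        "f1": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def aggregate_confusion(
    predictions: Iterable[OrthologPrediction],
    gold: pd.DataFrame,
    families: Sequence[str],
    species: Sequence[str],
) -> tuple[ConfusionCounts, pd.DataFrame]:
    """Tally confusion counts over every family x species cell.

    ``gold`` is a table with columns species, family_id, chrom, start, end,
    strand.  Returns the aggregate counts and a per-species breakdown.
    """
    by_cell_pred: dict[tuple[str, str], list[OrthologPrediction]] = {}
    for p in predictions:
        by_cell_pred.setdefault((p.family_id, p.target_species), []).append(p)
    by_cell_gold: dict[tuple[str, str], list[GenomicInterval]] = {}
    for _, row in gold.iterrows():
        iv = GenomicInterval(
            str(row["chrom"]), int(row["start"]), int(row["end"]), str(row["strand"])
        )
        by_cell_gold.setdefault((str(row["family_id"]), str(row["species"])), []).append(iv)
    total = ConfusionCounts()
    rows = []
    for sp in species:
        sp_counts = ConfusionCounts()
        for fam in families:
            cell = classify_cell(
                by_cell_pred.get((fam, sp), []), by_cell_gold.get((fam, sp), [])
            )
            sp_counts = sp_counts + cell
        m = metrics(sp_counts)
        rows.append(
            {
                "species": sp,
                "tp": sp_counts.tp,
                "fp": sp_counts.fp,
                "fn": sp_counts.fn,
                "tn": sp_counts.tn,
                **m,
            }
        )
        total = total + sp_counts
    return total, pd.DataFrame(rows)


def wga_block_call(
    human_mirna: GenomicInterval,
    block: Mapping[str, str],
    human_species: str,
    block_start: int,
    min_coverage: float = 0.7,
) -> dict[str, bool]:
    """Whole-genome-alignment baseline: a species carries an ortholog
    candidate iff its row covers at least ``min_coverage`` of the human
    miRNA locus excluding gaps.

    ``block`` maps species to aligned rows (gaps as '-'); the human row
    defines the columns and starts at ungapped human position
    ``block_start``.
    """
    if human_species not in block:
        raise ValueError(f"human row {human_species!r} absent from block")
    human_row = block[human_species]
    span_cols = []
    pos = block_start
    for col, c in enumerate(human_row):
        if c != "-":
            if human_mirna.start <= pos < human_mirna.end:
                span_cols.append(col)
            pos += 1
    need = min_coverage * len(human_mirna)
    out = {}
    for sp, row in block.items():
        if sp == human_species:
            continue
        covered = sum(1 for col in span_cols if col < len(row) and row[col] != "-")
        out[sp] = covered >= need
    return out


def naive_blast_call(
    mirna: MirnaRecord,
    target_genome: GenomeSequence,
    params: SearchEngineParams | None = None,
) -> SearchHit | None:
    """Naive baseline: the single best similarity hit, unconditionally (no
    reciprocal confirmation) — deliberately low-specificity."""
    hits = local_search(mirna.sequence, target_genome, params, query_id=mirna.mirna_id)
    return best_hit(hits)
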