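"""Training of the sequence+structure scoring model ("mini-CM").

The model is a deliberately small stand-in for a full covariance model: per
column a nucleotide log-odds emission (bits against a uniform background),
plus a covariation term for every paired column of the consensus secondary
structure, plus a linear gap penalty.  The reference pre-miRNA's own score
``S_ref`` is stored with the model; the ortholog search accepts hits scoring
at least a configurable fraction (default 50%) of ``S_ref``.

Training alignments come from the positional orthologs collected via
microsynteny.  The built-in aligner is an iterative star alignment against
the reference; the built-in folder is Nussinov maximum base pairing
(Watson-Crick + GU, minimum loop 3) on the column-majority consensus.  Both
are pluggable so that external alignment/folding programs can be substituted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .alignment_search import SearchEngineParams
from .genomics_io import (
    GeneAnnotation,
    GenomeSequence,
    MirnaRecord,
    decode_sequence,
    encode_sequence,
)
from .synteny import CoreBundle, SyntenyParams, collect_positional_ortholog

__all__ = [
    "TrainingAlignment",
    "StructureProfileModel",
    "global_align",
    "build_training_alignment",
    "train_model",
    "score_sequence",
    "create_models",
    "write_stockholm",
]

logger = logging.getLogger(__name__)

_BACKGROUND = 0.25


# ---------------------------------------------------------------------------
# pairwise global alignment (built-in star-alignment scoring)
# ---------------------------------------------------------------------------


def global_align(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[str, str]:
    """Needleman-Wunsch with linear gaps; deterministic traceback
    (diagonal preferred, then gap in ``b``, then gap in ``a``)."""
    ca, cb = encode_sequence(a), encode_sequence(b)
    na, nb = len(ca), len(cb)
    H = np.empty((na + 1, nb + 1), dtype=np.int64)
    H[0, :] = gap * np.arange(nb + 1)
    H[:, 0] = gap * np.arange(na + 1)
    for i in range(1, na + 1):
        prev = H[i - 1]
        cur = H[i]
        ai = ca[i - 1]
        sub = np.where((cb == ai) & (cb < 4), match, mismatch)
        for j in range(1, nb + 1):
            cur[j] = max(prev[j - 1] + sub[j - 1], prev[j] + gap, cur[j - 1] + gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = na, nb
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if (ca[i - 1] == cb[j - 1] and ca[i - 1] < 4) else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


# ---------------------------------------------------------------------------
# training alignment
# ---------------------------------------------------------------------------


@dataclass
class TrainingAlignment:
    """MSA over {A,C,G,T,-} plus a nested consensus pairing.

    ``pairs`` holds paired column index pairs (i, j), i < j, non-crossing;
    every column occurs in at most one pair.
    """

    rows: list[str]
    ids: list[str]
    pairs: list[tuple[int, int]]
    consensus: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows differ in length")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < L):
                raise ValueError(f"invalid pair ({i}, {j})")
            if i in seen or j in seen:
                raise ValueError("column in more than one pair")
            seen.update((i, j))
        stack: list[int] = []
        events = sorted(
            [(i, "o", j) for i, j in self.pairs] + [(j, "c", i) for i, j in self.pairs]
        )
        for pos, kind, partner in events:
            if kind == "o":
                stack.append(pos)
            else:
                if not stack or stack[-1] != partner:
                    raise ValueError("pairing is not nested (pseudoknot)")
                stack.pop()

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def dot_bracket(self) -> str:
        out = ["."] * self.n_columns
        for i, j in self.pairs:
            out[i] = "("
            out[j] = ")"
        return "".join(out)


def _star_merge(reference: str, aligned: list[tuple[str, str]]) -> list[str]:
    """Merge pairwise (ref, other) alignments into an MSA via reference
    coordinates ('once a gap, always a gap')."""
    L = len(reference)
    max_ins = [0] * (L + 1)
    per_seq: list[tuple[list[str], list[str]]] = []
    for ref_row, other_row in aligned:
        inserts = [""] * (L + 1)
        chars = [""] * L
        rpos = 0
        for rc, oc in zip(ref_row, other_row):
            if rc == "-":
                inserts[rpos] += oc
            else:
                chars[rpos] = oc
                rpos += 1
        for k in range(L + 1):
            max_ins[k] = max(max_ins[k], len(inserts[k]))
        per_seq.append((inserts, chars))
    rows = []
    ref_out = []
    for k in range(L):
        ref_out.append("-" * max_ins[k] + reference[k])
    ref_out.append("-" * max_ins[L])
    rows.append("".join(ref_out))
    for inserts, chars in per_seq:
        out = []
        for k in range(L):
            out.append(inserts[k].ljust(max_ins[k], "-") + chars[k])
        out.append(inserts[L].ljust(max_ins[L], "-"))
        rows.append("".join(out))
    return rows


def _column_consensus(rows: list[str]) -> tuple[str, list[bool]]:
    """Majority nucleotide per column (ties alphabetical) and a flag marking
    columns where gaps are in the majority (excluded from folding)."""
    L = len(rows[0])
    consensus = []
    foldable = []
    for j in range(L):
        col = [r[j] for r in rows]
        counts = {c: 0 for c in "ACGT"}
        gaps = 0
        for c in col:
            if c == "-":
                gaps += 1
            elif c in counts:
                counts[c] += 1
        best = max("ACGT", key=lambda c: (counts[c], -ord(c)))
        if counts[best] == 0:
            consensus.append("N")
            foldable.append(False)
        else:
            consensus.append(best)
            foldable.append(gaps * 2 <= len(col))
    return "".join(consensus), foldable


def _builtin_fold(consensus: str, foldable: list[bool], min_loop: int = 3):
    idx = [j for j, ok in enumerate(foldable) if ok]
    if len(idx) < 2:
        return []
    sub = encode_sequence("".join(consensus[j] for j in idx))
    raw = _kernels.nussinov_pairs(sub, min_loop)
    return [(idx[int(i)], idx[int(j)]) for i, j in raw]


def build_training_alignment(
    sequences: Sequence[str],
    ids: Sequence[str] | None = None,
    aligner: Callable[[Sequence[str]], list[str]] | None = None,
    folder: Callable[[str], list[tuple[int, int]]] | None = None,
    min_loop: int = 3,
) -> TrainingAlignment:
    """Align the training set (reference first) and annotate a consensus
    secondary structure.

    ``aligner`` may be any callable returning equal-length rows for the
    input sequences; the built-in fallback is an iterative star alignment
    against the reference.  ``folder`` maps the column-majority consensus to
    a nested pair list; the built-in fallback is Nussinov maximum base
    pairing.  A single-sequence training set is allowed but degenerates to a
    reference-only profile (a warning is emitted).
    """
    if not sequences:
        raise ValueError("at least one training sequence (the reference) required")
    sequences = [s.upper().replace("U", "T") for s in sequences]
    if len(sequences) == 1:
        warnings.warn(
            "training set holds only the reference; model degenerates to the "
            "reference profile",
            stacklevel=2,
        )
    if ids is None:
        ids = ["reference"] + [f"ortholog_{k}" for k in range(1, len(sequences))]
    if aligner is not None:
        rows = list(aligner(sequences))
    else:
        reference = sequences[0]
        aligned = [global_align(reference, s) for s in sequences[1:]]
        rows = _star_merge(reference, aligned)
    consensus, foldable = _column_consensus(rows)
    if folder is not None:
        pairs = folder(consensus)
    else:
        pairs = _builtin_fold(consensus, foldable, min_loop)
    return TrainingAlignment(rows=rows, ids=list(ids), pairs=pairs, consensus=consensus)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


@dataclass
class StructureProfileModel:
    """Trained sequence+structure profile.

    ``emissions`` is (L, 5): per-column log-odds in bits for A, C, G, T and
    N (N carries the unseen-character pseudocount value).  ``pair_emissions``
    is (P, 5, 5) covariation bits for the paired columns in ``pairs``.
    ``s_ref`` is the reference sequence's own score: the maximally achievable
    bit score used as the denominator of the acceptance threshold.
    """

    mirna_id: str
    emissions: np.ndarray
    pairs: np.ndarray  # (P, 2) int64
    pair_emissions: np.ndarray  # (P, 5, 5)
    gamma: float
    s_ref: float
    n_training: int
    consensus_structure: str = ""
    # registration of the columns on the ungapped reference sequence:
    # ref_offsets[j] = reference position of column j, or -1 where the
    # reference row is gapped.  Scan windows use the reference length.
    ref_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ref_offsets is None:
            self.ref_offsets = np.arange(self.emissions.shape[0], dtype=np.int64)

    @property
    def length(self) -> int:
        return int(self.emissions.shape[0])

    @property
    def ref_length(self) -> int:
        return int((self.ref_offsets >= 0).sum())

    def score(self, sequence: str) -> float:
        return score_sequence(self, sequence)

    def score_codes(self, codes: np.ndarray) -> float:
        total, _ = _kernels.profile_score(
            self.emissions,
            self.gamma,
            self.pairs[:, 0],
            self.pairs[:, 1],
            self.pair_emissions,
            codes,
        )
        return float(total)

    # -- serialization (bit-exact via hex floats) --------------------------

    def to_text(self) -> str:
        lines = ["#mirortho-model v1"]
        lines.append(f"mirna_id\t{self.mirna_id}")
        lines.append(f"L\t{self.length}")
        lines.append(f"gamma\t{float(self.gamma).hex()}")
        lines.append(f"s_ref\t{float(self.s_ref).hex()}")
        lines.append(f"n_training\t{self.n_training}")
        lines.append(f"ss_cons\t{self.consensus_structure or '.' * self.length}")
        lines.append(
            "ref_offsets\t" + ",".join(str(int(x)) for x in self.ref_offsets)
        )
        lines.append(f"n_pairs\t{self.pairs.shape[0]}")
        for p in range(self.pairs.shape[0]):
            lines.append(f"pair\t{int(self.pairs[p, 0])}\t{int(self.pairs[p, 1])}")
        for i in range(self.length):
            lines.append(
                "e\t" + "\t".join(float(x).hex() for x in self.emissions[i])
            )
        for p in range(self.pairs.shape[0]):
            flat = self.pair_emissions[p].ravel()
            lines.append("g\t" + "\t".join(float(x).hex() for x in flat))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "StructureProfileModel":
        header: dict[str, str] = {}
        pairs: list[tuple[int, int]] = []
        e_rows: list[list[float]] = []
        g_rows: list[list[float]] = []
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            key = fields[0]
            if key == "pair":
                pairs.append((int(fields[1]), int(fields[2])))
            elif key == "e":
                e_rows.append([float.fromhex(x) for x in fields[1:]])
            elif key == "g":
                g_rows.append([float.fromhex(x) for x in fields[1:]])
            else:
                header[key] = fields[1] if len(fields) > 1 else ""
        P = len(pairs)
        offsets = None
        if "ref_offsets" in header:
            offsets = np.array(
                [int(x) for x in header["ref_offsets"].split(",")], dtype=np.int64
            )
        return cls(
            mirna_id=header["mirna_id"],
            emissions=np.array(e_rows, dtype=np.float64),
            pairs=np.array(pairs, dtype=np.int64).reshape(P, 2),
            pair_emissions=np.array(g_rows, dtype=np.float64).reshape(P, 5, 5),
            gamma=float.fromhex(header["gamma"]),
            s_ref=float.fromhex(header["s_ref"]),
            n_training=int(header["n_training"]),
            consensus_structure=header.get("ss_cons", ""),
            ref_offsets=offsets,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "StructureProfileModel":
        return cls.from_text(Path(path).read_text())


def train_model(
    aln: TrainingAlignment,
    reference_sequence: str,
    alpha: float = 1.0,
    gamma: float = 2.0,
    mirna_id: str = "model",
) -> StructureProfileModel:
    """Estimate emissions from the training alignment.

    With m rows and column counts c_i(a) (gap rows excluded from the counts
    of their columns) the single-column emission is
    ``e_i(a) = log2(((c_i(a) + alpha) / (m + 4 alpha)) / 0.25)`` and the pair
    emission for paired columns (i, j) is the pointwise mutual information
    under the same Laplace smoothing.  ``S_ref`` is the ungapped reference's
    own score under the finished model.
    """
    reference_sequence = reference_sequence.upper().replace("U", "T")
    ref_row = next(
        (r for r in aln.rows if r.replace("-", "") == reference_sequence), None
    )
    if ref_row is None:
        raise ValueError("reference sequence is not a row of the alignment")
    ref_offsets = np.full(aln.n_columns, -1, dtype=np.int64)
    pos = 0
    for j, c in enumerate(ref_row):
        if c != "-":
            ref_offsets[j] = pos
            pos += 1
    m = aln.n_rows
    L = aln.n_columns
    cols = np.full((m, L), -1, dtype=np.int8)
    code = {c: k for k, c in enumerate("ACGTN")}
    for r, row in enumerate(aln.rows):
        for j, c in enumerate(row):
            cols[r, j] = code.get(c, -1) if c != "-" else -1
    emissions = np.empty((L, 5), dtype=np.float64)
    marg = np.empty((L, 4), dtype=np.float64)  # smoothed marginal probs
    for j in range(L):
        counts = np.zeros(4)
        for r in range(m):
            a = cols[r, j]
            if 0 <= a < 4:
                counts[a] += 1
        probs = (counts + alpha) / (m + 4 * alpha)
        marg[j] = probs
        emissions[j, :4] = np.log2(probs / _BACKGROUND)
        emissions[j, 4] = math.log2((alpha / (m + 4 * alpha)) / _BACKGROUND)
    P = len(aln.pairs)
    pairs = np.array(aln.pairs, dtype=np.int64).reshape(P, 2)
    pair_emissions = np.zeros((P, 5, 5), dtype=np.float64)
    for p, (i, j) in enumerate(aln.pairs):
        joint_counts = np.zeros((4, 4))
        for r in range(m):
            a, b = cols[r, i], cols[r, j]
            if 0 <= a < 4 and 0 <= b < 4:
                joint_counts[a, b] += 1
        joint = (joint_counts + alpha) / (m + 16 * alpha)
        for a in range(4):
            for b in range(4):
                pair_emissions[p, a, b] = math.log2(
                    joint[a, b] / (marg[i][a] * marg[j][b])
                )
        # N rows/columns carry no covariation information
        pair_emissions[p, 4, :] = 0.0
        pair_emissions[p, :, 4] = 0.0
    model = StructureProfileModel(
        mirna_id=mirna_id,
        emissions=emissions,
        pairs=pairs,
        pair_emissions=pair_emissions,
        gamma=gamma,
        s_ref=0.0,
        n_training=m,
        consensus_structure=aln.dot_bracket(),
        ref_offsets=ref_offsets,
    )
    model.s_ref = model.score(reference_sequence)
    if model.s_ref <= 0:
        logger.warning(
            "%s: reference score S_ref = %.2f <= 0; model is degenerate",
            mirna_id,
            model.s_ref,
        )
    return model


def score_sequence(model: StructureProfileModel, sequence: str) -> float:
    """Bits of the sequence under the model (two-stage: optimal gapped
    column alignment, then covariation bonus on matched pair columns)."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    return model.score_codes(encode_sequence(sequence.upper().replace("U", "T")))


# ---------------------------------------------------------------------------
# whole-reference model creation
# ---------------------------------------------------------------------------


def create_models(
    reference_genome: GenomeSequence,
    reference_annotation: GeneAnnotation,
    mirnas: Sequence[MirnaRecord],
    core_bundles: Sequence[CoreBundle],
    synteny_params: SyntenyParams | None = None,
    search_params: SearchEngineParams | None = None,
    alpha: float = 1.0,
    gamma: float = 2.0,
) -> tuple[dict[str, StructureProfileModel], "pd.DataFrame", dict[str, TrainingAlignment]]:
    """Collect positional orthologs from every core species, align, and train
    one model per reference miRNA.  Returns the models keyed by miRNA id, a
    per-miRNA training report, and the training alignments."""
    import pandas as pd

    synteny_params = synteny_params or SyntenyParams()
    search_params = search_params or SearchEngineParams()
    models: dict[str, StructureProfileModel] = {}
    alignments: dict[str, TrainingAlignment] = {}
    report_rows = []
    for mirna in mirnas:
        orthologs = []
        contributing = []
        for core in core_bundles:
            try:
                seq = collect_positional_ortholog(
                    mirna,
                    reference_annotation,
                    reference_genome,
                    core,
                    synteny_params,
                    search_params,
                )
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"core ortholog collection failed for {mirna.mirna_id} "
                    f"in {core.species}"
                ) from exc
            if seq is not None:
                orthologs.append(seq)
                contributing.append(core.species)
        sequences = [mirna.sequence] + orthologs
        ids = [mirna.mirna_id] + contributing
        with warnings.catch_warnings():
            if len(sequences) == 1:
                warnings.simplefilter("ignore")
                logger.warning(
                    "%s: no core ortholog found; training on the reference alone",
                    mirna.mirna_id,
                )
            aln = build_training_alignment(sequences, ids=ids)
        alignments[mirna.mirna_id] = aln
        models[mirna.mirna_id] = train_model(
            aln, mirna.sequence, alpha=alpha, gamma=gamma, mirna_id=mirna.mirna_id
        )
        report_rows.append(
            {
                "mirna_id": mirna.mirna_id,
                "n_core_orthologs": len(orthologs),
                "n_training_sequences": len(sequences),
                "core_species": ",".join(contributing),
            }
        )
    return models, pd.DataFrame(report_rows), alignments


def write_stockholm(aln: TrainingAlignment, path: str | Path) -> None:
    """Write the training alignment as Stockholm with a #=GC SS_cons line."""
    width = max(max(len(i) for i in aln.ids), len("#=GC SS_cons")) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n\n")
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f"{name.ljust(width)}{row}\n")
        fh.write(f"{'#=GC SS_cons'.ljust(width)}{aln.dot_bracket()}\n")
        fh.write("//\n")
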