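import math
from functools import lru_cache

import numpy as np
import pytest

from mirortho import _kernels
from mirortho.genomics_io import decode_sequence, encode_sequence
from mirortho.model_training import (
    StructureProfileModel,
    TrainingAlignment,
    build_training_alignment,
    global_align,
    score_sequence,
    train_model,
    write_stockholm,
)

HAIRPIN = "G" * 10 + "A" * 4 + "C" * 10


def profile_oracle(model, codes):
    """Exhaustive enumeration over all monotone column assignments; first
    maximum in (match, delete-column, insert) order, then pair bonus."""
    E, g, L, n = model.emissions, model.gamma, model.length, len(codes)
    best = [None]

    def rec(i, j, score, matched):
        if i == n and j == L:
            if best[0] is None or score > best[0][0]:
                best[0] = (score, tuple(matched))
            return
        if i < n and j < L:
            matched.append((j, codes[i]))
            rec(i + 1, j + 1, score + E[j][codes[i]], matched)
            matched.pop()
        if j < L:
            rec(i, j + 1, score - g, matched)
        if i < n:
            rec(i + 1, j, score - g, matched)

    rec(0, 0, 0.0, [])
    score, matched = best[0]
    md = dict(matched)
    for p in range(model.pairs.shape[0]):
        i, j = int(model.pairs[p, 0]), int(model.pairs[p, 1])
        if i in md and j in md:
            score += model.pair_emissions[p][md[i], md[j]]
    return score


def nussinov_oracle(seq, min_loop=3):
    """Maximum pairing count by exhaustive recursion with memoisation."""
    pairs = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}

    @lru_cache(maxsize=None)
    def rec(i, j):
        if j - i < 1:
            return 0
        best = max(rec(i + 1, j), rec(i, j - 1))
        if j - i - 1 >= min_loop and (seq[i], seq[j]) in pairs:
            best = max(best, rec(i + 1, j - 1) + 1)
        for k in range(i + 1, j):
            best = max(best, rec(i, k) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def random_dyadic_model(rng):
    """Random model with exactly-representable emissions, so alignment-score
    ties are exact regardless of summation order."""
    L = int(rng.integers(2, 9))
    E = np.round(rng.uniform(-2, 2, (L, 5)) * 1024) / 1024
    pairs = []
    used: set[int] = set()
    # sample a nested pairing by always nesting inside the previous pair
    lo, hi = 0, L - 1
    while hi - lo >= 1 and rng.random() < 0.6:
        pairs.append((lo, hi))
        used.update((lo, hi))
        lo, hi = lo + 1, hi - 1
    P = len(pairs)
    G = np.round(rng.uniform(-1, 1, (P, 5, 5)) * 1024) / 1024
    return StructureProfileModel(
        mirna_id="toy",
        emissions=E,
        pairs=np.array(pairs, dtype=np.int64).reshape(P, 2),
        pair_emissions=G,
        gamma=float(rng.choice([1.0, 1.5, 2.0])),
        s_ref=1.0,
        n_training=1,
    )


class TestGlobalAlign:
    def test_identical(self):
        assert global_align("ACGT", "ACGT") == ("ACGT", "ACGT")

    def test_gap_placement(self):
        a, b = global_align("ACGT", "AGT")
        assert a.replace("-", "") == "ACGT" and b.replace("-", "") == "AGT"
        assert len(a) == len(b) == 4


class TestBuildTrainingAlignment:
    def test_identical_sequences_gap_free(self):
        aln = build_training_alignment([HAIRPIN] * 3)
        assert aln.rows == [HAIRPIN] * 3
        assert aln.consensus == HAIRPIN

    def test_single_substitution_single_polymorphic_column(self):
        other = HAIRPIN[:5] + "T" + HAIRPIN[6:]
        aln = build_training_alignment([HAIRPIN, other])
        diff = [j for j in range(aln.n_columns) if aln.rows[0][j] != aln.rows[1][j]]
        assert diff == [5]

    def test_hairpin_folds_most_stem_columns(self):
        aln = build_training_alignment([HAIRPIN] * 2)
        assert len(aln.pairs) >= 8
        assert len(aln.pairs) == nussinov_oracle(HAIRPIN)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_training_alignment([])

    def test_reference_only_warns(self):
        with pytest.warns(UserWarning, match="degenerates"):
            build_training_alignment([HAIRPIN])

    def test_crossing_pairs_rejected(self):
        with pytest.raises(ValueError, match="nested|pair"):
            TrainingAlignment(
                rows=["ACGTACGT"], ids=["r"], pairs=[(0, 4), (2, 6)], consensus="ACGTACGT"
            )

    def test_nussinov_matches_exhaustive_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(6, 16))
            seq = decode_sequence(rng.integers(0, 4, n).astype(np.uint8))
            got = _kernels.nussinov_pairs(encode_sequence(seq), 3).shape[0]
            assert got == nussinov_oracle(seq)


class TestTrainModel:
    def test_single_row_emission_closed_form(self):
        with pytest.warns(UserWarning):
            aln = build_training_alignment([HAIRPIN])
        model = train_model(aln, HAIRPIN)
        # m=1, alpha=1: e(ref nt) = log2((2/5)/0.25)
        assert model.emissions[0, 2] == pytest.approx(math.log2((2 / 5) / 0.25), abs=1e-12)
        assert model.emissions[0, 2] == pytest.approx(0.678, abs=1e-3)

    def test_conserved_column_closed_form(self):
        aln = build_training_alignment(["AAAA"] * 4, min_loop=3)
        model = train_model(aln, "AAAA")
        # m=4, column all A: e = log2((5/8)/0.25) = 1.322
        assert model.emissions[0, 0] == pytest.approx(math.log2((5 / 8) / 0.25), abs=1e-12)
        assert model.emissions[0, 0] == pytest.approx(1.322, abs=1e-3)

    def test_reference_must_be_a_row(self):
        aln = build_training_alignment([HAIRPIN, HAIRPIN])
        with pytest.raises(ValueError, match="reference"):
            train_model(aln, "ACGT" * 6)

    def test_sref_is_reference_score(self):
        aln = build_training_alignment([HAIRPIN] * 3)
        model = train_model(aln, HAIRPIN)
        assert score_sequence(model, HAIRPIN) == model.s_ref
        assert model.s_ref > 0

    def test_adding_reference_copy_never_decreases_ref_emission(self):
        seqs = [HAIRPIN, HAIRPIN[:5] + "T" + HAIRPIN[6:]]
        m_small = train_model(build_training_alignment(seqs), HAIRPIN)
        m_big = train_model(build_training_alignment(seqs + [HAIRPIN]), HAIRPIN)
        codes = encode_sequence(HAIRPIN)
        for j, a in enumerate(codes):
            assert m_big.emissions[j, a] >= m_small.emissions[j, a] - 1e-12

    def test_mutated_sequence_scores_below_reference(self):
        aln = build_training_alignment([HAIRPIN] * 4)
        model = train_model(aln, HAIRPIN)
        mutated = "T" + HAIRPIN[1:]
        assert score_sequence(model, mutated) < model.s_ref


class TestScoreSequence:
    def test_empty_sequence_rejected(self):
        model = train_model(build_training_alignment([HAIRPIN] * 2), HAIRPIN)
        with pytest.raises(ValueError):
            score_sequence(model, "")

    def test_equals_exhaustive_enumeration_oracle(self, rng):
        for _ in range(80):
            model = random_dyadic_model(rng)
            codes = rng.integers(0, 4, int(rng.integers(1, 11))).astype(np.uint8)
            assert model.score_codes(codes) == profile_oracle(model, list(map(int, codes)))


class TestSerialization:
    def test_round_trip_bit_exact(self, rng):
        aln = build_training_alignment(
            [HAIRPIN, HAIRPIN[:4] + "T" + HAIRPIN[5:], HAIRPIN[:9] + "A" + HAIRPIN[10:]]
        )
        model = train_model(aln, HAIRPIN, mirna_id="mirX")
        back = StructureProfileModel.from_text(model.to_text())
        assert back.mirna_id == "mirX"
        assert np.array_equal(back.emissions, model.emissions)
        assert np.array_equal(back.pairs, model.pairs)
        assert np.array_equal(back.pair_emissions, model.pair_emissions)
        assert back.s_ref == model.s_ref and back.gamma == model.gamma
        assert back.consensus_structure == model.consensus_structure
        assert np.array_equal(back.ref_offsets, model.ref_offsets)

    def test_stockholm_output_parses(self, tmp_path):
        from Bio import AlignIO

        aln = build_training_alignment([HAIRPIN, HAIRPIN], ids=["ref", "ortholog"])
        write_stockholm(aln, tmp_path / "a.sto")
        parsed = AlignIO.read(tmp_path / "a.sto", "stockholm")
        assert [r.id for r in parsed] == ["ref", "ortholog"]
        assert str(parsed[0].seq) == HAIRPIN
        ss = parsed.column_annotations["secondary_structure"]
        assert ss.count("(") == len(aln.pairs)
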