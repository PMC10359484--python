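import shutil

import numpy as np
import pytest
from Bio import Align

from mirortho import _kernels
from mirortho.alignment_search import (
    LiftoverParams,
    SearchEngineParams,
    best_hit,
    confirm_by_reverse_search,
    external_local_search,
    liftover_mirna,
    local_search,
    parse_tabular_hits,
)
from mirortho.genomics_io import (
    GenomeSequence,
    GenomicInterval,
    MirnaRecord,
    decode_sequence,
    reverse_complement,
)


def random_seq(rng, n):
    return decode_sequence(rng.integers(0, 4, n).astype(np.uint8))


def sw_oracle():
    """Independent optimal-local-alignment oracle with the engine's scoring."""
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=2,
        mismatch_score=-3,
        open_gap_score=-5,
        extend_gap_score=-2,
    )
    return aligner


class TestLocalSearch:
    def test_exact_planted_query(self, rng):
        q = random_seq(rng, 60)
        backdrop = random_seq(rng, 5000)
        genome = GenomeSequence({"chr1": backdrop[:2000] + q + backdrop[2000:]})
        hit = best_hit(local_search(q, genome))
        assert hit.interval == GenomicInterval("chr1", 2000, 2060, "+")
        assert hit.identity == 100.0 and hit.coverage == 100.0

    def test_minus_strand_planting(self, rng):
        q = random_seq(rng, 60)
        backdrop = random_seq(rng, 4000)
        genome = GenomeSequence(
            {"chr1": backdrop[:1500] + reverse_complement(q) + backdrop[1500:]}
        )
        hit = best_hit(local_search(q, genome))
        assert hit.interval.strand == "-"
        assert hit.identity == 100.0
        assert hit.subject_sequence == q

    def test_absent_query_yields_no_hits(self):
        # subject shares no 11-mer with the query by construction
        subject = "A" * 600
        q = "CGTCGTCGTCGTCGTCGTCGTCGTCG"
        assert local_search(q, GenomeSequence({"c": subject})) == []

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            local_search("", GenomeSequence({"c": "A" * 100}))

    @pytest.mark.parametrize("length", [25, 40, 60])
    def test_planting_property(self, rng, length):
        """Any query >= 25 nt planted verbatim is found at full identity."""
        for _ in range(5):
            q = random_seq(rng, length)
            backdrop = random_seq(rng, 3000)
            pos = int(rng.integers(0, 3000 - length))
            genome = GenomeSequence({"c": backdrop[:pos] + q + backdrop[pos:]})
            hits = local_search(q, genome)
            cover = [
                h
                for h in hits
                if h.identity == 100.0
                and h.interval.start <= pos
                and h.interval.end >= pos + length
            ]
            assert cover, f"planted copy at {pos} not recovered"

    def test_mismatch_never_increases_score(self, rng):
        q = random_seq(rng, 60)
        backdrop = random_seq(rng, 2000)
        scores = []
        copy = list(q)
        for k in range(0, 6):
            genome = GenomeSequence(
                {"c": backdrop[:900] + "".join(copy) + backdrop[900:]}
            )
            hits = local_search(q, genome)
            scores.append(hits[0].bit_score if hits else 0.0)
            copy[10 + 7 * k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[10 + 7 * k]]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_tie_breaks_by_smaller_start(self, rng):
        q = random_seq(rng, 40)
        backdrop = random_seq(rng, 3000)
        genome = GenomeSequence(
            {"c": backdrop[:500] + q + backdrop[500:1800] + q + backdrop[1800:]}
        )
        hits = local_search(q, genome)
        assert len(hits) >= 2
        assert hits[0].bit_score == hits[1].bit_score
        assert hits[0].interval.start < hits[1].interval.start

    def test_agrees_with_smith_waterman_oracle(self, rng):
        aligner = sw_oracle()
        for _ in range(120):
            na, nb = int(rng.integers(30, 61)), int(rng.integers(30, 61))
            a = rng.integers(0, 4, na).astype(np.uint8)
            b = rng.integers(0, 4, nb).astype(np.uint8)
            wl = int(rng.integers(12, 25))
            w = rng.integers(0, 4, wl)
            a[: wl] = w
            pb = int(rng.integers(0, nb - wl + 1))
            b[pb : pb + wl] = w
            raw = _kernels.gotoh_local(a, b, 2, -3, 5, 2)[0]
            expected = aligner.score(decode_sequence(a), decode_sequence(b))
            assert raw == expected


class TestBestHit:
    def test_empty(self):
        assert best_hit([]) is None


class TestReverseConfirmation:
    @pytest.fixture()
    def reference(self, rng):
        backdrop = random_seq(rng, 6000)
        mirna_seq = random_seq(rng, 62)
        genome = GenomeSequence({"chr1": backdrop[:3000] + mirna_seq + backdrop[3000:]})
        mirna = MirnaRecord(
            "mir1", "fam1", GenomicInterval("chr1", 3000, 3062, "+"), mirna_seq
        )
        return genome, mirna, backdrop

    def test_self_sequence_confirms(self, reference):
        genome, mirna, _ = reference
        assert confirm_by_reverse_search(mirna.sequence, genome, mirna)

    def test_unrelated_locus_rejected(self, reference):
        genome, mirna, backdrop = reference
        assert not confirm_by_reverse_search(backdrop[100:162], genome, mirna)

    def test_paralog_best_hitting_decoy_rejected(self, rng):
        """A candidate closer to a planted decoy paralog than to the real
        locus best-hits the decoy and must be rejected."""
        backdrop = random_seq(rng, 9000)
        mirna_seq = random_seq(rng, 62)
        codes = np.frombuffer(mirna_seq.encode(), dtype=np.uint8)
        decoy = list(mirna_seq)
        for p in range(3, 62, 7):  # ~13% diverged decoy
            decoy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[decoy[p]]
        decoy = "".join(decoy)
        genome = GenomeSequence(
            {"chr1": backdrop[:3000] + mirna_seq + backdrop[3000:6000] + decoy + backdrop[6000:]}
        )
        mirna = MirnaRecord(
            "mir1", "fam1", GenomicInterval("chr1", 3000, 3062, "+"), mirna_seq
        )
        # candidate identical to the decoy: decoy locus wins the reverse search
        assert not confirm_by_reverse_search(decoy, genome, mirna)
        # candidate identical to the real miRNA still confirms
        assert confirm_by_reverse_search(mirna_seq, genome, mirna)


class TestLiftover:
    def _mirna(self, seq):
        return MirnaRecord("m", "f", GenomicInterval("ref", 0, len(seq), "+"), seq)

    def test_identical_locus(self, rng):
        seq = random_seq(rng, 60)
        backdrop = random_seq(rng, 2000)
        genome = GenomeSequence({"c": backdrop[:800] + seq + backdrop[800:]})
        iv = liftover_mirna(self._mirna(seq), genome)
        assert iv == GenomicInterval("c", 800, 860, "+")

    def test_low_identity_rejected(self, rng):
        seq = random_seq(rng, 60)
        copy = list(seq)
        # 7 substitutions in the first 40 nt (-> ~88% identity) leaving an
        # exact 20-nt tail so the seed stage still finds the locus
        for p in range(2, 37, 5):
            copy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[p]]
        backdrop = random_seq(rng, 2000)
        genome = GenomeSequence({"c": backdrop[:800] + "".join(copy) + backdrop[800:]})
        hits = local_search(seq, genome)
        assert hits
        assert all(h.identity < 90.0 or h.coverage < 80.0 for h in hits)
        assert liftover_mirna(self._mirna(seq), genome) is None

    def test_low_coverage_rejected(self, rng):
        seq = random_seq(rng, 60)
        backdrop = random_seq(rng, 2000)
        # only 60% of the query present (identity within the segment is 100%)
        genome = GenomeSequence({"c": backdrop[:800] + seq[:36] + backdrop[800:]})
        hits = local_search(seq, genome)
        assert hits
        assert all(h.coverage < 80.0 for h in hits)
        assert liftover_mirna(self._mirna(seq), genome) is None

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            LiftoverParams(min_identity=0)


class TestExternalAdapter:
    def test_parse_tabular(self):
        text = (
            "mir1\tchr5\t98.4\t100\t1001\t1062\tplus\t105.3\n"
            "mir1\tchr5\t91.0\t95\t2062\t2001\tminus\t80.1\n"
        )
        hits = parse_tabular_hits(text)
        assert hits[0].interval == GenomicInterval("chr5", 1000, 1062, "+")
        assert hits[1].interval == GenomicInterval("chr5", 2000, 2062, "-")
        assert hits[0].bit_score == 105.3 and hits[1].identity == 91.0

    def test_blastn_binary_roundtrip(self, rng, tmp_path):
        assert shutil.which("blastn"), "blastn expected on PATH"
        q = random_seq(rng, 60)
        backdrop = random_seq(rng, 1500)
        subject = backdrop[:700] + q + backdrop[700:]
        fa = tmp_path / "subject.fa"
        fa.write_text(f">chrT\n{subject}\n")
        hits = external_local_search(q, fa)
        assert hits, "external engine found no hit for a planted query"
        top = hits[0]
        assert top.interval.chrom == "chrT"
        assert top.interval.start == 700 and top.interval.end == 760
        assert top.identity == 100.0
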