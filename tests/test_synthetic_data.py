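import numpy as np
import pandas as pd
import pytest

from mirortho import _kernels
from mirortho.genomics_io import GenomicInterval, encode_sequence, extract_sequence
from mirortho.popvar import RegionClass, maf_fractions, snp_density
from mirortho.synthetic_data import (
    SimulationConfig,
    emit_variants,
    evolve_clade,
    generate_hairpin,
    write_bundle,
)


class TestGenerateHairpin:
    def test_default_dimensions(self, rng):
        seq, sub = generate_hairpin(25, 12, rng)
        assert len(seq) == 62
        assert sub == {"mature": (0, 22), "loop": (25, 37), "star": (40, 62)}

    def test_same_seed_identical(self):
        a, _ = generate_hairpin(25, 12, np.random.default_rng(7))
        b, _ = generate_hairpin(25, 12, np.random.default_rng(7))
        assert a == b

    def test_folds_as_hairpin(self, rng):
        for _ in range(5):
            seq, _ = generate_hairpin(25, 12, rng)
            pairs = _kernels.nussinov_pairs(encode_sequence(seq), 3)
            assert pairs.shape[0] >= 0.8 * 25

    def test_length_constraint_enforced(self, rng):
        with pytest.raises(ValueError):
            generate_hairpin(40, 12, rng)  # 92 nt > 70


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ValueError, match="loss_probability"):
            SimulationConfig(loss_probability=1.5).validate()

    def test_multiplier_ordering(self):
        with pytest.raises(ValueError, match="multipliers"):
            SimulationConfig(mature_multiplier=0.9, star_multiplier=0.2).validate()

    def test_error_lists_all_fields(self):
        with pytest.raises(ValueError) as exc:
            SimulationConfig(loss_probability=2.0, substitution_rate=-1.0).validate()
        assert "loss_probability" in str(exc.value)
        assert "substitution_rate" in str(exc.value)


class TestEvolveClade:
    def test_zero_rates_identical_species(self):
        cfg = SimulationConfig(
            seed=1, n_species=4, n_genes=40, n_families=4,
            substitution_rate=0.0, loss_probability=0.0, n_core_species=2,
        )
        b = evolve_clade(cfg)
        ref = b.reference_species
        for sp in b.species:
            for chrom in b.genomes[ref]:
                assert np.array_equal(
                    b.genomes[sp].codes(chrom), b.genomes[ref].codes(chrom)
                )
        assert len(b.truth) == 4 * 4
        assert (b.truth["copy"] == 1).all()
        assert b.truth["seed_identical"].all()

    def test_certain_loss_empties_non_reference_species(self):
        cfg = SimulationConfig(
            seed=2, n_species=4, n_genes=40, n_families=4,
            substitution_rate=0.0, loss_probability=1.0, n_core_species=2,
        )
        b = evolve_clade(cfg)
        t = b.truth
        # the reference lineage is protected; everything else is lost
        assert set(t["species"]) == {b.reference_species}
        assert len(t[t.species == b.reference_species]) == 4

    def test_wgd_doubles_retained_loci(self):
        cfg = SimulationConfig(
            seed=3, n_species=8, n_genes=80, n_families=6,
            substitution_rate=0.005, loss_probability=0.0,
            wgd_branches=("n05",), n_core_species=2,
        )
        b = evolve_clade(cfg)
        # balanced 8-leaf tree: n05 subtends sp05..sp08
        wgd_species = {"sp05", "sp06", "sp07", "sp08"}
        counts = b.truth.groupby(["species", "mirna_id"]).size()
        for (sp, _mid), n in counts.items():
            assert n == (2 if sp in wgd_species else 1)

    def test_truth_sequences_match_emitted_genomes(self):
        cfg = SimulationConfig(
            seed=4, n_species=8, n_genes=80, n_families=6,
            substitution_rate=0.01, loss_probability=0.1,
            duplication_probability=0.05, inversion_rate=0.5,
            wgd_branches=("n06",), n_core_species=2,
        )
        b = evolve_clade(cfg)
        assert len(b.truth) > 0
        for _, r in b.truth.iterrows():
            iv = GenomicInterval(r.chrom, r.start, r.end, r.strand)
            assert extract_sequence(b.genomes[r.species], iv) == r.sequence

    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(
            seed=9, n_species=4, n_genes=60, n_families=4,
            inversion_rate=0.3, duplication_probability=0.1, n_core_species=2,
        )
        a, b = evolve_clade(cfg), evolve_clade(cfg)
        for sp in a.species:
            for chrom in a.genomes[sp]:
                assert np.array_equal(a.genomes[sp].codes(chrom), b.genomes[sp].codes(chrom))
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_ortholog_tables_consistent(self, small_clade):
        for sp in small_clade.core_species:
            table = small_clade.ortholog_tables[sp]
            table.validate_against(small_clade.annotations[sp])

    def test_reference_mirna_table_matches_genome(self, small_clade):
        g = small_clade.genomes[small_clade.reference_species]
        for m in small_clade.mirnas:
            assert extract_sequence(g, m.interval) == m.sequence
            assert len(m.mature) == 22 and len(m.loop) == 12

    def test_gain_nodes_restrict_presence(self):
        cfg = SimulationConfig(
            seed=6, n_species=8, n_genes=80, n_families=4,
            substitution_rate=0.0, loss_probability=0.0, n_core_species=2,
            gain_nodes=(("fam01", "n02"), ("fam02", "sp01")),
        )
        b = evolve_clade(cfg)
        t = b.truth
        # balanced 8-leaf tree: n02 subtends sp01..sp04
        assert set(t[t.family_id == "fam01"]["species"]) == {"sp01", "sp02", "sp03", "sp04"}
        assert set(t[t.family_id == "fam02"]["species"]) == {"sp01"}
        assert set(t[t.family_id == "fam03"]["species"]) == set(b.species)

    def test_gain_node_must_cover_reference(self):
        cfg = SimulationConfig(
            seed=6, n_species=8, n_genes=80, n_families=4, n_core_species=2,
            gain_nodes=(("fam01", "n05"),),
        )
        with pytest.raises(ValueError, match="ancestral to the reference"):
            evolve_clade(cfg)

    def test_decoys_present_in_all_species(self):
        cfg = SimulationConfig(
            seed=7, n_species=4, n_genes=60, n_families=4,
            n_decoys=2, n_core_species=2,
        )
        b = evolve_clade(cfg)
        assert set(b.decoys["species"]) == set(b.species)

    def test_bundle_round_trips_through_files(self, tmp_path, small_clade):
        from mirortho.genomics_io import read_fasta, read_gff3, read_mirna_table

        write_bundle(small_clade, tmp_path)
        sp = small_clade.species[2]
        g = read_fasta(tmp_path / "genomes" / f"{sp}.fa")
        for chrom in small_clade.genomes[sp]:
            assert g.sequence(chrom) == small_clade.genomes[sp].sequence(chrom)
        ann = read_gff3(tmp_path / "annotations" / f"{sp}.gff3")
        assert len(ann) == len(small_clade.annotations[sp])
        mirnas = read_mirna_table(tmp_path / "mirnas.tsv")
        assert mirnas == small_clade.mirnas


class TestEmitVariants:
    def test_exact_density_and_maf_recovery(self):
        classes = {
            "mature": RegionClass("mature", [GenomicInterval("c", 0, 5000)]),
            "flank": RegionClass("flank", [GenomicInterval("c", 10000, 20000)]),
        }
        variants, expected = emit_variants(
            classes, {"mature": 2.0, "flank": 8.0}, maf_weights=(0.5, 0.3, 0.2)
        )
        mature = [v for v in variants if v.position < 5000]
        flank = [v for v in variants if v.position >= 10000]
        assert len(mature) == 10 and len(flank) == 80
        assert snp_density(classes["mature"], variants) == pytest.approx(2.0)
        assert snp_density(classes["flank"], variants) == pytest.approx(8.0)
        assert expected["mature"] == pytest.approx(2.0)
        fr = maf_fractions(flank)
        assert fr == pytest.approx((0.5, 0.3, 0.2))

    def test_configured_ordering_recovered(self):
        classes = {
            "mature": RegionClass("mature", [GenomicInterval("c", 0, 10000)]),
            "flank": RegionClass("flank", [GenomicInterval("c", 20000, 30000)]),
        }
        variants, _ = emit_variants(classes, {"mature": 1.0, "flank": 6.0})
        assert snp_density(classes["mature"], variants) < snp_density(
            classes["flank"], variants
        )
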