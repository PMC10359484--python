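# mirortho

Synteny-informed targeted search for microRNA orthologs in genome
assemblies, with no requirement for the target genomes to be annotated.

## The problem

MicroRNAs (miRNAs) are ~22 nt post-transcriptional regulators processed
from ~55–70 nt hairpin precursors (pre-miRNAs). Curated miRNA annotations
depend on multi-tissue small-RNA sequencing, so they exist for only a
handful of species; for everything else, the only practical route to a
miRNA catalogue is to search the genome sequence for orthologs of curated
reference miRNAs. Plain similarity search does this badly: pre-miRNAs are
short, their selective constraint is concentrated in the mature arm, and
paralogs and pseudogenes attract best hits away from the true ortholog.

`mirortho` addresses this with a two-stage pipeline:

1. **Model training via microsynteny.** For each reference pre-miRNA, a
   training set of high-confidence *positional orthologs* is collected from
   a small set of closely related "core" species: the protein-coding genes
   flanking the miRNA (its *syntenic anchors*) are mapped through pairwise
   ortholog tables into each core genome; a region is shared syntenic when
   the anchor orthologs lie on one chromosome with at most *k* genes
   between them (default *k* = 3, with up to *n* = 1 alternative anchors
   per side). A reciprocal best-hit search inside that region, confirmed by
   a reverse search against the reference genome, yields the ortholog. The
   training set is aligned, annotated with a consensus secondary structure,
   and used to train a sequence+structure scoring profile per miRNA.
2. **Targeted search.** Each target genome is scanned with the profile. In
   *quick* mode the search space is first narrowed to candidate regions: a
   similarity hit of the reference pre-miRNA extended by 1000 nt up- and
   downstream (~2 kb regions); *exhaustive* mode scans whole chromosomes.
   Candidate windows are accepted when they score at least 50% of the
   maximally achievable bit score — the reference sequence's own score
   S_ref under its model — and when a reverse search in the reference
   genome returns the reference miRNA as best hit. All confirmed hits for
   one miRNA are kept as co-orthologs, ranked by score.

The scoring model is a compact stand-in for a covariance model: per-column
nucleotide log-odds `e_i(a)` (bits against a uniform background), pairwise
covariation terms `g_ij(a,b)` for the paired columns of the consensus
structure, and a linear gap penalty γ. A sequence s scores

    S(s) = max_alignment Σ_i e_i(s_i) − γ·(#gaps)  +  Σ_(i,j)∈P g_ij(s_i, s_j)

and a hit is kept when `S(s) ≥ 0.5 · S_ref`. An adapter contract allows an
external search binary (e.g. BLAST+) to stand behind the similarity-search
stage.

Downstream modules reproduce the standard evolutionary analyses that such
ortholog catalogues feed: benchmark metrics against a gold-standard
location table (sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy,
F1), phylogenetic profile matrices, family-origin dating to the last common
ancestor of all carrier species, missing-data quantification, co-ortholog
spectra that flag whole-genome duplications, a concatenated supermatrix
(columns with >50% gaps removed) for phylogenomic inference by external ML
software, and SNP-density / minor-allele-frequency contrasts between miRNA
sub-regions and other genomic region classes.

A seeded synthetic-data generator (`mirortho.synthetic_data`) produces
complete fixtures — a species tree, genomes with conserved gene order,
planted hairpins evolving with substitutions, losses, tandem and
whole-genome duplications, inversions — together with an exact ground-truth
table, so every stage of the pipeline can be validated end to end.

## Worked example

Simulate an 8-species clade, train models from 3 core species, search all
genomes, and score the predictions against the simulator's ground truth:

```sh
mirortho simulate --seed 7 --out bundle --species 8 --genes 300 --families 10 --cores 3
# wrote bundle for 8 species to bundle
mirortho create-models --bundle bundle --out models
# trained 10 models -> models
mirortho search --bundle bundle --models models --out predictions --mode quick
# searched 8 species -> predictions
mirortho benchmark --predictions predictions --gold gold.tsv --out benchmark.tsv
# TP=69 FP=0 FN=0 TN=11 sensitivity=1.0000 specificity=1.0000 accuracy=1.0000 f1=1.0000
```

(`gold.tsv` here is the location subset of `bundle/truth.tsv`.) The counts
are per family × species cell: of the 8 species × 10 families, 69 cells
carry a surviving ortholog and all were recovered at the correct locus
(TP); 11 cells lost the miRNA along the simulated tree and the pipeline
correctly reported absence (TN). A prediction row records the locus, bit
score, score fraction relative to S_ref, co-ortholog rank and whether the
7-nt seed (mature positions 2–8) is identical to the reference:

```
mirna_id  family_id  target_species  chrom  start  end    strand  bit_score  score_fraction  seed_identical  rank
mir01     fam01      sp05            chr2   45007  45069  +       44.04      0.965           true            1
mir02     fam02      sp05            chr1   51445  51507  +       63.52      1.0             true            1
mir03     fam03      sp05            chr2   8569   8631   +       61.61      0.964           false           1
```

`mirortho profile`, `supermatrix` and `popvar` continue from the
prediction directory to profile matrices, a partitioned supermatrix
(FASTA + relaxed PHYLIP) and the SNP-density report.

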