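# Methods

This note documents the models and procedures implemented in `mirortho`,
the parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Coordinate model and formats

All coordinates are 0-based, half-open, with strand `+`/`-`. Conversion to
1-based inclusive coordinates happens only at the GFF3 boundary; BED output
is natively 0-based. Interval overlap is purely positional — strand is
ignored — because the benchmark's true-positive criterion is locus overlap,
and hairpins discovered on the opposite strand of the annotated locus are
still the same genomic element. Any overlap of ≥1 nt counts; no minimum
reciprocal overlap is required.

The miRNA input table is a TSV dialect with explicit sub-region columns
(mature, star, loop, two 30-nt flanks) in genomic coordinates; a column map
allows other dialects. Variants are read from VCF (CHROM, POS, AF), with
allele frequencies folded to minor allele frequencies `min(AF, 1−AF)`.

## Similarity search engine

The built-in engine is a seed-and-extend local aligner: exact word seeding
(word size 11), then an affine-gap Smith–Waterman (Gotoh) restricted to a
window around each seed cluster. Because the window always covers the full
extent a local alignment through the seed could reach, the reported raw
score equals the exact optimal local alignment score whenever a seed
exists; the test suite verifies this against an independent dynamic-
programming oracle. Scoring: match +2, mismatch −3, gap open −5 (first
gapped position), gap extend −2; bit score = (λ·S − ln K)/ln 2 with
λ = 0.625, K = 0.41. These are conventional nucleotide-search defaults;
they are parameters, not constants, and an external-binary adapter
(tabular fields `qseqid sseqid pident qcovs sstart send sstrand bitscore`)
can replace the engine for parity runs. Hits below 30 bits are suppressed;
ties sort by smaller subject start, then plus strand. No E-values are
computed anywhere — acceptance is by score rank and explicit cutoffs.

Reverse confirmation ("reciprocal best hit") accepts a candidate iff the
best hit of the candidate in the reference genome overlaps the reference
pre-miRNA locus by ≥1 nt. Annotation liftover between assemblies takes the
best hit passing ≥90% identity and ≥80% query coverage.

## Microsynteny

An intergenic miRNA is anchored by its flanking protein-coding genes (up
to n+1 per side, nearest first; default n = 1). A core-genome region is
shared syntenic when an anchor pair's orthologs share a chromosome with at
most k genes strictly between them in gene order (default k = 3). Anchor
pairs are tried nearest-first by (up-rank + down-rank, up-rank); the first
qualifying pair wins. Relative anchor orientation is ignored, so local
inversions are tolerated. An intragenic miRNA maps through its host gene's
ortholog; a host without an ortholog falls back to the intergenic logic.
The returned span includes the anchor genes and 100 nt of flank on each
side so hairpins at anchor edges are not clipped. Genes only partially
overlapping the miRNA are used neither as host nor as anchors.

## The sequence+structure profile ("mini-CM")

The model deliberately approximates a covariance model without the inside
algorithm or E-value calibration, trading statistical machinery for
desk-scale testability; the adapter contract allows an external CM toolkit
to stand behind the same interface, in which case its scores define S_ref.

Training: the positional orthologs plus the reference are aligned by an
iterative star alignment against the reference (match +1, mismatch −1,
gap −2; pluggable backend). The consensus structure is Nussinov maximum
base pairing (Watson–Crick + GU, minimum loop 3) on the column-majority
consensus, with majority-gap columns forced unpaired; the folder is also
pluggable. With m rows, Laplace pseudocount α = 1 and column counts
c_i(a) (gap rows excluded from their columns' counts):

    e_i(a)    = log2( ((c_i(a)+α)/(m+4α)) / 0.25 )                 [bits]
    g_ij(a,b) = log2( ((c_ij(a,b)+α)/(m+16α)) / (p_i(a)·p_j(b)) )  [bits]

where p_i(a) is the smoothed marginal. Scoring is two-stage: a global
alignment of the sequence to the model columns maximising Σe with a linear
γ = 2 bits per gap symbol (deterministic tie-break: match before column
deletion before insertion, leftmost first), then the covariation bonus for
every pair whose both columns matched. S_ref is the ungapped reference's
own score and is stored with the model; the 50% acceptance threshold is
applied as a fraction of S_ref, which preserves the decision rule under
any scoring backend even though absolute bit scales differ between
backends. Models serialize to a plain-text key-value + matrix format with
hexadecimal floats, so round trips are bit-exact; training alignments are
emitted as Stockholm with a `#=GC SS_cons` line.

The model records the registration of its columns on the ungapped
reference (`ref_offsets`). Scan windows have the reference's length, and
insertion columns contributed by a training ortholog are absorbed by the
alignment DP — this keeps the identity "score of the reference locus =
S_ref" exact even for models whose training alignment is wider than the
reference.

## Targeted search

Quick mode derives candidate regions from similarity hits of the reference
pre-miRNA, extended ±1000 nt, clipped and merged; exhaustive mode tiles
every chromosome (tiles of 2× the extension, overlapping by two hairpin
lengths, merged before scanning — equivalent to whole-chromosome scans).
Region scanning is filter-then-refine, the same layout real CM search
tools use: a vectorised gap-free profile sweep scores every window offset
on both strands, then the offsets within 5 bits of the acceptance
threshold (capped at 200 per strand, plus the top 5 unconditionally) are
rescored with the exact gapped DP. Windows have exactly the reference
length rather than a ±20% length range: the global aligner inside the
scorer absorbs small indels as paired insert+delete operations at 2γ
each, whereas longer windows would pay an unavoidable γ per surplus
nucleotide. Overlapping hits are deduplicated keeping the higher score
(across strands, since the reverse complement of a hairpin is again a
hairpin and can shadow the true strand). Hits at ≥ threshold·S_ref go to
reverse confirmation; survivors become co-ortholog predictions ranked by
score, ties by position. Seed status compares the 7 nt aligned opposite
mature positions 2–8 (1-based from the annotated mature 5′ end; the
offset convention is a documented choice).

The gap-free prefilter is a heuristic: a hit whose gap-free score sits
more than 5 bits below the threshold while its gapped score clears it
could in principle be missed. For hairpins without internal indels the two
scores coincide at the true locus, and the generator introduces indels
only through whole-locus events, so the filter is exact on the synthetic
benchmarks; on real data the margin and cap are parameters.

## Benchmarking

Counting is per family × species cell. Predictions are matched greedily in
descending score order, each consuming at most one gold entry of the same
family: overlap → TP, unmatched prediction → FP, unmatched gold → FN,
both sides empty → TN (one per empty cell). Metrics: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total, F1
2TP/(2TP+FP+FN); undefined denominators report as undefined rather than 0.
Two baselines are implemented: the naive unconditional best-hit caller,
and the whole-genome-alignment rule that calls a species present when its
block row covers ≥70% (inclusive) of the reference miRNA columns excluding
gaps.

## Profiles, dating, supermatrix

Profile matrices hold co-ortholog counts (0 = absent) with a seed status
per cell; family-level cells sum member counts and are seed-"identical"
if any member is. Family origins are dated to the LCA of the reference
plus all carrier species — for a tree this equals the LCA of the two most
distantly related carriers. Missing data is the fraction of zero cells
among species descending from the family's origin node. Co-ortholog
spectra bin presence counts into {1, 2, 3, ≥4}. The supermatrix
concatenates the rank-1 (best-scoring) co-ortholog per species per miRNA,
drops species represented in <20% of miRNAs, fills absences with all-gap
rows, and removes columns whose gap fraction strictly exceeds 50%;
partition tables map surviving columns back to miRNAs. Tree inference is
delegated to external ML software via FASTA/relaxed-PHYLIP/partition
outputs.

## Population variation

SNP density is (#variants in class / class length) × 1000 per kb, with a
variant at position p belonging to [start, end) iff start ≤ p < end; one
count per site. MAF bins: rare < 0.01%, uncommon < 1%, common ≥ 1%
(boundary inclusive in "common"). The two-sample contrast is a Welch
t-test on per-gene density vectors — the unit of observation is the
individual miRNA/gene, a documented choice.

## Synthetic data generator

The generator emulates the study design: a balanced or caterpillar species
tree (or user Newick), a root genome with protein-coding genes in fixed
order (default 300 nt genes, 200 nt spacers, 2 chromosomes), and hairpin
miRNAs planted intergenically (~70%) and intragenically (~30%). Hairpins
are 2×25 nt stems with a 12 nt loop (62 nt total), the 3′ arm the reverse
complement of the 5′ arm with ~10% GU wobble; mature = arm positions 1–22,
star = the complementary span, flanks = 30 nt of surrounding genome.

Evolution along each branch applies, in order: family gain filtering
(families are carried only by descendants of their planted gain node),
whole-genome duplication on designated branches (chromosome-set doubling
with independent subsequent divergence), gene-block inversions, losses
(whole-locus deletions; skipped on the reference lineage, so the reference
keeps the full complement a curated reference annotation would have),
tandem duplications (adjacent copy insertion), and Jukes–Cantor-style
substitutions at 1%/site/branch by default, scaled per hairpin sub-region
(multipliers mature 0.2 ≤ star 0.5 ≤ loop 0.8 ≤ flank 1.0, mirroring the
constraint gradient observed in real population data). Indels occur only
through whole-locus events, which keeps ground-truth checking
alignment-free and exact. Decoy pseudogenes (8% diverged copies with
evenly spaced substitutions, so seed words survive) can be planted at the
root in all species including the reference; they exercise the reverse-
search rejection and the naive-baseline contrast. Identical seeds yield
byte-identical fixtures; every event updates coordinates so the truth
table always matches the emitted FASTA exactly.

What the generator does **not** emulate: repeat landscapes (so the
repeat-driven candidate inflation seen for some real miRNAs is out of
reach of these tests), indel evolution within hairpins, selection beyond
the fixed rate multipliers, and assembly artefacts. Passing the synthetic
benchmarks therefore demonstrates the correctness of the pipeline's logic
under its stated assumptions, not its performance on repeat-rich or
low-quality real assemblies.

## Problem sizes used in the tests

The end-to-end suite simulates a 20-species clade with 3000 genes per
genome and 50 miRNA families (1%/site/branch substitutions, 5%/branch
loss, 4 core species); model training plus the quick search over all 20
genomes completes in well under ten minutes on one CPU. The
quick-vs-exhaustive consistency check runs the exhaustive scan on five of
the twenty species of that same clade, and the acceptance script on three
— the exhaustive scan is two orders of magnitude slower per genome, and a
species subset already covers every code path while keeping the default
runs compact. The WGD fixture (8 species, 20 families) disables stochastic
losses so the spectrum reflects duplication detection rather than the
simulator's erosion of second copies; the decoy fixture uses a high loss
rate (30%) to create the absent cells on which the naive baseline's false
positives become visible. Oracle-equivalence checks run on 1000 random
gene orders (synteny), 200 random profile models with ≤8 columns
(scoring; emissions quantised to 2⁻¹⁰ bits so optimal-alignment ties are
exact in floating point), and 500 random sequence pairs ≤60 nt sharing a
planted seed word (local alignment vs an independent Smith–Waterman
oracle).
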