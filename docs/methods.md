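# Methods

This note documents the models, algorithms, parameter choices and known
limitations of rflkit. It is written for users who want to understand what
each stage computes and what the synthetic-data tests do and do not
demonstrate about real data.

## Scientific setting

Cytoplasmic male sterility (CMS) in wheat carrying *Triticum timopheevii*
cytoplasm is caused by a chimeric mitochondrial open reading frame that
fuses the 5' part of a conserved gene (an *atp8*-like donor) to a novel,
hydrophobic-biased extension. Nuclear *Restorer-of-fertility* (*Rf*) genes
suppress the trait; in the grasses they are almost always
restorer-of-fertility-like (RFL) proteins of the P-class pentatricopeptide
repeat (PPR) family: tandem arrays of 35-residue helical repeats, each
repeat reading one RNA base through the residues at its positions 5 and 35
(the "PPR code"). A restorer binds the CMS transcript and induces cleavage
a short distance 3' of its binding site; in strand-specific RNA-seq the 5'
cleavage product is degraded and the 3' product persists, so the
fertile/sterile coverage ratio shows a sharp low-to-high step at the
cleavage position.

rflkit implements the computational chain that identifies such genes: ORF
screening, PPR motif annotation, identity clustering of capture panels into
orthogroups, phenotype-based candidate selection, mitochondrial genome
comparison, PPR-code binding-site prediction, and coverage-based cleavage
localisation. Every stage can be exercised end to end on synthetic inputs
with planted ground truth.

## Coordinates and sequence conventions

Internally all coordinates are 0-based half-open on the forward strand with
a strand flag; GFF3 (1-based inclusive) is converted at the I/O boundary
and human-readable reports print 1-based positions. DNA is canonicalised on
read (uppercase, U->T, N allowed); protein allows X and `*`. N and X are
neutral in all scoring (contribute 0) and never count as identities.

## ORF discovery

`find_orfs` reports, per frame and strand, every maximal stop-free
translated stretch between two stop codons or sequence ends
("between_stops", the getorf `-find 0` convention; default minimum 279 nt =
93 codons), or alternatively the first-ATG-to-stop reading of each stretch
("atg_to_stop"). ORF sizes are counted in coding codons, excluding the
terminating stop. Open-ended ORFs at contig edges are flagged rather than
dropped, because capture contigs truncate genes. Circular genomes are
handled by linearising with a min_nt-1 wrap pad and deduplicating wrapped
ORFs. The ">100 codons" mitochondrial screen is realised as
`min_codons_filter=101` (strict reading).

## PPR motif models and chaining

Motifs are modelled as ungapped fixed-length log-odds profiles (35 columns
for P; L and S profiles are also shipped), built from a consensus sequence
with tolerated-residue sets: the consensus residue scores 1.5, similar
residues 0.75, others -1.0, and the two base-specifying columns (5 and 35)
are unconstrained (0.25 for every residue) since they are under
diversifying selection in RFL proteins. PPR repeats are fixed-length and
ungapped, so position-specific scoring with a bit threshold (15.0 for P)
replaces a profile-HMM search; the thresholds sit roughly six standard
deviations above the random-window score distribution and recover planted
motifs exactly at the generator's mutation rates. Equivalent HMMER
E-value thresholds are tool-specific and cannot be transcribed directly;
the calibration here is against the synthetic study conditions
(741-790-codon proteins, 17-20 motifs, <=3% within-family divergence).

Overlapping hits are resolved by a dynamic program that maximises total
hit score plus an adjacency bonus (default 2.0) for consecutive hits with
an inter-motif gap of at most 2 residues, reflecting the tandem
organisation of RFL repeats; ties break toward more hits, then smaller
start-coordinate sum. The DP is tested against exhaustive subset
enumeration.

A protein is called RFL with >= 10 chained P motifs; full-length when it
additionally starts with M, has no internal stop and reaches 500 codons;
below 500 codons it is partial; otherwise truncated. Position-5/35
indexing is 1-based within the motif (protein offsets +4 and +34): an
off-by-one here corrupts every downstream binding-site prediction, which
is why the indexing is asserted in the unit tests.

## Orthogroup clustering and bait design

`greedy_cluster` mirrors CD-HIT's greedy longest-first strategy at a 96%
identity threshold: each sequence joins the first existing cluster whose
representative it matches at identity >= 0.96 over >= 105 alignment
columns with <= 60 residues of the shorter sequence unaligned; otherwise
it founds a cluster (a best-match mode is available). Every comparison is
a full affine-gap Smith-Waterman alignment (BLOSUM62, gap open 10 extend
1 for protein; +1/-2 with open 5 extend 2 for DNA; a gap of length L costs
open + L*extend). The traceback is deterministic: ties prefer diagonal
over vertical over horizontal moves, the path never crosses non-positive
cells, and the endpoint is the first maximal cell in row-major order.
Identity is matches / alignment columns. CD-HIT's word filter is not
reproduced; instead an admissible banded edit-distance bound (edlib) skips
pairs that provably cannot join — the screen is exact, so clustering
output is identical with it on or off, and is invariant to input order.

Capture baits tile each target with 95-nt probes every 36 nt, adding a
final probe flush with the target end whenever the tiling leaves an
uncovered tail; probes overlapping mask intervals are trimmed to their
longest unmasked stretch and kept only if >= 50 nt. (The flush rule
follows the worked tiling example for a 300-nt target: starts
0,36,...,180,205.)

## Candidate selection

Selection over orthogroups tests five named rules: presence of the group
in every restorer genotype (strict; an any-restorer relaxation exists
because single-accession capture data can miss a gene), absence of
full-length members from all non-restorer genotypes, placement inside the
genetically mapped interval (in/out/unknown from full-query infix
alignment against anchored reference contigs, with an ambiguity rule for
multi-locus hits), mode-specific provenance (an Rf1-type group must
contain a *T. timopheevii* member; an Rf3-type group must not contain a
*T. timopheevii* member 100%-identical over the full shorter length to a
restorer member — near-identical members do not disqualify), and a
length rule requiring a full-length (>= 500 codon) restorer member.
Presence and length are deliberately separate booleans so that a group
whose members are all sub-500-codon fragments passes the presence screen
and is then excluded by the length rule — the published Rf1 screen works
exactly this way, retaining two of four interval groups. The verdict is
the conjunction of the five rules, making it monotone: adding a
full-length member to a maintainer genotype can only demote a group.
Frameshift-split genes are flagged as pairs of partial members of
different groups lying within 1 kb on one contig in the same orientation.

## Mitochondrial genome comparison

Unique regions of genome A relative to genome B are found with a k-mer
screen (k = 31, both strands of B): runs of window starts whose k-mer is
absent from B are merged (gap < k), trimmed by k-1 per side and reported
at >= 50 nt. Anchor mode refines each raw run by locating the flanking
k-mers in B (required unique; otherwise k-mer boundaries are kept with a
warning) and extending exact matches inward, which recovers planted
insert boundaries exactly.

An ORF is lineage-specific when no single placement of the whole ORF in
the other genome reaches 0.95 x 0.95 edit similarity (edlib infix mode;
gaps and end-trimming both count against the score, so this lower-bounds
identity x coverage of the best local alignment). A chimera whose donor
prefix is shared but whose extension is not therefore remains specific.

Chimera annotation compares leading codons (codon-exact) against each
candidate donor CDS; the donor is the CDS with the longest identical
leading run (ties to the longest CDS). Codon bookkeeping: the ORF's codon
count excludes its stop codon, while the unique region is a genomic
interval that normally contains the stop — a chimera with a 96-codon
donor prefix and a 552-nt unique region is a 279-codon ORF (96 + 183
coding) whose unique region holds 184 codons (183 + stop). Both tallies
are reported.

## PPR-code binding-site prediction

The shipped code table maps (position-5, position-35) residue pairs to
per-base affinity vectors over A/C/G/U encoding the established
correspondences (T/N -> A, T/D -> G, S/N -> A, S/D -> G, N/D -> U over C,
N/N and N/S -> pyrimidines, with flatter vectors for weaker combinations);
the exact affinities derive from published in vitro binding work and every
value can be overridden from a TSV. Combinations absent from the table
score a uniform pseudo affinity (0.05), as do N bases. A window is scored
as the sum of natural-log affinities, motif i (N-terminal to C-terminal)
against base i (5' to 3'); all windows are scored and ranked (ties to the
left-most start), so a protein with 20 motifs predicts a 20-nt site. All
P-class pairs are scored (whether a C-terminal subset should be used is
not settled; scoring all pairs is the default). Scores are invariant to
T/U representation. A predicted site is called consistent with a cleavage
position when the cleavage lies 0-100 nt 3' of the site end.

## Expression and coverage analysis

Size factors use the DESeq2 pseudoreference: per-gene geometric means
across samples (genes with any zero excluded), per-sample median of
count/pseudoreference ratios taken in linear space. TPM is
length-normalised rate scaled to 1e6 per column. Fertile/sterile
contrasts are log2 ratios of size-factor-normalised counts with a 0.5
pseudocount, row-ordered by average-linkage hierarchical clustering on
Euclidean distances (scipy leaf order). Sample PCA is an SVD of
feature-centred log2(normalised+1) values.

Coverage tracks are normalised to unit mean over unmasked positions
(masks — rRNA and plastid-identical regions — are consumed as input, not
recomputed); the pre-normalisation mean is retained so depth gates can be
applied on the raw scale; normalisation is idempotent. Cleavage detection
scans the per-base ratio r = (fertile + 0.05)/(sterile + 0.05) in
transcript 5'->3' orientation with the two-window statistic
s(i) = mean r[i, i+w) / mean r[i-w, i) (w = 50 nt) and calls the argmax
boundary; a call passes at fold >= 3 with >= 10x raw sterile depth in
both windows. Because neighbouring statistics share w-1 of their w
positions, the argmax is localised to within ~2 nt at 100x depth; the
quoted resolution is therefore +/- 2 nt, and coverage-only calls cannot
be sharper than that without 5'-end sequencing.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of (parameters, seed) and emits a
machine-readable truth sidecar. Defaults encode the study conditions:
capture panels of 741-790-codon RFL proteins with 17-20 P motifs,
within-family identity >= 97% and between-family <= 90%, a six-genotype
panel (three restorer accessions, a *T. timopheevii* line, two
maintainers) in which one family is full-length only in restorers; a
genome pair differing by a 96-codon-prefix/552-nt-extension chimera plus
nine further specific ORFs of 101-200 codons (ten in all) on a 40-kb
backbone — a deliberately scaled-down stand-in for a ~440-kb
mitochondrial genome, chosen to keep the full suite fast while leaving
every length scale (k-mers, ORFs, windows) realistic; coverage at 100x
with fold-5 steps; negative-binomial counts (dispersion 0.05) with planted
fertile/sterile blocks and lognormal library sizes.

Family mutation is substitution-only by default so identity arithmetic is
exact; codon swaps never create stops and never touch the start codon.
Inserted cassettes are wrapped in a 12-nt palindromic stop block
(stops in all six frames) so no incidental reading frame can cross an
insert junction, and constructions are re-drawn deterministically if an
incidental lineage-specific ORF would still arise; insert boundary bases
are constrained to differ from the reference continuation so planted
interval recovery is exact rather than +/- 1.

Not emulated: read-level noise (FASTQ, sequencing error, capture bias),
indels and rearrangements (an indel mutation mode exists but is off by
default), paralog gene conversion, substoichiometric mitochondrial
shifting, and multi-copy repeats. Passing the planted-recovery suite
therefore demonstrates algorithmic correctness under the stated
statistical structure, not robustness to assembly artefacts or
repeat-induced ambiguity in real capture data.

Chosen test scales (each stated where used): size-factor recovery is
checked on 500-gene matrices because median-of-ratios normalisation is a
transcriptome-scale procedure — on a 44-transcript mitochondrial matrix
its sampling error is inherently several percent; block-contiguity of the
ratio clustering is checked at a 6-fold planted effect, matching the
near-silencing of suppressed CMS ORFs rather than marginal 2-fold
changes.

## Pipeline and reproducibility

The `run` workflow executes the nuclear chain (annotate -> cluster ->
select) and the mitochondrial chain (ORF screen -> genome comparison ->
binding sites -> cleavage calls) single-process and deterministically:
identical config and seed produce byte-identical report tables (timings
live only in the log). Configs are TOML with unknown keys rejected; the
resolved config is echoed into the report directory.
`scripts/acceptance.py` regenerates all study-condition inputs from a
seed and recomputes the headline quantities end to end.

## Known limitations

* Motif profiles are consensus-derived, not fitted to curated alignments;
  they are calibrated for RFL-like P arrays, and sensitivity for divergent
  PLS-class architectures is untested.
* The code table's affinity magnitudes are schematic (ordering, not Kd
  scale); predictions rank candidate sites but do not estimate binding
  energies.
* `place_in_interval` uses whole-gene infix alignment; it does not model
  split placements across scaffold boundaries.
* Genetic-map intervals are consumed as physical coordinates; no linkage
  analysis is performed.
* The specificity test reduces "absent from all other genomes" to one
  pairwise comparison; multi-genome intersection is a loop the caller
  writes.
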