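# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the numerical details a user extending the package should know.

## Coordinates and formats

All genomic coordinates are stored internally 0-based half-open (BED
arithmetic). Formats with 1-based positions — SNP and association tables,
RepeatMasker `.out` — are converted exactly once at the file boundary, on
read, and converted back on write. Aligned FASTA rows are checked for equal
length on read and a ragged record is a hard error naming the offender.
RepeatMasker `.out` is parsed by whitespace splitting after its three header
lines, keeping query, begin/end and the class/family label; an unrecognised
repeat-class token produces a warning but the record is kept, since class
vocabularies drift between RepeatMasker releases.

## ORF evolution analysis

Codon indices are 1-based over the amino acids of the reference ORF, with
the stop codon at index n+1; this matches the "amino acid position k"
convention used when describing cross-species events. Only the three forward
frames are scanned: inputs are transcripts or pre-oriented genomic slices.
The standard nuclear genetic code is used throughout; any codon containing N
is excluded from stop and synonymy calls.

Projection of the reference CDS through the alignment assigns, to each
reference codon, the species bases aligned to its three columns plus any
bases in columns where the reference row is gapped ("insertions", attached
after the codon position they follow). Disabler detection then walks the
codons in order:

- a premature stop is reported at every gap-free, N-free codon that
  translates to a stop while the cumulative net indel length upstream is
  0 mod 3 (after an uncompensated frameshift the reading frame is undefined,
  so stop calls are suppressed until the frame is restored);
- a frameshift is reported at every codon whose net indel length is not
  0 mod 3; when a species' total net indel over the CDS restores frame, its
  frameshift events are flagged `compensated` but still reported.

Enabler inference votes an ancestral state per codon over the non-focal
species and reports positions where that state is a disabler while the focal
state is not. The vote requires a **strict majority** (more than half of the
non-focal species sharing one state); a tie or mere plurality leaves the
state unknown and the position is skipped. Plurality voting was rejected
because a derived disabler shared by a two-species clade can become the
plurality state once background substitutions scatter the remaining
outgroups, producing a spurious "enabler" at the focal lineage; strict
majority cannot be fooled this way and reduces to the intuitive 2-of-2,
3-of-4 … rule.

One wording ambiguity is inherited from the domain: an ORF described as
"k codons" is stored as n_codons = k amino acids plus a stop, so its CDS
length is 3·(k+1) bp (a 194-amino-acid ORF has a 585-bp CDS).

## Splice junctions and Dollo parsimony

A junction is canonical iff its intron begins GT and ends AG. Classification
reads the terminal dinucleotides of a pre-oriented intron slice: a gapped or
N terminus, or fewer than four ungapped bases in the slice, yields `unknown`;
an entirely gapped slice yields `absent`. No reverse-complementing is
performed — alignments are presented in gene orientation.

Gain placement assumes a junction is gained once and lost any number of
times (Dollo). Every branch is scored as the putative gain point: a branch
is admissible iff its clade contains all carrier species, and its cost is
the number of known non-carrier leaves inside the clade (unknown-state
leaves are compatible with both presence and absence and never create
losses). Admissible clades form a chain from the carriers' MRCA to the root,
so the minimum-cost solution is found exactly; when several branches tie
(possible only through unknown-state leaves) the most rootward one is
reported and the result is flagged ambiguous.

## Repeat overlap

Coverage is computed per base on the merged union of repeat intervals, never
by summing per-repeat lengths, because overlapping RepeatMasker hits are
common. The "ORF" fraction of a gene model is computed over the spliced CDS
(the CDS span restricted to exons). A family filter (e.g. `Alu`) matches a
component of the `class/family` label case-insensitively; a filter matching
nothing returns 0 with a warning rather than an error.

## Population genetics

Estimators take the number of sampled chromosomes n (two per diploid), and
the reference sample size used throughout the worked examples is n = 180
(90 individuals). π uses the unbiased n/(n−1) correction. Nei–Gojobori site
counts are reported unrounded; their sum equals the CDS length exactly, by
construction (changes to or from stop codons never count as synonymous).

The segregating-sites distribution is computed by convolving the per-level
geometric mutation counts Q_k in ordinary double precision. Truncation of
the support is exact — P_n(s) for s ≤ s_max never consults higher terms —
and when no s_max is given the support is grown (starting past the mean plus
twelve standard deviations) until cumulative mass 1 − 10⁻¹² is captured,
then trimmed to the smallest sufficient s_max, with the remainder carried as
`tail_mass`. At n = 180, θ ≈ 1 no underflow occurs; the normalisation and
mean identities (Σ P + tail = 1, Σ s·P = θ·a_{n−1}) are verified to 10⁻⁹ in
the tests over (n, θ) ∈ {2, 10, 50, 180} × {0.1, 1, 5}.

The constraint test reports the lower tail P(S ≤ S_obs) by default.
Inclusive and exclusive conventions are both exposed (`inclusive=False`,
`--exclusive`); the inclusive tail is the default because it is the
conservative choice for a test of *deficient* polymorphism. The null rate
for the nonsynonymous test is the synonymous per-site rate times the
nonsynonymous length.

Sliding-window diversity tiles windows from position 0 (defaults: 100-bp
window, 25-bp step, both configurable since published track parameters are
rarely stated); the final partial window is scored over its true length.

## Candidate screen

The gene span is the transcript extent including UTRs (an associated SNP in
a 3'UTR counts as inside the gene), with configurable promoter padding
defaulting to 0. Significance thresholds are per-study inputs, never
hard-coded. Two convergence modes are exposed: `any_snp` (each association
study satisfied by some significant SNP in the span) and `same_snp` (one
common SNP significant in every study); `same_snp` results are provably a
subset of `any_snp` results. LD r² is computed from phased haplotype
frequencies; a monomorphic comparison SNP has undefined r² and is reported
as missing rather than 0. Feature annotations (exon/UTR/intron/intergenic,
miRNA-site labels) are inputs, not predictions.

## Synthetic data: what it emulates, and what it does not

The coalescent simulator implements the standard neutral model, time in
units of 2N generations: waiting time k(k−1)/2 between coalescences,
mutations Poisson at θ/2 per lineage per unit time under infinite sites,
derived counts equal to subtended leaf counts. This matches the recursion's
parameterisation exactly, so simulator and recursion serve as oracles for
each other, and the simulator is additionally cross-checked against msprime
in the unit tests. No recombination, selection or demography is modelled —
the tests therefore validate the estimators and the neutral null, not
robustness to demographic misspecification. A topology-free sampler of S
(using L = Σ k·T_k) is provided for bulk draws and is checked in law
against the full simulator.

Region fixtures draw each site class's SNPs from one genealogy at region
rate θ·l with uniform distinct positions in the class's coordinate block.
The estimator-recovery check runs 10,000 replicates per class at n = 180
with six 2,000-bp classes at a genome-typical background rate of
1.2×10⁻³/site; this region-scaled θ ≈ 2.4 makes the Monte-Carlo standard
error of the 10,000-replicate mean comfortably smaller than the 2%
recovery band being verified (a power consideration fixed before running,
not a tuning knob).

Ortholog fixtures evolve an annotated ancestral sequence down a phylogeny
under Jukes–Cantor background substitution (probability
¾(1−e^{−4rt/3}) per site per branch) with **no background indels**; planted
events — substitutions, premature stops, frameshifting indels, junction
gains/losses — are applied on named branches after background mutation, so
they override it, and insertions open true gap columns in all other rows.
The generative alignment is therefore exact, sidestepping aligner error
entirely; conclusions about robustness to *alignment* error are outside what
these fixtures can show. Background substitutions are rejected when they
would create or destroy an in-frame stop codon (read in the reference
frame), alter the ORF's start codon, or touch an annotated junction
dinucleotide: this guarantees the planted events are the only frame- or
junction-relevant differences between species, which is what makes the
zero-false-call recovery checks meaningful. Deletions planted at a codon
start after its first base — the same slot insertions occupy — so a focal
deletion exactly reverts a rootward insertion, reproducing the classic
"GGAA ancestral / G−AA focal" configuration at the same codon index.

Every generator is deterministic given (parameters, seed); stochastic tests
fix seeds and use 3-standard-error tolerances.

## Problem sizes in the validation suite

The suite verifies the recursion against 50,000 coalescent replicates at
(n = 20, θ = 5) per s ≤ 30; estimator recovery over 10,000 replicates per
class as above; plant-and-recover over 100 random five-primate fixtures
(plus the canonical stop-escape/indel configuration at codons 28 and 106);
Nei–Gojobori conservation over 1,000 random CDSs and all 61 sense codons;
and the screen over 20 fixture seeds. These sizes give per-check Monte-Carlo
error well inside each tolerance while keeping the whole suite under a
minute on one CPU.

## Known limitations

- Alignments are inputs; the package neither builds nor refines them.
- Dollo parsimony reports presence/absence gains only — no ancestral
  sequence reconstruction and no splice-strength scoring.
- The constraint test conditions on the null θ as known; uncertainty in the
  synonymous rate estimate is not propagated.
- Repeat fractions depend on the annotation supplied; reproducing published
  percentages requires the same genome assembly and RepeatMasker run.
- The screen implements the gene-level convergence filter only; upstream
  locus-level meta-analysis of mapping studies is out of scope.
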