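# denovogene

A toolkit for identifying and validating **species-specific de novo
protein-coding genes** — genes that arose from previously noncoding DNA on a
single lineage — from genetic mapping data, cross-species sequence
alignments, and population resequencing.

It is aimed at evolutionary and statistical geneticists who want to re-run,
on their own candidates, the computational workflow behind this class of
discovery:

1. **Convergence screen** (`denovogene.screen`) — find genes supported by
   *every* supplied genome-wide association study and *every* linkage study,
   that also carry a complete open reading frame with no identifiable
   homologues; rank linked SNPs (r² ≥ 0.8 with the index SNP) with
   exonic/UTR variants first.
2. **ORF evolution** (`denovogene.orf`) — scan transcripts for ORFs, project
   the reference CDS through an ortholog alignment, and report
   *frame-disrupting features* (premature stops, frameshifting indels) in
   other species together with the focal-lineage *enabler substitutions*
   that removed them (e.g. an ancestral TAG read as TGG only in the focal
   species).
3. **Splice-junction origination** (`denovogene.splice`) — classify each
   intron's donor/acceptor dinucleotides per species (GT–AG rule) and place
   the junction's gain on a phylogeny by Dollo parsimony.
4. **Repeat contribution** (`denovogene.repeats`) — per-base merged coverage
   of exons and the spliced CDS by annotated repeat elements such as Alu.
5. **Population-genetics constraint** (`denovogene.popgen`) — per-site-class
   polymorphism summaries and an exact neutrality test on the number of
   segregating sites.
6. **Synthetic data** (`denovogene.simulate`) — a neutral coalescent
   simulator and generative ortholog-alignment/screen fixtures with known
   ground truth, used to validate every stage.

## The statistics at the core

For a sample of *n* chromosomes with *S* segregating sites over *l*
surveyed bases, Watterson's estimator of the per-site population mutation
rate is

θ̂_W = S / (a_{n−1} · l),  a_{n−1} = Σ_{i=1}^{n−1} 1/i,

and nucleotide diversity is the unbiased average pairwise difference per
site, π̂ = Σ_j 2p_j(1−p_j) · n/(n−1) / l. Coding sites are partitioned into
synonymous and nonsynonymous fractions by Nei–Gojobori counting (each codon
position contributes f/3 synonymous sites, f = number of the three possible
single-base changes preserving the amino acid).

The constraint test uses the exact neutral distribution of S, computed by a
dynamic-programming recursion over the number of ancestral lineages: while
*k* lineages remain the number of mutations is geometric,

Q_k(i) = ((k−1)/(k−1+θ)) · (θ/(k−1+θ))^i,

and P_n(s) is the (n−1)-fold convolution P_k(s) = Σ_i Q_k(i)·P_{k−1}(s−i)
with P_2 = Q_2. The lower tail p = Σ_{s=0}^{S_obs} P_n(s), evaluated at a
null rate θ (per site × region length), measures whether a region harbours
significantly fewer polymorphisms than the null predicts — the signature of
purifying selection on a small putative protein.

## Worked example

A resequenced candidate locus in 90 diploid individuals (n = 180
chromosomes) shows S = 2 over its 434 nonsynonymous sites, while its 151
synonymous sites (S = 2) give a per-site rate of 2.2965×10⁻³:

```pycon
>>> import denovogene as dg
>>> dg.watterson_theta(4, 585, 180)          # whole CDS, theta/site
0.0011855630137151984
>>> theta_syn = dg.watterson_theta(2, 151, 180)
>>> dg.hudson_constraint_test(2, 434, theta_syn, 180)
0.09821964982699584
```

Under neutrality the nonsynonymous region would carry a mean of
θ·a₁₇₉ ≈ 5.75 segregating sites; observing ≤ 2 has probability ≈ 0.1 —
marginal evidence of protein-level constraint despite the small target.
The same test is available from the shell:

```
$ denovogene hudson-test --s-obs 2 --length 434 --theta-null 2.29e-3 --n 180 --digits 1
p = 0.1
```

The full constraint workflow (per-class diversity table, then the test of
the nonsynonymous class against the synonymous rate) runs as
`denovogene pipeline --config run.cfg`, and every stage has its own
subcommand (`orf-scan`, `disablers`, `splice-evo`, `repeat-overlap`,
`popgen`, `screen`, `ld`, `simulate ...`); each writes a provenance
manifest alongside its output.

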