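# Methods

This note records the models, defaults and numerical choices behind
`agorip`, and what the synthetic benchmarks do and do not establish.

## Scope and coordinates

The toolkit analyses AGO RIP-seq experiments: a UV cross-linked
immunoprecipitated library (RIP) against an IgG background control, for
both small-RNA and mRNA fractions. All genomic coordinates are 0-based,
half-open (BED-native) throughout; FASTQ qualities are Phred+33 only.
Paired-end handling is out of scope: mates are treated as independent
single reads upstream of this toolkit.

## Preprocessing

The cleanup cascade runs in a fixed order — N-filter → adapter clip →
3′ quality trim (Q20) → length filter (16 nt) — with chained per-stage
counts. Adapter clipping uses exact prefix matching with a minimum overlap
of 6 nt and no mismatches: deterministic, conservative, and easy to verify
by brute force. Quality trimming is strictly 3′-terminal; internal
low-quality bases are retained. Both the adapter sequence and every
threshold are flags; the defaults (TruSeq small-RNA adapter, Q20, 16 nt,
overlap 6) are the values a small-RNA pipeline of this design would use,
since real protocols vary in the adapter and rarely report overlap
settings.

## Alignment

Reads map to toy references by Hamming distance only (no indels: at sRNA
lengths and with mismatch-only parameters the substitution space is the
relevant one). The mapper seeds each read with `max_mm + 1` disjoint
segments over an exact k-mer index; by pigeonhole every placement within
the budget has an exact seed, so seed-and-verify is lossless. Reporting is
best-stratum: all placements at the minimal achieved mismatch count, never
the full ≤ `max_mm` set. Ceilings: 2 mismatches genomic, 1 mismatch against
the mature-miRNA catalog; a read may exceed the mature by up to 2 nt
(untrimmed templated ends). Multi-mappers: the mRNA pipeline discards them
(ambiguity removal before unique-read collapsing); the sRNA default is
fractional weighting (1/n per placement) because phasiRNA loci are
repetitive and discarding would bias locus counts; both are switchable.
There is no spliced alignment and no FM index — the design targets
kilobase-to-megabase toy references, with a brute-force scan as the test
oracle.

## Profiling

Length distributions cover 16–35 nt with an explicit `other` bin.
Composition matrices report per-position A/C/G/U fractions (T as U) over
reads of one length; row 1 is the 5′-nucleotide composition that AGO
sorting biases act on. PhasiRNA assignment requires full containment of
the hit interval in the locus and exact equality of read length and locus
class (21 or 24), on either strand — phasiRNAs derive from double-stranded
precursors, so no strand rule is imposed. Every summary fraction names its
denominator in metadata ("fraction of 21-nt reads on loci" vs "fraction of
all reads"), because the two are easy to conflate. TPM uses, by default,
the total count assigned to the quantified feature space (so TPM sums to
10^6); an explicit total (e.g. all clean reads) can be supplied and is
recorded in the output metadata. RPKM is `count · 10^9 / (span · total)`.

## Enrichment

RIP/IgG comparisons are per-feature `log2((A + c)/(B + c))` with
pseudocount `c = 1` (TPM units) — zero handling is otherwise undefined
when libraries are compared directly. Replicate-level proportion
differences use a two-sample t-test. Welch's unequal-variance form is the
analysis default (the safer assumption). A caveat measured here and worth
knowing: with only 2 replicates per group, Welch's Satterthwaite degrees
of freedom fall below the pooled value and the test becomes conservative
(type-I rate ≈ 2% at nominal 5% over 10^4 null simulations), while the
pooled form is exact at the nominal level under equal variances. The
calibration check therefore asserts the pooled flavor at 5% ± 1.5% and
Welch at ≤ 5%; with 2 replicates, Welch p-values err on the safe side.

## Peak calling

The mRNA path collapses single-location hits into unique reads, merges
overlapping (≥ 1 nt, same strand; book-ended intervals stay separate)
unique reads into clusters, and scores clusters per host gene against an
"in silico random IP" null: each of R = 500 repeats re-places the gene's
observed reads (same count, same length multiset) uniformly over the
gene's exonic span and records the maximum cluster read count. The
empirical FDR of a cluster of height h is the survival fraction of the
per-repeat maxima at h; ties share their FDR, with no interpolation. The
raw null is always exported so alternative readings (e.g. per-height
cluster-count expectations) can be recomputed. Design choices made where
the method was genuinely open:

- **Randomization space**: per gene, uniform over its concatenated exonic
  (transcript) coordinates — the minimal faithful null preserving the
  gene's read count and lengths. Observed clusters are merged in genomic
  coordinates; since only maximum cluster counts are compared, ignoring
  intron gaps in the null can only make it slightly more permissive to
  merging, i.e. conservative for calling.
- **IgG combination**: IgG evidence enters as a post-hoc interval filter —
  `(RIP + 1)/(IgG + 1) ≥ 2` over the peak interval, same strand — rather
  than subtracting IgG reads before clustering. This keeps the permutation
  null pure and the IgG counts auditable on every peak. Both the ratio and
  the pseudocount are flags; no library-size normalization is applied, so
  RIP and IgG libraries should be of comparable depth (as the simulated
  pairs are).
- **Bound genes** are genes hosting ≥ 1 significant peak (FDR ≤ 0.01 and
  ratio passed). Overlap of bound genes with externally predicted miRNA
  targets is summarised with an exact hypergeometric test over the gene
  universe; target prediction itself is external and only its output table
  is read.

## The synthetic-data generator

The generator exists so every stage is testable against ground truth
without downloads; its defaults are the study conditions the analysis is
meant for (a maize premeiotic-tassel-like composition):

| parameter | default | meaning |
| --- | --- | --- |
| length mixture | 21 nt: 0.15, 24 nt: 0.47, rest uniform 16–35 | 24-nt reads predominant, 21-nt second |
| phasi fraction | 21 nt: 0.54, 24 nt: 0.35 | per-class share drawn from phased locus registers |
| 5′ weights | 21-class U: 9, 24-class A: 3.4, others 1 | RIP selection; closed-form bound fractions 0.75 (5′-U) and 0.53 (5′-A) |
| miRNA fraction | 0.02 | exact mature copies; miRNAs are a small share of sRNA |
| N rate | 0.002/base | uniform N substitution |
| adapter / cycles | TruSeq small RNA / 50 | full adapter appended, read truncated to cycle count, low-quality random padding |

Phased reads start at `offset + k · class` from the locus 5′ end on the
locus strand. Hairpins plant a 5p arm forced to start A and a 3p arm
forced to start U (the arm asymmetry seen in miR2275-like hairpins), so
arm-selective binding is simulatable. The mRNA generator places background
reads uniformly over exonic space and site reads within ± 20 nt of planted
sites; with the default density model a site at fold F collects F× the
local background coverage, and `enrichment_fold = 0` is exactly the IgG
model. The benchmark geometry — 100 two-exon genes, ~1 Mb exonic space,
50-nt reads, 2×10^4 reads, 200-nt sites at 10× — was chosen as a
scaled-down sparse-coverage regime (~1× background coverage), which is the
regime where cluster-based peak calling is meaningful; at high coverage
all reads merge into gene-length clusters and no interval method can
separate sites.

What the generator does **not** emulate: sequencing substitution errors
beyond uniform N injection, ligation biases, PCR duplication structure,
expression heterogeneity across loci/genes, introns in read placement,
and secondary structure. Passing the parameter-recovery and peak-recovery
benchmarks therefore demonstrates correctness of the statistical
machinery under its own assumptions, not robustness to every artifact of
real libraries.

## Numerical and testing choices

- Determinism: every stochastic routine takes a seed; per-gene null seeds
  derive from one `SeedSequence`, and identical seeds give byte-identical
  output tables (verified end to end).
- Degenerate inputs raise explicit errors (zero TPM/RPKM denominators,
  < 2 replicates, empty base population, reads longer than a gene's exonic
  span — naming the gene) or return explicit empty results (composition of
  an absent read length) rather than NaNs.
- Recovery tests compare observations to *exact* generative expectations:
  the locus fraction includes the closed-form probability that a uniform
  background read falls inside a same-class locus, and the 5′-base check
  uses the closed form evaluated on the realized library composition,
  with a variance term for the finite number of locus registers. Sampling
  tolerances are 3 standard errors at the simulated n.
- Problem sizes in the standard benchmark runs (10^5 sRNA reads, 500
  random reads vs a 5-kb genome for the aligner oracle, 20 seeds of 2×10^4
  mRNA reads, 10^4 t-test null trials) keep full runs in the minutes range
  on one CPU while leaving every comparison well inside its statistical
  resolution.

## Known limitations

Toy-scale references only (the mapper is O(candidates) per read with an
exact k-mer index, not an FM index); no spliced alignment; no phasing
score / de novo PHAS locus discovery (locus coordinates are inputs); no
multiple-testing correction across miRNA ratios (none is standard for
these direct comparisons); the IgG filter assumes comparable library
depths; psRNATarget-style scoring is not reimplemented (only its output
table is consumed).
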