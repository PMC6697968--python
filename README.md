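# agorip

Analysis toolkit for Argonaute (AGO) RIP-seq experiments on plant small
RNAs, built around the question: *which small RNAs and mRNAs does an AGO
protein bind, and with what sequence preferences?* A cross-linking RNA
immunoprecipitation library (RIP) is sequenced next to a nonspecific IgG
control; the analysis characterises the bound population by read length,
5′-terminal nucleotide, membership in phased-siRNA (phasiRNA) loci and
mature-miRNA identity, and calls protein-bound sites on mRNAs with a
permutation null.

The package provides, as importable modules and as an `agorip` CLI:

- **simulate** — a synthetic-data generator that emulates AGO-bound
  libraries: a toy genome with planted 21-nt and 24-nt phasiRNA loci and
  miRNA hairpins (distinct 5p/3p arms and 5′ bases), adapter-ligated
  small-RNA reads with a configurable length mixture, RIP resampling with
  length-class-dependent 5′-base selection weights, and mRNA RIP reads
  concentrated at planted binding sites — each library with a ground-truth
  table.
- **preprocess** — the FASTQ cleanup cascade: discard reads with N bases,
  clip the 3′ adapter (exact prefix match, ≥ 6-nt overlap), trim 3′ bases
  below Q20, drop reads shorter than 16 nt; per-stage accounting.
- **align** — a seed-and-verify Hamming mapper (substitutions only,
  best-stratum reporting): genome mode at ≤ 2 mismatches, mature-miRNA
  mode at ≤ 1 mismatch; multi-mapper policies `discard` / `count_all` /
  `fractional`.
- **profile** — length distributions, per-position base composition (the
  matrix behind a sequence logo), phasiRNA locus assignment (full
  containment, exact class length, any strand), TPM and RPKM.
- **enrichment** — per-feature log2 RIP/IgG ratios with a pseudocount, and
  the replicate-level two-sample t-test (Welch default, pooled optional).
- **peakcall** — the mRNA peak caller: unique-read collapsing, overlap
  merging into clusters, a 500-repeat "in silico random IP" null per gene,
  empirical FDR (significant at FDR ≤ 0.01), an IgG ratio filter, and
  bound-gene calls with miRNA-target overlap statistics.

## The statistics at the core

For a gene with reads `r_1..r_n`, each permutation repeat re-places every
read uniformly over the gene's exonic span, merges overlapping placements
and records the maximum cluster read count `M_j`. A cluster of height `h`
gets the empirical false discovery rate

```
FDR(h) = #{ j : M_j >= h } / R          (R = 500 repeats)
```

and is a bound site when `FDR <= 0.01` and `(RIP + 1)/(IgG + 1) >= 2` over
its interval. For RIP selection on small RNAs, if `f_b` is the library's
5′-base composition in a length class and `w_b` the binding weight, the
bound fraction of base `b` is `w_b f_b / Σ_b' w_b' f_b'` — e.g. weights
9:1:1:1 on a uniform composition give a 75% 5′-U fraction. Abundances are
`TPM = count · 10^6 / total` and `RPKM = count · 10^9 / (length · total)`.

## Worked example

```
agorip demo --seed 11 --n-reads 20000 --out demo/
```

prints `RIP 21-nt phasiRNA fraction: 0.470; bound genes: 3` and writes all
tables under `demo/`. What they show, with the numbers this run produces:

- `srna_length_distribution.tsv` vs `rip_length_distribution.tsv`: the
  total sRNA library is dominated by 24-nt reads (46.0%, 21-nt: 16.8%),
  while the bound library shifts toward 21-nt reads (33.1%) — the bound
  population does not mirror the expressed one.
- `rip_composition_21nt.tsv`: position 1 of bound 21-nt reads is 77.6% U
  (positions 2+ stay near 25% per base) — the 5′-U selection the RIP
  weights encode.
- `mirna_rip_vs_igg.tsv`: hairpin 3p arms (5′-U) are RIP-enriched, e.g.
  `sim-miR1-3p log2 ratio +1.42`, while their 5p arms (5′-A) are depleted
  (`sim-miR1-5p −2.53`) — arm-selective binding.
- `mrna/peaks.tsv` and `mrna/bound_genes.tsv`: 3 significant peaks, one in
  each of the 3 genes carrying a planted binding site; background clusters
  sit at FDR ≈ 1 with IgG ratios ≈ 1.

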