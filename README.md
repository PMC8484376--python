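# poolcross

Pool-seq genome scans and backcross linkage analysis for mapping
within-feather pigmentation loci in chicken — and, more generally, for
any two-line backcross mapped with pooled whole-genome resequencing.

## The problem

Feather patterns such as autosomal barring segregate in crosses between
a patterned line (e.g. Fayoumi) and a wild-type line (e.g. Light Brown
Leghorn). Mapping the causal locus from such a backcross typically
combines:

1. **Pooled resequencing scans.** Progeny are pooled by phenotype and
   sequenced (~45×). Per biallelic variant with pool alt-allele
   frequencies p₁, p₂ (qᵢ = 1 − pᵢ),

   F_ST = (π_between − π_within) / π_between, with
   π_within = (2p₁q₁ + 2p₂q₂)/2 and π_between = p₁q₂ + p₂q₁,

   averaged over 30 kb windows, standardised genome-wide to Z scores
   and called significant by Bonferroni.
2. **Pooled heterozygosity (Hp).** For multi-breed pools (~10× each),
   per-variant major/minor read counts n_MAJ, n_MIN summed across all
   pools give, per 30 kb window,

   Hp = 2 Σn_MAJ Σn_MIN / (Σn_MAJ + Σn_MIN)², Z_Hp = (Hp − μ)/σ,

   with Z_Hp < −4.70 flagging putative identical-by-descent regions.
3. **Fine mapping.** Informative SNPs are chosen by pool-frequency
   filters (0.4–0.6 in the case pool, <0.2 in the control pool, ≥20
   reads, spacing 189–322 kb), progeny genotypes are coded by their
   count of founder-line alleles, and the maximal marker run without a
   recombination event delimits the candidate interval.
4. **Linkage and segregation statistics.** Pearson χ² against the 1:1
   backcross ratio, two-point LOD scores
   LOD = R·log₁₀(r̂/0.5) + (N−R)·log₁₀((1−r̂)/0.5) with r̂ = R/N, and
   the double-heterozygote expectation (1−r)/2.
5. **Expression follow-up.** ΔΔCt relative expression against two
   housekeeping genes (fold = 2^−ΔΔCt) and pyrosequencing allelic
   imbalance in heterozygotes against a genomic-DNA 50:50 control.

`poolcross` implements all five stages as a tested library, together
with a seeded synthetic-data generator (backcross pedigrees with
Haldane recombination, pooled binomial read sampling, multi-breed
pools with an optional shared IBD segment) so the entire pipeline runs
and is testable without any external sequencing data.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/hp_scan.py` simulates six breed pools of five birds at
10× coverage with a planted 100 kb IBD segment and scans it:

```
167 windows; 3 below the fixed Z_Hp cutoff -4.7
Lowest window: chrZ:2430000-2460000  Hp = 0.0011, Z_Hp = -7.31
Planted IBD segment: chrZ:2400000-2500000
```

The lowest-Hp window falls inside the planted segment: all pools are
fixed for one shared haplotype there, so read-level heterozygosity
collapses and its Z_Hp drops far below the fixed −4.70 cutoff.
Similarly, `python examples/fst_scan.py` shows the F_ST scan placing
its top windows on the causal chromosome as a multi-window plateau
around the causal locus, and `python examples/fine_mapping.py` recovers
a planted 1 Mb recombination cold region as the non-recombining
interval with a two-point LOD of ~80.

A YAML-configured end-to-end run (simulate → F_ST scan → Hp scan →
marker selection → interval → segregation, with a checksummed manifest)
is available both as `poolcross run --config cross.yaml` and as
`poolcross.run_pipeline(...)`; the other CLI subcommands (`fst-scan`,
`hp-scan`, `select-markers`, `interval`, `segregation`, `lod`,
`expression`, `allelic-imbalance`, `pool-heatmap`) wrap the same
library functions for file-based use.

## Layout

- `src/poolcross/simulate.py` — backcross pedigree, pooled-read and
  breed-pool generators
- `src/poolcross/poolseq.py` — F_ST, window scans, Z scores, Hp/Z_Hp
- `src/poolcross/markers.py` — SNP selection filters, genotype-matrix
  coding, non-recombining interval, pool fixed/segregating states
- `src/poolcross/linkage.py` — segregation χ², association tables,
  two-point LOD, double-heterozygote expectation
- `src/poolcross/expression.py` — ΔΔCt and allelic imbalance
- `src/poolcross/pipeline.py`, `cli.py`, `io.py`, `plotting.py` —
  orchestration, formats (TSV / VCF-with-AD / BED / JSON), renders

See `docs/methods.md` for the statistical models, defaults and known
limitations.
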