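# Methods

This note documents the statistical models implemented in `poolcross`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known
limitations. No empirical claim here goes beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Backcross simulation

**Design.** Founder dams from the patterned line are homozygous for a
"Fayoumi" allele (coded 1) at every marker; founder and backcross
sires are homozygous "Leghorn" (0). Defaults mirror the mapping
pedigree the package is built around: 5 founder dams × 2 sires, 12 F1
dams, 365 backcross (BC) progeny. Because the founders are fixed for
alternative alleles, every marker is line-diagnostic and a BC
genotype is simply the count of Fayoumi alleles (0 = homozygous
wild-type, 1 = heterozygous; 2 cannot arise on autosomes in a BC).

**Recombination.** Each BC progeny receives one recombinant maternal
gamete and one intact paternal (Leghorn) gamete. Crossovers follow
Haldane's model — Poisson-distributed on the genetic map with no
interference — because only an average rate (4 cM/Mb, the chicken
genome-wide figure) and the existence of a low-recombination region
are part of the design being emulated; nothing constrains
interference. A `cold_region` (chrom, start, end, rate) overrides the
local rate, emulating the suppressed recombination at distal
chromosome ends. The per-individual crossover positions are logged and
serve as ground truth for the breakpoint-detection oracle in the
tests.

**Transmission distortion** is one Bernoulli parameter: the
probability that a maternal gamete carries the Fayoumi allele at the
causal locus (default 0.5; a preset of 159/365 ≈ 0.436 reproduces the
observed carrier deficit). It is implemented by seeded rejection
sampling of the causal-chromosome gamete, which leaves the
recombination process conditionally unchanged.

**Phenotypes.** A conditional table P(category ∈ {AB, WT, UNCLEAR,
RB} | causal carrier, modifier carrier, sex) is fully configurable.
The default enforces the structural zeros of the observed cross — no
AB or UNCLEAR among non-carriers, red-belly (RB) males only — and,
among carriers, gives AB:UNCLEAR:RB odds of 66:3:5 with the modifier
and 36:25:27 without (the published tables print only the two
marginals; this joint assumes the modifier acts only among carriers
and reproduces both marginals). For females the RB mass is
renormalised away; non-carrier males show RB at rate 3/103.

**Pooled reads.** Per variant and pool, depth ~ Poisson(coverage);
each read reports the alternative allele with probability
f(1−e) + (1−f)e, where f is the pool allele frequency (every member
contributes two chromosomes equally) and e a symmetric per-read error
(default 0.001; no quality scores are modelled). Defaults are 45× for
backcross phenotype pools and 10× for breed pools of 5, matching the
pooled designs being emulated.

**Breed pools.** Each breed draws an independent allele frequency per
variant, uniform on [0.05, 0.95] — a deliberately flat neutral
spectrum: the Hp screen only needs polymorphic background, not a
realistic site-frequency spectrum. The realised pool frequency is a
binomial draw over the 2 × pool_size chromosomes. Inside an optional
IBD segment all breeds are fixed for one shared allele per variant.

**What the generator does not emulate:** linkage disequilibrium and
coalescent history within breeds, read-level artefacts (mapping bias,
indels, duplicates), variant-calling error beyond the symmetric flip,
multi-allelic sites, and sex chromosomes. Tests passing on this
generator therefore validate the estimators and their bookkeeping,
not robustness to alignment or calling artefacts in real pools.

## Genome scans

**F_ST.** The per-variant estimator uses pool read-frequencies only:
π_within = (2p₁q₁ + 2p₂q₂)/2, π_between = p₁q₂ + p₂q₁, F_ST =
(π_between − π_within)/π_between. This is the simplest frequency-based
reading of the ratio definition; no correction for finite pool size or
unequal individual contribution is applied (out of scope). Variants
with depth 0 in either pool are skipped; π_between = 0 makes the
statistic undefined and the variant is excluded from windows.

**Windows.** Arithmetic means over [start, start + 30 kb) on a grid
anchored at the chromosome start. "Sliding" step defaults to the
window size (non-overlapping): the Bonferroni count must be the number
of tested windows, which is ill-defined for overlapping windows; a
`step_bp` option slides if desired. Windows with fewer than
`min_variants` (default 10 — the "very low number of variants"
exclusion made concrete) are dropped before standardisation.

**Z scores.** z = (stat − mean)/sd over all retained windows
genome-wide, sample sd (n−1). One-tailed normal p — upper tail for
F_ST (differentiation), lower for Hp (reduced heterozygosity) — and
Bonferroni over the retained windows. The Hp scan additionally exposes
the fixed cutoff z < −4.70. The strict inequality follows the
"less than −4.70" phrasing of the original screen.

**Hp.** Per variant, n_MAJ/n_MIN are the larger/smaller of the two
allele read sums taken across all pools (ties toward reference, which
cannot affect the window sums); per window
Hp = 2·Σn_MAJ·Σn_MIN/(Σn_MAJ+Σn_MIN)², bounded in [0, 0.5] with the
maximum exactly at balanced sums. A `literal=True` flag evaluates the
alternative 2·Σn_MIN/(Σ+Σ)² form for comparison; it is not the
default because it is neither scale-invariant nor bounded like a
heterozygosity.

**A note on "top window" localisation.** In a backcross the expected
F_ST surface around the causal locus is a plateau: it declines by only
~0.06 per Mb at 4 cM/Mb, while the realised per-window values carry
noise from both the crossover process (allele-frequency steps of
1/(2·pool size) per crossover) and 45× read sampling. The single
top-ranked 30 kb window is therefore effectively a random draw among
the plateau windows — adjacent windows with no intervening crossover
tie exactly even at infinite coverage. The scan localises a region, as
pool-seq scans do in practice; tests assert plateau-level properties
(top window on the causal chromosome, causal window at the plateau
top) rather than single-window identification.

## Fine mapping

**Marker filters** default to the fine-mapping protocol: case-pool alt
fraction in [0.4, 0.6], control-pool < 0.2, ≥20 reads per pool, and
spacing 189–322 kb ("frequency" is read as pool alt-read fraction, the
only frequency observable from pools). An alternative mode filters on
per-variant F_ST > 0.35 instead. Thinning is greedy left-to-right with
a seeded random choice among in-range candidates; the first marker is
drawn within one minimum-gap of the leftmost candidate, which makes
the selection idempotent whenever 2·spacing_min > spacing_max (true
for the default range). Gaps larger than the maximum are tolerated and
flagged when no candidate exists.

**Non-recombining interval.** A recombination event is a change of
genotype code between adjacent markers within one individual (missing
codes are skipped). The interval is the maximal marker run containing
the anchor with zero events across all individuals; the anchor
defaults to the leftmost marker perfectly associated with the supplied
carrier flags. Reported coordinates are the first/last marker
positions of the run; the positions of the first flanking markers with
an event are exposed separately, since the choice between
flanking-marker and midpoint borders is a reporting convention.

**Pool states.** A pool at a variant is FIXED_REF / FIXED_ALT /
SEGREGATING by alt fraction against a threshold t (default 0.1). With
pools of five birds, one heterozygote gives an expected fraction of
exactly 0.1, so t should be tuned to pool size; it is a parameter, and
the boundary is exclusive.

## Linkage statistics

Pearson χ² uses no continuity correction (the published 6.05 for
206:159 against 1:1 is the uncorrected statistic; Yates would give
5.69). Two-point LOD is the backcross closed form with r̂ = R/N; the
R = 0 limit is N·log₁₀2. Only the two-point backcross case is
implemented — in a pure backcross it is exact, and general-pedigree
multipoint machinery is out of scope. The double-heterozygote
expectation is (1−r)/2: the double heterozygote requires the
non-recombinant maternal gamete carrying both founder alleles.

## Expression analysis

ΔCt = Ct_target − mean(Ct_HK1, Ct_HK2): the arithmetic mean of two
housekeeping Cts equals the geometric mean of their linear quantities
under the fixed efficiency-2 assumption of the ΔΔCt method (no
efficiency correction). ΔΔCt is centred on the calibrator-group mean
ΔCt, fold = 2^−ΔΔCt. The reported group fold change is 2^−mean(ΔΔCt)
(the geometric mean of per-sample folds), which makes the calibrator
group exactly 1 by construction; the quoted ± is the SEM of the
per-sample fold changes, and SEM is what the ± denotes throughout the
package's output. Group comparison is the equal-variance Student's t
test (Welch behind a flag). Allelic imbalance compares heterozygote
cDNA allele fractions against the gDNA heterozygote control with the
same t test, plus a deviation-from-50% one-sample summary; without
gDNA controls the means are still reported and the test skipped.

## Numerical and scale choices

- Coordinates: variant positions are 1-based (VCF convention); window
  and BED intervals are 0-based half-open.
- All randomness flows from one integer seed per operation through
  `numpy.random.default_rng`; equal inputs give bit-identical output.
- Degenerate inputs raise informative errors rather than NaNs: zero
  window variance (e.g. a fully monomorphic genome), empty pools
  (named), fewer than two retained windows, zero informative meioses,
  zero pooled variance with unequal means.
- Simulation-based tests use toy genomes of a few chromosomes totalling
  5–35 Mb with variant spacings of 1–5 kb — large enough for hundreds
  of 30 kb windows and realistic within-window variant counts, small
  enough for the suite to run in seconds. The statistical structure
  (365 BC progeny, pools at 45×, six breed pools of five at 10×, 30 kb
  windows) follows the study design the generator emulates.

## Known limitations

- No pool-size correction in allele-frequency or F_ST estimation.
- Biallelic SNVs only; other records are skipped and counted on VCF
  input.
- The Hp major/minor assignment from summed counts can misassign the
  minor allele at read-depth ties in tiny pools; the window sums are
  unaffected.
- CRI-MAP-style multipoint linkage, map ordering and QTL interval
  mapping are deliberately absent.
- The phenotype model is a conditional table, not a liability model;
  penetrance interactions beyond (causal × modifier × sex) require a
  user-supplied table.
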