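"""Fine mapping: informative-SNP selection, genotype-matrix coding,
the non-recombining interval, and a two-point LOD score.

A 1 Mb recombination cold region around the causal locus mimics the
suppressed recombination seen at distal chromosome ends; every
backcross progeny is then genotyped at the retained markers, coded by
its count of founder-line alleles, and the maximal marker run without
any recombination event is reported together with the linkage LOD
between the causal locus and a flanking marker.
"""

import poolcross as pc

config = pc.CrossConfig(
    chromosomes=[pc.Chromosome("chr11", 5_000_000)],
    causal_locus=("chr11", 4_500_000),
    cold_region=("chr11", 4_000_000, 5_000_000, 0.001),
    n_backcross=365, variant_spacing_bp=50_000, seed=6,
)
pedigree = pc.simulate_cross(config)
table = pedigree.genotype_table("BC")

positions = {f"chr11:{p}": int(p) for p in pedigree.markers["chr11"]}
matrix = pc.build_genotype_matrix(table, "chr11", positions)
carriers = pedigree.fay_counts("chr11", 4_500_000) >= 1
interval = pc.find_nonrecombining_interval(matrix, carriers)
print(f"Non-recombining interval: {interval.chrom}:{interval.start}-"
      f"{interval.end} ({interval.first_marker} .. {interval.last_marker})")
print(f"  informative meioses: {interval.n_informative_meioses}, "
      f"recombinants at the borders: {interval.n_recombinants_at_borders}")

res = pc.two_point_lod(table["chr11:4500000"], table["chr11:2525000"])
print(f"Two-point linkage causal vs chr11:2.5 Mb: N = {res.n_informative},"
      f" R = {res.n_recombinant}, r_hat = {res.r_hat:.3f}, "
      f"LOD = {res.lod:.1f}")
print("The interval should cover the planted 4-5 Mb cold region, and a "
      "LOD far above 3 confirms tight linkage.")
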