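"""Haplogroup structure and a pairwise-difference network for one region.

Sites at minor allele frequency <=5% are removed, haplotypes interrupted by
recombination between major haplotypes are screened out, the rest are
single-linkage clustered into haplogroups, and the distinct haplotypes are
joined by a minimum spanning tree over Hamming distances.
"""

import ovintro as ov
from ovintro.panel import Window

cfg = ov.outlier_config(seed=1)
panel, truth = ov.simulate_panel(cfg)
popmap = ov.popmap_for(cfg)

region = Window("chr1", 0, 150_000)
rh = ov.extract_region(panel, popmap, region, maf_min=0.05)
print(f"region {region.contig}:{region.start}-{region.end:,}: "
      f"{rh.n_sites} sites with MAF>0.05, {rh.n_haplotypes} haplotypes")

kept, flagged = ov.screen_recombinants(rh)
print(f"recombinant screening: {len(flagged)} haplotypes flagged as chimeras "
      f"of major haplotypes, {len(kept)} kept")

# donor and domestic haplotypes are deeply diverged; cluster at 20% difference
groups = ov.cluster_haplogroups(rh, max_diff_frac=0.20, hap_ids=kept)
print(f"haplogroups: {len(groups)}, sizes {[g.size for g in groups[:5]]} ...")
tab = ov.haplogroup_frequencies(groups[:3], popmap)
major = tab[tab.breed != "overall"].pivot(index="breed", columns="haplogroup",
                                          values="freq")
print("per-breed frequencies of the three largest haplogroups:")
print(major.to_string())

net = ov.build_network(rh)
print(f"network: {net.graph.number_of_nodes()} distinct haplotypes, "
      f"MST total weight {net.total_mst_weight():.0f} differences")
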