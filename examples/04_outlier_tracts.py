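"""Select adaptive-introgression candidate tracts.

A strong recent pulse (60%, 2 ka ago) into one meta-population leaves long
shared tracts. Candidates are kept when they are long (>=100 kb), non-rare
(total frequency >=0.05) and population-restricted (frequency SD > 0.1 across
meta-populations) — conserved within but not across populations — and are
then overlapped with highly differentiated (high-F_ST) regions.
"""

import ovintro as ov

cfg = ov.outlier_config(seed=1)
panel, truth = ov.simulate_panel(cfg)
popmap = ov.popmap_for(cfg)
metapops = ["DOM1", "DOM2", "DOM3", "DOM4"]

tracts = []
for g in metapops:
    tracts += ov.infer_tracts(panel, popmap, g, ["EU_OA", "WLD"], lam=1.5)
donor = [t for t in tracts if t.source == "WLD"]
L = {"WLD": ov.expected_ils_length(1e-8, 1_260_000, 4.0)}
filtered = ov.filter_tracts_by_L(donor, L)

profiles = ov.tract_frequency(filtered, popmap, metapops)
selected = ov.select_outlier_tracts(profiles)
print(f"{len(filtered)} donor tracts -> {len(profiles)} candidates -> "
      f"{len(selected)} outliers (long, frequent, population-restricted)")

scan = ov.scan_windows(panel, popmap, "EU_OA", "DOM1", "WLD", "OUT")
regions = ov.high_fst_regions(scan, p_cut=0.001, join_gap=50_000)
annotated = ov.overlap_regions(selected, regions)
n_hit = sum(1 for _, hits in annotated if hits)
print(f"high-F_ST regions (P<0.001 windows joined across <=50 kb): {len(regions)}")
print(f"outliers overlapping a high-F_ST region: {n_hit}/{len(selected)}")
print("(no selection is simulated, so an empty high-F_ST set is the expected null)")
if selected:
    p = max(selected, key=lambda p: p.total_freq)
    print(f"top outlier {p.contig}:{p.start:,}-{p.end:,} len={p.length:,} bp "
          f"total_freq={p.total_freq:.3f} sd={p.sd:.3f} freqs={p.freq_by_pop}")
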