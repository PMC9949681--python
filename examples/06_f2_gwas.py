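"""Mixed-model association scan on a simulated F2 intercross.

Two founder breeds are crossed; the F2 phenotype carries a single causal SNP
(beta = 0.8, trait heritability 0.4, n = 300). The scan fits
y = W a + x b + u + e with a SNP-derived kinship K, one SNP at a time, and
flags hits at the Bonferroni threshold 0.05/m.
"""

import ovintro as ov

cfg = ov.f2_founder_config(seed=5)
panel, _ = ov.simulate_panel(cfg)
popmap = ov.popmap_for(cfg)
ef, hu = popmap.samples_in_group("EF"), popmap.samples_in_group("HU")

causal = ov.pick_causal_site(panel, ef, hu)
causal_pos = panel.positions[causal[0]][causal[1]]
gt, phen = ov.simulate_f2_cross(
    panel, causal, beta=0.8, h2=0.4, n_f2=300, seed=5,
    founders_a=ef, founders_b=hu,
)
res = ov.assoc_scan(gt, phen, "ear_width")

thr = ov.bonferroni_threshold(0.05, len(res))
top = res.loc[res["p"].idxmin()]
print(f"{len(res)} SNPs tested after QC; Bonferroni threshold {thr:.3g}")
print(f"variance-ratio lambda (null ML): {top.lambda_:.2f}")
print(f"causal SNP at {causal[0]}:{causal_pos:,}")
print(f"top hit {top.snp} (distance {abs(top.pos - causal_pos):,} bp): "
      f"beta={top.beta:.2f} se={top.se:.2f} P={top.p:.2e}")
print(f"significant SNPs at the Bonferroni threshold: {int(res.significant.sum())}")
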