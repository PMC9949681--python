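"""Windowed introgression scan: F_ST, d_XY, D and f_d in 50-kb windows.

The scan runs on the quartet (P1 = non-introgressed European reference,
P2 = recipient meta-population, P3 = wild donor, outgroup); f_d estimates the
local admixture fraction wherever there is an ABBA excess (D > 0), and a
two-tailed Z-test flags windows at P < 0.001.
"""

import numpy as np

import ovintro as ov

cfg = ov.default_config(seed=1)
panel, truth = ov.simulate_panel(cfg)
popmap = ov.popmap_for(cfg)

df = ov.scan_windows(panel, popmap, "EU_OA", "DOM1", "WLD", "OUT")
fd = df["fd"].dropna()
print(f"{len(df)} windows (50 kb, 20-kb step); f_d defined in {len(fd)} of them")
print(f"mean f_d = {fd.mean():.3f}  (simulated admixture fraction: 0.10)")
print(f"windows significant at P<0.001 (two-tailed Z on f_d): {int(df.sig_fd.sum())}")

top = df.loc[df["fd"].idxmax()]
print(f"strongest window: {top.contig}:{int(top.start):,}-{int(top.end):,} "
      f"fd={top.fd:.2f} D={top.D:.2f} F_ST={top.fst:.2f} dxy={top.dxy:.2e}")

# permutation-derived genome-wide F_ST threshold (reduced replicates here)
thr = ov.fst_permutation_threshold(
    panel, popmap, ["DOM1", "DOM2", "DOM3", "DOM4"], "WLD",
    n_draw=10, reps=10, seed=1,
)
print(f"permutation F_ST threshold (max of 10 replicate maxima): {thr:.3f}")
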