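"""Windowed theta estimation along a synthetic chromosome.

Simulates a chromosome under a block recombination map (cold blocks with no
recombination alternating with hot blocks), writes the variants to a VCF,
recovers window-wise site frequency spectra, and prints per-regime medians of
the windowed estimates.  In cold blocks all windows share a single genealogy,
so estimates there scatter more and are correlated between neighboring
windows; in hot regions they concentrate near the true theta.
"""

import numpy as np
import msprime

from thetanet import (
    IterativeEstimator,
    WattersonEstimator,
    WindowConfig,
    make_block_recomb_map,
    read_variants,
    scan_estimates,
    sliding_window_sfs,
)

n, window = 40, 70_000
theta_window = 36.12  # 4 * N_e * mu * L at N_e=1e4, mu=1.29e-8, L=70 kb
rec_map = make_block_recomb_map(n_blocks=4, block_length=3 * window,
                                rho_high=200.0 / window)
length = rec_map.length
theta_total = theta_window * length / window

ts = msprime.sim_ancestry(
    samples=n, ploidy=1, population_size=1.0,
    recombination_rate=msprime.RateMap(position=rec_map.breakpoints,
                                       rate=rec_map.rates / 2.0),
    random_seed=11,
)
ts = msprime.sim_mutations(ts, rate=theta_total / (2 * length),
                           random_seed=11, discrete_genome=False)
with open("/tmp/synthetic_chromosome.vcf", "w") as fh:
    ts.write_vcf(fh, position_transform=lambda p: np.fmax(1, np.round(p)))

variants = read_variants("/tmp/synthetic_chromosome.vcf")
windows = sliding_window_sfs(variants, WindowConfig(window, window, n=n),
                             chrom_length=int(length))
table = scan_estimates(
    windows,
    [WattersonEstimator(n), IterativeEstimator(n, "futschik")],
    rec_map,
)

print(f"synthetic chromosome: {length / 1e6:.2f} Mb, true theta per 70 kb "
      f"window = {theta_window}")
print(table[["start", "end", "segregating_sites", "watterson",
             "futschik_iterative", "rho", "regime"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
for regime in ("other", "high"):
    sub = table[table["regime"] == regime]
    if len(sub):
        print(f"regime {regime:5s} (rho {'=0' if regime == 'other' else '>150'}"
              f" here): median Watterson {sub['watterson'].median():6.2f}, "
              f"median iter. Futschik {sub['futschik_iterative'].median():6.2f}")
print("\nWindowed medians near 36.12 indicate accurate local estimation; the")
print("cold-block windows share one tree, hence their larger deviations.")
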