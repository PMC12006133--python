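"""Soft-threshold selection by scale-free fit of the hyperdegree distribution.

Scans beta = 1..12 on the synthetic scenario, prints the signed R^2 of the
log-log degree-density regression and the mean hyperdegree per beta, and
shows the machinery on an exact power-law sample where a high R^2 is
guaranteed by construction.
"""

import numpy as np

import wgchna as w

X = w.generate(w.default_scenario()).expression
scan = w.scan_beta(X, tau=1.0, betas=list(range(1, 13)))
chosen = w.pick_beta(scan, r2_cut=0.8)

print("beta  signed R^2  mean hyperdegree")
for beta, r2, deg in zip(scan.betas, scan.r_squared, scan.mean_degree):
    marker = "  <- chosen" if beta == chosen else ""
    print(f"{beta:4d}  {r2:10.3f}  {deg:16.3f}{marker}")
print("mean hyperdegree shrinks as beta suppresses weak correlations;")
print("this dataset's degree distribution is not scale-free (low R^2), so the")
print("fallback picks the best available beta and flags it:", scan.below_cut)

u = np.random.default_rng(0).uniform(size=2000)
degrees = (1 - u) ** (-1.0)  # exact p(k) ~ k^-2 sample
print(f"\nexact power-law degree sample: signed R^2 = "
      f"{w.scale_free_fit(degrees, n_bins=10):.3f} (near 1 by construction)")
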