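"""Simulate traits at several strengths of phylogenetic signal and verify
the signal with Blomberg's K and a disparity-through-time curve.

Pagel's lambda scales the shared-path entries of the Brownian-motion
covariance: 0 = independent tips, 1 = perfect Brownian motion, 10 = tips
far more similar within clades than Brownian motion predicts.
"""

import numpy as np

from phylorisk import (blomberg_k, disparity_through_time, generate_batch,
                       lambda_transform, phylo_covariance, simulate_traits)

tree = generate_batch("yule", 64, 1, seed=1).trees[0]
base_cov = phylo_covariance(tree)
rng = np.random.default_rng(1)

print(f"{'lambda':>6} {'mean K':>8} {'late-time disparity':>20}")
for lam in (0.0, 1.0, 10.0):
    cov = lambda_transform(base_cov, lam)
    ks, late = [], []
    for _ in range(25):
        traits = simulate_traits(cov, rng)
        ks.append(blomberg_k(tree, traits))
        curve = disparity_through_time(tree, traits, n_sim=1, rng=rng)
        late.append(curve.observed[curve.times > 0.7].mean())
    print(f"{lam:>6.1f} {np.mean(ks):>8.2f} {np.mean(late):>20.2f}")

print("\nK ~ 1 under perfect Brownian motion, below it without signal, above")
print("it with excessive signal; late-time relative disparity is high when")
print("traits are phylogenetically random and collapses when subclades are")
print("internally homogeneous.")
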