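"""Build extinction-risk distributions from simulated traits.

Standardised traits pushed through the standard normal CDF give risks
with mean ~0.5: uniform when traits carry no phylogenetic signal,
unimodal under perfect Brownian motion, bimodal at extreme signal.
The mean-0.5 set is then rescaled to the low/medium/high threat levels.
"""

import numpy as np

from phylorisk import (generate_batch, lambda_transform, phylo_covariance,
                       rescale_mean, simulate_traits, traits_to_risks)

batch = generate_batch("yule", 64, 50, seed=2)
rng = np.random.default_rng(2)

print(f"{'lambda':>6} {'mean':>6} {'sd':>6} {'share in [0.4,0.6]':>19}")
pooled = {}
for lam in (0.0, 1.0, 10.0):
    vals = []
    for tree in batch:
        cov = lambda_transform(phylo_covariance(tree), lam)
        vals.append(traits_to_risks(simulate_traits(cov, rng)).to_numpy())
    p = np.concatenate(vals)
    pooled[lam] = p
    mid = np.mean((p >= 0.4) & (p <= 0.6))
    print(f"{lam:>6.1f} {p.mean():>6.3f} {p.std():>6.3f} {mid:>19.3f}")

p = pooled[1.0]
for target in (0.25, 0.75):
    q = rescale_mean(p, target)
    print(f"rescaled to mean {target}: mean={q.mean():.3f}, sd={q.std():.3f}, "
          f"max={q.max():.3f}")

print("\nThe shrinking middle share with rising lambda is the drift toward a")
print("bimodal risk distribution; the cap at 1 in the mean-0.75 rescale is")
print("what limits the risk variance at high mean threat.")
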