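# Methods

This note documents the models implemented in `phylorisk`, the defaults
chosen where the design was genuinely open, and what the simulations do
and do not capture about real comparative data.

## Tree generation

All four generators return rooted, strictly bifurcating, ultrametric
trees, which are then rescaled to a common depth of 1 so that PD
quantities are comparable across tree classes and the covariance diagonal
is 1.

* **Yule** (`simulate_yule`): the simple-sampling approach. Starting from
  the root split, waiting times between speciations are Exp(b·k) for k
  extant lineages (default birth rate b = 0.5) and the splitting lineage
  is uniform. A final Exp(b·n) interval is drawn *after* the n-th lineage
  appears. This last interval matters: the Pybus–Harvey gamma statistic is
  built from all n−1 internode intervals, and truncating the tree at the
  n-th birth forces the last interval to zero, biasing gamma upward by
  ≈ √(3/(n−2)) (+0.22 at n = 64). With the interval included, gamma is
  exactly centred (conditional on total length, the interior interval
  boundaries are distributed as uniform order statistics), and the test
  suite checks mean |γ̄| < 0.1 and sd within [0.9, 1.1] over 1000 trees.
* **Coalescent** (`simulate_coalescent`): Kingman's n-coalescent, pairwise
  mergers at rate k(k−1)/2. Mergers pile up near the present while the
  two-lineage basal period is the longest interval, so after depth
  normalisation these trees have long basal edges and strongly positive
  gamma — the "extreme" diversification scenario.
* **Balanced / unbalanced** (`make_balanced`, `make_unbalanced`):
  complete-binary and pectinate topologies. Every edge receives a
  provisional iid Uniform(0,1) length; pendant edges are then lengthened
  so each tip reaches the deepest provisional tip, making the tree
  ultrametric before normalisation. The interval of the uniform is
  irrelevant after depth rescaling up to shape noise. A pectinate tree
  built this way has short internal edges (O(1/n) of the depth) and long
  pendants on shallow-attaching tips. `make_balanced` also offers
  `edge_style="equal"` (every edge length 1), recorded in batch metadata.

## Traits and phylogenetic signal

Traits are one draw from N(0, C_λ), where C is the Brownian-motion
covariance of the tree (shared root-to-MRCA path lengths; diagonal = 1
after normalisation) and C_λ scales the off-diagonal by λ. The Brownian
rate and root state are fixed at 1 and 0: both cancel under the per-tree
standardisation that follows, so they are not exposed as parameters.

For λ ≤ 1 on an ultrametric tree, C_λ is always positive semi-definite and
is used as-is (property-tested). For λ > 1 an off-diagonal can exceed the
diagonal; each off-diagonal is then capped at (1 − 10⁻⁶)·min(Cᵢᵢ, Cⱼⱼ) and
any remaining negative eigenvalues are floored at zero (nearest-PSD
projection in Frobenius norm). At λ = 10 most off-diagonals saturate, so
tips within the deepest clades become near-perfectly correlated — the
regime in which trait (and hence risk) distributions go bimodal. Sampling
uses an eigendecomposition square root; a matrix whose smallest eigenvalue
is below −10⁻⁸·max(eig, 1) is rejected as a contract violation.

Diagnostics: `blomberg_k` (phylogenetic-GLS form, calibrated so the mean
over Brownian-motion replicates is ≈ 1; batch means increase monotonically
in the generating λ) and `disparity_through_time` (mean relative subclade
variance across the lineages crossing each internal-node age, with a
Brownian-motion reference curve averaged over simulations, 100 by
default). Singleton lineages contribute zero disparity, so the observed
curve ends at 0 at the tips.

## From traits to extinction probabilities

Per tree: standardise traits (population-sd convention by default;
`sd_ddof=1` switches to sample sd — both satisfy every downstream
property) and map through the standard normal CDF. As the probability
integral transform, this yields risks that are ~Uniform(0,1) when traits
are iid (λ = 0), unimodal around 0.5 under perfect Brownian motion, and
bimodal at extreme λ, with mean ≈ 0.5 in all cases.

The mean-0.5 distribution is rescaled to the low/medium/high threat
levels:

* 0.25 — divide by 2;
* 0.50 — identity;
* 0.75 — multiply by a common factor c and cap at 1, with c solved by
  bisection so the sample mean is exactly 0.75.

The capped multiplication was chosen over the symmetric alternative of
halving the survival probabilities (p → 1 − (1−p)/2): the latter quarters
the risk variance, which suppresses the clustering effect at high mean
risk so strongly that the high-threat condition falls *below* the
medium-threat one — reversing the ordering the sweep is designed to
expose. The cap is the natural way to honour p ≤ 1 while holding the mean
fixed, and it only slightly reduces the variance relative to uncapped
scaling. Its cost is degeneracy at extreme signal: once a whole clade's
risks hit the cap, that clade's extinction becomes certain (see
Limitations).

## Expected PD and the clustering statistic

`expected_pd` evaluates E(PD) = Σ ℓᵢ(1 − Π pⱼ) with the per-edge products
computed as exponentiated log-sums over an edge-by-tip incidence matrix
(risks of exactly 0 are clipped to 1e−300, so the joint extinction
probability underflows to exactly zero rather than producing −inf·0).
The implementation is verified against brute-force enumeration of all 2ⁿ
extinction outcomes on 200 random trees (n ≤ 10) to 1e−10, and against
the closed form Σ ℓᵢ(1 − p^{nᵢ}) for homogeneous risks.

The random baseline is the mean of E(PD) over uniform permutations of the
risk values across tips (default 10 shuffles per tree; the expectation is
the same as for a single shuffle, extra shuffles only shrink per-tree
Monte-Carlo noise, and an exhaustive-permutation oracle on 5 tips checks
convergence). The per-tree statistic is
%ΔE(PD) = 100·(E_rand − E_clust)/E_rand, and conditions are summarised by
the mean over trees with a normal-approximation 95% CI (1.96·sd/√n).

## The sweep

`ExperimentConfig` defaults encode the study conditions: λ grid
{0, 0.25, 0.5, 0.75, 1, 5, 10}, mean risks {0.25, 0.50, 0.75}, 1000 trees
per condition, 64 tips for every tree class plus a 128-tip Yule series,
birth rate 0.5. Every random stream is derived from
(seed, generator, n_tips, tree index, stage, λ, mean) via
`numpy.random.SeedSequence` spawn keys, so per-tree trees are shared
across λ and mean levels (as in a paired design), traits are shared across
mean levels, and a condition run standalone reproduces its slice of the
full sweep bitwise. Trees that fail a stage contract are logged and
skipped; a condition aborts if more than 1% of its trees do.

Problem sizes: the acceptance script runs the full 1000 trees per
condition (~25 s on one CPU for its 22 conditions); the test suite runs
reduced sweeps at 200 trees per condition, with tolerances widened
accordingly.

## What the generator does and does not emulate

The synthetic conditions isolate the causal chain tree shape → trait
covariance → risk clustering → PD loss. They do not attempt to mimic
several features of real data, so green tests here say nothing about:
empirically shaped (right-skewed, IUCN-like) risk distributions; trees
with extinction during growth (birth–death), polytomies, or inference
error; λ estimated from data rather than imposed; or correlations between
extinction risk and traits other than the single simulated one. The λ > 1
regime is a covariance-level proxy for early-burst-like similarity, not a
mechanistic model of it.

## Known limitations

* At λ = 10 on coalescent trees the combination of saturated within-clade
  correlations and the mean-0.75 cap drives entire basal clades to
  p(ext) = 1, making their loss deterministic; the high-threat coalescent
  condition is therefore extremely sensitive to the exact λ > 1 and
  mean-rescaling conventions, far more than any other condition in the
  sweep.
* The CI uses the normal approximation; per-tree %ΔE(PD) distributions at
  extreme conditions are skewed, so coverage there is approximate.
* `phylo_covariance` and the edge incidence are O(n²) memory/time —
  appropriate for the n ≤ 128 study sizes, not for very large trees.
* Risk values of exactly 1 are representable (they arise from the cap);
  risk values of exactly 0 only via user input, handled by clipping in
  log space as described above.
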