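# phylorisk

Simulation toolkit for asking how much *extra* phylogenetic diversity (PD)
humanity stands to lose because extinction risk is phylogenetically
clustered — related species tending to share the biology that puts them in
danger — rather than scattered at random across the tree of life.

It is aimed at comparative and conservation phylogeneticists who want a
reproducible, fully synthetic test bed: every input (trees, traits, risks)
is simulated under controlled conditions, so the effect of tree shape,
signal strength and mean threat level can be isolated.

## The model

**Expected future PD.** For a rooted tree with edge lengths ℓᵢ and
independent per-tip extinction probabilities p(ext)ⱼ over some projection
horizon (the *generalized field-of-bullets* model), the expected surviving
PD is

    E(PD) = Σᵢ ℓᵢ · (1 − Π_{j ∈ tips(i)} pⱼ)

— each edge survives if at least one tip it subtends survives.

**Clustered risks.** Tip traits are drawn from a multivariate normal with
the Brownian-motion covariance C (Cᵢⱼ = shared root-to-MRCA path length),
whose off-diagonal is scaled by Pagel's λ: λ=0 removes all signal, λ=1 is
perfect Brownian motion, λ>1 (clamped and projected back to the PSD cone)
makes tips within clades more similar than Brownian motion allows, as under
early-burst evolution. Traits are standardised per tree, mapped through the
standard normal CDF to risks with mean ≈ 0.5, and rescaled to mean 0.25
(halving), 0.50 (identity) or 0.75 (capped multiplication that holds the
mean exactly while keeping p ≤ 1).

**The statistic.** Clustering's footprint is the percent difference in
projected PD,

    %ΔE(PD) = 100 · (E_random − E_clustered) / E_random,

where E_random is E(PD) for the same risk values shuffled uniformly across
tips. Positive values mean clustered risks destroy more evolutionary
history than random extinction.

Four tree classes at a common depth of 1 serve as study conditions: Yule
(pure birth, the simple-sampling approach), Kingman coalescent, perfectly
balanced, and pectinate (maximally unbalanced) trees.

## Worked example

`examples/pd_loss_sweep.py` runs a reduced sweep (100 Yule/64 trees per
condition) over λ ∈ {0, 1, 10} and the three mean-risk levels:

```
mean %dE(PD) (positive = clustering destroys extra PD)
mean_pext  0.25  0.50   0.75
lambda
0.0       -0.15 -0.44  -0.45
1.0        0.26  4.69  15.89
10.0       0.69  7.22  19.90

95% CI half-widths
mean_pext  0.25  0.50  0.75
lambda
0.0        0.21  0.53  1.00
1.0        0.30  0.87  1.66
10.0       0.38  1.24  2.57
```

Reading: with no phylogenetic signal (λ=0) the clustered and shuffled
scenarios are statistically indistinguishable (the CI covers 0). The extra
loss grows with both the signal strength and the mean extinction risk, but
stays below ~1% when mean p(ext) is low — clustered risks alone barely
change the PD outlook unless threat levels are high as well.

The other examples cover the building blocks: `simulate_trees.py` (tree
classes and their gamma/Colless statistics), `trait_signal.py` (Blomberg's
K and disparity-through-time across λ), `risk_distributions.py` (the
uniform → unimodal → bimodal progression of risk distributions and the
mean rescaling).

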