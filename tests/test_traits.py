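"""Phylogenetic covariance, Pagel's lambda transform, trait simulation, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phylorisk import (PhyloCovariance, blomberg_k, disparity_through_time,
                       generate_batch, lambda_transform, phylo_covariance,
                       simulate_traits, simulate_yule, rescale_depth)


@pytest.fixture(scope="module")
def yule16():
    return generate_batch("yule", 16, 1, seed=5).trees[0]


def test_covariance_two_tip_identity(two_tip):
    assert np.allclose(phylo_covariance(two_tip).matrix, np.eye(2))


def test_covariance_balanced_hand_values(balanced4):
    """Within-cherry shared path 0.5, across cherries 0, diagonal = depth 1."""
    c = phylo_covariance(balanced4).to_frame()
    assert c.loc["A", "B"] == pytest.approx(0.5)
    assert c.loc["C", "D"] == pytest.approx(0.5)
    assert c.loc["A", "C"] == pytest.approx(0.0)
    assert np.allclose(np.diag(c.to_numpy()), 1.0)


def test_covariance_star_limit_is_identity(star4):
    assert np.allclose(phylo_covariance(star4).matrix, np.eye(4))


def test_covariance_invariants(yule16):
    c = phylo_covariance(yule16).matrix
    assert np.allclose(c, c.T)
    assert np.allclose(np.diag(c), 1.0)
    off = c[~np.eye(16, dtype=bool)]
    assert np.all(off >= 0) and np.all(off <= 1 + 1e-12)
    assert np.linalg.eigvalsh(c)[0] > -1e-10


def test_lambda_identity_is_bitwise(yule16):
    c = phylo_covariance(yule16)
    assert np.array_equal(lambda_transform(c, 1.0).matrix, c.matrix)


def test_lambda_zero_diagonalizes(yule16):
    m = lambda_transform(phylo_covariance(yule16), 0.0).matrix
    assert np.all(m[~np.eye(16, dtype=bool)] == 0.0)
    assert np.allclose(np.diag(m), 1.0)


def test_lambda_plain_scaling_below_clamp():
    c = PhyloCovariance(np.array([[1.0, 0.3], [0.3, 1.0]]), ("A", "B"))
    assert lambda_transform(c, 2.0).matrix[0, 1] == pytest.approx(0.6)


def test_lambda_negative_rejected(yule16):
    with pytest.raises(ValueError):
        lambda_transform(phylo_covariance(yule16), -0.1)


def test_lambda_at_most_one_never_leaves_psd_cone():
    """For lambda <= 1 on ultrametric trees the scaled matrix is PSD as-is."""
    for i in range(100):
        t = rescale_depth(simulate_yule(16, 0.5, np.random.default_rng(200 + i)), 1.0)
        c = phylo_covariance(t)
        for lam in (0.25, 0.75, 1.0):
            m = lambda_transform(c, lam).matrix
            # plain scaling, no clamp/projection applied
            expect = c.matrix * lam
            np.fill_diagonal(expect, np.diag(c.matrix))
            assert np.array_equal(m, expect)
            assert np.linalg.eigvalsh(m)[0] > -1e-10


def test_lambda_high_is_psd_and_capped(yule16):
    m = lambda_transform(phylo_covariance(yule16), 10.0).matrix
    assert np.linalg.eigvalsh(m)[0] > -1e-8
    assert np.all(m[~np.eye(16, dtype=bool)] <= 1.0 + 1e-6)


def test_traits_near_zero_variance_limit(rng, balanced4):
    c = PhyloCovariance(1e-4 * np.eye(4), tuple("ABCD"))
    x = simulate_traits(c, rng)
    assert np.all(np.abs(x.to_numpy()) < 4 * 1e-2)


def test_traits_identity_covariance_lln(rng):
    c = PhyloCovariance(np.eye(5), tuple("ABCDE"))
    draws = np.stack([simulate_traits(c, rng).to_numpy() for _ in range(10_000)])
    assert np.allclose(draws.var(axis=0), 1.0, rtol=0.05)


def test_empirical_covariance_matches_transform(rng):
    """Tip-tip sample covariance over 5000 draws matches the lambda-scaled matrix."""
    t = generate_batch("yule", 8, 1, seed=4).trees[0]
    c = lambda_transform(phylo_covariance(t), 0.5)
    draws = np.stack([simulate_traits(c, rng).to_numpy() for _ in range(5000)])
    emp = np.cov(draws.T, ddof=1)
    assert np.allclose(emp, c.matrix, rtol=0.10, atol=0.06)


def test_high_lambda_separates_subclades(rng):
    """At lambda = 10 trait variance between the root's daughter clades dominates within."""
    t = generate_batch("yule", 64, 1, seed=6).trees[0]
    c = lambda_transform(phylo_covariance(t), 10.0)
    left, right = t.children[t.root]
    M = t.edge_tip_matrix()
    within, between = [], []
    for _ in range(20):
        x = simulate_traits(c, rng).to_numpy()
        a, b = x[M[left]], x[M[right]]
        within.append((a.var() + b.var()) / 2)
        between.append(np.var([a.mean(), b.mean()]))
    assert np.mean(between) > np.mean(within)


def test_blomberg_k_calibrated_under_bm(rng):
    """Mean K over replicate BM datasets is ~1 on the untransformed tree."""
    t = generate_batch("yule", 32, 1, seed=8).trees[0]
    c = phylo_covariance(t)
    ks = [blomberg_k(t, simulate_traits(c, rng)) for _ in range(300)]
    assert np.mean(ks) == pytest.approx(1.0, abs=0.15)


def test_blomberg_k_monotone_in_lambda(rng):
    """Batch-mean K increases with the lambda used to generate the traits."""
    t = generate_batch("yule", 32, 1, seed=8).trees[0]
    c0 = phylo_covariance(t)
    lams = [0.0, 0.5, 1.0, 5.0, 10.0]
    means = []
    for lam in lams:
        c = lambda_transform(c0, lam)
        means.append(np.mean([blomberg_k(t, simulate_traits(c, rng))
                              for _ in range(150)]))
    rho = spearmanr(lams, means).statistic
    assert rho > 0.999  # rank correlation of batch means is exactly 1 up to fp noise
    assert means[0] < means[2] < means[-1]


def test_blomberg_k_zero_variance_rejected(yule16):
    with pytest.raises(ValueError):
        blomberg_k(yule16, np.zeros(16))


def test_dtt_constant_subclade_contributes_zero(balanced4):
    traits = pd.Series({"A": 1.0, "B": 1.0, "C": 0.0, "D": 2.0})
    curve = disparity_through_time(balanced4, traits, n_sim=5,
                                   rng=np.random.default_rng(0))
    # just after the root: subclades {A,B} (variance 0) and {C,D} (variance 1);
    # whole-tree variance of (1,1,0,2) is 0.5 -> mean relative disparity 1.0
    assert curve.observed[0] == pytest.approx((0.0 + 1.0) / 2 / 0.5)
    assert curve.times[0] == 0.0 and curve.times[-1] == 1.0
    assert curve.observed[-1] == 0.0


def test_dtt_signal_ordering_near_tips(rng):
    """No-signal traits stay disparate near the tips; excessive signal does not."""
    t = generate_batch("yule", 32, 1, seed=12).trees[0]
    c0 = phylo_covariance(t)
    late = {}
    for lam in (0.0, 10.0):
        c = lambda_transform(c0, lam)
        vals = []
        for _ in range(10):
            x = simulate_traits(c, rng)
            curve = disparity_through_time(t, x, n_sim=1, rng=rng)
            sel = curve.times > 0.7
            vals.append(curve.observed[sel].mean())
        late[lam] = np.mean(vals)
    assert late[0.0] > late[10.0]


def test_dtt_requires_four_tips(two_tip, rng):
    with pytest.raises(ValueError):
        disparity_through_time(two_tip, [1.0, 2.0], rng=rng)
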