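"""Tree generators, depth normalisation, Newick round-trip, gamma statistic."""

import numpy as np
import pytest

from phylorisk import (Phylogeny, colless_index, gamma_statistic,
                       generate_batch, make_balanced, make_unbalanced,
                       phylo_covariance, rescale_depth, simulate_coalescent,
                       simulate_yule, total_pd)


class QueueRng:
    """Duck-typed random source returning scripted uniform draws."""

    def __init__(self, values):
        self.values = list(values)

    def uniform(self, low=0.0, high=1.0):
        return self.values.pop(0) if self.values else 0.5


@pytest.mark.parametrize("maker", [
    lambda rng: simulate_yule(64, 0.5, rng),
    lambda rng: simulate_coalescent(64, rng),
    lambda rng: make_balanced(64, rng),
    lambda rng: make_unbalanced(64, rng),
])
def test_generators_produce_valid_ultrametric_trees(maker, rng):
    """Every generator yields a bifurcating ultrametric tree with the node-count identities."""
    t = maker(rng)
    assert t.n_tips == 64
    assert t.n_nodes == 127          # n-1 internal nodes
    assert t.n_edges == 126          # 2n-2 edges
    assert len(set(t.tip_labels)) == 64
    assert np.all(t.edge_length >= 0)
    t = rescale_depth(t, 1.0)
    d = t.tip_depths()
    assert d.max() - d.min() < 1e-9
    assert abs(t.depth - 1.0) < 1e-12


@pytest.mark.parametrize("func,args", [
    (simulate_yule, (1, 0.5)), (simulate_coalescent, (1,)),
    (make_balanced, (1,)), (make_unbalanced, (1,)),
])
def test_generators_reject_fewer_than_two_tips(func, args, rng):
    with pytest.raises(ValueError):
        func(*args, rng)


def test_yule_invalid_birth_rate(rng):
    with pytest.raises(ValueError):
        simulate_yule(8, 0.0, rng)


def test_balanced_requires_power_of_two(rng):
    with pytest.raises(ValueError):
        make_balanced(6, rng)


def test_yule_two_tips_is_root_with_equal_pendants(rng):
    t = simulate_yule(2, 0.5, rng)
    assert t.n_tips == 2
    assert abs(t.edge_length[0] - t.edge_length[1]) < 1e-15


def test_coalescent_two_tip_depth_is_standard_exponential():
    """E[depth] = 1 for two lineages merging at rate 1."""
    depths = [simulate_coalescent(2, np.random.default_rng(1000 + i)).depth
              for i in range(3000)]
    assert abs(np.mean(depths) - 1.0) < 0.08


def test_colless_extremes(rng):
    assert colless_index(make_balanced(64, rng)) == 0
    assert colless_index(make_unbalanced(64, rng)) == (63 * 62) // 2


def test_balanced_forced_half_edges_completes_pendants_to_half():
    """With every draw forced to 0.5, all pendant edges end up 0.5 and depth is 1."""
    t = make_balanced(4, QueueRng([0.5] * 6))
    assert np.allclose(t.edge_length[:4], 0.5)
    assert abs(t.depth - 1.0) < 1e-15


def test_balanced_equal_style_is_uniform_depth(rng):
    t = make_balanced(8, rng, edge_style="equal")
    assert np.allclose(t.edge_length[np.arange(t.n_nodes) != t.root], 1.0)
    assert t.is_ultrametric(1e-12)


def test_unbalanced_first_pendant_longest():
    """Pectinate 3-tip tree, internal edge 0.4: the shallow tip's pendant exceeds the cherry pendants."""
    t = make_unbalanced(3, QueueRng([0.4, 0.3, 0.6, 0.2]))
    cherry = [t.edge_length[1], t.edge_length[2]]
    assert t.edge_length[0] > max(cherry)
    assert t.is_ultrametric(1e-12)
    assert abs(t.edge_length[0] - 1.0) < 1e-12  # deepest provisional tip sets the depth


def test_rescale_depth_scales_edges_and_pd(two_tip):
    t = Phylogeny(two_tip.parent, two_tip.edge_length * 3.0, two_tip.tip_labels)
    s = rescale_depth(t, 1.0)
    assert np.allclose(s.edge_length[:2], 1.0)
    assert abs(total_pd(s) - total_pd(t) / 3.0) < 1e-12


def test_rescale_depth_rejects_non_ultrametric():
    t = Phylogeny.from_newick("(A:1,(B:1,C:2):1);")
    with pytest.raises(ValueError, match="ultrametric"):
        rescale_depth(t, 1.0)


def test_gamma_three_tip_hand_value():
    """g2 = g3 = 0.5: T = 2.5, numerator 1 - 1.25, gamma = -0.3464."""
    t = Phylogeny.from_newick("((A:0.5,B:0.5):0.5,C:1);")
    assert gamma_statistic(t) == pytest.approx(-0.25 / (2.5 * np.sqrt(1 / 12)), abs=1e-12)
    assert gamma_statistic(t) == pytest.approx(-0.3464, abs=1e-4)


def test_gamma_requires_three_tips(two_tip):
    with pytest.raises(ValueError):
        gamma_statistic(two_tip)


def test_gamma_scale_invariant(rng):
    """Uniform edge scaling leaves gamma unchanged (T and numerator scale together)."""
    for _ in range(20):
        t = simulate_yule(16, 0.5, rng)
        g0 = gamma_statistic(t)
        g1 = gamma_statistic(rescale_depth(t, 1.0))
        assert g0 == pytest.approx(g1, abs=1e-9)


def test_yule_gamma_batch_centred():
    batch = generate_batch("yule", 64, 300, seed=11)
    g = np.array([gamma_statistic(t) for t in batch])
    assert abs(g.mean()) < 0.2
    assert 0.8 < g.std(ddof=1) < 1.2


def test_coalescent_gamma_far_above_yule():
    """Coalescent mergers pile up near the present, so gamma is strongly positive."""
    gy = np.mean([gamma_statistic(t) for t in generate_batch("yule", 64, 100, seed=3)])
    gc = np.mean([gamma_statistic(t) for t in generate_batch("coalescent", 64, 100, seed=3)])
    assert gc > gy + 3
    assert gc > 0


def test_newick_round_trip_exact(rng):
    for maker in (lambda: simulate_yule(20, 0.5, rng),
                  lambda: simulate_coalescent(20, rng)):
        t = rescale_depth(maker(), 1.0)
        r = Phylogeny.from_newick(t.to_newick())
        assert set(r.tip_labels) == set(t.tip_labels)
        assert total_pd(r) == pytest.approx(total_pd(t), abs=1e-12)
        ct = phylo_covariance(t).to_frame()
        cr = phylo_covariance(r).to_frame().loc[list(ct.index), list(ct.columns)]
        assert np.allclose(ct.to_numpy(), cr.to_numpy(), atol=1e-12)


def test_batch_write_read_round_trip(tmp_path, rng):
    batch = generate_batch("balanced", 8, 5, seed=2)
    path = tmp_path / "trees.nwk"
    batch.write(path)
    back = type(batch).read(path)
    assert back.generator == "balanced" and back.n_tips == 8 and back.size == 5
    for a, b in zip(batch, back):
        assert total_pd(a) == pytest.approx(total_pd(b), abs=1e-12)


def test_batch_determinism_and_metadata():
    b1 = generate_batch("yule", 16, 4, seed=9)
    b2 = generate_batch("yule", 16, 4, seed=9)
    for a, b in zip(b1, b2):
        assert np.array_equal(a.edge_length, b.edge_length)
    assert b1.size == len(b1.trees) == 4
    with pytest.raises(ValueError):
        generate_batch("nonsense", 16, 2, seed=0)
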