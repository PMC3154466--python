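"""Model-tree generation and tree statistics.

Four classes of rooted, strictly bifurcating trees are used as study
conditions for extinction-risk simulations:

* Yule (pure-birth) trees grown by the simple-sampling approach at a
  constant per-lineage speciation rate;
* Kingman coalescent trees (pairwise mergers at rate k(k-1)/2);
* perfectly balanced (complete binary) trees with random edge lengths;
* perfectly unbalanced (pectinate / caterpillar) trees.

All generators return ultrametric trees; :func:`rescale_depth` normalises
the root-to-tip distance to a common value (1 by convention) so that
branch-length quantities are comparable across tree classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeBatch",
    "simulate_yule",
    "simulate_coalescent",
    "make_balanced",
    "make_unbalanced",
    "rescale_depth",
    "gamma_statistic",
    "colless_index",
    "generate_batch",
    "write_newick_batch",
    "read_newick_batch",
    "GENERATORS",
]

#: integer codes used when deriving per-tree random seeds
GENERATOR_CODES = {"yule": 1, "coalescent": 2, "balanced": 3, "unbalanced": 4}
GENERATORS = tuple(GENERATOR_CODES)


class Phylogeny:
    """A rooted, strictly bifurcating phylogeny with edge lengths.

    Nodes are integers: tips ``0 .. n_tips-1`` (carrying labels), internal
    nodes ``n_tips .. 2*n_tips-2``.  ``parent[root] == -1`` and the root
    carries no edge (``edge_length[root]`` is ignored and stored as 0).

    Parameters
    ----------
    parent
        Integer array of length ``2*n_tips - 1`` with the parent of each
        node (``-1`` for the root).
    edge_length
        Length of the edge above each node, in time units; non-negative.
    tip_labels
        Unique label per tip, aligned with tip indices.
    """

    __slots__ = ("n_tips", "parent", "edge_length", "tip_labels", "root",
                 "children", "_postorder", "_node_depths", "_incidence")

    def __init__(self, parent: Sequence[int], edge_length: Sequence[float],
                 tip_labels: Sequence[str]):
        parent = np.asarray(parent, dtype=np.int64)
        edge_length = np.asarray(edge_length, dtype=float).copy()
        n_nodes = parent.size
        if n_nodes < 3 or n_nodes % 2 == 0:
            raise ValueError(f"a bifurcating tree has an odd node count >= 3, got {n_nodes}")
        n_tips = (n_nodes + 1) // 2
        if len(tip_labels) != n_tips:
            raise ValueError("one label per tip required")
        if len(set(tip_labels)) != n_tips:
            raise ValueError("tip labels must be unique")
        roots = np.flatnonzero(parent == -1)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        root = int(roots[0])
        if root < n_tips:
            raise ValueError("root must be an internal node")
        if edge_length.size != n_nodes:
            raise ValueError("edge_length must align with parent")
        edge_length[root] = 0.0
        if np.any(edge_length < 0):
            raise ValueError("edge lengths must be non-negative")

        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for v in range(n_nodes):
            if v != root:
                p = int(parent[v])
                if not (n_tips <= p < n_nodes):
                    raise ValueError(f"node {v} has non-internal parent {p}")
                children[p].append(v)
        for v in range(n_tips):
            if children[v]:
                raise ValueError(f"tip {v} has children")
        for v in range(n_tips, n_nodes):
            if len(children[v]) != 2:
                raise ValueError(f"internal node {v} has {len(children[v])} children; tree must be bifurcating")

        self.n_tips = n_tips
        self.parent = parent
        self.edge_length = edge_length
        self.tip_labels = tuple(str(s) for s in tip_labels)
        self.root = root
        self.children = children
        self._postorder: np.ndarray | None = None
        self._node_depths: np.ndarray | None = None
        self._incidence: np.ndarray | None = None

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_edges(self) -> int:
        """Number of edges (every node but the root carries one)."""
        return self.n_nodes - 1

    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents)."""
        if self._postorder is None:
            order = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.asarray(order[::-1], dtype=np.int64)
        return self._postorder

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root depth 0)."""
        if self._node_depths is None:
            depths = np.zeros(self.n_nodes)
            for v in self.postorder()[::-1]:  # preorder
                if v != self.root:
                    depths[v] = depths[self.parent[v]] + self.edge_length[v]
            self._node_depths = depths
        return self._node_depths

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_tips]

    @property
    def depth(self) -> float:
        """Mean root-to-tip distance (tips are equidistant on an ultrametric tree)."""
        return float(self.tip_depths().mean())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return float(d.max() - d.min()) <= tol * max(float(d.max()), 1e-300)

    def edge_tip_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) incidence: row v marks tips subtended by v."""
        if self._incidence is None:
            M = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
            M[np.arange(self.n_tips), np.arange(self.n_tips)] = True
            for v in self.postorder():
                for c in self.children[v]:
                    M[v] |= M[c]
            self._incidence = M
        return self._incidence

    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    # ------------------------------------------------------------------ I/O
    def to_newick(self, precision: int = 17) -> str:
        """Serialise to a semicolon-terminated Newick string with branch lengths."""
        fmt = f"%.{precision}g"

        def rec(v: int) -> str:
            if v < self.n_tips:
                core = self.tip_labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return core + ":" + (fmt % self.edge_length[v])

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        leaves = [nd for nd in tree.leaf_node_iter()]
        internals = [nd for nd in tree.preorder_internal_node_iter()]
        idx: dict[int, int] = {}
        labels = []
        for i, nd in enumerate(leaves):
            idx[id(nd)] = i
            labels.append(nd.taxon.label if nd.taxon else str(i))
        for j, nd in enumerate(internals):
            idx[id(nd)] = len(leaves) + j
        n_nodes = len(leaves) + len(internals)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        elen = np.zeros(n_nodes)
        for nd in tree.preorder_node_iter():
            v = idx[id(nd)]
            if nd.parent_node is not None:
                parent[v] = idx[id(nd.parent_node)]
                elen[v] = float(nd.edge.length or 0.0)
        return cls(parent, elen, labels)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True,
                                 taxon_namespace=taxon_namespace)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny n_tips={self.n_tips} depth={self.depth:.4g}>"


def _default_labels(n: int) -> list[str]:
    return [f"t{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _check_n(n_tips: int) -> None:
    if n_tips < 2:
        raise ValueError(f"need at least 2 tips, got {n_tips}")


def simulate_yule(n_tips: int, birth_rate: float, rng: np.random.Generator) -> "Phylogeny":
    """Grow a pure-birth tree by the simple-sampling approach.

    Starting from the root split (two lineages at time 0), waiting times
    between speciations are exponential with rate ``birth_rate * k`` for
    ``k`` extant lineages and the splitting lineage is chosen uniformly.
    A final waiting interval is drawn while ``n_tips`` lineages are extant,
    so that all n-1 internode intervals of the reconstructed process are
    represented (the Pybus–Harvey gamma statistic of these trees is then
    standard normal).  The tree is *not* depth-normalised.
    """
    _check_n(n_tips)
    if birth_rate <= 0:
        raise ValueError(f"birth_rate must be positive, got {birth_rate}")
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    birth = np.zeros(n_nodes)
    split = np.zeros(n_nodes)
    root = n_tips  # first internal node created
    next_internal = n_tips + 1
    t = 0.0
    k = 2
    # active lineages as (parent node, birth time); slot i becomes tip i at the end
    lineages: list[tuple[int, float]] = [(root, 0.0), (root, 0.0)]
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        par, b = lineages[i]
        v = next_internal
        next_internal += 1
        parent[v] = par
        birth[v] = b
        split[v] = t
        lineages[i] = (v, t)
        lineages.append((v, t))
        k += 1
    t += rng.exponential(1.0 / (birth_rate * n_tips))  # hanging interval at n lineages
    elen = np.zeros(n_nodes)
    for v in range(n_tips, n_nodes):
        elen[v] = split[v] - birth[v]
    for j, (par, b) in enumerate(lineages):
        parent[j] = par
        elen[j] = t - b
    return Phylogeny(parent, elen, _default_labels(n_tips))


def simulate_coalescent(n_tips: int, rng: np.random.Generator) -> "Phylogeny":
    """Simulate a Kingman coalescent genealogy.

    With ``k`` lineages, the time to the next merger is exponential with
    rate ``k*(k-1)/2`` and the merging pair is uniform.  Node ages are
    measured from the tips; the resulting tree is ultrametric but not
    depth-normalised.
    """
    _check_n(n_tips)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    active = list(range(n_tips))
    t = 0.0
    nxt = n_tips
    k = n_tips
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        age[nxt] = t
        parent[a] = nxt
        parent[b] = nxt
        active[min(i, j)] = nxt
        active.pop(max(i, j))
        nxt += 1
        k -= 1
    elen = np.zeros(n_nodes)
    for v in range(n_nodes):
        if parent[v] != -1:
            elen[v] = age[parent[v]] - age[v]
    return Phylogeny(parent, elen, _default_labels(n_tips))


def _complete_pendants(parent: np.ndarray, elen: np.ndarray, n_tips: int,
                       draws: np.ndarray, root: int) -> None:
    """Lengthen pendant edges so every tip reaches the deepest provisional tip.

    ``draws`` are the provisional pendant lengths; each pendant is set to
    ``D - depth(parent)`` with ``D = max_j depth(parent_j) + draws_j``, which
    makes the tree ultrametric while keeping every pendant at least as long
    as its draw.
    """
    n_nodes = parent.size
    depth = np.zeros(n_nodes)
    order = sorted(range(n_tips, n_nodes), key=lambda v: -1 if v == root else 0)
    # compute internal depths via repeated relaxation (trees are small); use preorder
    # derived from parent pointers instead:
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for v in range(n_nodes):
        if parent[v] != -1:
            children[parent[v]].append(v)
    stack = [root]
    while stack:
        v = stack.pop()
        for c in children[v]:
            depth[c] = depth[v] + (elen[c] if c >= n_tips else 0.0)
            stack.append(c)
    parent_depth = depth[parent[np.arange(n_tips)]]
    D = float(np.max(parent_depth + draws))
    elen[:n_tips] = D - parent_depth


def make_balanced(n_tips: int, rng: np.random.Generator,
                  edge_style: str = "uniform") -> "Phylogeny":
    """Build a perfectly balanced (complete binary) ultrametric tree.

    ``edge_style='uniform'`` draws every edge length iid Uniform(0,1) and then
    lengthens pendant edges so all tips are equidistant from the root;
    ``edge_style='equal'`` gives every edge length 1 (already ultrametric).
    """
    _check_n(n_tips)
    if n_tips & (n_tips - 1):
        raise ValueError(f"n_tips must be a power of two, got {n_tips}")
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    root = n_tips
    nxt = [n_tips + 1]

    def build(tips: range, node: int) -> None:
        half = len(tips) // 2
        for sub in (tips[:half], tips[half:]):
            if len(sub) == 1:
                parent[sub[0]] = node
            else:
                v = nxt[0]
                nxt[0] += 1
                parent[v] = node
                build(sub, v)

    build(range(n_tips), root)
    elen = np.zeros(n_nodes)
    if edge_style == "equal":
        elen[:] = 1.0
    elif edge_style == "uniform":
        for v in range(n_tips, n_nodes):
            if v != root:
                elen[v] = rng.uniform(0.0, 1.0)
        draws = np.array([rng.uniform(0.0, 1.0) for _ in range(n_tips)])
        _complete_pendants(parent, elen, n_tips, draws, root)
    else:
        raise ValueError(f"unknown edge_style {edge_style!r}")
    elen[root] = 0.0
    return Phylogeny(parent, elen, _default_labels(n_tips))


def make_unbalanced(n_tips: int, rng: np.random.Generator) -> "Phylogeny":
    """Build a pectinate (caterpillar) ultrametric tree.

    Internal (spine) edges are iid Uniform(0,1); pendant edges are drawn the
    same way and then lengthened so the tree is ultrametric.  After depth
    normalisation internal edges are short and shallow-attaching tips carry
    long pendant edges — the maximally imbalanced shape (Colless index
    ``(n-1)(n-2)/2``).
    """
    _check_n(n_tips)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    root = n_tips
    elen = np.zeros(n_nodes)
    # spine: root -> tip 0 + internal; internal_k -> tip k + internal_{k+1};
    # the last internal subtends the final cherry (tips n-2, n-1)
    cur = root
    for k in range(n_tips - 2):
        parent[k] = cur
        v = cur + 1
        parent[v] = cur
        elen[v] = rng.uniform(0.0, 1.0)
        cur = v
    parent[n_tips - 2] = cur
    parent[n_tips - 1] = cur
    draws = np.array([rng.uniform(0.0, 1.0) for _ in range(n_tips)])
    _complete_pendants(parent, elen, n_tips, draws, root)
    return Phylogeny(parent, elen, _default_labels(n_tips))


# ---------------------------------------------------------------------------
# transforms & statistics
# ---------------------------------------------------------------------------

def rescale_depth(tree: Phylogeny, target_depth: float = 1.0) -> Phylogeny:
    """Rescale all edges so the root-to-tip distance equals ``target_depth``."""
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    d = tree.tip_depths()
    spread = float(d.max() - d.min())
    if spread > 1e-6 * max(float(d.max()), 1e-300):
        raise ValueError(f"tree is not ultrametric: tip-depth spread {spread:g}")
    factor = target_depth / float(d.mean())
    return Phylogeny(tree.parent.copy(), tree.edge_length * factor, tree.tip_labels)


def gamma_statistic(tree: Phylogeny) -> float:
    """Pybus–Harvey gamma statistic of an ultrametric tree.

    Computed from the internode intervals g_k (duration with k lineages,
    k = 2..n); standard normal under the pure-birth model.  Positive values
    indicate nodes concentrated toward the tips, negative toward the root.
    """
    n = tree.n_tips
    if n < 3:
        raise ValueError("gamma statistic requires at least 3 tips")
    if not tree.is_ultrametric(1e-6):
        raise ValueError("gamma statistic requires an ultrametric tree")
    depths = np.sort(tree.node_depths()[n:])  # internal node depths, root first
    tip_depth = float(tree.tip_depths().mean())
    times = np.concatenate([depths, [tip_depth]])
    g = np.diff(times)  # g[k-2] = interval with k lineages, k = 2..n
    ks = np.arange(2, n + 1)
    kg = ks * g
    T = float(kg.sum())
    prefix = np.cumsum(kg)  # prefix[i-2] = sum_{k=2..i} k g_k
    num = prefix[: n - 2].sum() / (n - 2) - T / 2.0
    den = T * np.sqrt(1.0 / (12.0 * (n - 2)))
    return float(num / den)


def colless_index(tree: Phylogeny) -> int:
    """Colless imbalance: sum over internal nodes of |left tips − right tips|."""
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    counts[: tree.n_tips] = 1
    total = 0
    for v in tree.postorder():
        ch = tree.children[v]
        if ch:
            counts[v] = counts[ch[0]] + counts[ch[1]]
            total += abs(int(counts[ch[0]]) - int(counts[ch[1]]))
    return total


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

def tree_rng(seed: int, generator: str, n_tips: int, index: int) -> np.random.Generator:
    """Deterministic per-tree random stream for batch generation."""
    if generator not in GENERATOR_CODES:
        raise ValueError(f"unknown generator {generator!r}")
    code = GENERATOR_CODES[generator]
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(code, n_tips, index, 0))
    return np.random.default_rng(ss)


@dataclass
class TreeBatch:
    """A homogeneous batch of simulated trees plus its provenance."""

    trees: list[Phylogeny]
    generator: str
    n_tips: int
    seed: int | None = None
    birth_rate: float | None = None
    edge_style: str | None = None
    size: int = field(init=False)

    def __post_init__(self) -> None:
        if self.generator not in GENERATOR_CODES:
            raise ValueError(f"unknown generator {self.generator!r}")
        for t in self.trees:
            if t.n_tips != self.n_tips:
                raise ValueError("all batch members must share n_tips")
        self.size = len(self.trees)

    def __len__(self) -> int:
        return self.size

    def __iter__(self):
        return iter(self.trees)

    def write(self, path: str | Path) -> None:
        """Write one Newick per line to ``path`` plus a ``.meta.json`` sidecar."""
        path = Path(path)
        write_newick_batch(self.trees, path)
        meta = {"generator": self.generator, "n_tips": self.n_tips,
                "seed": self.seed, "birth_rate": self.birth_rate,
                "edge_style": self.edge_style, "size": self.size}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "TreeBatch":
        path = Path(path)
        trees = read_newick_batch(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(trees=trees, generator=meta["generator"], n_tips=meta["n_tips"],
                   seed=meta.get("seed"), birth_rate=meta.get("birth_rate"),
                   edge_style=meta.get("edge_style"))


def generate_batch(generator: str, n_tips: int, n_trees: int, seed: int,
                   birth_rate: float = 0.5, edge_style: str = "uniform",
                   normalize: bool = True, target_depth: float = 1.0) -> TreeBatch:
    """Generate a reproducible batch of trees of one class.

    Per-tree random streams are derived from ``(seed, generator, n_tips,
    index)``, so batches are reproducible and order-independent.  With
    ``normalize`` every tree is rescaled to ``target_depth``.
    """
    trees = []
    for i in range(n_trees):
        rng = tree_rng(seed, generator, n_tips, i)
        if generator == "yule":
            t = simulate_yule(n_tips, birth_rate, rng)
        elif generator == "coalescent":
            t = simulate_coalescent(n_tips, rng)
        elif generator == "balanced":
            t = make_balanced(n_tips, rng, edge_style=edge_style)
        elif generator == "unbalanced":
            t = make_unbalanced(n_tips, rng)
        else:
            raise ValueError(f"unknown generator {generator!r}")
        if normalize:
            t = rescale_depth(t, target_depth)
        trees.append(t)
    return TreeBatch(trees=trees, generator=generator, n_tips=n_tips, seed=seed,
                     birth_rate=birth_rate if generator == "yule" else None,
                     edge_style=edge_style if generator == "balanced" else None)


def write_newick_batch(trees: Iterable[Phylogeny], path: str | Path) -> None:
    Path(path).write_text("".join(t.to_newick() + "\n" for t in trees))


def read_newick_batch(path: str | Path) -> list[Phylogeny]:
    return [Phylogeny.from_newick(line) for line in
            Path(path).read_text().splitlines() if line.strip()]
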