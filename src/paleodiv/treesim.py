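"""Forward simulation of birth-death trees with extinct tips retained.

A Gillespie simulation starts from a single lineage: with N lineages alive
and per-lineage rates lam (possibly diversity-dependent) and mu, the waiting
time to the next event is exponential with rate N (lam + mu); the event is a
speciation with probability lam / (lam + mu), else an extinction. Extinct
lineages stay in the tree as tips with positive age. The simulation stops at
``max_height`` (all survivors become extant tips) or when ``max_tips`` is
reached. Under diversity dependence the speciation rate declines linearly
with standing diversity, lam(N) = max(0, lam0 - (lam0 - mu0) N / K), so that
lam(K) = mu0 at the carrying capacity K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .phylo import TimeTree
from ._rng import rng_from_seed, spawn_seeds

__all__ = [
    "BDSimConfig",
    "SimBatchConfig",
    "SimulationFailure",
    "simulate_bd_tree",
    "simulate_dd_tree",
    "drop_random_tips",
    "graft_random_tips",
    "simulate_batch",
    "dd_batch_config",
    "constant_batch_config",
]


class SimulationFailure(RuntimeError):
    pass


@dataclass
class BDSimConfig:
    """One tree's simulation settings; K = inf disables diversity dependence."""

    lambda0: float
    mu0: float
    K: float = math.inf
    max_height: float = 7.0
    min_tips: int = 4
    max_tips: int = 500
    seed: int = 0
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        if not (self.lambda0 > self.mu0 >= 0):
            raise ValueError("need lambda0 > mu0 >= 0 for a viable clade")
        if not self.K > 1:
            raise ValueError("carrying capacity K must be > 1")
        if not self.max_height > 0:
            raise ValueError("max_height must be > 0")


def _grow_tree(config: BDSimConfig, rng: np.random.Generator) -> dendropy.Tree:
    """One forward pass; the returned tree may have fewer tips than ``min_tips``."""
    lam0, mu0, K = config.lambda0, config.mu0, config.K

    def lam(n: int) -> float:
        if math.isinf(K):
            return lam0
        return max(0.0, lam0 - (lam0 - mu0) * n / K)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    # alive: node -> birth time (forward time from the origin at 0)
    t = 0.0
    alive: dict[dendropy.Node, float] = {root: 0.0}
    n_tips = 1
    while alive:
        n = len(alive)
        rate_lam = lam(n)
        assert rate_lam >= 0.0
        total = n * (rate_lam + mu0)
        if total <= 0:
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next >= config.max_height:
            t = config.max_height
            break
        t = t_next
        node = list(alive)[rng.integers(n)]
        birth = alive.pop(node)
        node.edge.length = t - birth
        if rng.uniform() < rate_lam / (rate_lam + mu0):
            c1, c2 = dendropy.Node(), dendropy.Node()
            node.add_child(c1)
            node.add_child(c2)
            alive[c1] = t
            alive[c2] = t
            n_tips += 1
            if n_tips >= config.max_tips:
                break
        # else: extinction; node stays a leaf with its closed edge
    for node, birth in alive.items():
        node.edge.length = t - birth
    root.edge.length = None  # drop the stem; the tree is rooted at the first split
    leaves = [lf for lf in tree.leaf_node_iter()]
    for i, lf in enumerate(leaves):
        lf.taxon = taxa.new_taxon(label=f"t{i + 1}")
    return tree


def simulate_bd_tree(config: BDSimConfig) -> TimeTree:
    """Simulate one constant-rate (or diversity-dependent, if K finite) tree.

    Redraws until the tree has at least ``min_tips`` tips; raises
    :class:`SimulationFailure` after ``max_rejections`` failed attempts.
    """
    rng = rng_from_seed(config.seed)
    min_tips = max(2, config.min_tips)
    for _ in range(config.max_rejections):
        tree = _grow_tree(config, rng)
        if sum(1 for _ in tree.leaf_node_iter()) >= min_tips:
            return TimeTree(tree)
    raise SimulationFailure(
        f"clade died before reaching {config.min_tips} tips in "
        f"{config.max_rejections} attempts (lambda0={config.lambda0}, mu0={config.mu0})"
    )


def simulate_dd_tree(config: BDSimConfig) -> TimeTree:
    """Simulate one diversity-dependent tree; requires finite K."""
    if math.isinf(config.K):
        return simulate_bd_tree(config)
    return simulate_bd_tree(config)


def drop_random_tips(tree: TimeTree, fraction_max: float = 0.4,
                     seed: int | np.random.Generator = 0,
                     min_keep: int = 3) -> TimeTree:
    """Randomly remove up to ``fraction_max`` of tips (at least one).

    The number removed is uniform on {1, ..., floor(fraction_max * n)},
    capped so at least ``min_keep`` tips survive; the tips are drawn
    uniformly without replacement, and resulting unifurcations are
    suppressed with branch lengths merged so surviving root-to-tip distances
    are unchanged.
    """
    if not (0 <= fraction_max < 1):
        raise ValueError("need 0 <= fraction_max < 1")
    rng = rng_from_seed(seed)
    n = len(tree)
    k_max = min(int(math.floor(fraction_max * n)), n - min_keep)
    if k_max < 1:
        raise ValueError(
            f"fraction_max={fraction_max} of {n} tips leaves nothing to drop"
        )
    k = int(rng.integers(1, k_max + 1))
    to_drop = [tree.tip_labels[i] for i in rng.choice(n, size=k, replace=False)]
    clone = tree.tree.clone(depth=1)
    root_depths_kept = {
        lbl: tree.depth(lbl) for lbl in tree.tip_labels if lbl not in to_drop
    }
    clone.prune_taxa_with_labels(to_drop, suppress_unifurcations=True)
    # dendropy may leave (or re-root through) a degree-1 seed node; preserve
    # root-to-tip path lengths by keeping any residual length on the root edge.
    out = TimeTree(clone, groups={k_: v for k_, v in tree.groups.items() if k_ not in to_drop})
    ref = next(iter(root_depths_kept))
    shift = root_depths_kept[ref] - out.depth(ref)
    if abs(shift) > 1e-9:
        out.tree.seed_node.edge.length = (out.tree.seed_node.edge.length or 0.0) + shift
        out = TimeTree(out.tree, groups=out.groups)
    return out


def graft_random_tips(tree: TimeTree, max_added_fraction: float = 0.5,
                      group: str | None = None,
                      seed: int | np.random.Generator = 0) -> TimeTree:
    """Graft extra tips at random positions within a group's subtree span.

    Adds k ~ Uniform{1, ..., ceil(fraction * n_group)} tips. Each attaches at
    a uniform point along a uniformly chosen branch on the paths from the
    group's MRCA to the group's tips; the new tip's age is uniform between 0
    and the attachment age, so its branch length is positive. Existing
    pairwise MRCA times are untouched (edges are only subdivided).
    """
    if max_added_fraction < 0:
        raise ValueError("max_added_fraction must be >= 0")
    rng = rng_from_seed(seed)
    out = tree.clone()
    if max_added_fraction == 0:
        return out
    if group is None:
        group_tips = list(out.tip_labels)
    else:
        group_tips = [lbl for lbl in out.tip_labels if out.groups.get(lbl) == group]
    if len(group_tips) < 2:
        raise ValueError("group must have >= 2 tips to define a subtree span")
    k = int(rng.integers(1, int(math.ceil(max_added_fraction * len(group_tips))) + 1))
    next_id = 1
    from .phylo import mrca_node

    for _ in range(k):
        # candidate edges: paths from the group's MRCA down to the group's tips
        mrca = mrca_node(out, group_tips)
        on_path: set = set()
        leaf_by_label = {lf.taxon.label: lf for lf in out.tree.leaf_node_iter()}
        for lbl in group_tips:
            node = leaf_by_label[lbl]
            while node is not mrca and node is not None:
                on_path.add(node)
                node = node.parent_node
        candidates = list(on_path)
        if not candidates:
            raise SimulationFailure("no valid attachment edge in the group's subtree")
        node = candidates[rng.integers(len(candidates))]
        length = float(node.edge.length)
        u = rng.uniform()
        depth_child = out._depth[node]
        attach_depth = depth_child - u * length
        attach_age = out.height - attach_depth
        if attach_age <= 0:
            attach_age = out.height - (depth_child - 0.5 * length)
            attach_depth = out.height - attach_age
        tip_age = rng.uniform(0.0, attach_age)
        # split the edge at the attachment point
        parent = node.parent_node
        mid = dendropy.Node()
        parent.remove_child(node)
        parent.add_child(mid)
        mid.add_child(node)
        mid.edge.length = length - u * length
        node.edge.length = u * length
        new_leaf = dendropy.Node()
        mid.add_child(new_leaf)
        new_leaf.edge.length = attach_age - tip_age
        label = f"added_{next_id}"
        while label in out.tip_labels or label in group_tips:
            next_id += 1
            label = f"added_{next_id}"
        new_leaf.taxon = out.tree.taxon_namespace.new_taxon(label=label)
        next_id += 1
        if group is not None:
            out.groups[label] = group
        group_tips.append(label)
        out = TimeTree(out.tree, groups=out.groups)
    return out


@dataclass
class SimBatchConfig:
    """A batch of simulated trees with rates drawn per tree from normal distributions."""

    n_trees: int = 1000
    lambda0_mean: float = 0.9
    lambda0_sd: float = 0.2
    mu0_mean: float = 0.3
    mu0_sd: float = 0.1
    K_mean: float | None = 17.0
    K_sd: float | None = 3.0
    max_height: float = 7.0
    min_tips: int = 4
    max_tips: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def draw_params(self, rng: np.random.Generator) -> tuple[float, float, float]:
        """Draw (lambda0, mu0, K), redrawing until lambda0 > mu0 > 0 (and K > 1)."""
        for _ in range(10_000):
            lam = rng.normal(self.lambda0_mean, self.lambda0_sd)
            mu = rng.normal(self.mu0_mean, self.mu0_sd)
            if self.K_mean is None:
                K = math.inf
            else:
                K = rng.normal(self.K_mean, self.K_sd)
                if not K > 1:
                    continue
            if lam > mu > 0:
                return lam, mu, K
        raise SimulationFailure("could not draw valid batch parameters")


def dd_batch_config(n_trees: int = 1000, seed: int = 0, **overrides) -> SimBatchConfig:
    """Diversity-dependent regime defaults (rates and K per tree from normals)."""
    return SimBatchConfig(n_trees=n_trees, seed=seed, **overrides)


def constant_batch_config(n_trees: int = 1000, seed: int = 0, **overrides) -> SimBatchConfig:
    """Constant-rate regime defaults, tuned to a median total tip count near 17."""
    defaults = dict(
        lambda0_mean=0.52, lambda0_sd=0.11, mu0_mean=0.17, mu0_sd=0.06,
        K_mean=None, K_sd=None,
    )
    defaults.update(overrides)
    return SimBatchConfig(n_trees=n_trees, seed=seed, **defaults)


def simulate_batch(batch: SimBatchConfig) -> tuple[list[TimeTree], pd.DataFrame]:
    """Simulate a batch; returns the trees and a manifest of per-tree parameters."""
    seeds = spawn_seeds(batch.seed, 2 * batch.n_trees)
    param_rng = rng_from_seed(seeds[-1])
    trees = []
    rows = []
    for i in range(batch.n_trees):
        lam, mu, K = batch.draw_params(param_rng)
        cfg = BDSimConfig(
            lambda0=lam, mu0=mu, K=K, max_height=batch.max_height,
            min_tips=batch.min_tips, max_tips=batch.max_tips, seed=seeds[i],
        )
        tree = simulate_bd_tree(cfg)
        trees.append(tree)
        rows.append({
            "tree_id": i, "seed": seeds[i], "lambda0": lam, "mu0": mu,
            "K": (np.nan if math.isinf(K) else K),
            "n_tips": len(tree), "n_extant": tree.n_extant,
        })
    return trees, pd.DataFrame(rows)
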