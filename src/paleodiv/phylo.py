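"""Tree-based speciation-rate statistics and the PGLS diversity-dependence detector.

Works on rooted, time-calibrated, possibly non-ultrametric trees (extinct
tips end above the present). Tip ages are measured from the tree's own
present, defined as the maximum root-to-tip path length.

The tip speciation-rate statistic DR for tip i is the inverse of the
equal-splits weighted sum of edge lengths on the root-to-tip path,

    DR_i = ( sum_{j=1..N_i} l_j * 2^-(j-1) )^-1,

with j = 1 the edge nearest the tip: recent, rapidly splitting tips get
large DR. The diversity a tip "experienced" is the number of branches
crossing a time slice a fixed offset before the tip's height. The detector
regresses DR on that sliced diversity with Brownian-motion residual
covariance (PGLS) and classifies the slope's sign when significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TimeTree",
    "PglsFit",
    "GroupContrastFit",
    "read_newick",
    "write_newick",
    "tip_dr",
    "diversity_at_offset",
    "tip_rate_table",
    "pgls_fit",
    "brownian_covariance",
    "classify_trend",
    "fit_group_contrast",
]


class NewickFormatError(ValueError):
    pass


class TimeTree:
    """A rooted tree with branch lengths in Myr and per-tip ages/groups."""

    def __init__(self, tree: dendropy.Tree, groups: dict[str, str] | None = None):
        self.tree = tree
        self.groups = dict(groups or {})
        self._index()

    def _index(self) -> None:
        t = self.tree
        self._depth: dict[dendropy.Node, float] = {}
        for node in t.preorder_node_iter():
            if node.parent_node is None:
                self._depth[node] = 0.0
            else:
                length = node.edge.length
                if length is None:
                    raise NewickFormatError("tree has an edge with no branch length")
                if length < 0:
                    raise ValueError(f"negative branch length {length}")
                self._depth[node] = self._depth[node.parent_node] + float(length)
        self.leaves = [lf for lf in t.leaf_node_iter()]
        if len(self.leaves) < 2:
            raise ValueError("tree must have >= 2 tips")
        self.tip_labels = tuple(lf.taxon.label for lf in self.leaves)
        self.height = max(self._depth[lf] for lf in self.leaves)
        self._leaf_by_label = {lf.taxon.label: lf for lf in self.leaves}
        for lf in self.leaves:
            if lf.edge.length == 0:
                warnings.warn(f"zero-length terminal branch at tip {lf.taxon.label!r}")
                break

    def __len__(self) -> int:
        return len(self.leaves)

    def depth(self, label: str) -> float:
        return self._depth[self._leaf_by_label[label]]

    def tip_age(self, label: str) -> float:
        """Age of a tip in Ma before the tree's present (0 for the youngest tips)."""
        return self.height - self.depth(label)

    @property
    def tip_ages(self) -> dict[str, float]:
        return {lbl: self.tip_age(lbl) for lbl in self.tip_labels}

    @property
    def n_extant(self) -> int:
        return sum(1 for lbl in self.tip_labels if self.tip_age(lbl) < 1e-9)

    def clone(self) -> "TimeTree":
        return TimeTree(self.tree.clone(depth=1), groups=self.groups)

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        ).strip()


def read_newick(path: str | Path, groups: dict[str, str] | None = None) -> TimeTree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return TimeTree(tree, groups=groups)


def write_newick(tree: TimeTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


def tree_from_newick_string(s: str, groups: dict[str, str] | None = None) -> TimeTree:
    t = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    return TimeTree(t, groups=groups)


def mrca_node(tree: TimeTree, labels) -> dendropy.Node:
    """Most recent common ancestor of a set of tips (robust to tree surgery)."""
    labels = list(labels)
    chains = []
    for lbl in labels:
        node = tree._leaf_by_label[lbl]
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains.append(chain[::-1])  # root -> leaf
    k = 0
    while all(len(c) > k for c in chains) and all(c[k] is chains[0][k] for c in chains):
        k += 1
    return chains[0][k - 1]


def tip_dr(tree: TimeTree, tip: str) -> float:
    """Equal-splits tip speciation rate (per Myr) for one tip."""
    node = tree._leaf_by_label[tip]
    total = 0.0
    weight = 1.0
    while node.parent_node is not None:
        total += float(node.edge.length) * weight
        weight *= 0.5
        node = node.parent_node
    if total <= 0:
        raise ValueError(f"tip {tip!r}: all weighted path lengths are zero; DR undefined")
    return 1.0 / total


def diversity_at_offset(tree: TimeTree, tip: str, offset: float) -> int:
    """Number of lineages alive ``offset`` Myr before the tip's height.

    Counts the branches of the tree crossing the time slice at age
    (tip age + offset); the focal tip's own ancestral lineage is one of
    them. A slice at or above the root returns 1 (the stem lineage) with a
    warning.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    t = tree.tip_age(tip) + offset
    if t >= tree.height:
        warnings.warn(
            f"slice at {t} Ma is at or above the root ({tree.height} Ma); returning the stem"
        )
        return 1
    count = 0
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        node_age = tree.height - tree._depth[node]
        parent_age = tree.height - tree._depth[node.parent_node]
        if node_age <= t < parent_age:
            count += 1
    return count


def tip_rate_table(tree: TimeTree, offset: float = 0.5,
                   groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-tip DR and sliced diversity (SD), as a DataFrame indexed by tip."""
    groups = groups if groups is not None else tree.groups
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lbl in tree.tip_labels:
            rows.append({
                "tip": lbl,
                "group": groups.get(lbl),
                "dr": tip_dr(tree, lbl),
                "sd": diversity_at_offset(tree, lbl, offset),
            })
    return pd.DataFrame(rows).set_index("tip")


def brownian_covariance(tree: TimeTree, labels: list[str] | None = None) -> np.ndarray:
    """Brownian-motion covariance: V[i, j] = root-to-MRCA path length.

    On a non-ultrametric tree the diagonal is each tip's root-to-tip depth,
    so residual variance grows with the evolutionary time a tip accumulated
    (this is how non-contemporaneous tips are weighted).
    """
    labels = list(labels or tree.tip_labels)
    pos = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    leaf_sets: dict[dendropy.Node, list[int]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            idx = [pos[lbl]] if lbl in pos else []
            leaf_sets[node] = idx
            for i in idx:
                V[i, i] = tree._depth[node]
        else:
            child_sets = [leaf_sets[c] for c in node.child_nodes()]
            depth = tree._depth[node]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            V[i, j] = V[j, i] = depth
            leaf_sets[node] = [i for s in child_sets for i in s]
    return V


@dataclass
class PglsFit:
    """Coefficients of a phylogenetic GLS fit with t-tests at n - p df."""

    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    sigma2: float

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues},
            index=list(self.names),
        )


def pgls_fit(tree: TimeTree, response: pd.Series | dict,
             predictors: pd.DataFrame, add_intercept: bool = True) -> PglsFit:
    """Generalized least squares with Brownian residual covariance from the tree.

    ``response`` and ``predictors`` are indexed by tip label; every tip used
    must carry both. Estimates b = (X' V^-1 X)^-1 X' V^-1 y and tests each
    coefficient with a two-sided t-test at n - p degrees of freedom.
    """
    if isinstance(response, dict):
        response = pd.Series(response)
    labels = list(predictors.index)
    y = response.loc[labels].to_numpy(dtype=float)
    X = predictors.to_numpy(dtype=float)
    names = list(predictors.columns)
    if add_intercept:
        X = np.column_stack([np.ones(len(labels)), X])
        names = ["intercept"] + names
    V = brownian_covariance(tree, labels)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"Brownian covariance matrix is singular or near-singular (cond={cond:.3g})"
        )
    res = sm.GLS(y, X, sigma=V).fit()
    return PglsFit(
        names=tuple(names),
        params=np.asarray(res.params, float),
        bse=np.asarray(res.bse, float),
        tvalues=np.asarray(res.tvalues, float),
        pvalues=np.asarray(res.pvalues, float),
        df_resid=int(res.df_resid),
        sigma2=float(res.scale),
    )


def classify_trend(tree: TimeTree, offset: float = 0.5,
                   alpha_level: float = 0.05) -> str:
    """Detect diversity dependence of speciation on one tree.

    Fits DR ~ diversity-at-offset by PGLS (single group, no group term) and
    returns "negative" or "positive" if the slope is significant two-sided at
    ``alpha_level``, else "none". Degenerate trees (constant diversity,
    singular covariance) return "none" with a warning rather than raising, so
    calibration sweeps never abort.
    """
    if len(tree) < 4:
        raise ValueError("detector needs >= 4 tips")
    tab = tip_rate_table(tree, offset=offset)
    sd = tab["sd"].to_numpy(dtype=float)
    if np.ptp(sd) == 0:
        warnings.warn("diversity predictor is constant across tips; no trend detectable")
        return "none"
    try:
        fit = pgls_fit(tree, tab["dr"], tab[["sd"]])
    except np.linalg.LinAlgError as err:
        warnings.warn(f"PGLS failed ({err}); classifying as none")
        return "none"
    p = fit.pvalue("sd")
    if not np.isfinite(p) or p >= alpha_level:
        return "none"
    return "negative" if fit.coef("sd") < 0 else "positive"


@dataclass
class GroupContrastFit:
    """Two-group PGLS with a diversity-by-group interaction."""

    fit: PglsFit
    groups: tuple[str, str]
    interaction_p: float
    simple_slopes: dict[str, float]


def fit_group_contrast(tree: TimeTree, groups: dict[str, str],
                       offset: float = 0.5) -> GroupContrastFit:
    """Fit DR ~ SD x group and report the slope contrast between the groups.

    The first (alphabetical) group is the reference; the interaction
    coefficient is the difference between the second group's slope and the
    reference slope.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    for g in labels:
        if sum(1 for v in groups.values() if v == g) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 tips")
    tab = tip_rate_table(tree, offset=offset, groups=groups)
    ind = (tab["group"] == labels[1]).astype(float)
    X = pd.DataFrame(
        {"sd": tab["sd"].astype(float), "group": ind, "sd_x_group": tab["sd"] * ind},
        index=tab.index,
    )
    fit = pgls_fit(tree, tab["dr"], X)
    slope_ref = fit.coef("sd")
    slope_other = slope_ref + fit.coef("sd_x_group")
    return GroupContrastFit(
        fit=fit,
        groups=(labels[0], labels[1]),
        interaction_p=fit.pvalue("sd_x_group"),
        simple_slopes={labels[0]: slope_ref, labels[1]: slope_other},
    )
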