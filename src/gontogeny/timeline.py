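"""Evolutionary timelines from rooted trees of functions.

A rooted tree of functions (ToF) orders its leaves from most ancient to most
recent.  The relative age of a leaf is its node distance ``nd``: the number
of internal nodes on the root-to-leaf path (excluding the root itself),
normalized by the maximum such depth so that the most basal leaf scores 0 and
the deepest leaf scores 1.  Alongside ``nd`` the timeline records the
distribution index ``f`` (fraction of genomes encoding the taxon) and the
Venn group (which superkingdoms contain it).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .census import AbundanceMatrix, GenomeMeta
from .parsimony import PhyloTree

DEFAULT_AGE_BINS = (0.0, 0.4, 0.6, 1.0)


def leaf_depths(tree: PhyloTree) -> dict[str, int]:
    """Internal nodes on the root-to-leaf path, excluding the root.

    Equivalently the edge count of the path minus one; a leaf attached
    directly at the root split has depth 0.
    """
    if tree.root is None:
        raise ValueError("node distances require a rooted tree")
    depths: dict[str, int] = {}
    stack = [(tree.root, None, 0)]
    while stack:
        node, par, edges = stack.pop()
        if node in tree.labels and node != tree.root:
            depths[tree.labels[node]] = edges - 1
        for nb in tree.adj[node]:
            if nb != par:
                stack.append((nb, node, edges + 1))
    return depths


def node_distance(
    tree: PhyloTree, divisor: int | None = None
) -> dict[str, float]:
    """Relative age per leaf: depth / max depth, on a 0 (ancient) to 1
    (recent) scale.

    ``divisor`` overrides the default max-depth normalization (e.g. to use
    the taxon count instead); values are kept at full precision — rounding
    is presentation-side.
    """
    depths = leaf_depths(tree)
    denom = divisor if divisor is not None else max(depths.values())
    if denom == 0:
        return {leaf: 0.0 for leaf in depths}
    return {leaf: d / denom for leaf, d in depths.items()}


def distribution_index(
    m: AbundanceMatrix, genomes: list[str] | None = None
) -> dict[str, float]:
    """f(t) = fraction of in-scope genomes with a non-zero census of t."""
    scope = m.genomes if genomes is None else [g for g in m.genomes if g in set(genomes)]
    if not scope:
        raise ValueError("empty genome scope")
    sub = m.counts[scope]
    present = (sub.values > 0).sum(axis=1)
    return {t: n / len(scope) for t, n in zip(m.taxa, present)}


def venn_group(
    m: AbundanceMatrix, meta: GenomeMeta
) -> tuple[dict[str, str], set[str]]:
    """Superkingdom combination (letters in A, B, E order) per taxon.

    Returns ``(groups, absent)`` where ``absent`` collects taxa found in no
    genome at all (they carry no group).
    """
    missing = [g for g in m.genomes if g not in meta.superkingdom]
    if missing:
        raise ValueError(f"genomes without superkingdom labels: {missing}")
    groups: dict[str, str] = {}
    absent: set[str] = set()
    sk = np.array([meta.superkingdom[g] for g in m.genomes])
    present = m.counts.values > 0
    for i, taxon in enumerate(m.taxa):
        letters = "".join(k for k in "ABE" if np.any(present[i] & (sk == k)))
        if letters:
            groups[taxon] = letters
        else:
            absent.add(taxon)
    return groups, absent


# ---------------------------------------------------------------------------
# genealogical sorting


def _union_nodes(tree: PhyloTree, group_leaves: set[int]) -> int:
    """Internal nodes on the union of leaf-to-MRCA paths for the group."""
    parent: dict[int, int | None] = {tree.root: None}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for nb in tree.adj[node]:
            if nb not in parent:
                parent[nb] = node
                stack.append(nb)

    def path_to_root(leaf: int) -> list[int]:
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = parent[node]
        return path

    paths = [path_to_root(l) for l in group_leaves]
    # MRCA = deepest node common to all root paths
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    mrca = max(common, key=lambda n: len(path_to_root(n)))
    union: set[int] = set()
    for p in paths:
        for node in p:
            union.add(node)
            if node == mrca:
                break
    return len(union - set(group_leaves))


def gsi_statistic(tree: PhyloTree, group: set[str]) -> float:
    """Genealogical sorting statistic on a rooted binary tree.

    gs = (n - 1) / |U| where U is the set of internal nodes needed to unite
    the ``n`` group members (the union of their paths to the group MRCA).
    Equals 1 iff the group is monophyletic, decreasing toward 0 as members
    disperse; a group spanning all leaves scores 1.
    """
    if tree.root is None:
        raise ValueError("GSI requires a rooted tree")
    by_label = {l: n for n, l in tree.labels.items()}
    unknown = group - set(by_label)
    if unknown:
        raise ValueError(f"group members not in tree: {sorted(unknown)}")
    if len(group) < 2:
        raise ValueError("group must have at least 2 members")
    nodes = {by_label[l] for l in group}
    return (len(group) - 1) / _union_nodes(tree, nodes)


def gsi(
    tree: PhyloTree,
    group: set[str],
    n_perm: int = 10_000,
    seed: int = 0,
    exact_limit: int = 200_000,
) -> tuple[float, float]:
    """GSI with a permutation p-value under random leaf labelling.

    When the number of possible group placements C(L, n) is at most
    ``exact_limit`` the null is enumerated exhaustively; otherwise ``n_perm``
    Monte Carlo draws are used.  p = fraction of placements with a statistic
    at least as large as observed.
    """
    obs = gsi_statistic(tree, group)
    leaves = sorted(tree.leaf_labels())
    k = len(group)
    total = math.comb(len(leaves), k)
    if total <= exact_limit:
        hits = sum(
            1
            for combo in itertools.combinations(leaves, k)
            if gsi_statistic(tree, set(combo)) >= obs - 1e-12
        )
        return obs, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        combo = rng.choice(len(leaves), size=k, replace=False)
        if gsi_statistic(tree, {leaves[i] for i in combo}) >= obs - 1e-12:
            hits += 1
    return obs, hits / n_perm


# ---------------------------------------------------------------------------
# timeline assembly and summaries


@dataclass
class Timeline:
    """Per-taxon evolutionary record for one hierarchy level."""

    table: pd.DataFrame  # columns: taxon, nd, f, venn, categories (set)

    def to_tsv(self, handle) -> None:
        df = self.table.copy()
        df["categories"] = df["categories"].map(lambda s: ",".join(sorted(s)))
        df.to_csv(handle, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Timeline":
        df = df.copy()
        if "categories" in df and df["categories"].dtype == object:
            df["categories"] = df["categories"].map(
                lambda v: set(v.split(",")) if isinstance(v, str) and v else
                (v if isinstance(v, set) else set())
            )
        return cls(df)


def build_timeline(
    tree: PhyloTree,
    matrix: AbundanceMatrix,
    meta: GenomeMeta,
    categories: dict[str, set[str]] | None = None,
    divisor: int | None = None,
) -> Timeline:
    """Assemble nd, f, Venn group and level-1 categories for each leaf."""
    nd = node_distance(tree, divisor=divisor)
    f = distribution_index(matrix)
    groups, absent = venn_group(matrix, meta)
    rows = []
    for taxon in sorted(nd):
        rows.append(
            {
                "taxon": taxon,
                "nd": nd[taxon],
                "f": f.get(taxon, 0.0),
                "venn": groups.get(taxon, ""),
                "categories": set(categories.get(taxon, set())) if categories else set(),
            }
        )
    return Timeline(pd.DataFrame(rows))


def age_histogram(
    timeline: Timeline, bins: tuple[float, ...] = DEFAULT_AGE_BINS
) -> pd.DataFrame:
    """Counts of taxa per (nd bin, level-1 category).

    Bins are half-open [lo, hi) except the last, which is closed; taxa in
    several categories count once per category.
    """
    df = timeline.table
    if ((df["nd"] < 0) | (df["nd"] > 1)).any():
        raise ValueError("nd values must lie in [0, 1]")
    labels = [f"{lo}-{hi}" for lo, hi in zip(bins[:-1], bins[1:])]

    def bin_of(nd: float) -> str:
        for i, (lo, hi) in enumerate(zip(bins[:-1], bins[1:])):
            last = i == len(labels) - 1
            if lo <= nd < hi or (last and nd <= hi):
                return labels[i]
        raise ValueError(f"nd {nd} outside bins {bins}")

    counts: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        cats = row["categories"] or {""}
        b = bin_of(row["nd"])
        for cat in cats:
            counts[(b, cat)] = counts.get((b, cat), 0) + 1
    table = pd.Series(counts).unstack(fill_value=0)
    return table.reindex(labels, fill_value=0)


def accumulation_curve(nd_values: dict[str, float]) -> pd.DataFrame:
    """Step function of cumulative distinct-taxon count by nd."""
    s = pd.Series(nd_values).sort_values(kind="mergesort")
    grid = s.unique()
    cum = [int((s <= x).sum()) for x in grid]
    return pd.DataFrame({"nd": grid, "cumulative": cum})


def accumulation_regression(
    reference: dict[str, float], other: dict[str, float]
) -> dict[str, float | None]:
    """OLS line through paired cumulative counts of two levels.

    At every nd in the union grid, x = cumulative count of the reference
    level and y = of the other level; slope/intercept/R^2 of y on x.  Slope
    is omitted (None) with fewer than 3 grid points.
    """
    grid = np.unique(np.concatenate([
        np.fromiter(reference.values(), float),
        np.fromiter(other.values(), float),
    ]))
    ref = np.sort(np.fromiter(reference.values(), float))
    oth = np.sort(np.fromiter(other.values(), float))
    x = np.searchsorted(ref, grid, side="right")
    y = np.searchsorted(oth, grid, side="right")
    if len(grid) < 3 or np.ptp(x) == 0:
        return {"slope": None, "intercept": None, "r2": None}
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
    }
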