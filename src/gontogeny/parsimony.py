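"""Maximum parsimony for linearly ordered (Wagner/additive) characters.

Characters take integer states 0-31 and a change from state ``i`` to ``j``
costs ``|i - j|`` steps.  Tree length is computed with the Farris interval
down-pass; an independent Sankoff dynamic program over the full state space
serves as a cross-check oracle.  Heuristic tree search uses stepwise addition
with random addition sequences followed by tree bisection and reconnection
(TBR).  Unrooted most-parsimonious trees are rooted with the Lundberg method:
a hypothetical ancestor with user-specified states is attached to every edge
in turn and the cheapest attachment point becomes the root.

Trees are strictly binary (internal degree 3 unrooted; the root has degree 2
after rooting); leaves carry taxon labels matching the rows of the character
matrix (a pandas DataFrame of integer states).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_INF = np.int64(1 << 30)


# ---------------------------------------------------------------------------
# tree structure


class PhyloTree:
    """Unrooted (or rooted) tree over integer nodes with labelled leaves."""

    __slots__ = ("adj", "labels", "root", "_next")

    def __init__(
        self,
        adj: Mapping[int, Iterable[int]],
        labels: Mapping[int, str],
        root: int | None = None,
    ) -> None:
        self.adj: dict[int, set[int]] = {n: set(nb) for n, nb in adj.items()}
        self.labels: dict[int, str] = dict(labels)
        self.root = root
        self._next = max(self.adj, default=-1) + 1

    # -- construction -------------------------------------------------

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "PhyloTree":
        """Unique topology on 1-3 leaves (a point, an edge, or a star)."""
        n = len(labels)
        if n == 0:
            raise ValueError("need at least one taxon")
        if n == 1:
            return cls({0: set()}, {0: labels[0]})
        if n == 2:
            return cls({0: {1}, 1: {0}}, {0: labels[0], 1: labels[1]})
        if n == 3:
            adj = {0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}}
            return cls(adj, {i: l for i, l in enumerate(labels)})
        raise ValueError("from_labels builds trees for up to 3 taxa; insert the rest")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.adj, self.labels, self.root)

    # -- basic queries -------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaves(self) -> dict[int, str]:
        return dict(self.labels)

    def leaf_labels(self) -> set[str]:
        return set(self.labels.values())

    def edges(self) -> list[tuple[int, int]]:
        """Deterministically ordered edge list (sorted node pairs)."""
        return sorted(
            (min(u, v), max(u, v)) for u in self.adj for v in self.adj[u] if u < v
        )

    def new_node(self) -> int:
        node = self._next
        self._next += 1
        self.adj[node] = set()
        return node

    # -- surgery --------------------------------------------------------

    def insert_leaf(self, edge: tuple[int, int], label: str) -> tuple[int, int]:
        """Subdivide ``edge`` and attach a new leaf; returns (junction, leaf)."""
        u, v = edge
        if v not in self.adj[u]:
            raise ValueError(f"{edge} is not an edge")
        w = self.new_node()
        leaf = self.new_node()
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.adj[u].add(w)
        self.adj[v].add(w)
        self.adj[w] |= {u, v, leaf}
        self.adj[leaf].add(w)
        self.labels[leaf] = label
        return w, leaf

    def remove_leaf(self, leaf: int) -> None:
        """Detach a leaf and splice out its degree-2 junction."""
        (junction,) = self.adj[leaf]
        self.adj[junction].discard(leaf)
        del self.adj[leaf]
        del self.labels[leaf]
        if len(self.adj[junction]) == 2 and junction not in self.labels:
            a, b = self.adj[junction]
            self.adj[a].discard(junction)
            self.adj[b].discard(junction)
            self.adj[a].add(b)
            self.adj[b].add(a)
            del self.adj[junction]
            if self.root == junction:
                self.root = None

    def root_on_edge(self, edge: tuple[int, int]) -> int:
        """Place a degree-2 root on ``edge``; returns the root node."""
        u, v = edge
        if v not in self.adj[u]:
            raise ValueError(f"{edge} is not an edge")
        r = self.new_node()
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.adj[u].add(r)
        self.adj[v].add(r)
        self.adj[r] |= {u, v}
        self.root = r
        return r

    def unrooted(self) -> "PhyloTree":
        """Copy with a degree-2 root spliced out."""
        t = self.copy()
        r = t.root
        t.root = None
        if r is not None and len(t.adj[r]) == 2 and r not in t.labels:
            a, b = t.adj[r]
            t.adj[a].discard(r)
            t.adj[b].discard(r)
            t.adj[a].add(b)
            t.adj[b].add(a)
            del t.adj[r]
        return t

    # -- bipartitions and newick ----------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each written as the side without the
        lexicographically smallest taxon (canonical)."""
        ref = min(self.labels.values())
        out: set[frozenset[str]] = set()
        for u, v in self.edges():
            side = self._side_labels(u, v)
            if ref in side:
                side = self.leaf_labels() - side
            if 1 < len(side) < self.n_leaves - 1:
                out.add(frozenset(side))
        return out

    def _side_labels(self, start: int, blocked: int) -> set[str]:
        seen = {blocked, start}
        stack = [start]
        labels = set()
        while stack:
            node = stack.pop()
            if node in self.labels:
                labels.add(self.labels[node])
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return labels

    def to_newick(self, branch_labels: Mapping[frozenset[str], str] | None = None) -> str:
        """Deterministic newick string; rooted trees keep their root, unrooted
        trees are written from the junction next to the smallest leaf."""
        if self.n_leaves == 1:
            return f"{next(iter(self.labels.values()))};"
        if self.root is not None:
            top, parent = self.root, None
        else:
            leaf = min(self.labels, key=lambda n: self.labels[n])
            if self.n_leaves == 2:
                a, b = sorted(self.labels.values())
                return f"({a},{b});"
            (top,) = [n for n in self.adj[leaf]]
            parent = None

        def clade_key(node: int, par: int) -> str:
            return min(self._subtree_labels(node, par))

        def write(node: int, par: int | None) -> str:
            kids = sorted(
                (nb for nb in self.adj[node] if nb != par),
                key=lambda k: clade_key(k, node),
            )
            if not kids:
                return self.labels[node]
            inner = ",".join(write(k, node) for k in kids)
            label = ""
            if branch_labels and par is not None:
                split = self._canonical_split(node, par)
                label = branch_labels.get(split, "")
            return f"({inner}){label}"

        return write(top, parent) + ";"

    def _subtree_labels(self, node: int, par: int | None) -> set[str]:
        if par is None:
            return self.leaf_labels()
        return self._side_labels(node, par)

    def _canonical_split(self, node: int, par: int) -> frozenset[str]:
        side = self._side_labels(node, par)
        if min(self.labels.values()) in side:
            side = self.leaf_labels() - side
        return frozenset(side)


def from_newick(text: str, rooted: bool = False) -> PhyloTree:
    """Parse a (labelled-leaf) newick string into a :class:`PhyloTree`.

    Internal node labels and branch lengths are ignored.  With ``rooted``
    the top-level node is kept as the root (it must have exactly two
    children for downstream node-distance work); otherwise a degree-2 top
    node is spliced out.
    """
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")
    tree = PhyloTree({}, {})
    ids: dict[object, int] = {}

    def nid(dnode) -> int:
        if dnode not in ids:
            ids[dnode] = tree.new_node()
        return ids[dnode]

    for dnode in dtree.preorder_node_iter():
        u = nid(dnode)
        if dnode.is_leaf():
            tree.labels[u] = dnode.taxon.label.replace(" ", "_")
        for child in dnode.child_nodes():
            v = nid(child)
            tree.adj[u].add(v)
            tree.adj[v].add(u)
    top = nid(dtree.seed_node)
    if rooted:
        tree.root = top
    elif len(tree.adj[top]) == 2 and top not in tree.labels:
        a, b = tree.adj[top]
        tree.adj[a].discard(top)
        tree.adj[b].discard(top)
        tree.adj[a].add(b)
        tree.adj[b].add(a)
        del tree.adj[top]
    return tree


# ---------------------------------------------------------------------------
# character handling


def _state_dict(states: pd.DataFrame | Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    if isinstance(states, pd.DataFrame):
        return {
            str(label): np.asarray(row.values, dtype=np.int64)
            for label, row in states.iterrows()
        }
    return {k: np.asarray(v, dtype=np.int64) for k, v in states.items()}


def _check_taxa(tree: PhyloTree, S: Mapping[str, np.ndarray]) -> None:
    missing = tree.leaf_labels() - set(S)
    if missing:
        raise ValueError(f"taxa without character rows: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Farris interval length


def _combine(lo1, hi1, lo2, hi2):
    """Farris interval combination: intersection when non-empty, otherwise
    the gap interval, with the gap width as incurred cost."""
    lo = np.maximum(lo1, lo2)
    hi = np.minimum(hi1, hi2)
    gap = lo - hi
    disjoint = gap > 0
    new_lo = np.where(disjoint, hi, lo)
    new_hi = np.where(disjoint, lo, hi)
    return new_lo, new_hi, np.where(disjoint, gap, 0)


def _topo_order(tree: PhyloTree, start: int, blocked: int | None) -> list[tuple[int, int | None]]:
    order = []
    stack = [(start, blocked)]
    while stack:
        node, par = stack.pop()
        order.append((node, par))
        for nb in tree.adj[node]:
            if nb != par:
                stack.append((nb, node))
    return order


def _subtree_interval(tree, start, blocked, S, steps, n_chars):
    """Down-pass interval of the component hanging from ``start`` away from
    ``blocked``; accumulates per-character steps in ``steps``."""
    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}
    for node, par in reversed(_topo_order(tree, start, blocked)):
        kids = [nb for nb in tree.adj[node] if nb != par]
        if not kids:
            s = S[tree.labels[node]]
            lo[node] = s
            hi[node] = s
        elif len(kids) == 1:
            lo[node], hi[node] = lo[kids[0]], hi[kids[0]]
        elif len(kids) == 2:
            l, h, g = _combine(lo[kids[0]], hi[kids[0]], lo[kids[1]], hi[kids[1]])
            steps += g
            lo[node], hi[node] = l, h
        else:
            raise ValueError("tree is not binary (internal polytomy)")
    return lo[start], hi[start]


def wagner_length(
    tree: PhyloTree,
    states: pd.DataFrame | Mapping[str, np.ndarray],
    per_character: bool = False,
):
    """Minimum total steps under ordered-character (additive) costs.

    Computed with the Farris interval down-pass on an arbitrary rooting; the
    result is independent of that rooting.
    """
    S = _state_dict(states)
    _check_taxa(tree, S)
    n_chars = len(next(iter(S.values())))
    steps = np.zeros(n_chars, dtype=np.int64)
    if tree.n_leaves >= 2:
        work = tree.unrooted() if tree.root is not None else tree
        u, v = work.edges()[0]
        lo1, hi1 = _subtree_interval(work, u, v, S, steps, n_chars)
        lo2, hi2 = _subtree_interval(work, v, u, S, steps, n_chars)
        _, _, g = _combine(lo1, hi1, lo2, hi2)
        steps += g
    if per_character:
        return steps
    return int(steps.sum())


# ---------------------------------------------------------------------------
# Sankoff oracle


def sankoff_length(
    tree: PhyloTree,
    states: pd.DataFrame | Mapping[str, np.ndarray],
    n_states: int | None = None,
) -> int:
    """Generalized parsimony DP with cost matrix ``c(i, j) = |i - j|``.

    Independent of :func:`wagner_length`; must agree with it on every
    instance.  Child-to-parent messages use the linear-cost distance
    transform over the state axis.
    """
    S = _state_dict(states)
    _check_taxa(tree, S)
    if tree.n_leaves < 2:
        return 0
    if n_states is None:
        n_states = int(max(v.max() for v in S.values())) + 1
    n_chars = len(next(iter(S.values())))

    def message(cost: np.ndarray) -> np.ndarray:
        m = cost.copy()
        for j in range(1, n_states):
            np.minimum(m[:, j], m[:, j - 1] + 1, out=m[:, j])
        for j in range(n_states - 2, -1, -1):
            np.minimum(m[:, j], m[:, j + 1] + 1, out=m[:, j])
        return m

    def node_cost(node: int, par: int | None, cost_of: dict) -> np.ndarray:
        kids = [nb for nb in tree.adj[node] if nb != par]
        if not kids:
            c = np.full((n_chars, n_states), _INF, dtype=np.int64)
            c[np.arange(n_chars), S[tree.labels[node]]] = 0
            return c
        return sum(message(cost_of[k]) for k in kids)

    work = tree.unrooted() if tree.root is not None else tree
    u, v = work.edges()[0]

    def down(start: int, blocked: int) -> np.ndarray:
        cost_of: dict[int, np.ndarray] = {}
        for node, par in reversed(_topo_order(work, start, blocked)):
            cost_of[node] = node_cost(node, par, cost_of)
            for nb in work.adj[node]:
                if nb != par:
                    cost_of.pop(nb, None)
        return cost_of[start]

    cu = down(u, v)
    cv = message(down(v, u))
    total = (cu + cv).min(axis=1).sum()
    return int(total)


# ---------------------------------------------------------------------------
# search


def enumerate_topologies(labels: Sequence[str]):
    """Yield every unrooted binary topology over ``labels`` (3 or more)."""
    labels = list(labels)
    if len(labels) < 4:
        yield PhyloTree.from_labels(labels)
        return

    def grow(tree: PhyloTree, remaining: list[str]):
        if not remaining:
            yield tree
            return
        label, rest = remaining[0], remaining[1:]
        for edge in tree.edges():
            t = tree.copy()
            t.insert_leaf(edge, label)
            yield from grow(t, rest)

    yield from grow(PhyloTree.from_labels(labels[:3]), labels[3:])


@dataclass
class SearchResult:
    trees: list[PhyloTree]
    length: int
    n_replicates: int = 0

    @property
    def best(self) -> PhyloTree:
        """First tree in the canonical newick sort (the downstream choice)."""
        return self.trees[0]


def _edge_attachment_intervals(tree: PhyloTree, S, n_chars):
    """Per-edge Farris attachment intervals and the component length.

    For every edge, the interval of optimal states of a junction subdividing
    it, from the down-pass subtree interval on one side combined with the
    up-pass rest-of-tree interval on the other.
    """
    steps = np.zeros(n_chars, dtype=np.int64)
    if tree.n_leaves == 1:
        leaf = next(iter(tree.labels))
        s = S[tree.labels[leaf]]
        return {None: (s, s)}, 0
    u, v = tree.edges()[0]
    order = _topo_order(tree, u, v) + _topo_order(tree, v, u)
    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}
    for node, par in reversed(order):
        kids = [nb for nb in tree.adj[node] if nb != par]
        if not kids:
            s = S[tree.labels[node]]
            lo[node], hi[node] = s, s
        elif len(kids) == 1:
            lo[node], hi[node] = lo[kids[0]], hi[kids[0]]
        else:
            l, h, g = _combine(lo[kids[0]], hi[kids[0]], lo[kids[1]], hi[kids[1]])
            steps += g
            lo[node], hi[node] = l, h
    _, _, g = _combine(lo[u], hi[u], lo[v], hi[v])
    steps += g
    length = int(steps.sum())

    # up intervals: rest-of-tree seen from each directed edge (par -> node)
    up_lo: dict[tuple[int, int], np.ndarray] = {}
    up_hi: dict[tuple[int, int], np.ndarray] = {}
    up_lo[(v, u)] = lo[v]
    up_hi[(v, u)] = hi[v]
    up_lo[(u, v)] = lo[u]
    up_hi[(u, v)] = hi[u]
    for node, par in order:
        if par is None:
            continue
        kids = [nb for nb in tree.adj[node] if nb != par]
        for k in kids:
            others = [o for o in kids if o != k]
            l, h = up_lo[(par, node)], up_hi[(par, node)]
            for o in others:
                l, h, _ = _combine(l, h, lo[o], hi[o])
            up_lo[(node, k)] = l
            up_hi[(node, k)] = h

    intervals = {}
    for a, b in tree.edges():
        if (a, b) in up_lo:
            l, h, _ = _combine(up_lo[(a, b)], up_hi[(a, b)], lo[b], hi[b])
        else:
            l, h, _ = _combine(up_lo[(b, a)], up_hi[(b, a)], lo[a], hi[a])
        intervals[(a, b)] = (l, h)
    return intervals, length


def _interval_gap(i1, i2) -> int:
    lo1, hi1 = i1
    lo2, hi2 = i2
    gap = np.maximum(np.maximum(lo1, lo2) - np.minimum(hi1, hi2), 0)
    return int(gap.sum())


def _split_components(tree: PhyloTree, u: int, v: int):
    """Bisect at edge (u, v); return the two spliced components."""

    def extract(start: int, other: int) -> PhyloTree:
        nodes = set()
        stack = [start]
        while stack:
            n = stack.pop()
            if n in nodes:
                continue
            nodes.add(n)
            stack.extend(nb for nb in tree.adj[n] if nb != other and nb not in nodes)
        comp = PhyloTree(
            {n: tree.adj[n] & nodes for n in nodes},
            {n: l for n, l in tree.labels.items() if n in nodes},
        )
        if len(comp.adj[start]) == 2 and start not in comp.labels:
            a, b = comp.adj[start]
            comp.adj[a].discard(start)
            comp.adj[b].discard(start)
            comp.adj[a].add(b)
            comp.adj[b].add(a)
            del comp.adj[start]
        return comp

    return extract(u, v), extract(v, u)


def _reconnect(comp1: PhyloTree, e1, comp2: PhyloTree, e2) -> PhyloTree:
    """Join two components by a new edge between subdivisions of e1 and e2."""
    t = comp1.copy()
    if e1 is None:
        x = next(iter(t.adj))
    else:
        x = t.new_node()
        a, b = e1
        t.adj[a].discard(b)
        t.adj[b].discard(a)
        t.adj[a].add(x)
        t.adj[b].add(x)
        t.adj[x] |= {a, b}
    offset = t._next
    mapped = {n: n + offset for n in comp2.adj}
    for n, nbs in comp2.adj.items():
        t.adj[mapped[n]] = {mapped[m] for m in nbs}
    for n, l in comp2.labels.items():
        t.labels[mapped[n]] = l
    t._next = offset + (max(comp2.adj) if comp2.adj else 0) + 1
    if e2 is None:
        y = mapped[next(iter(comp2.adj))]
    else:
        y = t.new_node()
        a, b = mapped[e2[0]], mapped[e2[1]]
        t.adj[a].discard(b)
        t.adj[b].discard(a)
        t.adj[a].add(y)
        t.adj[b].add(y)
        t.adj[y] |= {a, b}
    t.adj[x].add(y)
    t.adj[y].add(x)
    return t


def tbr_improve(
    tree: PhyloTree,
    states,
    prune: bool | None = None,
    max_rounds: int | None = None,
) -> tuple[PhyloTree, int]:
    """First-improvement TBR descent to a local optimum.

    With ``prune`` (default: automatic above 12 taxa) reconnection candidates
    are screened with the exact lower bound L1 + L2 + interval gap; every
    adopted move is confirmed by a full length evaluation.
    """
    S = _state_dict(states)
    _check_taxa(tree, S)
    n_chars = len(next(iter(S.values())))
    if prune is None:
        prune = tree.n_leaves > 12
    best = tree
    best_len = wagner_length(tree, S)
    rounds = 0
    improved = True
    while improved and (max_rounds is None or rounds < max_rounds):
        improved = False
        rounds += 1
        for u, v in best.edges():
            comp1, comp2 = _split_components(best, u, v)
            if comp1.n_leaves < 1 or comp2.n_leaves < 1:
                continue
            iv1, L1 = _edge_attachment_intervals(comp1, S, n_chars)
            iv2, L2 = _edge_attachment_intervals(comp2, S, n_chars)
            for e1, e2 in itertools.product(iv1, iv2):
                if prune and L1 + L2 + _interval_gap(iv1[e1], iv2[e2]) >= best_len:
                    continue
                cand = _reconnect(comp1, e1, comp2, e2)
                cand_len = wagner_length(cand, S)
                if cand_len < best_len:
                    best, best_len = cand, cand_len
                    improved = True
                    break
            if improved:
                break
    return best, best_len


def heuristic_search(
    states: pd.DataFrame | Mapping[str, np.ndarray],
    n_addition_sequences: int = 10,
    seed: int = 0,
    tbr: bool = True,
    max_trees: int = 64,
    tbr_max_rounds: int | None = None,
) -> SearchResult:
    """Stepwise addition (random addition order per replicate) plus TBR.

    Returns all distinct minimal-length trees found across replicates,
    sorted by canonical newick string.  Deterministic given ``seed``;
    replicate streams are independent of replicate order.
    """
    S = _state_dict(states)
    labels = sorted(S)
    if len(labels) < 4:
        t = PhyloTree.from_labels(labels)
        return SearchResult([t], wagner_length(t, S), n_replicates=0)

    found: dict[str, PhyloTree] = {}
    best_len = None
    for rep in range(n_addition_sequences):
        rng = np.random.default_rng([seed, rep])
        order = [labels[i] for i in rng.permutation(len(labels))]
        tree = PhyloTree.from_labels(order[:3])
        for label in order[3:]:
            cand_best = None
            cand_len = None
            for edge in tree.edges():
                t = tree.copy()
                t.insert_leaf(edge, label)
                l = wagner_length(t, S)
                if cand_len is None or l < cand_len:
                    cand_best, cand_len = t, l
            tree = cand_best
        length = wagner_length(tree, S)
        if tbr:
            tree, length = tbr_improve(tree, S, max_rounds=tbr_max_rounds)
        if best_len is None or length < best_len:
            best_len = length
            found = {}
        if length == best_len and len(found) < max_trees:
            found.setdefault(tree.to_newick(), tree)

    newicks = sorted(found)
    return SearchResult(
        [found[k] for k in newicks], int(best_len), n_replicates=n_addition_sequences
    )


# ---------------------------------------------------------------------------
# rooting


def max_state_ancestor(states: pd.DataFrame) -> np.ndarray:
    """Per-character maximum observed state (ancestor for trees of
    functions: the most abundant condition is taken as ancestral)."""
    return np.asarray(states.values.max(axis=0), dtype=np.int64)

def zero_ancestor(states: pd.DataFrame) -> np.ndarray:
    """All-zero ancestor (for trees of organisms: ancestral functionomes
    assumed to encode only a handful of functions)."""
    return np.zeros(states.shape[1], dtype=np.int64)


@dataclass
class RootingResult:
    tree: PhyloTree  # rooted
    edge: tuple[int, int]  # edge of the unrooted tree chosen for the root
    attachment_cost: int
    rooted_length: int
    tied_edges: list[tuple[int, int]] = field(default_factory=list)


def lundberg_root(
    tree: PhyloTree,
    states: pd.DataFrame | Mapping[str, np.ndarray],
    ancestor: np.ndarray,
) -> RootingResult:
    """Root at the most parsimonious attachment of a hypothetical ancestor.

    The ancestor (one state per character) is attached to every edge in
    turn; the cheapest attachment wins and the root is placed at that
    junction (the ancestor leaf itself is not kept in the reported tree).
    Ties resolve to the first edge in the canonical edge ordering; all tied
    edges are reported.
    """
    S = _state_dict(states)
    _check_taxa(tree, S)
    ancestor = np.asarray(ancestor, dtype=np.int64)
    n_chars = len(next(iter(S.values())))
    if ancestor.shape != (n_chars,):
        raise ValueError(f"ancestor must have {n_chars} states")
    S = dict(S)
    anc_label = "__ancestor__"
    while anc_label in tree.leaf_labels():
        anc_label += "_"
    S[anc_label] = ancestor

    base = wagner_length(tree, states)
    best_edge = None
    best_len = None
    ties: list[tuple[int, int]] = []
    for edge in tree.edges():
        t = tree.copy()
        t.insert_leaf(edge, anc_label)
        l = wagner_length(t, S)
        if best_len is None or l < best_len:
            best_edge, best_len = edge, l
            ties = [edge]
        elif l == best_len:
            ties.append(edge)

    rooted = tree.copy()
    rooted.root_on_edge(best_edge)
    return RootingResult(
        tree=rooted,
        edge=best_edge,
        attachment_cost=int(best_len - base),
        rooted_length=int(best_len),
        tied_edges=ties,
    )


# ---------------------------------------------------------------------------
# fit indices


@dataclass
class FitIndices:
    min_steps: np.ndarray  # per character
    max_steps: np.ndarray
    obs_steps: np.ndarray
    ci: float
    ri: float | None
    hi: float
    per_character_hi: np.ndarray

    @property
    def tree_length(self) -> int:
        return int(self.obs_steps.sum())


def fit_indices(tree: PhyloTree, states: pd.DataFrame | Mapping[str, np.ndarray]) -> FitIndices:
    """Consistency, retention and homoplasy indices for ordered characters.

    Per character: min = state range; max = star-tree length (sum of absolute
    deviations from the median state); obs = Farris steps on the tree.
    Ensemble CI = sum(min)/sum(obs); RI = (sum(max)-sum(obs)) /
    (sum(max)-sum(min)), undefined (None) when max == min; HI = 1 - CI.
    """
    S = _state_dict(states)
    _check_taxa(tree, S)
    X = np.stack([S[l] for l in sorted(tree.leaf_labels())])
    min_steps = X.max(axis=0) - X.min(axis=0)
    med = np.median(X, axis=0)
    max_steps = np.abs(X - med).sum(axis=0).round().astype(np.int64)
    obs = wagner_length(tree, S, per_character=True)

    sum_min, sum_max, sum_obs = int(min_steps.sum()), int(max_steps.sum()), int(obs.sum())
    ci = sum_min / sum_obs if sum_obs > 0 else 1.0
    ri = (sum_max - sum_obs) / (sum_max - sum_min) if sum_max > sum_min else None
    per_hi = np.where(obs > 0, 1.0 - np.divide(min_steps, np.maximum(obs, 1)), 0.0)
    return FitIndices(
        min_steps=min_steps.astype(np.int64),
        max_steps=max_steps,
        obs_steps=obs,
        ci=ci,
        ri=ri,
        hi=1.0 - ci,
        per_character_hi=per_hi,
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    states: pd.DataFrame,
    reference: PhyloTree,
    n_reps: int = 100,
    seed: int = 0,
    n_addition_sequences: int = 1,
    tbr: bool = True,
) -> dict[frozenset[str], float]:
    """Non-parametric bootstrap: percent of replicates whose best tree
    contains each bipartition of the reference tree.

    Characters (columns) are resampled with replacement per replicate; each
    replicate runs its own heuristic search.  Replicate RNG streams derive
    from (seed, replicate index), so results are order-independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ref_splits = reference.bipartitions()
    hits = {split: 0 for split in ref_splits}
    n_chars = states.shape[1]
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 1_000_003 + rep])
        cols = rng.integers(0, n_chars, size=n_chars)
        resampled = states.iloc[:, cols]
        res = heuristic_search(
            resampled,
            n_addition_sequences=n_addition_sequences,
            seed=int(rng.integers(0, 2**31 - 1)),
            tbr=tbr,
        )
        rep_splits = res.best.bipartitions()
        for split in ref_splits:
            if split in rep_splits:
                hits[split] += 1
    return {split: 100.0 * n / n_reps for split, n in hits.items()}


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Strict consensus of co-optimal unrooted trees (via dendropy)."""
    import dendropy

    if len(trees) == 1:
        return trees[0].copy()
    taxa = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(
        [
            dendropy.Tree.get(data=t.to_newick(), schema="newick", taxon_namespace=taxa)
            for t in trees
        ]
    )
    cons = tl.consensus(min_freq=1.0)
    return from_newick(cons.as_string(schema="newick"))
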