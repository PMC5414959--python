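"""Multi-level ontology network annotated with evolutionary ages.

Connects the analyzed taxa of consecutive hierarchy levels (1 -> 2 -> 3 ->
terminal) with is_a descent edges and carries each node's relative age (nd)
from its level's timeline, supporting hub detection (highly connected terms)
and Pajek export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, TextIO

import networkx as nx

from .ontology import GoDag, TerminalMapping

LEVEL_ORDER = (1, 2, 3, "terminal")


@dataclass
class GoNetwork:
    """Nodes are (term, level) pairs; edges join adjacent analyzed levels."""

    nodes: dict[tuple[str, int | str], float]  # (term, level) -> nd
    edges: list[tuple[str, int | str, str, int | str]]  # u, level_u, v, level_v
    link_counts: dict[tuple[str, int | str], int] = field(default_factory=dict)

    def nodes_at(self, level) -> list[str]:
        return sorted(t for t, l in self.nodes if l == level)

    def to_edge_tsv(self, handle: TextIO) -> None:
        handle.write("u\tlevel_u\tv\tlevel_v\tnd_u\tnd_v\n")
        for u, lu, v, lv in self.edges:
            handle.write(
                f"{u}\t{lu}\t{v}\t{lv}\t{self.nodes[(u, lu)]:.4f}\t{self.nodes[(v, lv)]:.4f}\n"
            )

    def to_pajek(self, handle: TextIO) -> None:
        """Pajek .net: vertices sorted by level then nd, arcs by index."""
        keys = sorted(self.nodes, key=lambda k: (LEVEL_ORDER.index(k[1]), self.nodes[k], k[0]))
        index = {k: i + 1 for i, k in enumerate(keys)}
        handle.write(f"*Vertices {len(keys)}\n")
        for k in keys:
            term, level = k
            handle.write(f'{index[k]} "{term}|L{level}|nd={self.nodes[k]:.4f}"\n')
        handle.write("*Arcs\n")
        for u, lu, v, lv in self.edges:
            handle.write(f"{index[(u, lu)]} {index[(v, lv)]}\n")


def build_network(
    timelines: Mapping[int | str, Mapping[str, float]],
    dag: GoDag,
    mappings: Mapping[int, TerminalMapping] | None = None,
) -> GoNetwork:
    """Assemble the level 1 -> 2 -> 3 -> terminal network.

    ``timelines`` maps each analyzed level (1, 2, 3 and/or "terminal") to
    {term: nd}.  An edge (u at level L, v at the next analyzed level) exists
    when v is an is_a descendant of u; for the terminal level, membership in
    the level-3 selection constituency is used when ``mappings`` provides
    it.  Terms appearing at two consecutive levels (promoted childless taxa)
    contribute no self-edge.
    """
    present = [l for l in LEVEL_ORDER if l in timelines and timelines[l]]
    for level in present:
        for term, nd in timelines[level].items():
            if nd is None:
                raise ValueError(f"term {term} at level {level} has no nd age")

    g = dag.is_a_graph()
    desc_cache: dict[str, set[str]] = {}

    def descendants(term: str) -> set[str]:
        if term not in desc_cache:
            desc_cache[term] = set(nx.ancestors(g, term)) if term in g else set()
        return desc_cache[term]

    nodes = {
        (term, level): float(nd)
        for level in present
        for term, nd in timelines[level].items()
    }
    edges: list[tuple[str, int | str, str, int | str]] = []
    for upper, lower in zip(present[:-1], present[1:]):
        lower_terms = timelines[lower]
        for u in sorted(timelines[upper]):
            if lower == "terminal" and mappings and upper in mappings:
                constituency = mappings[upper].taxa.get(u, set())
                targets = constituency & set(lower_terms)
            else:
                targets = descendants(u) & set(lower_terms)
            for v in sorted(targets):
                if v == u:
                    continue
                edges.append((u, upper, v, lower))

    link_counts: dict[tuple[str, int | str], int] = {
        (t, l): 0 for l in present for t in timelines[l]
    }
    for u, lu, v, lv in edges:
        link_counts[(u, lu)] += 1
    return GoNetwork(nodes=nodes, edges=edges, link_counts=link_counts)


def hub_terms(net: GoNetwork, level: int | str, min_links: int = 6) -> list[dict]:
    """Terms at ``level`` with at least ``min_links`` links to the next
    lower level, sorted by nd ascending (ties by term id)."""
    if level not in {l for _, l in net.nodes}:
        raise ValueError(f"level {level!r} not present in network")
    hubs = [
        {"term": term, "level": lvl, "links": n, "nd": net.nodes[(term, lvl)]}
        for (term, lvl), n in net.link_counts.items()
        if lvl == level and n >= min_links
    ]
    return sorted(hubs, key=lambda h: (h["nd"], h["term"]))
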