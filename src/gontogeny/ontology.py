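"""Gene Ontology DAG handling: parsing, hierarchy levels, taxon selection.

The molecular-function namespace of the Gene Ontology is a rooted directed
acyclic graph (DAG) whose terms are connected by ``is_a``, ``part_of`` and
regulation-family relations.  Because a term can have several parents, it can
sit at several *levels* at once, where a level is the length of an ``is_a``
path from the namespace root (``GO:0003674``, level 0).  This module parses
OBO files, computes the full level sets, and selects the "taxa" used for
phylogenetic reconstruction at levels 1-3 together with the terminal terms
(terms directly assigned to gene products) each taxon subsumes.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

MF_ROOT = "GO:0003674"
_ACCESSION_RE = re.compile(r"GO:\d{7}$")

#: relations collapsed into a single "regulates" family for taxon selection
REGULATION_RELATIONS = frozenset(
    {"regulates", "positively_regulates", "negatively_regulates"}
)


class OboParseError(ValueError):
    """Raised when an OBO stream is structurally unusable."""


@dataclass(frozen=True)
class GoTerm:
    id: str
    name: str = ""
    namespace: str = "molecular_function"
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not _ACCESSION_RE.match(self.id):
            raise ValueError(f"not a GO accession: {self.id!r}")


@dataclass
class GoDag:
    """Typed multigraph of GO terms.

    ``edges`` hold ``(child, parent, relation)`` triples; ``alt_ids`` maps
    secondary accessions to their canonical term.
    """

    terms: dict[str, GoTerm]
    edges: set[tuple[str, str, str]]
    root: str = MF_ROOT
    alt_ids: dict[str, str] = field(default_factory=dict)

    def is_a_graph(self) -> nx.DiGraph:
        """Child -> parent digraph restricted to ``is_a`` edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, r in self.edges if r == "is_a")
        return g

    def parents(self, term: str, relation: str | None = None) -> set[str]:
        return {
            p
            for c, p, r in self.edges
            if c == term and (relation is None or r == relation)
        }

    def children(self, term: str, relation: str | None = None) -> set[str]:
        return {
            c
            for c, p, r in self.edges
            if p == term and (relation is None or r == relation)
        }

    def canonical(self, term: str) -> str:
        """Resolve an alt_id to its canonical accession (identity otherwise)."""
        return self.alt_ids.get(term, term)


@dataclass
class TerminalMapping:
    """Level-``level`` taxa and the terminal terms each one subsumes.

    ``provenance`` records, per taxon, whether it is a normal level-``level``
    term (``"child"``) or a childless shallower term promoted to this level
    (``"promoted"``).  ``unmapped`` collects terminal terms excluded because
    their only links upward use non-``is_a`` relations.
    """

    level: int
    taxa: dict[str, set[str]]
    provenance: dict[str, str]
    unmapped: set[str] = field(default_factory=set)

    def to_tsv(self, handle: TextIO) -> None:
        handle.write("taxon\tlevel\tterminal\n")
        for taxon in sorted(self.taxa):
            for term in sorted(self.taxa[taxon]):
                handle.write(f"{taxon}\t{self.level}\t{term}\n")


def _prescan(text: str) -> None:
    """Cheap structural scan so malformed stanzas fail with a line number."""
    in_term = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"malformed stanza header at line {lineno}: {line!r}")
            in_term = line == "[Term]"
        elif in_term and line and ":" not in line:
            raise OboParseError(f"malformed tag line at line {lineno}: {line!r}")


def parse_obo(stream: str | TextIO, require_root: bool = True) -> GoDag:
    """Parse OBO 1.2 text into a :class:`GoDag`.

    Obsolete terms are kept but stripped of outgoing edges; ``alt_id`` lines
    populate the alias table.  With ``require_root`` the molecular_function
    root must be present.
    """
    text = stream if isinstance(stream, str) else stream.read()
    _prescan(text)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    terms: dict[str, GoTerm] = {}
    edges: set[tuple[str, str, str]] = set()
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[node] = GoTerm(
            id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", "molecular_function"),
            obsolete=obsolete,
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
        if obsolete:
            continue
        # obonet stores child -> parent edges keyed by relation type
        for _, parent, relation in graph.out_edges(node, keys=True):
            edges.add((node, parent, relation))

    if require_root and MF_ROOT not in terms:
        raise OboParseError(f"molecular_function root {MF_ROOT} missing from ontology")

    dag = GoDag(terms=terms, edges=edges, alt_ids=alt_ids)
    g = dag.is_a_graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OboParseError(f"is_a cycle detected: {cycle}")
    return dag


def term_levels(dag: GoDag, max_depth: int = 20) -> dict[str, set[int]]:
    """All distinct ``is_a`` path lengths from the root, per term.

    A multi-parent term holds every length realised by some root-to-term
    ``is_a`` path (capped at ``max_depth``).  Terms not reachable from the
    root by ``is_a`` edges get an empty level set.
    """
    g = dag.is_a_graph()
    if not nx.is_directed_acyclic_graph(g):
        raise OboParseError("is_a cycle detected")
    levels: dict[str, set[int]] = {t: set() for t in dag.terms}
    levels[dag.root] = {0}
    # child->parent edges: process in topological order of the parent->child
    # reversal so every parent's level set is complete before its children.
    for term in nx.topological_sort(g.reverse(copy=True)):
        for child in (c for c, p in g.in_edges(term)):
            levels.setdefault(child, set())
        if term == dag.root:
            continue
        acc: set[int] = set()
        for _, parent in g.out_edges(term):
            acc.update(l + 1 for l in levels.get(parent, ()) if l + 1 <= max_depth)
        levels[term] = acc
    return levels


def select_level_taxa(
    dag: GoDag,
    terminals: Iterable[str],
    level: int,
    levels: Mapping[str, set[int]] | None = None,
    overrides: Mapping[str, str] | None = None,
) -> TerminalMapping:
    """Select the level-``level`` taxa and their terminal constituencies.

    Selection applies, in order: (i) a childless term shallower than
    ``level`` that is itself annotated is promoted to its own taxon;
    (ii) candidates whose every parental link is ``part_of`` or a regulation
    relation are excluded; (iii) multi-parent candidates appear once;
    (iv) a term holding several levels is eligible at each of them.
    ``overrides`` maps a term id to the taxon id it should be re-assigned to
    (user-supplied special cases).
    """
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2 or 3, got {level}")
    terminals = {dag.canonical(t) for t in terminals}
    levels = levels if levels is not None else term_levels(dag)
    overrides = dict(overrides or {})

    g = dag.is_a_graph()

    def has_isa_parent_link(t: str) -> bool:
        return bool(dag.parents(t, "is_a"))

    taxa: dict[str, set[str]] = {}
    provenance: dict[str, str] = {}
    candidates: set[str] = set()
    for term in dag.terms:
        if dag.terms[term].obsolete or term == dag.root:
            continue
        lv = levels.get(term, set())
        if level in lv:
            candidates.add(term)
        elif lv and min(lv) < level and not dag.children(term, "is_a"):
            # criterion (i): childless shallow term promoted to this level,
            # but only when it is itself an annotated terminal
            if term in terminals:
                candidates.add(term)

    for term in sorted(candidates):
        if not has_isa_parent_link(term):
            # criterion (ii): parental links are exclusively part_of/regulates
            continue
        lv = levels.get(term, set())
        promoted = level not in lv
        # in the child->parent graph, nodes with a path TO the taxon are its
        # is_a descendants (the terms that ascend to it)
        constituency = (set(nx.ancestors(g, term)) | {term}) & terminals
        if promoted and term not in terminals:
            continue
        if not constituency:
            # taxa unconnected to any annotated terminal carry no census
            # signal (e.g. childless unannotated terms at their own level)
            continue
        taxa[term] = constituency
        provenance[term] = "promoted" if promoted else "child"

    for term, target in overrides.items():
        if term in taxa and target in taxa:
            taxa[target] |= taxa.pop(term)
            provenance.pop(term, None)

    mapped = set().union(*taxa.values()) if taxa else set()
    unmapped = {
        t for t in terminals - mapped
        if t in dag.terms and not dag.terms[t].obsolete
    }
    return TerminalMapping(level=level, taxa=taxa, provenance=provenance, unmapped=unmapped)


def map_terminals(
    dag: GoDag,
    mapping: TerminalMapping,
    annotated_terminals: Iterable[str],
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Restrict a mapping's constituencies to annotated terminal terms.

    Returns ``(taxon -> annotated terminals, report)`` where the report
    counts annotations skipped as unknown or obsolete.  Terminals reachable
    from several taxa count toward each (the DAG is many-to-many).
    """
    report = {"unknown": 0, "obsolete": 0}
    kept: set[str] = set()
    for term in annotated_terminals:
        term = dag.canonical(term)
        if term not in dag.terms:
            report["unknown"] += 1
            continue
        if dag.terms[term].obsolete:
            report["obsolete"] += 1
            continue
        kept.add(term)
    restricted = {
        taxon: constituency & kept for taxon, constituency in mapping.taxa.items()
    }
    return restricted, report
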