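"""Synthetic ontologies and functionomes with known ground truth.

The generator emulates the birth-spread-loss dynamics assumed by census
phylogenomics: molecular functions are born in order along a three-
superkingdom lineage tree, spread vertically to descendant genomes, lose
members independently per lineage, and accumulate gene copies at a rate
proportional to their age — so older terms are both more widespread and more
abundant.  Optional horizontal contamination adds terms whose presence is
purely due to transfer events, with their genes labelled as horizontally
transferred proteins (HTPs).  Everything is a deterministic function of the
parameters and the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .census import GenomeMeta
from .ontology import GoDag, MF_ROOT, parse_obo, term_levels


@dataclass
class SimParams:
    """Study conditions for the synthetic generator.

    ``n_terms`` terminal terms are annotated across ``3 *
    n_genomes_per_superkingdom`` genomes.  ``growth_rate`` is the expected
    gene copies per present genome for the oldest term; mean abundance
    declines geometrically with birth rank down to ~1 for the youngest.
    ``loss_prob`` is the probability that a descendant genome lineage
    independently loses a term.
    ``hgt_rate`` is the probability that a term is horizontally mobile:
    mobile terms have no vertical descent and appear only in randomly drawn
    recipient genomes, with genes HTP-labelled at ``htp_label_prob``.
    """

    n_terms: int = 40
    dag_depth: int = 4
    branching: int = 3
    multi_parent_prob: float = 0.1
    non_isa_prob: float = 0.1
    n_genomes_per_superkingdom: int = 10
    growth_rate: float = 100.0
    loss_prob: float = 0.05
    hgt_rate: float = 0.0
    htp_label_prob: float = 1.0
    hgt_spread: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("multi_parent_prob", "non_isa_prob", "loss_prob",
                     "hgt_rate", "htp_label_prob", "hgt_spread"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_terms < 1 or self.n_genomes_per_superkingdom < 1:
            raise ValueError("counts must be >= 1")
        if self.branching < 2 or self.dag_depth < 2:
            raise ValueError("need branching >= 2 and dag_depth >= 2")
        if self.branching ** self.dag_depth < self.n_terms:
            raise ValueError(
                f"branching {self.branching} ^ depth {self.dag_depth} yields "
                f"fewer than n_terms={self.n_terms} deepest terms"
            )


@dataclass
class GroundTruth:
    birth_rank: dict[str, int]  # terminal term -> 0-based birth order
    genome_tree_newick: str
    hgt_events: list[tuple[str, str, str]]  # (term, donor, recipient)
    htp_genes: set[str]
    hgt_only_terms: set[str] = field(default_factory=set)


@dataclass
class SimData:
    obo_text: str
    dag: GoDag
    gaf: dict[str, str]  # genome -> GAF text
    meta: GenomeMeta
    truth: GroundTruth
    terminal_terms: list[str]

    def combined_gaf(self) -> str:
        header = "!gaf-version: 2.2\n"
        return header + "".join(
            "\n".join(l for l in text.splitlines() if not l.startswith("!")) + "\n"
            for text in self.gaf.values()
        )


def _accession(i: int) -> str:
    return f"GO:09{i:05d}"


def generate_dag(p: SimParams) -> tuple[str, GoDag]:
    """Random layered molecular-function-like DAG, as OBO text + parsed DAG.

    The backbone is a ``branching``-ary is_a tree of depth ``dag_depth``.
    On top of it the generator adds: extra is_a parents (multi-parent terms
    whose level set can span several levels), part_of/regulates cross edges,
    one term per mid level with no children, and one term attached to its
    parent by part_of only.  Deterministic given ``p.seed``.
    """
    rng = np.random.default_rng([p.seed, 7])
    counter = itertools.count(1)
    levels: dict[int, list[str]] = {0: [MF_ROOT]}
    edges: list[tuple[str, str, str]] = []
    names: dict[str, str] = {MF_ROOT: "molecular_function"}

    for depth in range(1, p.dag_depth + 1):
        levels[depth] = []
        for parent in levels[depth - 1]:
            for _ in range(p.branching):
                term = _accession(next(counter))
                names[term] = f"synthetic activity {term[-5:]}"
                edges.append((term, parent, "is_a"))
                levels[depth].append(term)

    all_terms = [t for lv in levels.values() for t in lv]

    # extra is_a parents: multi-parent terms, possibly at unequal depths
    for depth in range(2, p.dag_depth + 1):
        for term in levels[depth]:
            if rng.random() < p.multi_parent_prob:
                shallower = [
                    t
                    for d in range(1, depth)
                    for t in levels[d]
                    if (t, term) not in {(e[1], e[0]) for e in edges}
                ]
                if shallower:
                    extra = shallower[rng.integers(len(shallower))]
                    edges.append((term, extra, "is_a"))

    # part_of / regulates cross edges (in addition to is_a backbones)
    relations = ["part_of", "regulates", "positively_regulates", "negatively_regulates"]
    for term in all_terms[1:]:
        if rng.random() < p.non_isa_prob:
            target = all_terms[rng.integers(1, len(all_terms))]
            if target != term:
                edges.append((term, target, relations[rng.integers(len(relations))]))

    # one childless term per mid level (exercises childless-term promotion)
    # and one part_of-only term (exercises the is_a-only selection rule)
    for depth in range(1, p.dag_depth):
        term = _accession(next(counter))
        names[term] = f"childless synthetic activity {term[-5:]}"
        parent = levels[depth - 1][int(rng.integers(len(levels[depth - 1])))]
        edges.append((term, parent, "is_a"))
        levels[depth].append(term)
    if p.non_isa_prob > 0:
        term = _accession(next(counter))
        names[term] = f"part_of-only synthetic activity {term[-5:]}"
        parent = levels[1][int(rng.integers(len(levels[1])))]
        edges.append((term, parent, "part_of"))
        levels[1].append(term)

    lines = ["format-version: 1.2", "ontology: go-synthetic", ""]
    for term in sorted(names):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {names[term]}")
        lines.append("namespace: molecular_function")
        for child, parent, rel in sorted(edges):
            if child != term:
                continue
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {names[parent]}")
            else:
                lines.append(f"relationship: {rel} {parent} ! {names[parent]}")
        lines.append("")
    obo_text = "\n".join(lines)
    return obo_text, parse_obo(obo_text)


# ---------------------------------------------------------------------------
# genome lineage tree


class _LineageNode:
    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[_LineageNode] = []

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        return [l for c in self.children for l in c.leaves()]

    def newick(self) -> str:
        if not self.children:
            return self.name
        return "(" + ",".join(c.newick() for c in self.children) + ")"


def _caterpillar(names: list[str]) -> _LineageNode:
    node = _LineageNode(names[-1])
    for name in reversed(names[:-1]):
        parent = _LineageNode()
        parent.children = [_LineageNode(name), node]
        node = parent
    return node


def _genome_tree(n_per_sk: int) -> _LineageNode:
    """Fixed ((A),(B,E)) skeleton with caterpillar superkingdom clades."""
    clades = {
        sk: _caterpillar([f"{sk}{i + 1:02d}" for i in range(n_per_sk)])
        for sk in "ABE"
    }
    be = _LineageNode()
    be.children = [clades["B"], clades["E"]]
    root = _LineageNode()
    root.children = [clades["A"], be]
    return root


def _paths_to_leaves(root: _LineageNode) -> dict[str, list[_LineageNode]]:
    paths: dict[str, list[_LineageNode]] = {}

    def walk(node: _LineageNode, path: list[_LineageNode]):
        path = path + [node]
        if not node.children:
            paths[node.name] = path
        for c in node.children:
            walk(c, path)

    walk(root, [])
    return paths


def generate_functionomes(
    dag: GoDag, p: SimParams
) -> SimData:
    """Simulate functionomes under the birth-spread-loss model.

    Terminal terms (the DAG's deepest level) are born in rank order at
    progressively shallower-to-deeper points of the genome lineage tree; a
    term is present in the genomes descending from its birth point minus
    per-edge losses, and each present genome carries ``1 + Poisson(rate *
    (T - rank) / T)`` gene copies.  Horizontally mobile terms skip vertical
    descent entirely (see :class:`SimParams`).
    """
    rng = np.random.default_rng([p.seed, 11])
    lv = term_levels(dag)
    deepest = max(max(s) for s in lv.values() if s)
    candidates = sorted(t for t, s in lv.items() if s and max(s) == deepest)
    if len(candidates) < p.n_terms:
        raise ValueError(
            f"only {len(candidates)} deepest terms available for n_terms={p.n_terms}"
        )
    terms = candidates[: p.n_terms]

    tree = _genome_tree(p.n_genomes_per_superkingdom)
    genomes = tree.leaves()
    T = p.n_terms

    # all lineage-tree nodes with their descendant genome sets, so a birth
    # point can be drawn to match a target breadth
    node_leaves: list[tuple[_LineageNode, frozenset[str]]] = []

    def collect(node: _LineageNode):
        node_leaves.append((node, frozenset(node.leaves())))
        for c in node.children:
            collect(c)

    collect(tree)

    birth_rank = {t: r for r, t in enumerate(terms)}
    birth_node: dict[str, _LineageNode] = {}
    presence: dict[str, set[str]] = {}
    hgt_only: set[str] = set()
    hgt_events: list[tuple[str, str, str]] = []

    def descend_with_loss(node: _LineageNode) -> set[str]:
        # independent loss per descendant genome lineage
        return {g for g in node.leaves() if rng.random() >= p.loss_prob}

    for term in terms:
        r = birth_rank[term]
        if rng.random() < p.hgt_rate:
            hgt_only.add(term)
            n_rec = max(3, int(rng.binomial(len(genomes), p.hgt_spread)))
            recipients = [genomes[i] for i in rng.choice(len(genomes), size=n_rec, replace=False)]
            donor = genomes[int(rng.integers(len(genomes)))]
            presence[term] = set(recipients)
            hgt_events.extend((term, donor, rec) for rec in recipients)
            continue
        # expected breadth declines linearly with birth rank: the oldest
        # term descends from the root, the youngest from a single genome
        target = max(1, round(len(genomes) * (T - r) / T))
        best = min(abs(len(lv) - target) for _, lv in node_leaves)
        options = [n for n, lv in node_leaves if abs(len(lv) - target) == best]
        birth_node[term] = options[int(rng.integers(len(options)))]
        presence[term] = descend_with_loss(birth_node[term])

    # gene copies and GAF emission
    htp_genes: set[str] = set()
    rows_by_genome: dict[str, list[str]] = {g: [] for g in genomes}
    serial = itertools.count(1)
    for term in terms:
        r = birth_rank[term]
        # geometric decline: the oldest term averages ~growth_rate copies
        # per genome, the youngest ~1, so the log-scale census spans the
        # full encoded state range like real multi-order censuses
        lam = p.growth_rate ** ((T - r) / T)
        for genome in sorted(presence[term]):
            n_genes = 1 + int(rng.poisson(lam - 1.0))
            for _ in range(n_genes):
                gene = f"{genome}_g{next(serial):06d}"
                if term in hgt_only and rng.random() < p.htp_label_prob:
                    htp_genes.add(gene)
                rows_by_genome[genome].append(
                    "\t".join(
                        [
                            "SYN", gene, gene, "enables", term, "SYN_REF:0000001",
                            "IEA", "", "F", "", "", "protein", genome,
                            "20260101", "SYN", "", "",
                        ]
                    )
                )

    gaf = {
        g: "!gaf-version: 2.2\n" + "\n".join(rows) + ("\n" if rows else "")
        for g, rows in rows_by_genome.items()
    }
    meta = GenomeMeta(
        superkingdom={g: g[0] for g in genomes},
        lifestyle={g: GenomeMeta.FREE_LIVING for g in genomes},
    )
    truth = GroundTruth(
        birth_rank=birth_rank,
        genome_tree_newick=tree.newick() + ";",
        hgt_events=hgt_events,
        htp_genes=htp_genes,
        hgt_only_terms=hgt_only,
    )
    return SimData(
        obo_text="", dag=dag, gaf=gaf, meta=meta, truth=truth, terminal_terms=terms
    )


def simulate(p: SimParams) -> SimData:
    """Generate DAG and functionomes in one go."""
    obo_text, dag = generate_dag(p)
    data = generate_functionomes(dag, p)
    data.obo_text = obo_text
    return data


def evaluate_recovery(
    truth: GroundTruth, nd_by_term: dict[str, float]
) -> tuple[float, float]:
    """Spearman correlation between true birth rank and reconstructed nd.

    For 8 or fewer shared terms the permutation p-value is exact (full
    enumeration); otherwise the asymptotic p of the Spearman test is used.
    """
    common = sorted(set(truth.birth_rank) & set(nd_by_term))
    if len(common) < 3:
        raise ValueError("need at least 3 shared taxa to correlate")
    x = np.array([truth.birth_rank[t] for t in common], dtype=float)
    y = np.array([nd_by_term[t] for t in common], dtype=float)
    rho, p_asym = stats.spearmanr(x, y)
    n = len(common)
    if n <= 8:
        obs = rho
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r, _ = stats.spearmanr(x, y[list(perm)])
            total += 1
            if r >= obs - 1e-12:
                hits += 1
        return float(rho), hits / total
    return float(rho), float(p_asym)
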