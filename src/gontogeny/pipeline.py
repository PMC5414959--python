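"""End-to-end convenience drivers: census -> encode -> search -> root -> ages."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .census import (
    AbundanceMatrix,
    AnnotationSet,
    GenomeMeta,
    build_matrix,
    normalize_encode,
)
from .parsimony import (
    PhyloTree,
    SearchResult,
    heuristic_search,
    lundberg_root,
    max_state_ancestor,
    zero_ancestor,
)
from .timeline import node_distance


@dataclass
class TofRun:
    matrix: AbundanceMatrix
    states: pd.DataFrame  # taxa x characters, 0-31
    search: SearchResult
    rooted: PhyloTree
    nd: dict[str, float]
    tree_length: int


def tof_from_annotations(
    ann: AnnotationSet,
    meta: GenomeMeta,
    mapping: dict[str, set[str]] | None = None,
    seed: int = 0,
    n_addition_sequences: int = 3,
    free_living_only: bool = False,
    tbr_max_rounds: int | None = None,
) -> TofRun:
    """Reconstruct a rooted tree of functions and its timeline.

    Taxa are GO taxa (terminal terms when ``mapping`` is None); characters
    are genomes.  The tree is rooted with the Lundberg method using the
    per-character maximum observed state as the hypothetical ancestor.
    """
    matrix = build_matrix(ann, mapping, meta, free_living_only=free_living_only)
    states = normalize_encode(matrix).states
    search = heuristic_search(
        states,
        n_addition_sequences=n_addition_sequences,
        seed=seed,
        tbr_max_rounds=tbr_max_rounds,
    )
    rooting = lundberg_root(search.best, states, max_state_ancestor(states))
    nd = node_distance(rooting.tree)
    return TofRun(
        matrix=matrix,
        states=states,
        search=search,
        rooted=rooting.tree,
        nd=nd,
        tree_length=search.length,
    )


def tol_from_annotations(
    ann: AnnotationSet,
    meta: GenomeMeta,
    mapping: dict[str, set[str]] | None = None,
    seed: int = 0,
    n_addition_sequences: int = 3,
    free_living_only: bool = False,
    tbr_max_rounds: int | None = None,
) -> TofRun:
    """Tree of organisms: taxa are genomes, characters are GO taxa; rooted
    with the all-zero ancestor (sparse ancestral functionomes)."""
    matrix = build_matrix(ann, mapping, meta, free_living_only=free_living_only)
    states = normalize_encode(matrix).states.T  # genomes as rows
    search = heuristic_search(
        states,
        n_addition_sequences=n_addition_sequences,
        seed=seed,
        tbr_max_rounds=tbr_max_rounds,
    )
    rooting = lundberg_root(search.best, states, zero_ancestor(states))
    nd = node_distance(rooting.tree)
    return TofRun(
        matrix=matrix,
        states=states,
        search=search,
        rooted=rooting.tree,
        nd=nd,
        tree_length=search.length,
    )
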