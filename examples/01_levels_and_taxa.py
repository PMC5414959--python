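"""Hierarchy levels and taxon selection on a synthetic ontology.

Generates a small molecular-function-like DAG, computes every term's level
set (all is_a path lengths from the root — multi-parent terms can hold
several levels) and selects the level-1 taxa with their terminal-term
constituencies.
"""

from gontogeny import SimParams, generate_dag, select_level_taxa, term_levels

obo_text, dag = generate_dag(SimParams(seed=7, multi_parent_prob=0.3))
levels = term_levels(dag)

multi = {t: lv for t, lv in levels.items() if len(lv) > 1}
print(f"terms: {len(dag.terms)}, multi-level terms: {len(multi)}")
for term, lv in sorted(multi.items())[:3]:
    print(f"  {term} sits at levels {sorted(lv)}")

deepest = max(max(lv) for lv in levels.values() if lv)
terminals = {t for t, lv in levels.items() if lv and max(lv) == deepest}
mapping = select_level_taxa(dag, terminals, level=1)
print(f"level-1 taxa: {len(mapping.taxa)} (terminal terms: {len(terminals)})")
for taxon, constituency in sorted(mapping.taxa.items())[:3]:
    print(f"  {taxon} subsumes {len(constituency)} terminal terms")
# Each level-1 taxon aggregates the terminal terms that reach it by is_a
# ascent; a terminal under two taxa counts toward both (the DAG is
# many-to-many).
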