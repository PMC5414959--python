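# Methods

## Model and assumptions

The package reconstructs the history of molecular functions from their
genomic census under three assumptions: (i) the repertoire of GO
molecular-function terms of a genome (its functionome) is a heritable
character set; (ii) ancient functions had more time to spread across
genomes and to accumulate gene copies within them, so abundance and breadth
carry age signal; (iii) homoplasy — convergent gain, loss, horizontal
transfer — is minimized, not absent, and is quantified (CI/RI/HI, bootstrap)
and mitigated (HTP enrichment filter) rather than assumed away.

Characters are linearly ordered: moving a census cell from state *i* to *j*
costs |*i* − *j*| steps.  This is the Wagner/additive model; it encodes the
belief that abundance changes gradually.  Polarization is imposed only at
rooting time, through the hypothetical ancestor of the Lundberg attachment:
maximum observed state per character for trees of functions (abundant =
old), zero for trees of organisms (ancestral functionomes were sparse).

## Hierarchy levels and taxon selection

A term's level set contains **all** `is_a` path lengths from the
molecular-function root, not only the shortest, so a multi-parent term can
legitimately appear at several levels; enumeration is capped at a
configurable depth (default 20, far above the ontology's real depth).
Taxon selection at level *L* follows four rules, in order: childless terms
shallower than *L* that are themselves annotated are promoted to their own
taxon; candidates whose every parental link is `part_of` or a regulation
relation are excluded; multi-parent candidates appear once; and a term
holding several levels is eligible at each.  Taxa that subsume no annotated
terminal are dropped — they carry no census signal.  Terminal status is
operational (directly annotated in a GAF record), not topological leafness.
Hand-curated re-assignments are supported as a user-supplied override table
rather than hard-coded cases.

## Census and encoding

Abundance counts *distinct gene products* per taxon: a gene with two
terminal annotations under one taxon counts once; under two taxa it counts
once in each (the DAG is many-to-many and the constituencies are not a
partition).  Gene products annotated only to non-terminal terms are
excluded.  All evidence codes are retained, including electronic (IEA)
annotations, since censuses are dominated by them; NOT-qualified records
are dropped at parse time and duplicate gene–term pairs across evidence
codes collapse to one.

Normalization is `state = round(ln(g+1) / ln(g_max+1) × 31)` with `g_max`
the matrix-wide maximum for the level being analyzed (not per row or
column).  Rounding is half-away-from-zero, stated once and applied
everywhere.  The encoding is monotone, maps 0 → 0 and `g_max` → 31, and
spans exactly 32 states over a full-range census.  NEXUS output declares
`SYMBOLS="0~9A~V"` and an ASSUMPTIONS block typing all characters ordered.

The HTP filter is a per-term one-sided Fisher exact test (hypergeometric
upper tail) of HTP membership among the term's gene products against all
other gene products, with **no** multiple-testing correction: the screen
intentionally mirrors a raw *p* < 0.05 cut, favouring sensitivity over
specificity since its goal is noise removal, not inference.

## Parsimony engine

Tree length per ordered character is computed by the Farris interval pass
on an arbitrary edge rooting (interval intersection when non-empty,
otherwise the gap interval at gap-width cost); the result is independent of
that rooting.  An independent Sankoff dynamic program over the full state
space, using the linear-cost distance transform for child-to-parent
messages, serves as the oracle: the two must agree on every instance, and
the test suite checks 1,000+ random instances plus exhaustive enumerations.

Search trees are strictly binary; polytomies arise only in strict consensus
of co-optimal trees.  Stepwise addition inserts taxa in a random order
(one RNG stream per addition sequence, derived from the master seed and the
replicate index, so replicates are order-independent), each placement
minimizing incremental length with ties broken by the canonical edge
ordering.  TBR descent is first-improvement; above 12 taxa, reconnection
candidates are screened with the exact lower bound
`L1 + L2 + interval gap`, and any adopted move is confirmed by a full
length evaluation, so pruning can never mis-report a length.  When several
co-optimal trees survive, downstream analyses use the first tree in the
canonical newick sort and a strict consensus is available alongside;
default search settings are 10 random addition sequences with unbounded
saved co-optima.

Fit indices per character: minimum steps = state range; maximum steps =
star-tree length (sum of absolute deviations from the median state);
observed = Farris steps.  Ensemble CI = Σmin/Σobs, RI =
(Σmax−Σobs)/(Σmax−Σmin) (reported as missing when Σmax = Σmin), HI = 1−CI.
Bootstrap support resamples characters with replacement, runs a reduced
search per replicate and reports the percentage of replicates containing
each reference bipartition.

Lundberg rooting evaluates the ancestor attachment on every edge
exhaustively; ties resolve to the first edge in the canonical post-order
edge enumeration and all tied placements are reported.

## Timelines

Node distance is the number of internal nodes on the root-to-leaf path
excluding the root, **normalized by the maximum leaf depth**.  The divisor
is configurable because an alternative convention (dividing by the taxon
count) circulates in the literature; the max-depth form is the one
consistent with the published timeline tables bundled here (e.g. 0.07 =
1/14 on a 17-taxon tree, 0.0096 = 1/104 on a 257-taxon tree) and is the
default.  Values are kept at full precision; the bundled tables print 2
decimals at levels 1–2 and 4 decimals at level 3.

The GSI implementation counts the internal nodes needed to unite a group on
the rooted tree: gs = (n−1)/|U| with U the union of leaf-to-MRCA paths.  It
equals 1 exactly for monophyletic groups (and, by construction, for the
group of all leaves) and decreases toward 0 with dispersal.  The original
publication's min–max rescaling is deliberately omitted: it can reach
exactly 0 for maximally dispersed groups, while this package's contract is
gsi ∈ (0, 1] with gsi = 1 ⟺ monophyly.  Permutation *p*-values enumerate
all group placements exhaustively when C(leaves, group size) ≤ 200,000 and
fall back to Monte Carlo otherwise.

Age histograms default to the three bins 0–0.4 / 0.4–0.6 / 0.6–1.0,
half-open on the left except the final bin; taxa in several level-1
categories count once per category and the marginals therefore sum to
category multiplicity, not taxon count.  Accumulation regressions are
ordinary least squares through paired cumulative counts on the union nd
grid, omitted below 3 grid points.

## Synthetic data generator

The generator emulates the study conditions end to end: a layered
`is_a` backbone DAG (default branching 3, depth 4) with multi-parent terms,
`part_of`/regulation cross-edges, childless mid-level terms and a
`part_of`-only term, so every selection rule is exercised; and functionomes
over 30 genomes (10 per superkingdom) on a fixed ((A),(B,E)) lineage
skeleton with caterpillar clades, reflecting the bacteria–eukarya affinity
seen in census trees (configurable).

Forty terminal terms are born in rank order.  A term's birth point is the
lineage-tree node whose descendant-genome count best matches a breadth
target declining linearly with rank (oldest → all 30 genomes, youngest →
1), realizing "older ⇒ more widespread" directly; under zero loss, any two
presence sets are therefore nested or disjoint, with the older term the
superset.  Each descendant genome independently loses the term with
probability 0.05 (default).  Gene copies per present genome are
1 + Poisson(mean − 1) with mean declining **geometrically** from
`growth_rate` (default 100) for the oldest term to ~1 for the youngest:
real censuses span orders of magnitude (up to ~10⁴ copies), and only a
multiplicative gradient survives the logarithmic 32-state encoding with a
usable signal-to-noise ratio — a linear 1–6 gradient collapses into two or
three adjacent states and is swamped by Poisson noise.  Horizontally mobile
terms (probability `hgt_rate`) have no vertical descent: they appear only
in ≥ 3 randomly drawn recipient genomes and their genes are HTP-labelled
with probability `htp_label_prob`, so "purely transfer-derived" terms exist
as a clean target for the enrichment filter.

What the generator does **not** emulate: annotation bias across
superkingdoms, genome-size heterogeneity beyond the abundance model,
within-term rate variation, gene-level sequence evolution, and calibrated
time.  Passing tests therefore demonstrate that the pipeline recovers a
birth order *when the census actually carries the assumed age signal*; they
do not validate the biological assumptions on real data.

## Numerical and reproducibility choices

All randomness flows from a master seed through `numpy` SeedSequence-style
`default_rng([seed, stream])` derivations; bootstrap and addition-sequence
streams are replicate-indexed and order-independent.  Ties (edge choices,
co-optimal trees, hub ordering) break on canonical sorted order.  Degenerate
inputs fail loudly: all-zero census matrices (undefined `g_max`), unrooted
trees passed to node distance, empty genome scopes, missing metadata.
Test and example problem sizes (40 terms × 30 genomes; ≤ 8 taxa for
exhaustive enumerations; 100 bootstrap replicates) were chosen so the full
suite exercises every code path with exact oracles at small n.

## Known limitations

TBR is first-improvement rather than best-improvement and is not guaranteed
to reach the global optimum beyond the exhaustively verified sizes;
bootstrap inside each replicate uses a reduced search (1 addition
sequence).  The OBO reader targets OBO 1.2 `[Term]` stanzas (no OWL).  GAF
ingestion keys genomes on the taxon column, which assumes one proteome per
taxon identifier.  The hub thresholds are conventions inherited from
printed hub tables (≥ 6 links at level 2, ≥ 30 at level 3) and should be
re-tuned per dataset; both are parameters.
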