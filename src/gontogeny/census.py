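"""Genomic census of molecular-function terms.

Builds taxa x genome abundance matrices from GAF annotation files, filters
terms enriched in horizontally transferred proteins, log-normalizes raw
counts onto 32 ordered character states (symbols ``0``-``9`` then ``A``-``V``)
and writes/reads NEXUS character matrices suitable for ordered-character
(Wagner) parsimony.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUV"
N_STATES = len(ALPHABET)  # 32

_GAF_COLUMNS = [
    "db", "db_object_id", "db_object_symbol", "qualifier", "go_id",
    "db_reference", "evidence_code", "with_from", "aspect", "db_object_name",
    "db_object_synonym", "db_object_type", "taxon", "date", "assigned_by",
    "annotation_extension", "gene_product_form_id",
]


class GafParseError(ValueError):
    pass


@dataclass
class AnnotationSet:
    """Deduplicated (genome, gene product, terminal term) associations."""

    records: pd.DataFrame  # columns: genome, gene, term
    n_dropped_not: int = 0
    n_dropped_aspect: int = 0

    def __post_init__(self) -> None:
        self.records = self.records.drop_duplicates(
            subset=["genome", "gene", "term"]
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genomes(self) -> list[str]:
        return sorted(self.records["genome"].unique())

    @property
    def terms(self) -> list[str]:
        return sorted(self.records["term"].unique())

    def genes(self, genome: str | None = None) -> set[str]:
        df = self.records
        if genome is not None:
            df = df[df["genome"] == genome]
        return set(df["gene"])


@dataclass
class GenomeMeta:
    """Superkingdom (A/B/E) and lifestyle labels per genome."""

    superkingdom: dict[str, str]
    lifestyle: dict[str, str] = field(default_factory=dict)

    FREE_LIVING = "free-living"

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.superkingdom.items() if s not in "ABE" or len(s) != 1}
        if bad:
            raise ValueError(f"superkingdom labels must be one of A/B/E: {bad}")

    def free_living(self) -> set[str]:
        if not self.lifestyle:
            return set(self.superkingdom)
        return {g for g in self.superkingdom if self.lifestyle.get(g) == self.FREE_LIVING}

    @classmethod
    def from_tsv(cls, handle: TextIO) -> "GenomeMeta":
        df = pd.read_csv(handle, sep="\t", dtype=str)
        required = {"genome", "superkingdom"}
        if not required <= set(df.columns):
            raise ValueError(f"metadata TSV needs columns {sorted(required)}")
        sk = dict(zip(df["genome"], df["superkingdom"]))
        ls = dict(zip(df["genome"], df["lifestyle"])) if "lifestyle" in df else {}
        return cls(superkingdom=sk, lifestyle=ls)

    def to_tsv(self, handle: TextIO) -> None:
        handle.write("genome\tsuperkingdom\tlifestyle\n")
        for g in sorted(self.superkingdom):
            ls = self.lifestyle.get(g, self.FREE_LIVING)
            handle.write(f"{g}\t{self.superkingdom[g]}\t{ls}\n")


@dataclass
class AbundanceMatrix:
    """Non-negative integer census counts, taxa x genomes."""

    counts: pd.DataFrame  # index: taxa (GO taxa), columns: genomes

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("abundance counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def g_max(self) -> int:
        return int(self.counts.values.max())

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class EncodedMatrix:
    """Ordered 0-31 states with the 32-symbol alphanumeric alphabet."""

    states: pd.DataFrame  # same shape as the abundance matrix

    def __post_init__(self) -> None:
        vals = self.states.values
        if vals.min() < 0 or vals.max() >= N_STATES:
            raise ValueError("states must lie in [0, 31]")
        self.states = self.states.astype(np.int64)

    def symbols(self) -> pd.DataFrame:
        return self.states.map(lambda s: ALPHABET[s])


def parse_gaf(stream: str | TextIO) -> AnnotationSet:
    """Parse GAF 2.x text, keeping deduplicated molecular-function rows.

    The genome identifier is taken from the taxon column (``taxon:...``);
    rows whose qualifier contains ``NOT`` are dropped, as are rows with a
    non-``F`` aspect.
    """
    text = stream if isinstance(stream, str) else stream.read()
    rows = []
    n_not = 0
    n_aspect = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        parts = line.split("\t")
        if len(parts) not in (15, 17):
            raise GafParseError(
                f"line {lineno}: expected 15 or 17 tab-separated columns, got {len(parts)}"
            )
        rec = dict(zip(_GAF_COLUMNS, parts))
        if "NOT" in rec["qualifier"].split("|"):
            n_not += 1
            continue
        if rec["aspect"] != "F":
            n_aspect += 1
            continue
        taxon = rec["taxon"].split("|")[0]
        rows.append((taxon, rec["db_object_id"], rec["go_id"]))
    df = pd.DataFrame(rows, columns=["genome", "gene", "term"])
    return AnnotationSet(records=df, n_dropped_not=n_not, n_dropped_aspect=n_aspect)


def build_matrix(
    ann: AnnotationSet,
    mapping: Mapping[str, Iterable[str]] | None,
    meta: GenomeMeta | None = None,
    free_living_only: bool = False,
) -> AbundanceMatrix:
    """Census matrix: cell (taxon, genome) = distinct gene products of the
    genome annotated to any terminal in the taxon's constituency.

    With ``mapping=None`` each terminal term is its own taxon
    (terminal-identity census).  A gene annotated to two terminals under one
    taxon counts once for it; a gene under two taxa counts once in each.
    """
    df = ann.records
    genomes = sorted(df["genome"].unique())
    if meta is not None:
        missing = [g for g in genomes if g not in meta.superkingdom]
        if missing:
            raise ValueError(f"genomes without metadata: {missing}")
        if free_living_only:
            keep = meta.free_living()
            genomes = [g for g in genomes if g in keep]
            df = df[df["genome"].isin(keep)]
    elif free_living_only:
        raise ValueError("free_living_only requires genome metadata")

    if mapping is None:
        mapping = {t: {t} for t in sorted(df["term"].unique())}

    term_to_taxa: dict[str, list[str]] = {}
    for taxon, constituency in mapping.items():
        for term in constituency:
            term_to_taxa.setdefault(term, []).append(taxon)

    taxa = sorted(mapping)
    counts = pd.DataFrame(0, index=taxa, columns=genomes, dtype=np.int64)
    hits = df[df["term"].isin(term_to_taxa)]
    exploded = hits.assign(
        taxon=hits["term"].map(term_to_taxa)
    ).explode("taxon")
    grouped = (
        exploded.drop_duplicates(subset=["genome", "gene", "taxon"])
        .groupby(["taxon", "genome"])
        .size()
    )
    for (taxon, genome), n in grouped.items():
        counts.at[taxon, genome] = n
    return AbundanceMatrix(counts=counts)


def hgt_enrichment_filter(
    ann: AnnotationSet,
    htp_genes: Iterable[str],
    alpha: float = 0.05,
) -> tuple[set[str], AnnotationSet, dict[str, float]]:
    """Remove terminal terms significantly enriched in HTPs.

    For every terminal term a one-sided Fisher exact (hypergeometric upper
    tail) test compares HTP membership among the term's gene products against
    the remaining gene products; terms with raw ``p < alpha`` (no multiple
    testing correction) are removed from the annotation set.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    htp = set(htp_genes)
    all_genes = ann.genes()
    stray = htp - all_genes
    if stray:
        import warnings

        warnings.warn(f"{len(stray)} HTP gene ids absent from annotations", stacklevel=2)
        htp &= all_genes

    pvals: dict[str, float] = {}
    removed: set[str] = set()
    if not htp:
        return removed, ann, pvals

    population = len(all_genes)
    n_htp = len(htp)
    for term, sub in ann.records.groupby("term"):
        genes = set(sub["gene"])
        k = len(genes & htp)
        m = len(genes)
        # P(X >= k) with X ~ Hypergeom(population, n_htp, m)
        p = float(hypergeom.sf(k - 1, population, n_htp, m))
        pvals[term] = p
        if p < alpha:
            removed.add(term)

    kept = AnnotationSet(
        records=ann.records[~ann.records["term"].isin(removed)].reset_index(drop=True)
    )
    return removed, kept, pvals


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (0.5 -> 1), elementwise."""
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def normalize_encode(m: AbundanceMatrix) -> EncodedMatrix:
    """Log-normalize counts onto 32 ordered states.

    ``state = round(ln(g + 1) / ln(g_max + 1) * 31)`` with g_max the
    matrix-wide maximum; rounding is half-away-from-zero.  The encoding is
    monotone in g, maps 0 to state 0 and g_max to state 31.
    """
    g_max = m.g_max
    if g_max < 1:
        raise ValueError("all-zero matrix: g_max undefined for scaling")
    scaled = np.log(m.counts.values + 1.0) / math.log(g_max + 1.0) * 31.0
    states = _round_half_away(scaled).astype(np.int64)
    return EncodedMatrix(
        states=pd.DataFrame(states, index=m.counts.index, columns=m.counts.columns)
    )


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.]", "_", name)


def write_character_matrix(
    e: EncodedMatrix, orientation: str = "tof", handle: TextIO | None = None
) -> str:
    """Emit a NEXUS DATA block of the encoded census.

    ``orientation="tof"`` writes one row per GO taxon (characters are
    genomes); ``"tol"`` transposes so rows are genomes and characters are GO
    taxa.  An ASSUMPTIONS block declares every character ordered (Wagner).
    """
    if orientation not in ("tof", "tol"):
        raise ValueError("orientation must be 'tof' or 'tol'")
    states = e.states if orientation == "tof" else e.states.T
    names = [_sanitize(str(t)) for t in states.index]
    if len(set(names)) != len(names):
        raise ValueError("taxon name collision after sanitization")
    width = max(len(n) for n in names) + 2

    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"    DIMENSIONS NTAX={len(names)} NCHAR={states.shape[1]};\n")
    out.write('    FORMAT SYMBOLS="0~9A~V" MISSING=? GAP=-;\n')
    out.write("    MATRIX\n")
    for name, (_, row) in zip(names, states.iterrows()):
        symbols = "".join(ALPHABET[s] for s in row.values)
        out.write(f"    {name:<{width}}{symbols}\n")
    out.write("    ;\nEND;\n\nBEGIN ASSUMPTIONS;\n")
    out.write(f"    TYPESET * wagner = ord: 1-{states.shape[1]};\n")
    out.write("END;\n")
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def read_character_matrix(stream: str | TextIO) -> pd.DataFrame:
    """Read back a NEXUS matrix written by :func:`write_character_matrix`.

    Returns an integer state DataFrame (rows = taxa, columns = 0..nchar-1).
    """
    text = stream if isinstance(stream, str) else stream.read()
    m = re.search(r"MATRIX\s*\n(.*?)\n\s*;", text, re.S)
    if not m:
        raise ValueError("no MATRIX block found")
    rows: dict[str, list[int]] = {}
    for line in m.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        name, symbols = line.split(None, 1)
        rows[name] = [ALPHABET.index(c) for c in symbols.strip()]
    return pd.DataFrame.from_dict(rows, orient="index")
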