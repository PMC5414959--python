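"""Bundled reference tables.

The package ships the published evolutionary timelines of molecular-function
terms at hierarchy levels 1-3 (census of 249 free-living genomes from the
three superkingdoms), as plain TSV: accession, name, Venn group and relative
age (nd) per term.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {
    1: "level1_timeline.tsv",
    2: "level2_timeline.tsv",
    3: "level3_timeline.tsv",
}


def reference_timeline(level: int) -> pd.DataFrame:
    """Published level-1/2/3 timeline table (accession, name, venn, nd)."""
    if level not in _FILES:
        raise ValueError(f"no bundled timeline for level {level!r}")
    ref = resources.files("gontogeny.data") / _FILES[level]
    with ref.open() as handle:
        return pd.read_csv(handle, sep="\t", dtype={"nd": float})
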