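"""Working with the bundled reference timelines (levels 1-3).

The package ships the published evolutionary timelines of molecular-function
terms from a census of 249 free-living genomes: per term, its Venn group
(which superkingdoms encode it) and its relative age nd.  This example
summarizes them and builds the multi-level age-annotated network.
"""

import pandas as pd

from gontogeny import accumulation_regression, reference_timeline

for level in (1, 2, 3):
    df = reference_timeline(level)
    venn = df["venn"].value_counts().to_dict()
    print(f"level {level}: {len(df)} taxa, Venn groups {venn}")
# ABE = present in all three superkingdoms (the ancient core); E-only terms
# concentrate late in the timeline.

level1 = reference_timeline(1)
print("\noldest level-1 functions:")
print(level1.nsmallest(3, "nd")[["accession", "name", "nd"]].to_string(index=False))

# accumulation of lower-level terms relative to level 1
for level in (2, 3):
    other = reference_timeline(level)
    fit = accumulation_regression(
        dict(zip(level1["accession"], level1["nd"])),
        dict(zip(other["accession"], other["nd"])),
    )
    print(f"\nlevel {level} vs level 1 cumulative counts: "
          f"y = {fit['slope']:.2f}x + {fit['intercept']:.2f} (R^2 = {fit['r2']:.2f})")
# The slope estimates how many level-L terms accumulate per level-1 term
# along the timeline.
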