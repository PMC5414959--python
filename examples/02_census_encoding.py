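"""From annotations to a 32-state ordered character matrix.

Builds the genome x term abundance census from synthetic GAF files, then
log-normalizes counts onto the 0-31 state scale (symbols 0-9, A-V) used for
ordered-character parsimony: state = round(ln(g+1)/ln(g_max+1) * 31).
"""

from gontogeny import (
    SimParams, build_matrix, normalize_encode, parse_gaf, simulate,
    write_character_matrix,
)

data = simulate(SimParams(seed=3, n_terms=10, n_genomes_per_superkingdom=2))
ann = parse_gaf(data.combined_gaf())
matrix = build_matrix(ann, None, data.meta)
print(f"census: {len(matrix.taxa)} terms x {len(matrix.genomes)} genomes, "
      f"g_max = {matrix.g_max}")

encoded = normalize_encode(matrix)
print("encoded states (rows = terms, columns = genomes):")
print(encoded.symbols().to_string())
# '0' means the term is absent from that genome; 'V' marks the cell(s)
# holding the matrix-wide maximum abundance. Older terms show uniformly
# high symbols, younger ones mostly zeros.

print()
print(write_character_matrix(encoded, orientation="tof")[:400])
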