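"""Score the standard genetic code's mutational error on all four indices.

The error is the transition-weighted (w=5) mean absolute change of a
physio-chemical index across all 263 stop-free single-base codon pairs:
small values mean point mutations tend to substitute biochemically similar
amino acids.
"""
from codonopt import GeneticCode, INDICES, load_index_table, mutational_error, neighbor_pairs

table = load_index_table()
sgc = GeneticCode.standard()

print(f"stop-free single-base codon pairs in SGC: {len(neighbor_pairs(sgc))}")
for index in INDICES:
    rep = mutational_error(sgc, table, index, w=5.0)
    print(f"{index:>14}: delta = {rep.delta:.4f}  (n = {rep.n_pairs} pairs)")
print("\nLower delta = more error-robust code; deltas are on the z-score")
print("scale of each index, so they are comparable across indices.")
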