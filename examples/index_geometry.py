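"""Geometry of the four amino-acid indices (20 amino acids + stop).

Polarity and hydrophobicity are strongly anti-correlated, which is why
optimizing a code for polarity alone also reduces hydrophobicity errors.
"""
from codonopt import load_index_table
from codonopt.analysis import index_correlation, index_pca

table = load_index_table()
res = index_pca(table, include_stop=True)
print("variance explained:",
      ", ".join(f"PC{k+1} {f:.2f}%" for k, f in enumerate(res.variance_fractions)))
r = index_correlation(table, "polarity", "hydrophobicity")
print(f"corr(polarity, hydrophobicity) = {r:+.3f}")
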