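"""Evolve error-minimizing genetic codes with the Hopfield TSP solver.

Each restart anneals a 21x21 mean-field network on polarity distances,
decodes an amino-acid tour, and maps it through the codon wheel into a full
genetic code with the standard code's degeneracy structure.  Most valid
codes end up with a smaller polarity error than the standard code itself.
(A production run uses hundreds or thousands of restarts.)
"""
from codonopt import INDICES
from codonopt.analysis import ExperimentConfig, find_super_optimal, run_optimization_ensemble

cfg = ExperimentConfig(indices=("polarity",), restarts=60, n_perm=500, seed=42)
summary = run_optimization_ensemble(cfg)

print(f"valid codes: {summary.n_valid}/{cfg.restarts}")
for index in INDICES:
    print(f"{index:>14}: SGC z = {summary.sgc_z[index]:+.2f}, "
          f"fraction of codes beating SGC = {summary.frac_beat_sgc[index]:.2f}")
best = summary.deltas["polarity"].idxmin()
print("\nbest code (lowest polarity error), as a translation string:")
print(summary.codes[best].to_translation_string())
print(f"its polarity error: {summary.deltas.at[best, 'polarity']:.4f} "
      f"(SGC: {summary.sgc_deltas['polarity']:.4f})")
print("codes with all four z-scores < -2:", len(find_super_optimal(summary, -2.0)))
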