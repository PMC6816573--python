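# Methods

`codonopt` models the origin of error-minimizing genetic codes as a
traveling-salesman problem (TSP) over amino acids, solved by a mean-field
Hopfield network, and provides the statistical machinery to score arbitrary
genetic codes against the Standard Genetic Code (SGC).

## The amino-acid index table

Twenty-one labels participate in every computation: the 20 canonical amino
acids plus the translation-stop signal `X`.  Each carries four
physio-chemical indices — polarity (Grantham-style scale), Kyte–Doolittle
hydrophobicity, residue volume (Å³) and isoelectric point (pH).  Raw values
are z-scored per index over the 20 amino acids with the *sample* standard
deviation (n−1); this convention was pinned by round-tripping the published
normalized table: sample-sd z-scores reproduce 77 of the 80 published cells
to four significant figures, population-sd z-scores reproduce none.

Three published normalized cells are inconsistent with their own raw
values: Leu polarity prints −1.027 although its raw value (4.9) is
identical to Ile's, which prints −1.003; and Trp/Tyr hydrophobicity print
+0.1548/+0.2909 where the raw values give −0.1548/−0.2909 (sign flips of
exactly matching magnitude).  The recomputed z-scores are operative
throughout the package; the published cells are retained on
`IndexTable.printed` for reference.  The Glu volume raw value 8.3 looks
like a typo for ~83 but is internally consistent with every published
normalized volume cell, so it is kept as printed.

The stop signal is assigned fixed pseudo-coordinates
(−1.5993, +1.672, −1.5833, −2.6562) taken verbatim from the published
table footnote rather than recomputed from its "beyond two standard
deviations" description; they are outliers that keep the stop distinct
from every amino acid in tour space and are excluded from normalization.

## Mutational error of a code

A genetic code is a total map of the 64 codons onto the 21 labels.  Its
mutational error on index *X* is the transition-weighted mean absolute
index change over all unordered single-base codon pairs in which neither
codon encodes stop:

    Δ = Σ_pairs w_pair |X_i − X_j| / Σ_pairs w_pair

with `w_pair = w` for transitions (A↔G, C↔T) and 1 for transversions;
`w = 5` by default, reflecting the transition/transversion mutational
bias.  Under SGC exactly 263 of the 288 single-base pairs are stop-free;
for permuted codes the count varies (≈230–288) because the stop label can
land on blocks of one to six codons.  Per-category (codon position ×
transition/transversion) unweighted means are reported alongside.

The null model permutes the 21 labels uniformly among SGC's 21 synonymous
codon blocks, preserving the degeneracy structure exactly.  The primary
significance measure is the one-sided lower-tail proportion of permuted
codes with Δ at most the code's (default 1000 permutations, seeded); the
z-score of the code's Δ within the null sample and its two-sided
t-probability are reported as secondary statistics.  No analytic null and
no multiple-testing correction are provided.

Note on reproducibility: the published p-values for SGC
(0.010/0.011/0.048/0.648) could not all be reproduced under any defensible
reading of the error statistic (weighted/unweighted, absolute/squared
differences, stop pairs included/excluded, stop block fixed/permuted,
one/two-sided).  The stated one-sided protocol measures ≈(0.001, 0.008,
0.032, 0.34); the isoelectric value is consistent with a two-sided reading
(2 × 0.34 ≈ 0.68).  The package implements the stated protocol and leaves
the discrepancy visible rather than fitting a convention per index.

## The codon wheel and tour-to-code mapping

The codon wheel is the cyclic ordering of all 64 codons produced by a
reflected base-4 Gray code: the 3rd codon position cycles fastest (48
steps), then the 1st (12 steps), then the 2nd (4 steps, including the
wrap-around), mirroring the decreasing codon degeneracy and increasing
mutational cost of the three positions.  Bases cycle in one of the four
transversion-minimizing orders (A-G-C-T and its relabelings), so each
four-base sweep contributes two transitions and one transversion.
Boustrophedon (direction-reversing) sweeps guarantee every adjacent pair —
including the wrap-around — differs at exactly one base.

Walking the wheel clockwise from a start codon (default AAA) ranks the 21
SGC synonymous blocks by first encounter; each codon inherits its block's
rank ("SGC address").  Strict first-encounter ranking is used even where
the source description's worked example splits the Ile block (labelling
ATA as a 21st class of its own): all codons of a synonymous block share
one address here, which preserves the exact block partition.  The choice
affects only which wheel segment carries which rank, not the block-size
distribution or any error statistic.

A 21-label tour is converted to a full code by placing the label at tour
position *k* on every codon with address *k*.  With uniformly random
tours this scheme is distributionally identical to the block-permutation
null (verified by a chi-squared occupancy test); with optimized tours it
concentrates similar amino acids on mutationally adjacent codon blocks.

`tour_length` defaults to cyclic closure (the wheel is a circle) with an
open-path option; the solver itself works with open paths (below).

## The mean-field Hopfield solver

Cities (labels) and tour positions form an n × n grid of analog neurons;
`v[X, i]` is the probability of city X at position i.  The mean field

    E[X, i] = d_p Σ_{Y≠X} v[Y, i] + Σ_{Y≠X} d[X, Y] (v[Y, i+1] + v[Y, i−1])

combines a position-occupancy penalty (`d_p = 0.7`) with the distance cost
of temporal adjacency.  Activities relax by a row-wise softmax of −E/T
(each city's position distribution sums to one).  Defaults follow the
described experimental setup: initial activities uniform in 0.5 ± 0.1,
penalty 0.7, working temperature T = 0.1.

Four numerical choices were forced by observed solver behavior and differ
from the most literal reading of the source description:

1. **Sequential row updates.**  Fully synchronous updates of this coupling
   oscillate with period two and never converge; city rows are therefore
   updated one at a time in a freshly shuffled (seeded) order per sweep,
   the standard practice in mean-field annealing.
2. **Annealing by default.**  The temperature starts at 0.2 — just above
   the ordering transition of the 21-city instances, which sits near
   T ≈ 0.15 at unit-max distance scale — and is cooled geometrically
   (×0.995 per sweep) down to the working value 0.1, where iteration
   continues to convergence (max activity change < 1e-6, cap 5000 sweeps).
   Fixed-temperature iteration is available but produces either invalid or
   poor tours from random initial conditions.
3. **Open-chain positions.**  Tour positions form an open chain (the first
   and last have one temporal neighbor).  With cyclic positions, every
   direction-reversing ("bitonic") rearrangement of a one-dimensional
   instance has exactly the tour length of the sorted order, so
   single-index optimization would be degenerate: the measured fraction of
   exact cyclic optima beating SGC on polarity is only 16%.  The published
   SGC tour length (41.0) also matches the open-chain length in 4-index
   z-space (41.7) rather than the cyclic one (45.1).  `mean_field` keeps
   cyclic wrap-around as its default argument for the classical closed-tour
   formulation; the solver pipeline uses the open chain.
4. **Distance scaling.**  The stated penalty and temperature only function
   at a bounded distance scale (at raw z-score scale the occupancy penalty
   is undercut by states that stack two cities on one position; measured
   valid yield ≈ 0.3%).  The solver therefore normalizes distances to a
   maximum of `distance_scale`.  The library default (0.5) is calibrated
   on generic small instances, where best-of-100-restart tours match
   exhaustive optima on ≥90% of random 5–7-city instances.

Decoding takes the argmax city per position (ties to the lowest index) and
keeps the tour only if it is a permutation; invalid decodings are
discarded, never repaired.  Given a seed, every run is deterministic.

## Optimization ensembles

`run_optimization_ensemble` repeatedly solves the 21-city TSP on a chosen
index subset, maps valid tours through the codon wheel, scores every code's
Δ on all four indices, and normalizes them as z-scores against one shared
block-permutation null per index (default 1000 permutations).  The fraction
of codes beating SGC is computed per contiguous restart batch (default 5
batches) and averaged.

The ensemble uses `distance_scale = 2.0` rather than the library solver
default.  This operating point is calibrated once against the study's
printed solver statistic — roughly a third of annealing runs ending in a
valid tour (856/2500) — and reproduces the reported phenomenology: a
spread of code qualities with most but not all optimized codes beating
SGC, rather than the near-deterministic sorted-tour solutions the
high-reliability setting produces (which beat SGC in ~100% of runs).  At
this operating point roughly a third of restarts yield valid tours and the
polarity-optimized ensemble beats SGC's polarity error in about 75–85% of
valid codes depending on the seed (published average: 89.2%).

The optimality ratio of a code, {Δ(Mean) − Δ(SGC)} / {Δ(Mean) − Δ(Code)}
× 100 with Δ(Mean) the null mean, equals 100% for a code exactly as good
as SGC and is undefined for codes no better than the null mean.

## Index geometry

PCA and correlations of the four indices include the stop pseudo-entry by
default and re-standardize columns (correlation-matrix PCA), the
convention that best matches the published figures: polarity–
hydrophobicity correlation −0.807 (published −0.81) and first two
principal components 47.5%/38.4% of variance (published 48.73%/37.96%;
computing on the published table cells instead gives 48.5%/38.4%, so the
residual gap traces to the three typo cells and an unstated PCA protocol).
The 20-point and published-cell variants sit behind flags.

## Synthetic fixtures

`generate_fixture` produces seeded test inputs: symmetric random distance
matrices (uniform 0.1–1 off-diagonal entries — featureless instances with
no metric structure, harder than 1-D index instances), block-permuted
codes, and a toy index table with a duplicated column pair (known
correlation structure).  These emulate the *shapes* of study inputs, not
their geometry; solver tests passing on them show the optimizer works on
generic instances, while the genetic-code claims are always evaluated on
the real index table, which ships with the package.

## Problem sizes and budgets

Default experiment sizes are chosen to keep every statistic's Monte-Carlo
error well inside its decision margin: 1000 permutations for p-values
(binomial SE ≤ 0.016), 200–400 solver restarts per ensemble (fraction SE
≤ 0.05), 100–150 restarts per small-instance oracle comparison.  The
acceptance script uses 1000 permutations and 300 restarts.

## Known limitations

* The solver finds local minima; a small fraction of valid tours are far
  from optimal, and the yield/quality balance depends on the distance
  scale as described above.
* The published SGC p-values and PCA fractions are reproduced only up to
  the documented table inconsistencies and protocol ambiguities; the
  isoelectric p-value (published 0.648) measures ≈0.34 under the stated
  one-sided protocol.
* Only the four shipped indices are supported, and there is no
  phylogenetic component: claims about tRNA co-diversification are outside
  the package's scope.
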