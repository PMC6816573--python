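"""Mutational-error statistic, block-permutation null, and optimality ratio.

A genetic code's mutational error on an index is the transition-weighted
mean absolute change of that index across all single-base, stop-free codon
pairs:

    Delta = sum_pairs w_pair * |X_i - X_j| / sum_pairs w_pair

with w_pair = w for transitions and 1 for transversions (default w = 5,
reflecting the transition/transversion mutational bias).  The null model
permutes the 21 labels among the standard code's 21 synonymous codon
blocks, preserving degeneracy exactly; the stop block moves with the
permutation, so the stop-free pair count n varies across null draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .code_tables import (
    INDICES,
    STOP,
    GeneticCode,
    IndexTable,
    neighbor_pairs,
)

#: the six mutation categories: codon position x substitution kind
CATEGORIES = tuple(
    (pos, kind) for pos in (1, 2, 3) for kind in ("transition", "transversion")
)

DEFAULT_TI_TV_WEIGHT = 5.0


@dataclass(frozen=True)
class ErrorReport:
    """Weighted mutational error of one code on one index."""

    index: str
    delta: float                    # weighted mean |X_i - X_j|
    w: float                        # ti/tv weight
    n_pairs: int                    # stop-free single-base pairs
    category_means: dict[tuple[int, str], float]   # unweighted per-category
    category_counts: dict[tuple[int, str], int]

    def __post_init__(self):
        if self.delta < 0 or self.n_pairs <= 0:
            raise ValueError("ErrorReport requires delta >= 0 and n_pairs > 0")
        if sum(self.category_counts.values()) != self.n_pairs:
            raise ValueError("per-category pair counts must sum to n_pairs")


def pair_errors(
    code: GeneticCode, table: IndexTable, index: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """|X_i - X_j|, position and transition flag per stop-free neighbor pair."""
    vals = table.normalized(index)
    pairs = neighbor_pairs(code)
    err = np.array([abs(vals[p.label1] - vals[p.label2]) for p in pairs])
    pos = np.array([p.position for p in pairs])
    is_ti = np.array([p.kind == "transition" for p in pairs])
    return err, pos, is_ti


def mutational_error(
    code: GeneticCode,
    table: IndexTable,
    index: str,
    w: float = DEFAULT_TI_TV_WEIGHT,
) -> ErrorReport:
    """Transition-weighted mean index error over single-base codon pairs."""
    if index not in INDICES:
        raise KeyError(f"unknown index {index!r}")
    if w <= 0:
        raise ValueError("ti/tv weight w must be positive")
    err, pos, is_ti = pair_errors(code, table, index)
    weights = np.where(is_ti, w, 1.0)
    delta = float((weights * err).sum() / weights.sum())
    means, counts = {}, {}
    for pos_k, kind in CATEGORIES:
        sel = (pos == pos_k) & (is_ti == (kind == "transition"))
        counts[(pos_k, kind)] = int(sel.sum())
        if sel.any():
            means[(pos_k, kind)] = float(err[sel].mean())
    return ErrorReport(index, delta, w, len(err), means, counts)


# ---------------------------------------------------------------------------
# block-permutation null
# ---------------------------------------------------------------------------

_SGC = GeneticCode.standard()
_SGC_BLOCKS = tuple(sorted(_SGC.blocks().items()))  # fixed label order


def permute_code(rng: np.random.Generator) -> GeneticCode:
    """Uniform random bijection of the 21 labels onto the SGC codon blocks.

    The synonymous-block structure (which codons are synonymous, and the
    block-size multiset) is exactly that of the standard code; only the
    labels, including stop, are shuffled among blocks.
    """
    labels = [l for l, _ in _SGC_BLOCKS]
    shuffled = list(rng.permutation(labels))
    mapping = {}
    for (old, codons), new in zip(_SGC_BLOCKS, shuffled):
        for c in codons:
            mapping[c] = new
    return GeneticCode(mapping, provenance="permuted")


@dataclass(frozen=True)
class NullDistribution:
    """Mutational errors of block-permuted codes on one index."""

    index: str
    w: float
    deltas: np.ndarray
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return len(self.deltas)

    @property
    def mean(self) -> float:
        return float(self.deltas.mean())

    @property
    def sd(self) -> float:
        return float(self.deltas.std(ddof=1))


def null_distribution(
    table: IndexTable,
    index: str,
    w: float = DEFAULT_TI_TV_WEIGHT,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> NullDistribution:
    """Sample the block-permutation null of the mutational error."""
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    deltas = np.array(
        [
            mutational_error(permute_code(rng), table, index, w).delta
            for _ in range(n_perm)
        ]
    )
    return NullDistribution(index, w, deltas, seed)


@dataclass(frozen=True)
class PermutationTest:
    """One-sided (lower-tail) permutation test of a code's error."""

    index: str
    delta: float
    p_value: float            # proportion of null draws with Delta <= code's
    null: NullDistribution
    t_p_value: float          # secondary: two-sided t-probability of the code's z

    @property
    def z_score(self) -> float:
        return (self.delta - self.null.mean) / self.null.sd


def permutation_pvalue(
    code: GeneticCode,
    table: IndexTable,
    index: str,
    w: float = DEFAULT_TI_TV_WEIGHT,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    null: NullDistribution | None = None,
) -> PermutationTest:
    """Proportion of block-permuted codes with an equal or smaller error.

    The permutation proportion is the primary statistic.  As a secondary
    normal-theory approximation, the code's error is standardized against
    the null sample and the two-sided tail probability of the resulting z
    is taken from a Student t distribution with ``n_perm - 1`` degrees of
    freedom.
    """
    if null is None:
        if n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        null = null_distribution(table, index, w, n_perm, rng)
    delta = mutational_error(code, table, index, w).delta
    p = float((null.deltas <= delta).mean())
    z = (delta - null.mean) / null.sd
    t_p = float(2.0 * _stats.t.sf(abs(z), df=null.n_perm - 1))
    return PermutationTest(index, delta, p, null, t_p)


def per_category_test(
    code: GeneticCode,
    table: IndexTable,
    index: str,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict[tuple[int, str], float]:
    """Lower-tail permutation p-value of each (position, ti/tv) category mean.

    Categories are compared unweighted: the code's mean |X_i - X_j| within a
    category against the same category's mean under block permutation.
    Categories with no pairs in the code are absent from the result.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(rng)
    obs = mutational_error(code, table, index).category_means
    hits = {cat: 0 for cat in obs}
    valid = {cat: 0 for cat in obs}
    for _ in range(n_perm):
        perm = mutational_error(permute_code(rng), table, index).category_means
        for cat in obs:
            if cat in perm:
                valid[cat] += 1
                if perm[cat] <= obs[cat]:
                    hits[cat] += 1
    return {cat: hits[cat] / valid[cat] for cat in obs if valid[cat] > 0}


def optimality_ratio(
    delta_code: float, delta_sgc: float, delta_mean: float
) -> float:
    """Percentage optimality of the standard code relative to a given code.

    ``(Delta(Mean) - Delta(SGC)) / (Delta(Mean) - Delta(Code)) * 100``,
    where Delta(Mean) is the average error of random (block-permuted)
    codes.  Equals 100% when the code matches the standard code's error;
    undefined when the code is no better than the random-code average.
    """
    if delta_mean <= delta_code:
        raise ValueError(
            "optimality ratio undefined: code error must be below the null mean"
        )
    return float((delta_mean - delta_sgc) / (delta_mean - delta_code) * 100.0)
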