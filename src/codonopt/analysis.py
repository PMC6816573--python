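"""Experiment drivers: index diagnostics, optimization ensembles, fixtures.

`run_optimization_ensemble` wires the whole pipeline together: solve the
21-city amino-acid TSP repeatedly on a chosen index subset, map every valid
tour through the codon wheel into a full genetic code, score each code's
mutational error on all four indices, and normalize the errors against a
block-permutation null (z-scores share one null sample per index across the
whole ensemble).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .code_tables import (
    INDICES,
    LABELS,
    STOP,
    GeneticCode,
    IndexTable,
    build_index_table,
    distance_matrix,
    load_index_table,
)
from .codon_wheel import assign_addresses, build_wheel, code_from_path
from .error_stats import (
    DEFAULT_TI_TV_WEIGHT,
    NullDistribution,
    mutational_error,
    null_distribution,
    permute_code,
)
from .hopfield_tsp import SolverParams, solve

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# index geometry diagnostics
# ---------------------------------------------------------------------------


def _index_matrix(
    table: IndexTable, include_stop: bool, use_printed: bool
) -> pd.DataFrame:
    if use_printed:
        if table.printed is None:
            raise ValueError("table carries no published reference values")
        m = table.printed.copy()
    else:
        m = table.coordinates()
    if not include_stop:
        m = m.drop(index=STOP)
    return m


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame          # indices x components
    variance_fractions: np.ndarray  # percentages, sum to 100


def index_pca(
    table: IndexTable,
    include_stop: bool = True,
    use_printed: bool = False,
) -> PCAResult:
    """PCA of the 21 labels (stop included by default) in 4-index space.

    Columns are re-standardized before decomposition (correlation-matrix
    PCA), since appending the stop pseudo-entry perturbs the unit scale of
    the z-scored columns.  Set ``include_stop=False`` for the 20-point
    variant.
    """
    from sklearn.decomposition import PCA

    m = _index_matrix(table, include_stop, use_printed)
    x = (m - m.mean()) / m.std(ddof=1)
    pca = PCA().fit(x.to_numpy())
    loadings = pd.DataFrame(
        pca.components_.T,
        index=m.columns,
        columns=[f"PC{k+1}" for k in range(pca.n_components_)],
    )
    return PCAResult(loadings, pca.explained_variance_ratio_ * 100.0)


def index_correlation(
    table: IndexTable,
    a: str,
    b: str,
    include_stop: bool = True,
    use_printed: bool = False,
) -> float:
    """Pearson correlation of two normalized index vectors."""
    m = _index_matrix(table, include_stop, use_printed)
    return float(np.corrcoef(m[a], m[b])[0, 1])


# ---------------------------------------------------------------------------
# optimization ensembles
# ---------------------------------------------------------------------------


#: solver operating point for code-optimization experiments, calibrated
#: once against the study's reported valid-path yield (~a third of
#: annealing runs decode to a valid tour); the library-wide SolverParams
#: default instead favors reliability on generic TSP instances
EXPERIMENT_SOLVER = SolverParams(distance_scale=2.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for one Hopfield-optimization ensemble."""

    indices: tuple[str, ...] = ("polarity",)
    restarts: int = 2500
    solver: SolverParams = field(default_factory=lambda: EXPERIMENT_SOLVER)
    n_perm: int = 1000
    w: float = DEFAULT_TI_TV_WEIGHT
    seed: int = 0
    wheel_variant: str = "AGCTTCGA"
    start_codon: str = "AAA"
    n_batches: int = 5
    out_dir: str | None = None

    def __post_init__(self):
        if not self.indices or any(i not in INDICES for i in self.indices):
            raise ValueError(f"indices must be a nonempty subset of {INDICES}")
        if self.restarts < 0 or self.n_perm < 0 or self.n_batches < 1:
            raise ValueError("restarts/n_perm must be >= 0, n_batches >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["indices"] = list(self.indices)
        d["solver"] = asdict(self.solver)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        solver = SolverParams(**d.pop("solver", {}))
        d["indices"] = tuple(d.get("indices", ("polarity",)))
        return cls(solver=solver, **d)


@dataclass(frozen=True)
class EnsembleSummary:
    """Scored output of an optimization ensemble."""

    config: ExperimentConfig
    codes: tuple[GeneticCode, ...]
    paths: tuple[tuple[str, ...], ...]
    restart_index: tuple[int, ...]        # which restart produced each code
    deltas: pd.DataFrame                  # codes x 4 indices, raw errors
    z_scores: pd.DataFrame                # same, normalized against the null
    sgc_deltas: dict[str, float]
    sgc_z: dict[str, float]
    null_stats: dict[str, tuple[float, float]]   # index -> (mean, sd)
    n_restarts: int
    frac_beat_sgc: dict[str, float]       # batch-averaged, per index

    @property
    def n_valid(self) -> int:
        return len(self.codes)

    def to_csv(self, path: str | Path) -> None:
        df = self.deltas.add_suffix("_delta").join(self.z_scores.add_suffix("_z"))
        df.insert(0, "restart", self.restart_index)
        df.insert(1, "translation", [c.to_translation_string() for c in self.codes])
        df.to_csv(path, index_label="code")


def _batch_fraction(
    restart_index: np.ndarray,
    beats: np.ndarray,
    n_restarts: int,
    n_batches: int,
) -> float:
    """Fraction of valid codes beating the reference, averaged over
    contiguous restart batches (batches with no valid code are skipped)."""
    if len(beats) == 0:
        return float("nan")
    edges = np.linspace(0, n_restarts, n_batches + 1)
    fracs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (restart_index >= lo) & (restart_index < hi)
        if sel.any():
            fracs.append(beats[sel].mean())
    return float(np.mean(fracs))


def run_optimization_ensemble(
    cfg: ExperimentConfig,
    table: IndexTable | None = None,
    progress: bool = False,
) -> EnsembleSummary:
    """Solve, map, and score a Hopfield-optimized code ensemble.

    Each restart draws its own child RNG from ``cfg.seed``; the permutation
    null (one sample of ``cfg.n_perm`` codes, scored on all four indices)
    is shared by every code in the ensemble.
    """
    table = table if table is not None else load_index_table()
    d = distance_matrix(table, cfg.indices)
    wheel = build_wheel(cfg.wheel_variant, cfg.start_codon)
    addresses = assign_addresses(wheel, GeneticCode.standard())

    ss = np.random.SeedSequence(cfg.seed)
    solver_seed, null_seed = ss.spawn(2)
    restart_rngs = [np.random.default_rng(s) for s in solver_seed.spawn(cfg.restarts)]

    codes, paths, restart_index = [], [], []
    for r, rng in enumerate(restart_rngs):
        res = solve(d, cfg.solver, rng)
        logger.debug(
            "restart %d: valid=%s sweeps=%d%s",
            r, res.valid, res.sweeps,
            "" if res.valid else f" ({res.invalid_reason})",
        )
        if not res.valid:
            continue
        label_path = tuple(LABELS[city] for city in res.path)
        codes.append(code_from_path(label_path, addresses))
        paths.append(label_path)
        restart_index.append(r)
    logger.info(
        "ensemble %s: %d/%d valid tours", "+".join(cfg.indices),
        len(codes), cfg.restarts,
    )

    sgc = GeneticCode.standard()
    null_rng = np.random.default_rng(null_seed)
    nulls: dict[str, NullDistribution] = {}
    perm_codes = [permute_code(null_rng) for _ in range(cfg.n_perm)]
    for idx in INDICES:
        deltas = np.array(
            [mutational_error(c, table, idx, cfg.w).delta for c in perm_codes]
        )
        nulls[idx] = NullDistribution(idx, cfg.w, deltas)

    deltas = pd.DataFrame(
        {
            idx: [mutational_error(c, table, idx, cfg.w).delta for c in codes]
            for idx in INDICES
        }
    )
    null_stats = {idx: (nulls[idx].mean, nulls[idx].sd) for idx in INDICES}
    z_scores = pd.DataFrame(
        {idx: (deltas[idx] - nulls[idx].mean) / nulls[idx].sd for idx in INDICES}
    )
    sgc_deltas = {
        idx: mutational_error(sgc, table, idx, cfg.w).delta for idx in INDICES
    }
    sgc_z = {
        idx: (sgc_deltas[idx] - nulls[idx].mean) / nulls[idx].sd for idx in INDICES
    }
    ri = np.array(restart_index)
    frac_beat_sgc = {
        idx: _batch_fraction(
            ri,
            (deltas[idx].to_numpy() < sgc_deltas[idx]),
            cfg.restarts,
            cfg.n_batches,
        )
        for idx in INDICES
    }
    return EnsembleSummary(
        config=cfg,
        codes=tuple(codes),
        paths=tuple(paths),
        restart_index=tuple(restart_index),
        deltas=deltas,
        z_scores=z_scores,
        sgc_deltas=sgc_deltas,
        sgc_z=sgc_z,
        null_stats=null_stats,
        n_restarts=cfg.restarts,
        frac_beat_sgc=frac_beat_sgc,
    )


def find_super_optimal(
    summary: EnsembleSummary, threshold_z: float = -2.0
) -> list[int]:
    """Indices of ensemble codes whose z-scored errors beat ``threshold_z``
    on every one of the four indices."""
    mask = (summary.z_scores < threshold_z).all(axis=1)
    return list(summary.z_scores.index[mask])


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


def generate_fixture(kind: str, size: int = 5, seed: int = 0):
    """Deterministic synthetic inputs for testing.

    ``random-distances``
        A ``size x size`` symmetric nonnegative zero-diagonal matrix.
    ``random-code``
        One block-permuted genetic code.
    ``toy-index-table``
        A 20-amino-acid index table built from random raw values in which
        hydrophobicity duplicates polarity exactly (correlation 1), with
        outlier stop pseudo-values.
    """
    rng = np.random.default_rng(seed)
    if kind == "random-distances":
        m = rng.uniform(0.1, 1.0, (size, size))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        return d
    if kind == "random-code":
        return permute_code(rng)
    if kind == "toy-index-table":
        aas = [l for l in LABELS if l != STOP]
        polarity = rng.normal(size=20)
        raw = pd.DataFrame(
            {
                "polarity": polarity,
                "hydrophobicity": polarity.copy(),
                "volume": rng.normal(size=20),
                "isoelectric": rng.normal(size=20),
            },
            index=aas,
        )
        stop = {i: 3.0 for i in INDICES}
        return build_index_table(raw, stop)
    raise ValueError(f"unknown fixture kind {kind!r}")
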