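"""Amino-acid alphabet, physio-chemical index table, and codon-level utilities.

The package works with 21 labels: the 20 canonical amino acids plus the
translation-stop signal, written ``X``.  Each label carries four
physio-chemical indices (polarity, hydrophobicity, volume, isoelectric
point).  Raw index values are z-scored over the 20 amino acids; the stop
signal instead carries fixed pseudo-coordinates chosen to be an outlier on
every index so that it can participate in distances and tours without
resembling any amino acid.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: the four physio-chemical indices, in table-column order
INDICES = ("polarity", "hydrophobicity", "volume", "isoelectric")

STOP = "X"

#: all 64 codons in NCBI translation-table order (TTT, TTC, ..., GGG)
NCBI_CODON_ORDER = tuple(
    a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
)

#: all 64 codons in lexicographic ACGT order
CODONS = tuple("".join(p) for p in itertools.product(BASES, repeat=3))


def normalize_codon(codon: str) -> str:
    """Uppercase a codon and map RNA ``U`` to DNA ``T``; validate it."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in BASES for b in c):
        raise ValueError(f"not a codon: {codon!r}")
    return c


# ---------------------------------------------------------------------------
# index table
# ---------------------------------------------------------------------------

_DATA_FILE = "amino_acid_indices.csv"

#: SHA-256 of the packaged index-table CSV (guards against silent edits)
DATA_SHA256 = "9086ed48e9108d5070b48e9771b0735757273f0d5f79a3452cadb448aef3a1bd"


class IndexTable:
    """Raw and normalized physio-chemical values for the 21 labels.

    Normalized values are z-scores computed over the 20 amino acids only
    (sample standard deviation, n-1 denominator); the stop signal's
    normalized coordinates are fixed pseudo-values passed through unchanged.
    A separate ``printed`` frame carries the published normalized values for
    cross-checking; the computed z-scores are the operative coordinates.
    """

    def __init__(self, frame: pd.DataFrame, printed: pd.DataFrame | None = None):
        missing = [i for i in INDICES if f"{i}_norm" not in frame.columns]
        if missing:
            raise ValueError(f"index table missing normalized columns: {missing}")
        self._frame = frame
        self._printed = printed

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def printed(self) -> pd.DataFrame | None:
        """Published normalized values (reference only), or None."""
        return self._printed

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._frame.index)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l != STOP)

    def raw(self, index: str) -> pd.Series:
        self._check_index(index)
        return self._frame[f"{index}_raw"]

    def normalized(self, index: str) -> pd.Series:
        self._check_index(index)
        return self._frame[f"{index}_norm"]

    def value(self, label: str, index: str) -> float:
        """Normalized value of one label on one index."""
        self._check_index(index)
        return float(self._frame.at[label, f"{index}_norm"])

    def coordinates(self, indices: Sequence[str] | None = None) -> pd.DataFrame:
        """Normalized coordinates of all 21 labels over the chosen indices."""
        indices = tuple(indices) if indices is not None else INDICES
        for i in indices:
            self._check_index(i)
        return self._frame[[f"{i}_norm" for i in indices]].set_axis(
            list(indices), axis=1
        )

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index_label="code1")

    def _check_index(self, index: str) -> None:
        if index not in INDICES:
            raise KeyError(f"unknown index {index!r}; expected one of {INDICES}")


def build_index_table(
    raw_values: pd.DataFrame,
    stop_values: Mapping[str, float],
    code3: Mapping[str, str] | None = None,
) -> IndexTable:
    """Z-score raw per-amino-acid index values and append the stop entry.

    Parameters
    ----------
    raw_values
        One row per amino acid (single-letter index), one column per index
        in :data:`INDICES`; exactly the 20 canonical amino acids.
    stop_values
        Fixed normalized pseudo-coordinates for the stop signal, one per
        index.  These are **not** produced by the normalization; they are
        constants chosen to make the stop an outlier.
    """
    aas = sorted(raw_values.index)
    if len(aas) != 20 or STOP in aas:
        raise ValueError("raw_values must cover exactly the 20 amino acids")
    for i in INDICES:
        if i not in raw_values.columns:
            raise ValueError(f"raw_values missing index column {i!r}")
        if i not in stop_values:
            raise ValueError(f"stop_values missing index {i!r}")
    if raw_values[list(INDICES)].isna().any().any():
        raise ValueError("raw_values contains missing entries")

    out = {}
    for i in INDICES:
        col = raw_values[i].astype(float)
        z = (col - col.mean()) / col.std(ddof=1)  # sample sd pins Table scale
        out[f"{i}_raw"] = col
        out[f"{i}_norm"] = z
    frame = pd.DataFrame(out, index=raw_values.index)
    stop_row = {f"{i}_raw": np.nan for i in INDICES}
    stop_row.update({f"{i}_norm": float(stop_values[i]) for i in INDICES})
    frame.loc[STOP] = stop_row
    frame = frame.sort_index()
    return IndexTable(frame)


def load_index_table() -> IndexTable:
    """Load the packaged 21-label index table (raw values + published z-scores).

    Normalized coordinates are recomputed from the raw values; the published
    normalized column is kept on ``IndexTable.printed`` for reference.  Three
    published cells (Leu polarity, Trp and Tyr hydrophobicity) are internally
    inconsistent with their own raw values — the recomputed z-scores are used.
    """
    with resources.files("codonopt.data").joinpath(_DATA_FILE).open("rb") as fh:
        blob = fh.read()
    df = pd.read_csv(pd.io.common.BytesIO(blob), index_col="code1")
    raw = df.loc[df.index != STOP, [f"{i}_raw" for i in INDICES]]
    raw.columns = list(INDICES)
    stop = {i: df.at[STOP, f"{i}_printed"] for i in INDICES}
    table = build_index_table(raw, stop)
    printed = df[[f"{i}_printed" for i in INDICES]].set_axis(list(INDICES), axis=1)
    table._printed = printed
    table._frame["code3"] = df["code3"]
    return table


def packaged_data_sha256() -> str:
    blob = resources.files("codonopt.data").joinpath(_DATA_FILE).read_bytes()
    return hashlib.sha256(blob).hexdigest()


#: the 21 labels in canonical (table-row) order; also the TSP city order
LABELS = ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L", "M",
          "N", "P", "Q", "R", "S", "T", "V", "W", STOP, "Y")


def amino_acid_distance(
    x: str,
    y: str,
    table: IndexTable,
    indices: Sequence[str] = INDICES,
) -> float:
    """Euclidean distance between two labels in normalized index space."""
    indices = tuple(indices)
    if not indices:
        raise ValueError("indices must be a nonempty subset of the four indices")
    dx = np.array([table.value(x, i) - table.value(y, i) for i in indices])
    return float(np.sqrt((dx**2).sum()))


def distance_matrix(
    table: IndexTable,
    indices: Sequence[str] = INDICES,
    labels: Sequence[str] = LABELS,
) -> np.ndarray:
    """Symmetric pairwise distance matrix over ``labels`` (default all 21)."""
    coords = table.coordinates(indices).loc[list(labels)].to_numpy()
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(-1))


# ---------------------------------------------------------------------------
# genetic codes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticCode:
    """A total mapping of the 64 codons onto the 21 labels.

    ``provenance`` records how the code arose: ``"sgc"`` for the standard
    code, ``"permuted"`` for a synonymous-block permutation, ``"hopfield"``
    for a code built from an optimized amino-acid tour.
    """

    mapping: Mapping[str, str]
    provenance: str = "unknown"

    def __post_init__(self):
        m = {normalize_codon(c): str(l) for c, l in self.mapping.items()}
        if len(m) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(m)}")
        object.__setattr__(self, "mapping", m)

    def __getitem__(self, codon: str) -> str:
        return self.mapping[normalize_codon(codon)]

    def labels_used(self) -> frozenset[str]:
        return frozenset(self.mapping.values())

    def blocks(self) -> dict[str, frozenset[str]]:
        """Synonymous blocks: label -> set of codons encoding it."""
        out: dict[str, set[str]] = {}
        for codon, label in self.mapping.items():
            out.setdefault(label, set()).add(codon)
        return {l: frozenset(cs) for l, cs in out.items()}

    def block_size_multiset(self) -> tuple[int, ...]:
        return tuple(sorted(len(b) for b in self.blocks().values()))

    # -- I/O ---------------------------------------------------------------

    def to_translation_string(self) -> str:
        """64-character NCBI-style translation string (TTT..GGG order, '*'=stop)."""
        return "".join(
            "*" if self.mapping[c] == STOP else self.mapping[c]
            for c in NCBI_CODON_ORDER
        )

    @classmethod
    def from_translation_string(cls, s: str, provenance: str = "unknown") -> "GeneticCode":
        if len(s) != 64:
            raise ValueError("translation string must have 64 characters")
        mapping = {
            c: (STOP if a == "*" else a.upper())
            for c, a in zip(NCBI_CODON_ORDER, s)
        }
        return cls(mapping, provenance)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"codon": list(self.mapping), "label": list(self.mapping.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "unknown") -> "GeneticCode":
        df = pd.read_csv(path)
        return cls(dict(zip(df["codon"], df["label"])), provenance)

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The Standard Genetic Code (NCBI translation table 1)."""
        t = _BioCodonTable.unambiguous_dna_by_id[1]
        mapping = dict(t.forward_table)
        for c in t.stop_codons:
            mapping[c] = STOP
        return cls(mapping, provenance="sgc")


# ---------------------------------------------------------------------------
# single-base neighbors
# ---------------------------------------------------------------------------


def mutation_class(c1: str, c2: str) -> tuple[int, str] | None:
    """Differing codon position (1-3) and substitution kind, or None.

    Returns ``(position, "transition" | "transversion")`` when the two
    codons differ at exactly one position; ``None`` (not-a-neighbor) for
    identical codons or codons differing at two or more positions.
    Transitions are A<->G and C<->T.
    """
    a, b = normalize_codon(c1), normalize_codon(c2)
    diffs = [i for i in range(3) if a[i] != b[i]]
    if len(diffs) != 1:
        return None
    i = diffs[0]
    ti = {a[i], b[i]} <= PURINES or {a[i], b[i]} <= PYRIMIDINES
    return (i + 1, "transition" if ti else "transversion")


@dataclass(frozen=True)
class NeighborPair:
    codon1: str
    codon2: str
    position: int
    kind: str  # "transition" | "transversion"
    label1: str
    label2: str


def _all_single_base_pairs() -> list[tuple[str, str, int, str]]:
    pairs = []
    for c in CODONS:
        for i in range(3):
            for b in BASES:
                if b > c[i]:  # unordered: count each pair once
                    c2 = c[:i] + b + c[i + 1:]
                    pos, kind = mutation_class(c, c2)
                    pairs.append((c, c2, pos, kind))
    return pairs


#: all 288 unordered single-base codon pairs with position and ti/tv kind
SINGLE_BASE_PAIRS = tuple(_all_single_base_pairs())


def neighbor_pairs(code: GeneticCode) -> list[NeighborPair]:
    """Stop-free single-base codon pairs of a code, annotated by class.

    Pairs in which either codon encodes the stop signal are excluded; under
    the standard code this leaves 263 of the 288 single-base pairs.
    """
    out = []
    for c1, c2, pos, kind in SINGLE_BASE_PAIRS:
        l1, l2 = code[c1], code[c2]
        if l1 == STOP or l2 == STOP:
            continue
        out.append(NeighborPair(c1, c2, pos, kind, l1, l2))
    return out
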