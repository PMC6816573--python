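"""Transversion-minimizing codon wheel and tour-to-code mapping.

The wheel is a cyclic ordering of all 64 codons in which consecutive codons
differ at exactly one base.  The third codon position cycles fastest, then
the first, then the second — mirroring the decreasing codon degeneracy (and
increasing mutational cost) of substitutions at the 3rd, 1st and 2nd
positions.  Within a position the four bases are cycled in one of the four
orders that minimize transversion steps (e.g. A-G-C-T, whose steps are
ti, tv, ti and a wrap-around tv).  Direction-reversing (boustrophedon)
traversal keeps every adjacent pair a single-base neighbor, which makes the
ordering a reflected base-4 Gray code over the three positions.

Walking the wheel past the standard code gives every synonymous codon block
an integer "SGC address" (order of first encounter).  A 21-label tour path
is turned into a full genetic code by placing the label at tour position k
on every codon whose address is k; the construction therefore preserves the
standard code's block-size distribution exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .code_tables import (
    INDICES,
    LABELS,
    STOP,
    GeneticCode,
    IndexTable,
    amino_acid_distance,
    mutation_class,
    normalize_codon,
)

#: the four transversion-minimizing base-cycling sequences (forward half +
#: mirrored return half, as the wheel sweeps back and forth)
WHEEL_VARIANTS = ("AGCTTCGA", "AGTCCTGA", "GACTTCAG", "GATCCTAG")

# slowest-to-fastest cycling: 2nd, then 1st, then 3rd codon position
_POSITION_ORDER = (1, 0, 2)


def build_wheel(variant: str = "AGCTTCGA", start: str = "AAA") -> "CodonWheel":
    """Build the cyclic codon wheel for a cycling variant, rotated to ``start``.

    The cycle itself is fixed by the variant; the start codon only chooses
    where the walk (and hence the addressing) begins.
    """
    if variant not in WHEEL_VARIANTS:
        raise ValueError(
            f"unknown wheel variant {variant!r}; expected one of {WHEEL_VARIANTS}"
        )
    start = normalize_codon(start)
    order = variant[:4]
    codons = []
    for k in range(64):
        d2 = k // 16                      # 2nd position: slowest
        j = k % 16
        d1 = j // 4 if d2 % 2 == 0 else (15 - j) // 4
        m = j % 4                         # 3rd position: fastest, reflected
        d3 = m if (k // 4) % 2 == 0 else 3 - m
        codons.append(order[d1] + order[d2] + order[d3])
    i = codons.index(start)
    codons = codons[i:] + codons[:i]
    return CodonWheel(tuple(codons), variant, start)


@dataclass(frozen=True)
class CodonWheel:
    """Cyclic ordering of the 64 codons; adjacent codons differ at one base."""

    codons: tuple[str, ...]
    variant: str
    start: str

    def steps(self) -> list[tuple[int, str]]:
        """Per-step (position, kind) annotations, wrap-around step included."""
        out = []
        for a, b in zip(self.codons, self.codons[1:] + self.codons[:1]):
            mc = mutation_class(a, b)
            if mc is None:  # unreachable for a well-formed wheel
                raise ValueError(f"wheel step {a}->{b} is not single-base")
            out.append(mc)
        return out

    def step_position_census(self) -> dict[int, int]:
        census = {1: 0, 2: 0, 3: 0}
        for pos, _ in self.steps():
            census[pos] += 1
        return census

    def to_frame(self, reference: GeneticCode | None = None) -> pd.DataFrame:
        """Tabular wheel layout (rank, codon, step class; optionally addresses)."""
        steps = self.steps()
        df = pd.DataFrame(
            {
                "rank": range(1, 65),
                "codon": self.codons,
                "step_position": [p for p, _ in steps],
                "step_kind": [k for _, k in steps],
            }
        )
        if reference is not None:
            addr = assign_addresses(self, reference)
            df["address"] = [addr.codon_to_address[c] for c in self.codons]
            df["label"] = [reference[c] for c in self.codons]
        return df

    def to_csv(self, path: str | Path, reference: GeneticCode | None = None) -> None:
        self.to_frame(reference).to_csv(path, index=False)


@dataclass(frozen=True)
class AddressMap:
    """Codon -> block address (1..21) and address -> reference label."""

    codon_to_address: dict[str, int]
    address_to_label: dict[int, str]

    def __post_init__(self):
        if sorted(self.address_to_label) != list(range(1, 22)):
            raise ValueError("addresses must cover 1..21")


def assign_addresses(wheel: CodonWheel, reference: GeneticCode) -> AddressMap:
    """Rank the reference code's 21 synonymous blocks by first wheel encounter.

    Walking the wheel clockwise from its start codon, each distinct
    reference label is ranked in order of first appearance; every codon then
    inherits the rank of its label's block.  All codons of a synonymous
    block — contiguous on the wheel or not — share one address.
    """
    labels = reference.labels_used()
    if len(labels) != 21:
        raise ValueError(f"reference code uses {len(labels)} labels, expected 21")
    label_rank: dict[str, int] = {}
    for codon in wheel.codons:
        lab = reference[codon]
        if lab not in label_rank:
            label_rank[lab] = len(label_rank) + 1
    return AddressMap(
        codon_to_address={c: label_rank[reference[c]] for c in wheel.codons},
        address_to_label={r: l for l, r in label_rank.items()},
    )


# ---------------------------------------------------------------------------
# tour paths
# ---------------------------------------------------------------------------


def validate_tour(path: Sequence[str], labels: Sequence[str] = LABELS) -> None:
    if sorted(path) != sorted(labels):
        raise ValueError(
            f"tour path must visit each of the {len(labels)} labels exactly once"
        )


def code_from_path(
    path: Sequence[str],
    addresses: AddressMap,
    provenance: str = "hopfield",
) -> GeneticCode:
    """Assign the label at tour position k to every codon with address k."""
    validate_tour(path, list(addresses.address_to_label.values()))
    pos_of = {label: k + 1 for k, label in enumerate(path)}
    by_address = {pos_of[l]: l for l in path}
    mapping = {
        c: by_address[a] for c, a in addresses.codon_to_address.items()
    }
    return GeneticCode(mapping, provenance)


def identity_path(addresses: AddressMap) -> tuple[str, ...]:
    """The path whose tour positions equal the reference block addresses."""
    return tuple(addresses.address_to_label[k] for k in range(1, 22))


def tour_length(
    path: Sequence[str],
    table: IndexTable,
    indices: Sequence[str] = INDICES,
    cyclic: bool = True,
) -> float:
    """Sum of amino-acid distances along consecutive tour labels."""
    if not path or len(set(path)) != len(path):
        raise ValueError("tour path must be nonempty with no repeated label")
    pairs = list(zip(path, path[1:]))
    if cyclic and len(path) > 2:
        pairs.append((path[-1], path[0]))
    return sum(amino_acid_distance(a, b, table, indices) for a, b in pairs)
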