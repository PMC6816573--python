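"""Codon wheel construction, SGC addressing, and tour-to-code mapping."""

import collections

import numpy as np
import pytest

from codonopt import (
    LABELS,
    WHEEL_VARIANTS,
    GeneticCode,
    assign_addresses,
    build_wheel,
    code_from_path,
    identity_path,
    mutation_class,
    permute_code,
    tour_length,
)
from codonopt.code_tables import CODONS, STOP
from codonopt.codon_wheel import validate_tour


class TestBuildWheel:
    def test_documented_walk_from_aaa(self, wheel):
        assert wheel.codons[:8] == (
            "AAA", "AAG", "AAC", "AAT", "GAT", "GAC", "GAG", "GAA",
        )
        assert wheel.codons[-4:] == ("ATT", "ATC", "ATG", "ATA")

    @pytest.mark.parametrize("variant", WHEEL_VARIANTS)
    def test_every_codon_once_and_single_base_steps(self, variant):
        w = build_wheel(variant, start=variant[0] * 3)
        assert sorted(w.codons) == sorted(CODONS)
        for (pos, kind) in w.steps():
            assert pos in (1, 2, 3) and kind in ("transition", "transversion")

    @pytest.mark.parametrize("variant", WHEEL_VARIANTS)
    def test_step_position_census_48_12_4_for_all_starts(self, variant):
        # brute force over every rotation of every transversion-minimizing wheel
        for start in CODONS:
            w = build_wheel(variant, start)
            assert w.step_position_census() == {3: 48, 1: 12, 2: 4}

    def test_transversion_minimization_within_positions(self, wheel):
        kinds = collections.Counter(k for _, k in wheel.steps())
        # each A-G-C-T sweep contributes 2 transitions + 1 transversion;
        # 16 + 4 + 1 sweeps plus the wrap-around transversion
        assert kinds["transition"] == 2 * (16 + 4 + 1)
        assert kinds["transversion"] == 64 - kinds["transition"]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_wheel("ACGTTGCA")


class TestAssignAddresses:
    def test_documented_address_walk(self, addresses):
        expected = {
            "AAA": 1, "AAG": 1, "AAC": 2, "AAT": 2,
            "GAT": 3, "GAC": 3, "GAG": 4, "GAA": 4,
        }
        for codon, addr in expected.items():
            assert addresses.codon_to_address[codon] == addr

    def test_addresses_cover_1_to_21(self, addresses):
        assert set(addresses.codon_to_address.values()) == set(range(1, 22))
        assert sorted(addresses.address_to_label) == list(range(1, 22))

    def test_synonymous_blocks_share_one_address(self, addresses, sgc):
        for label, codons in sgc.blocks().items():
            assert len({addresses.codon_to_address[c] for c in codons}) == 1

    def test_ile_codons_share_rank_including_ata(self, addresses, sgc):
        # strict first-encounter ranking keeps ATA in the isoleucine block
        assert addresses.codon_to_address["ATA"] == addresses.codon_to_address["ATT"]

    def test_wrong_label_count_rejected(self, wheel):
        two_label = GeneticCode({c: "A" if c[0] == "A" else "L" for c in CODONS})
        with pytest.raises(ValueError):
            assign_addresses(wheel, two_label)


class TestCodeFromPath:
    @pytest.mark.parametrize("variant", WHEEL_VARIANTS)
    def test_identity_path_reconstructs_sgc(self, variant, sgc):
        w = build_wheel(variant, "AAA")
        addr = assign_addresses(w, sgc)
        rebuilt = code_from_path(identity_path(addr), addr)
        assert rebuilt.mapping == sgc.mapping

    def test_label_at_position_k_lands_on_address_k_codons(self, addresses, sgc):
        path = identity_path(addresses)
        # swap lysine into tour position 4 (the Glu block GAG/GAA)
        path = list(path)
        k_pos, four_pos = path.index("K"), 3
        path[k_pos], path[four_pos] = path[four_pos], path[k_pos]
        code = code_from_path(tuple(path), addresses)
        assert code["GAG"] == "K" and code["GAA"] == "K"

    def test_block_size_multiset_preserved_for_random_paths(self, addresses, sgc):
        rng = np.random.default_rng(1)
        for _ in range(25):
            path = tuple(rng.permutation(LABELS))
            code = code_from_path(path, addresses)
            assert code.block_size_multiset() == sgc.block_size_multiset()

    def test_invalid_path_rejected(self, addresses):
        with pytest.raises(ValueError):
            code_from_path(("A",) * 21, addresses)
        with pytest.raises(ValueError):
            code_from_path(LABELS[:-1], addresses)

    def test_random_paths_match_block_permutation_scheme(self, addresses, sgc):
        """Mapping uniformly random tours through the wheel is distributionally
        the same as permuting labels among synonymous blocks: every label hits
        every block uniformly."""
        from scipy import stats

        rng = np.random.default_rng(7)
        blocks = sorted(sgc.blocks().items())
        block_of_codon = {}
        for b, (_, codons) in enumerate(blocks):
            for c in codons:
                block_of_codon[c] = b
        counts = np.zeros((21, 21))
        label_idx = {l: i for i, l in enumerate(LABELS)}
        n_draws = 1000
        for _ in range(n_draws):
            code = code_from_path(tuple(rng.permutation(LABELS)), addresses)
            seen = set()
            for codon, label in code.mapping.items():
                b = block_of_codon[codon]
                if b not in seen:
                    counts[label_idx[label], b] += 1
                    seen.add(b)
        assert counts.sum() == n_draws * 21
        expected = n_draws / 21
        chi2 = ((counts - expected) ** 2 / expected).sum()
        dof = 20 * 20  # doubly stochastic constraint
        assert stats.chi2.sf(chi2, dof) > 1e-3

    def test_permute_code_same_invariants(self, sgc):
        rng = np.random.default_rng(3)
        for _ in range(25):
            code = permute_code(rng)
            assert code.block_size_multiset() == sgc.block_size_multiset()
            assert code.labels_used() == frozenset(LABELS)


class TestTourLength:
    def test_reversal_leaves_cyclic_length_unchanged(self, table):
        rng = np.random.default_rng(5)
        path = tuple(rng.permutation(LABELS))
        fwd = tour_length(path, table, ("polarity",), cyclic=True)
        rev = tour_length(path[::-1], table, ("polarity",), cyclic=True)
        assert fwd == pytest.approx(rev)

    def test_three_label_path_hand_summed(self, table):
        # d(A,C) + d(C,D) on published polarity values:
        # |-0.1672 + 1.043| + |-1.043 - 2.221| = 0.8758 + 3.264
        length = tour_length(("A", "C", "D"), table, ("polarity",), cyclic=False)
        assert length == pytest.approx(0.8758 + 3.264, abs=5e-3)

    def test_cyclic_adds_closing_edge(self, table):
        open_len = tour_length(("A", "C", "D"), table, ("polarity",), cyclic=False)
        closed = tour_length(("A", "C", "D"), table, ("polarity",), cyclic=True)
        from codonopt import amino_acid_distance

        assert closed == pytest.approx(
            open_len + amino_acid_distance("D", "A", table, ("polarity",))
        )

    def test_repeated_label_rejected(self, table):
        with pytest.raises(ValueError):
            tour_length(("A", "A", "C"), table)
        with pytest.raises(ValueError):
            validate_tour(("A",) * 21)
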