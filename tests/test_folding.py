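"""Folding thermodynamics: enumeration oracle, dynamic programs, pfold."""

import math

import numpy as np
import pytest

from attcfold.attc import ConstraintSet, recombinogenic_constraints
from attcfold.folding import (
    EmptyEnsembleError,
    ReferenceModel,
    SecondaryStructure,
    enumerate_structures,
    fold,
    pfold,
    strand_stability_gap,
)
from attcfold.synthetic import AttCGeneratorParams, generate_attc
from attcfold.vienna import ViennaDNAModel

from conftest import random_compatible_constraint, random_sequence


def independent_structure_count(seq: str, min_loop: int = 3) -> int:
    """Second, independent recursive counter of valid structures."""
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

    def count(i, j):
        if j - i < 0:
            return 1
        total = count(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in pairs:
                total += count(i + 1, k - 1) * count(k + 1, j)
        return total

    return count(0, len(seq) - 1)


class TestEnumeration:
    def test_no_complementary_pair_single_structure(self):
        structs = enumerate_structures("AAAA")
        assert len(structs) == 1
        assert structs[0][0] == "...." and structs[0][1] == 0.0

    def test_hand_enumeration(self):
        structs = enumerate_structures("GAAAC")
        assert sorted(s for s, _ in structs) == ["(...)", "....."]

    def test_count_matches_independent_counter(self):
        for seq in ("GGAAACC", "GCGCAAAAGCGC", "ATATATATAT"):
            assert len(enumerate_structures(seq)) == \
                independent_structure_count(seq)

    def test_refuses_long_sequences(self):
        with pytest.raises(ValueError, match="oracle"):
            enumerate_structures("A" * 25)


class TestFold:
    def test_open_chain(self, ref_model):
        out = fold("AAAAAA", ref_model)
        assert out.mfe_energy == 0.0
        assert out.mfe_structure == "......"
        assert out.ensemble_free_energy <= 0.0

    def test_hairpin_matches_oracle_minimum(self, ref_model):
        seq = "GGGGAAAACCCC"
        out = fold(seq, ref_model)
        emin = min(e for _, e in enumerate_structures(seq, ref_model))
        assert out.mfe_structure == "((((....))))"
        assert math.isclose(out.mfe_energy, emin, abs_tol=1e-12)

    def test_forced_pair_between_as_is_empty(self, ref_model):
        cs = ConstraintSet(frozenset({(0, 7)}), "bottom")
        with pytest.raises(EmptyEnsembleError):
            fold("AAAAAAAA", ref_model, cs)

    def test_mfe_structure_contains_forced_pairs(self, ref_model):
        rng = np.random.default_rng(3)
        for _ in range(30):
            seq = random_sequence(rng, int(rng.integers(8, 19)))
            cs = random_compatible_constraint(rng, seq, ref_model)
            if cs is None:
                continue
            out = fold(seq, ref_model, cs)
            assert frozenset(cs) <= out.mfe_structure.pairs()

    def test_dp_agrees_with_oracle(self, ref_model):
        rng = np.random.default_rng(11)
        for _ in range(60):
            seq = random_sequence(rng, int(rng.integers(5, 19)))
            structs = enumerate_structures(seq, ref_model)
            z = sum(math.exp(-e / ref_model.rt) for _, e in structs)
            out = fold(seq, ref_model)
            assert math.isclose(
                math.exp(-out.ensemble_free_energy / ref_model.rt), z,
                rel_tol=1e-9)
            assert math.isclose(out.mfe_energy,
                                min(e for _, e in structs), abs_tol=1e-9)

    def test_energy_of_traceback_structure_is_mfe(self, ref_model):
        rng = np.random.default_rng(5)
        for _ in range(40):
            seq = random_sequence(rng, int(rng.integers(6, 19)))
            out = fold(seq, ref_model)
            assert math.isclose(
                ref_model.energy(seq, out.mfe_structure.pairs()),
                out.mfe_energy, abs_tol=1e-9)


class TestPfold:
    def test_empty_constraints_give_exactly_one(self, ref_model):
        res = pfold("GGGGAAAACCCC", ref_model,
                    ConstraintSet(frozenset(), "bottom"))
        assert res.pfold == 1.0
        assert res.ec == res.eu

    def test_matches_enumeration_ratio(self, ref_model):
        seq = "GGCGAAAACGCTAAA"  # 15-nt toy
        cs = ConstraintSet(frozenset({(0, 11), (1, 10)}), "bottom")
        sat = enumerate_structures(seq, ref_model, cs)
        allst = enumerate_structures(seq, ref_model)
        zc = sum(math.exp(-e / ref_model.rt) for _, e in sat)
        zu = sum(math.exp(-e / ref_model.rt) for _, e in allst)
        assert math.isclose(pfold(seq, ref_model, cs).pfold, zc / zu,
                            rel_tol=1e-9)

    def test_unsatisfiable_constraint_maps_to_zero(self, ref_model):
        res = pfold("AAAAAAAA", ref_model,
                    ConstraintSet(frozenset({(0, 7)}), "bottom"))
        assert res.pfold == 0.0 and math.isinf(res.ec)

    def test_monotone_under_added_constraints(self, ref_model):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 15:
            seq = random_sequence(rng, int(rng.integers(10, 19)))
            cs2 = random_compatible_constraint(rng, seq, ref_model,
                                               max_pairs=2)
            if cs2 is None or len(cs2) < 2:
                continue
            sub = ConstraintSet(frozenset(sorted(cs2)[:1]), "bottom")
            p_sub = pfold(seq, ref_model, sub).pfold
            p_full = pfold(seq, ref_model, cs2).pfold
            assert p_full <= p_sub + 1e-12
            assert 0.0 <= p_full <= 1.0
            checked += 1


class TestStrandGap:
    def test_palindrome_gap_zero(self, ref_model):
        site, _ = generate_attc(AttCGeneratorParams(), seed=2)
        # a self-reverse-complement sequence equals its own bottom strand
        from attcfold.attc import AttCSite, reverse_complement
        half = "GGCATACG"
        seq = half + "AAAA" + reverse_complement(half)
        with pytest.warns(UserWarning):
            pal = AttCSite(id="pal", top_strand=seq)
        assert strand_stability_gap(pal, ref_model) == 0.0

    def test_deterministic(self, ref_model):
        site, _ = generate_attc(AttCGeneratorParams(), seed=9)
        g1 = strand_stability_gap(site, ref_model, "unconstrained")
        g2 = strand_stability_gap(site, ref_model, "unconstrained")
        assert g1 == g2

    def test_constrained_mode_runs(self, ref_model):
        site, _ = generate_attc(AttCGeneratorParams(), seed=10)
        g = strand_stability_gap(site, ref_model, "constrained")
        assert math.isfinite(g)


class TestViennaBackend:
    def test_constrained_ensemble_never_below_unconstrained(self):
        vm = ViennaDNAModel()
        site, _ = generate_attc(AttCGeneratorParams(), seed=1)
        cs = recombinogenic_constraints(site, "bottom")
        eu = fold(site.bottom, vm).ensemble_free_energy
        ec = fold(site.bottom, vm, cs).ensemble_free_energy
        assert ec >= eu - 1e-6

    def test_pfold_in_unit_interval_and_high_for_clean_hairpin(self):
        vm = ViennaDNAModel()
        site, _ = generate_attc(AttCGeneratorParams(), seed=6)
        res = pfold(site.bottom, vm,
                    recombinogenic_constraints(site, "bottom"))
        assert 0.0 <= res.pfold <= 1.0
        assert res.pfold > 0.1  # mismatch-free stem folds recombinogenically

    def test_non_complementary_forced_pair_maps_to_zero(self):
        vm = ViennaDNAModel()
        res = pfold("AAAATTTTAAAA", vm,
                    ConstraintSet(frozenset({(0, 11)}), "bottom"))
        assert res.pfold == 0.0

    def test_temperature_configurable(self):
        vm = ViennaDNAModel(temperature=298.15)
        out = fold("GGGGCGAAAAGCGCCCC", vm)
        assert out.temperature == 298.15
        assert out.mfe_energy < 0


class TestSecondaryStructure:
    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            SecondaryStructure("((.)")

    def test_pairs_round_trip(self):
        s = SecondaryStructure("((...)).")
        assert SecondaryStructure.from_pairs(s.pairs(), len(s)) == s
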