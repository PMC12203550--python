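"""Recursive kinship computation: worked examples, X mode, MZ handling,
block-diagonal assembly and the distance transform."""

import numpy as np
import pytest

from pedkit.kinship import (
    apply_mz_twins,
    assemble_block_diagonal,
    kinship,
    kinship_autosomal,
    kinship_to_distance,
    kinship_x,
)
from pedkit.model import IndividualRecord, Pedigree, RelCode, Relationship, Sex


class TestAutosomal:
    def test_full_siblings(self, fx):
        k = kinship_autosomal(fx["nuclear"])
        assert k["S1", "S2"] == 0.25

    def test_first_cousins(self, fx):
        k = kinship_autosomal(fx["first_cousins"])
        assert k["C", "D"] == 0.0625

    def test_founder_self_kinship(self, fx):
        k = kinship_autosomal(fx["trio"])
        assert k["F", "F"] == 0.5

    def test_parent_child(self, fx):
        k = kinship_autosomal(fx["trio"])
        assert k["F", "C"] == 0.25

    def test_inbred_child_self_kinship(self, fx):
        # child of a full-sib mating: F = 1/4, self-kinship (1+F)/2 = 0.625
        k = kinship_autosomal(fx["sib_mating_loop"])
        assert k["C", "C"] == 0.625

    def test_unrelated_founders(self, fx):
        k = kinship_autosomal(fx["first_cousins"])
        assert k["SA", "SB"] == 0.0

    def test_record_order_permutation_invariance(self, fx):
        ped = fx["first_cousins"]
        k1 = kinship_autosomal(ped)
        reordered = Pedigree(list(reversed(ped.records)))
        k2 = kinship_autosomal(reordered)
        for a in ped.keys:
            for b in ped.keys:
                assert k1[a, b] == k2[a, b]

    def test_no_inbreeding_means_diagonal_exactly_half(self, fx):
        for name in ("trio", "nuclear", "first_cousins", "twins"):
            k = kinship_autosomal(fx[name])
            assert np.all(k.matrix.diagonal() == 0.5), name

    @pytest.mark.parametrize("name", ["trio", "nuclear", "first_cousins",
                                      "sib_mating_loop", "cross_generation",
                                      "twins", "two_families"])
    def test_matrix_properties(self, fx, name):
        k = kinship_autosomal(fx[name])
        dense = k.dense()
        assert np.array_equal(dense, dense.T)
        assert dense.min() >= 0.0 and dense.max() <= 1.0
        assert np.all(dense.diagonal() >= 0.5)
        assert np.linalg.eigvalsh(dense).min() > -1e-12


class TestXLinked:
    def test_father_son_share_no_x(self, fx):
        k = kinship_x(fx["nuclear"])  # S1, S3 male; S2 female
        assert k["F", "S1"] == 0.0

    def test_father_daughter(self, fx):
        k = kinship_x(fx["trio"])  # C female
        assert k["F", "C"] == 0.5

    def test_male_self_kinship_is_one(self, fx):
        k = kinship_x(fx["trio"])
        assert k["F", "F"] == 1.0

    def test_mother_son(self, fx):
        k = kinship_x(fx["nuclear"])
        assert k["M", "S1"] == 0.5

    def test_sister_sister(self):
        # K_X = 1/2*(K_X(F,sis) + K_X(M,sis)) = 1/2*(1/2 + 1/4) = 0.375:
        # sisters always share the paternal X
        ped = Pedigree([
            IndividualRecord(id="F", sex=Sex.MALE),
            IndividualRecord(id="M", sex=Sex.FEMALE),
            IndividualRecord(id="A", dadid="F", momid="M", sex=Sex.FEMALE),
            IndividualRecord(id="B", dadid="F", momid="M", sex=Sex.FEMALE),
        ])
        assert kinship_x(ped)["A", "B"] == 0.375

    def test_unknown_sex_rejected(self):
        ped = Pedigree([IndividualRecord(id="U", sex=Sex.UNKNOWN)])
        with pytest.raises(ValueError, match="unknown sex"):
            kinship_x(ped)


class TestMZTwins:
    def test_mz_pair_kinship_equals_self_kinship(self, fx):
        k = kinship_autosomal(fx["twins"])
        assert k["T1", "T2"] == k["T1", "T1"] == 0.5

    def test_dz_pair_is_ordinary_sibs(self, fx):
        k = kinship_autosomal(fx["twins"])
        assert k["D1", "D2"] == 0.25

    def test_child_of_one_twin_relates_equally_to_both(self):
        recs = [
            IndividualRecord(id="F", sex=Sex.MALE),
            IndividualRecord(id="M", sex=Sex.FEMALE),
            IndividualRecord(id="T1", dadid="F", momid="M", sex=Sex.MALE),
            IndividualRecord(id="T2", dadid="F", momid="M", sex=Sex.MALE),
            IndividualRecord(id="W", sex=Sex.FEMALE),
            IndividualRecord(id="K", dadid="T1", momid="W", sex=Sex.FEMALE),
        ]
        ped = Pedigree(recs, [Relationship("T1", "T2", RelCode.MZ_TWIN)])
        k = kinship_autosomal(ped)
        assert k["K", "T2"] == k["K", "T1"] == 0.25

    def test_no_twins_leaves_matrix_unchanged(self, fx):
        ped = fx["nuclear"]
        k_plain = kinship(ped, mz_adjust=False)
        k_adj = apply_mz_twins(k_plain, ped)
        assert np.array_equal(k_plain.dense(), k_adj.dense())

    def test_apply_mz_matches_collapsed_recursion(self, fx):
        ped = fx["twins"]
        k_plain = kinship(ped, mz_adjust=False)
        k_applied = apply_mz_twins(k_plain, ped)
        k_direct = kinship(ped, mz_adjust=True)
        assert k_applied.ids == k_plain.ids
        for a in ped.keys:
            for b in ped.keys:
                assert k_applied[a, b] == k_direct[a, b]

    def test_x_mode_mz_collapse(self, fx):
        k = kinship_x(fx["twins"])  # T1, T2 male MZ pair
        assert k["T1", "T2"] == 1.0


class TestBlockDiagonal:
    def test_two_trios_give_two_blocks(self, fx):
        k = kinship_autosomal(fx["two_families"])
        assert k.shape == (6, 6)
        dense = k.dense()
        assert np.all(dense[:3, 3:] == 0.0)
        assert np.all(dense[:3, :3].diagonal() == 0.5)

    def test_cross_family_entry_is_zero(self, fx):
        k = kinship_autosomal(fx["two_families"])
        assert k[("1", "C"), ("2", "C")] == 0.0

    def test_assemble_single_family_is_identity(self, fx):
        k = kinship_autosomal(fx["trio"])
        out = assemble_block_diagonal([k])
        assert out.ids == k.ids
        assert np.array_equal(out.dense(), k.dense())

    def test_assemble_two_families(self, fx):
        k1 = kinship_autosomal(fx["trio"])
        ped2 = Pedigree([
            IndividualRecord(id="X", famid="9", sex=Sex.MALE),
            IndividualRecord(id="Y", famid="9", sex=Sex.FEMALE),
        ])
        k2 = kinship_autosomal(ped2)
        out = assemble_block_diagonal([k1, k2])
        assert out.ids == k1.ids + k2.ids
        assert out[("1", "F"), ("9", "X")] == 0.0

    def test_duplicate_keys_rejected(self, fx):
        k = kinship_autosomal(fx["trio"])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_block_diagonal([k, k])

    def test_mixed_modes_rejected(self, fx):
        ka = kinship_autosomal(fx["trio"])
        kx = kinship_x(fx["two_families"])
        with pytest.raises(ValueError, match="mixed"):
            assemble_block_diagonal([ka, kx])


class TestDistance:
    @pytest.mark.parametrize("k,d", [
        (0.25, 2.0), (0.0625, 4.0), (0.5, 1.0), (1.0, 0.0)])
    def test_closed_form(self, k, d):
        assert kinship_to_distance(k) == d

    def test_zero_kinship_is_infinite(self):
        assert kinship_to_distance(0.0) == np.inf

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            kinship_to_distance(bad)

    def test_vectorized(self):
        out = kinship_to_distance(np.array([0.25, 0.0, 0.5]))
        assert out[0] == 2.0 and np.isinf(out[1]) and out[2] == 1.0
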