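"""Layout: generation assignment, ordering hints, alignment invariants,
loop duplication and the spouse-alignment bypass."""

import pytest

from pedkit.layout import (
    LayoutError,
    align,
    assign_generations,
    auto_hints,
)
from pedkit.model import Hints, IndividualRecord, Pedigree, Sex


def entry_map(table):
    return {(e.key, e.copy_index): e for e in table.entries}


class TestGenerations:
    def test_trio(self, fx):
        gens = assign_generations(fx["trio"]).generation
        assert gens[("1", "F")] == gens[("1", "M")] == 0
        assert gens[("1", "C")] == 1

    def test_three_generation_chain(self, fx):
        gens = assign_generations(fx["sib_mating_loop"]).generation
        assert [gens[("1", i)] for i in ("F", "S1", "C")] == [0, 1, 2]

    def test_married_in_founder_pulled_down(self, fx):
        gens = assign_generations(fx["first_cousins"]).generation
        assert gens[("1", "SA")] == gens[("1", "A")] == 1

    def test_cross_generation_couple_flagged(self, fx):
        result = assign_generations(fx["cross_generation"])
        assert (("1", "O"), ("1", "K")) in result.uneven_couples
        # the child still sits one step below its lower parent
        assert result.generation[("1", "Z")] == \
            max(result.generation[("1", "O")],
                result.generation[("1", "K")]) + 1

    def test_child_always_below_parents(self, fx):
        for name, ped in fx.items():
            gens = assign_generations(ped).generation
            for rec in ped.records:
                for p in ped.parents_of(rec.key):
                    assert gens[rec.key] >= gens[p] + 1, name


class TestAutoHints:
    def test_nuclear_family_keeps_input_order(self, fx):
        hints = auto_hints(fx["nuclear"])
        ranks = [hints.sibling_order[("1", s)] for s in ("S1", "S2", "S3")]
        assert ranks == [1, 2, 3]

    def test_sib_mating_pair_made_adjacent(self, fx):
        hints = auto_hints(fx["sib_mating_loop"])
        r1 = hints.sibling_order[("1", "S1")]
        r2 = hints.sibling_order[("1", "S2")]
        assert abs(r1 - r2) == 1

    def test_user_hints_pass_through(self, fx):
        ped = fx["nuclear"]
        custom = Hints(sibling_order={("1", "S3"): 1})
        ped2 = Pedigree(ped.records, hints=custom)
        assert auto_hints(ped2) is custom


class TestAlign:
    @pytest.mark.parametrize("name", ["trio", "nuclear", "first_cousins",
                                      "sib_mating_loop", "twins",
                                      "two_families"])
    def test_invariants(self, fx, name):
        table = align(fx[name])
        ped = fx[name]
        # every member drawn at least once
        drawn = {e.key for e in table.entries}
        assert drawn == set(ped.keys)
        # rows strictly increasing with gap >= 1
        for gen, idxs in table.rows.items():
            xs = [table.entries[i].x for i in idxs]
            assert all(b - a >= 1.0 - 1e-9 for a, b in zip(xs, xs[1:]))
        # each drawn child connector spans exactly one generation downward
        for union in table.unions:
            parent_gen = max(table.entries[union.dad_entry].generation,
                             table.entries[union.mom_entry].generation)
            for c in union.children_entries:
                assert table.entries[c].generation == parent_gen + 1

    def test_trio_child_centered(self, fx):
        table = align(fx["trio"])
        e = entry_map(table)
        parents_mid = 0.5 * (e[(("1", "F"), 0)].x + e[(("1", "M"), 0)].x)
        assert e[(("1", "C"), 0)].x == pytest.approx(parents_mid)

    def test_spouses_adjacent_same_generation(self, fx):
        table = align(fx["first_cousins"])
        for union in table.unions:
            if not union.same_generation:
                continue
            d, m = table.entries[union.dad_entry], table.entries[union.mom_entry]
            row = table.rows[d.generation]
            assert abs(row.index(union.dad_entry)
                       - row.index(union.mom_entry)) == 1

    def test_sib_mating_drawn_without_duplication(self, fx):
        table = align(fx["sib_mating_loop"])
        assert all(e.dup_group is None for e in table.entries)
        e = entry_map(table)
        assert abs(e[(("1", "S1"), 0)].x - e[(("1", "S2"), 0)].x) == \
            pytest.approx(1.0)

    def test_cousin_mating_duplicates_one_individual(self, fx):
        base = fx["first_cousins"]
        ped = Pedigree(list(base.records) + [
            IndividualRecord(id="E", dadid="D", momid="C", sex=Sex.MALE)])
        table = align(ped)
        dups = [e for e in table.entries if e.dup_group is not None]
        assert len(dups) == 2
        assert len({e.dup_group for e in dups}) == 1
        assert len({e.key for e in dups}) == 1
        copies = sorted(e.copy_index for e in dups)
        assert copies == [0, 1]

    def test_cross_generation_requires_bypass(self, fx):
        with pytest.raises(LayoutError, match="bypass"):
            align(fx["cross_generation"])
        table = align(fx["cross_generation"], bypass_spouse_alignment=True)
        # valid table, no duplication needed, uneven union recorded
        assert all(e.dup_group is None for e in table.entries)
        uneven = [u for u in table.unions if not u.same_generation]
        assert len(uneven) == 1

    def test_deterministic(self, fx):
        for name in ("first_cousins", "twins", "cross_generation"):
            kwargs = {"bypass_spouse_alignment": name == "cross_generation"}
            t1 = align(fx[name], **kwargs)
            t2 = align(fx[name], **kwargs)
            assert [(e.key, e.copy_index, e.generation, e.x, e.dup_group)
                    for e in t1.entries] == \
                   [(e.key, e.copy_index, e.generation, e.x, e.dup_group)
                    for e in t2.entries]

    def test_two_families_do_not_overlap(self, fx):
        table = align(fx["two_families"])
        fam1 = [e.x for e in table.entries if e.key[0] == "1"]
        fam2 = [e.x for e in table.entries if e.key[0] == "2"]
        assert max(fam1) < min(fam2)

    def test_to_frame_export(self, fx):
        frame = align(fx["trio"]).to_frame()
        assert list(frame.columns) == ["famid", "id", "copy", "generation",
                                       "x", "spouse", "dup_group"]
        assert len(frame) == 3
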