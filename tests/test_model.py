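"""Pedigree model: normalization repairs, validation rules, family
assignment and subsetting."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedkit.model import (
    Hints,
    IndividualRecord,
    Pedigree,
    PedigreeError,
    RelCode,
    Relationship,
    Sex,
    make_famid,
    normalize,
    subset,
    validate,
)


def raw(rows, columns=("famid", "id", "dadid", "momid", "sex")):
    return pd.DataFrame(rows, columns=list(columns), dtype=str)


class TestNormalize:
    def test_missing_codes_make_founders(self):
        records, report = normalize(raw([("1", "A", "0", "0", "1"),
                                         ("1", "B", "", "NA", "2")]))
        assert report.ok and not report.corrections
        assert all(r.is_founder for r in records)
        assert records[0].sex is Sex.MALE and records[1].sex is Sex.FEMALE

    @pytest.mark.parametrize("token,expected", [
        ("m", Sex.MALE), ("MALE", Sex.MALE), ("1", Sex.MALE),
        ("F", Sex.FEMALE), ("female", Sex.FEMALE), ("2", Sex.FEMALE),
        ("0", Sex.UNKNOWN), ("herm", Sex.UNKNOWN), ("", Sex.UNKNOWN),
    ])
    def test_sex_coercion_table(self, token, expected):
        records, _ = normalize(raw([("1", "A", "0", "0", token)]))
        assert records[0].sex is expected

    def test_mis_sexed_parent_corrected_not_errored(self):
        records, report = normalize(raw([
            ("1", "X", "0", "0", "2"),          # declared female...
            ("1", "M", "0", "0", "2"),
            ("1", "Y", "X", "M", "1"),          # ...but used as a father
        ]))
        assert report.ok
        assert {r.id: r.sex for r in records}["X"] is Sex.MALE
        fixes = [c for c in report.corrections if c.action == "mis-sexed parent"]
        assert len(fixes) == 1 and fixes[0].ids == ("1", "X")
        assert (fixes[0].before, fixes[0].after) == ("female", "male")

    def test_unknown_sex_parent_inferred_silently(self):
        records, report = normalize(raw([
            ("1", "X", "0", "0", "0"),
            ("1", "M", "0", "0", "2"),
            ("1", "Y", "X", "M", "1"),
        ]))
        assert {r.id: r.sex for r in records}["X"] is Sex.MALE
        assert not any(c.action == "mis-sexed parent"
                       for c in report.corrections)

    def test_single_known_parent_gets_placeholder(self):
        records, report = normalize(raw([
            ("1", "P", "0", "0", "1"),
            ("1", "Z", "P", "0", "2"),
        ]))
        assert report.ok
        child = {r.id: r for r in records}["Z"]
        assert child.momid == "Z_mother"
        mother = {r.id: r for r in records}["Z_mother"]
        assert mother.sex is Sex.FEMALE and mother.is_founder
        # every child now has zero or two parents: re-validation is clean
        assert validate(records).ok

    def test_placeholder_id_collision_gets_suffix(self):
        records, report = normalize(raw([
            ("1", "P", "0", "0", "1"),
            ("1", "Z_mother", "0", "0", "2"),
            ("1", "Z", "P", "0", "2"),
        ]))
        child = {r.id: r for r in records}["Z"]
        assert child.momid == "Z_mother_2"

    def test_referenced_absent_parent_created_as_founder(self):
        records, report = normalize(raw([("1", "C", "A", "B", "1")]))
        ids = {r.id for r in records}
        assert ids == {"C", "A", "B"}
        by_id = {r.id: r for r in records}
        assert by_id["A"].sex is Sex.MALE and by_id["B"].sex is Sex.FEMALE

    def test_id_in_both_parent_columns_is_an_error(self):
        _, report = normalize(raw([
            ("1", "X", "0", "0", "0"),
            ("1", "M", "0", "0", "2"),
            ("1", "F", "0", "0", "1"),
            ("1", "Y", "X", "M", "1"),
            ("1", "W", "F", "X", "2"),
        ]))
        assert any(e.rule == "unresolvable-sex" for e in report.errors)

    def test_duplicate_id_within_family_is_an_error(self):
        _, report = normalize(raw([("1", "A", "0", "0", "1"),
                                   ("1", "A", "0", "0", "2")]))
        assert any(e.rule == "duplicate-id" for e in report.errors)

    def test_same_id_in_different_families_is_fine(self):
        _, report = normalize(raw([("1", "A", "0", "0", "1"),
                                   ("2", "A", "0", "0", "2")]))
        assert report.ok

    def test_affection_parsing(self):
        df = raw([("1", "A", "0", "0", "1", "1.5", "-9"),
                  ("1", "B", "0", "0", "2", "0", "1")],
                 columns=("famid", "id", "dadid", "momid", "sex", "p1", "p2"))
        records, _ = normalize(df, affection_columns=["p1", "p2"])
        assert records[0].affections == (1.5, None)
        assert records[1].affections == (0.0, 1.0)

    def test_idempotent(self):
        df = raw([
            ("1", "X", "0", "0", "2"),
            ("1", "Z", "X", "0", "2"),
        ])
        records, report1 = normalize(df)
        assert report1.corrections
        # serialize the normalized records back into a raw table
        back = raw([(r.famid, r.id, r.dadid or "0", r.momid or "0",
                     r.sex.value) for r in records])
        records2, report2 = normalize(back)
        assert not report2.corrections
        assert [(r.famid, r.id, r.dadid, r.momid, r.sex)
                for r in records2] == \
               [(r.famid, r.id, r.dadid, r.momid, r.sex) for r in records]


class TestValidate:
    def test_clean_fixtures_are_silent(self, fx):
        for name, ped in fx.items():
            report = validate(ped.records, ped.relationships)
            assert report.ok, name

    def test_self_ancestor_loop_detected(self):
        records = [
            IndividualRecord(id="A", dadid="B", momid="MA", sex=Sex.MALE),
            IndividualRecord(id="B", dadid="A", momid="MB", sex=Sex.MALE),
            IndividualRecord(id="MA", sex=Sex.FEMALE),
            IndividualRecord(id="MB", sex=Sex.FEMALE),
        ]
        report = validate(records)
        loop = [e for e in report.errors if e.rule == "self-ancestor"]
        assert loop and {("1", "A"), ("1", "B")} <= set(loop[0].ids)

    def test_mz_twins_must_share_sex(self):
        records = [
            IndividualRecord(id="F", sex=Sex.MALE),
            IndividualRecord(id="M", sex=Sex.FEMALE),
            IndividualRecord(id="T1", dadid="F", momid="M", sex=Sex.MALE),
            IndividualRecord(id="T2", dadid="F", momid="M", sex=Sex.FEMALE),
        ]
        rels = [Relationship("T1", "T2", RelCode.MZ_TWIN)]
        report = validate(records, rels)
        assert any(e.rule == "mz-sex" for e in report.errors)
        # the same pair as DZ twins is fine
        assert validate(records,
                        [Relationship("T1", "T2", RelCode.DZ_TWIN)]).ok

    def test_relationship_ids_must_exist(self):
        records = [IndividualRecord(id="A", sex=Sex.MALE),
                   IndividualRecord(id="B", sex=Sex.FEMALE)]
        rels = [Relationship("A", "GHOST", RelCode.SPOUSE_NO_CHILD)]
        report = validate(records, rels)
        assert any(e.rule == "rel-id-missing" for e in report.errors)

    def test_twins_must_share_parents(self):
        records = [
            IndividualRecord(id="F", sex=Sex.MALE),
            IndividualRecord(id="M", sex=Sex.FEMALE),
            IndividualRecord(id="M2", sex=Sex.FEMALE),
            IndividualRecord(id="T1", dadid="F", momid="M", sex=Sex.MALE),
            IndividualRecord(id="T2", dadid="F", momid="M2", sex=Sex.MALE),
        ]
        report = validate(records, [Relationship("T1", "T2", RelCode.MZ_TWIN)])
        assert any(e.rule == "twin-parents" for e in report.errors)

    def test_parent_sex_rule(self):
        records = [
            IndividualRecord(id="F", sex=Sex.FEMALE),
            IndividualRecord(id="M", sex=Sex.FEMALE),
            IndividualRecord(id="C", dadid="F", momid="M", sex=Sex.MALE),
        ]
        assert any(e.rule == "parent-sex" for e in validate(records).errors)

    def test_constructor_raises_on_errors(self):
        with pytest.raises(PedigreeError, match="self-ancestor"):
            Pedigree([
                IndividualRecord(id="A", dadid="A", momid="M", sex=Sex.MALE),
                IndividualRecord(id="M", sex=Sex.FEMALE),
            ])


class TestMakeFamid:
    def trio(self, suffix):
        return [
            IndividualRecord(id=f"F{suffix}", sex=Sex.MALE),
            IndividualRecord(id=f"M{suffix}", sex=Sex.FEMALE),
            IndividualRecord(id=f"C{suffix}", dadid=f"F{suffix}",
                             momid=f"M{suffix}", sex=Sex.MALE),
        ]

    def test_disjoint_trios_get_distinct_famids(self):
        records, _ = make_famid(self.trio("a") + self.trio("b"))
        fams = {r.id: r.famid for r in records}
        assert fams["Fa"] == fams["Ca"] != fams["Fb"] == fams["Cb"]

    def test_singleton_gets_own_famid(self):
        records, _ = make_famid(self.trio("a")
                                + [IndividualRecord(id="X", sex=Sex.MALE)])
        assert len({r.famid for r in records}) == 2

    def test_spouse_relationship_joins_families(self):
        rels = [Relationship("Fa", "Mb", RelCode.SPOUSE_NO_CHILD)]
        records, out_rels = make_famid(self.trio("a") + self.trio("b"), rels)
        assert len({r.famid for r in records}) == 1
        assert out_rels[0].famid == records[0].famid

    def test_partition_is_connected_and_disconnected_across(self):
        records, _ = make_famid(self.trio("a") + self.trio("b"))
        ped = Pedigree(records)
        graph = ped.undirected_graph()
        import networkx as nx
        for famid in ped.famids:
            nodes = [r.key for r in ped.family(famid)]
            assert nx.is_connected(graph.subgraph(nodes))
        # no edge crosses families
        assert all(a[0] == b[0] for a, b in graph.edges)


class TestSubset:
    def test_keep_all_is_identity(self, fx):
        ped = fx["nuclear"]
        out = subset(ped, ped.keys)
        assert out.records == ped.records

    def test_dropping_one_parent_clears_both_links(self, fx):
        ped = fx["trio"]
        out = subset(ped, [("1", "M"), ("1", "C")])
        child = out[("1", "C")]
        assert child.dadid is None and child.momid is None

    def test_dropping_a_twin_removes_its_relationships(self, fx):
        ped = fx["twins"]
        keep = [k for k in ped.keys if k != ("1", "T2")]
        out = subset(ped, keep)
        assert all("T2" not in (r.id1, r.id2) for r in out.relationships)
        assert len(out.relationships) == 1  # the DZ pair survives

    def test_result_always_validates(self, fx):
        ped = fx["first_cousins"]
        out = subset(ped, [("1", "C"), ("1", "D"), ("1", "A")])
        assert validate(out.records, out.relationships).ok

    def test_hints_filtered(self, fx):
        ped = fx["nuclear"]
        ped2 = Pedigree(ped.records, hints=Hints(
            sibling_order={("1", "S1"): 1, ("1", "S2"): 2}))
        out = subset(ped2, [("1", "F"), ("1", "M"), ("1", "S1")])
        assert out.hints.sibling_order == {("1", "S1"): 1}


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(
    st.tuples(st.sampled_from("ABCDEFGH"), st.sampled_from(["0", "A", "B"]),
              st.sampled_from(["0", "C", "D"]),
              st.sampled_from(["0", "1", "2"])),
    min_size=1, max_size=8,
    unique_by=lambda r: r[0]))
def test_normalize_output_always_revalidates_or_reports(rows):
    """Whatever the raw table, normalize either reports an error or yields
    records on which every structural rule holds (self-parent rows aside)."""
    df = pd.DataFrame([("1", i, d, m, s) for i, d, m, s in rows],
                      columns=["famid", "id", "dadid", "momid", "sex"],
                      dtype=str)
    records, report = normalize(df)
    if report.ok:
        after = validate(records)
        # normalization cannot repair self-parenting or ancestor loops;
        # everything else must now hold
        residual = {e.rule for e in after.errors}
        assert residual <= {"self-parent", "self-ancestor"}
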