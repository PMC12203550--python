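"""Validated pedigree data model.

A pedigree is held as four coupled pieces of information, mirroring the
conventional split used by pedigree packages:

* individual records (identity, parent links, sex, affections, vital
  status, proband/availability flags),
* special pairwise relationships that plain parent links cannot express
  (monozygotic/dizygotic/unknown-zygosity twins, childless spouses),
* fill scales mapping affection values to colours (see :mod:`pedkit.scales`),
* layout hints (horizontal ordering of siblings and spouses).

Construction is strict: a :class:`Pedigree` can only be built from records
that pass every validation rule.  Raw tabular input goes through
:func:`normalize` first, which coerces sex codes, repairs mis-sexed parents,
and completes half-specified parentage with placeholder founders, reporting
every correction it makes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Sex",
    "Status",
    "RelCode",
    "IndividualRecord",
    "Relationship",
    "Hints",
    "ValidationIssue",
    "Correction",
    "ValidationReport",
    "PedigreeError",
    "Pedigree",
    "normalize",
    "validate",
    "make_famid",
    "subset",
    "DEFAULT_MISSING_CODES",
    "DEFAULT_AFFECTION_MISSING_CODES",
]

DEFAULT_MISSING_CODES = frozenset({"0", "", "NA"})
DEFAULT_AFFECTION_MISSING_CODES = frozenset({"", "NA", "-9"})

#: canonical column names understood by :func:`normalize`
CANONICAL_COLUMNS = ("famid", "id", "dadid", "momid", "sex",
                     "status", "avail", "proband")


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Status(Enum):
    ALIVE = "alive"
    DEAD = "dead"
    UNKNOWN = "unknown"


class RelCode(Enum):
    MZ_TWIN = "MZ_twin"
    DZ_TWIN = "DZ_twin"
    UZ_TWIN = "UZ_twin"
    SPOUSE_NO_CHILD = "spouse_no_child"


_SEX_CODES = {
    "m": Sex.MALE, "male": Sex.MALE, "1": Sex.MALE,
    "f": Sex.FEMALE, "female": Sex.FEMALE, "2": Sex.FEMALE,
}

_TWIN_CODES = (RelCode.MZ_TWIN, RelCode.DZ_TWIN, RelCode.UZ_TWIN)


def coerce_sex(token: str) -> Sex:
    """Map a raw sex token to :class:`Sex` (case-insensitive, never errors)."""
    return _SEX_CODES.get(str(token).strip().lower(), Sex.UNKNOWN)


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree member.

    ``dadid``/``momid`` are ``None`` for founders; after :func:`normalize`
    they are always both present or both ``None``.  ``affections`` holds one
    value per affection column: ``0.0``/``1.0`` for binary traits, any float
    for quantitative ones, ``None`` for missing.
    """

    id: str
    dadid: Optional[str] = None
    momid: Optional[str] = None
    famid: str = "1"
    sex: Sex = Sex.UNKNOWN
    affections: tuple = ()
    status: Status = Status.UNKNOWN
    proband: bool = False
    avail: bool = False

    @property
    def key(self) -> tuple:
        return (self.famid, self.id)

    @property
    def is_founder(self) -> bool:
        return self.dadid is None and self.momid is None


@dataclass(frozen=True)
class Relationship:
    """A special pairwise relation: twins or a childless spouse pair."""

    id1: str
    id2: str
    code: RelCode
    famid: str = "1"

    @property
    def pair(self) -> frozenset:
        return frozenset(((self.famid, self.id1), (self.famid, self.id2)))


@dataclass
class Hints:
    """Horizontal ordering hints for the layout stage.

    ``sibling_order`` maps ``(famid, id)`` to a positive rank within the
    individual's sibship; ``spouse_side`` lists
    ``((famid, id), (famid, spouse_id), side)`` with side "left"/"right".
    """

    sibling_order: dict = field(default_factory=dict)
    spouse_side: list = field(default_factory=list)


@dataclass(frozen=True)
class ValidationIssue:
    rule: str
    ids: tuple
    message: str


@dataclass(frozen=True)
class Correction:
    action: str
    ids: tuple
    before: str
    after: str


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    corrections: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def extend(self, other: "ValidationReport") -> None:
        self.errors.extend(other.errors)
        self.corrections.extend(other.corrections)


class PedigreeError(ValueError):
    """Raised when a pedigree fails validation at construction time."""

    def __init__(self, report: ValidationReport):
        self.report = report
        lines = [f"[{e.rule}] {','.join(map(str, e.ids))}: {e.message}"
                 for e in report.errors]
        super().__init__("pedigree validation failed:\n" + "\n".join(lines))


# ---------------------------------------------------------------------------
# normalization

def _clean(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = str(value).strip()
    if s.lower() == "nan":
        return ""
    return s


def _parse_bool(token: str) -> bool:
    return token.strip().lower() in {"1", "true", "t", "yes", "y"}


def _parse_status(token: str) -> Status:
    t = token.strip().lower()
    if t in {"1", "dead", "deceased"}:
        return Status.DEAD
    if t in {"0", "alive", "living"}:
        return Status.ALIVE
    return Status.UNKNOWN


def _parse_affection(token: str, missing: frozenset) -> Optional[float]:
    if token in missing:
        return None
    try:
        return float(token)
    except ValueError:
        return None


def normalize(
    raw_records: pd.DataFrame,
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
    *,
    affection_columns: Optional[Sequence[str]] = None,
    affection_missing_codes: Iterable[str] = DEFAULT_AFFECTION_MISSING_CODES,
) -> tuple:
    """Coerce a raw string table into clean :class:`IndividualRecord` rows.

    Standardization performed (each repair is reported as a correction):

    * sex tokens coerced case-insensitively ("m"/"male"/"1", "f"/"female"/"2",
      anything else -> unknown);
    * an id used in a dad column is forced male (mom column -> female); when
      this contradicts the declared sex a "mis-sexed parent" correction is
      recorded;
    * parent ids matching ``missing_codes`` become missing;
    * a parent referenced but absent from the table is created as a founder;
    * an individual with exactly one known parent receives a placeholder
      founder of the required sex (``<child>_father``/``<child>_mother``,
      numeric suffix on collision) so every child has zero or two parents.

    Unrepairable problems (an id used both as dad and as mom, duplicate ids
    within a family) are reported as errors.

    Returns ``(records, report)``.  ``normalize`` is idempotent: a second
    pass over its own output adds no further corrections.
    """
    missing = frozenset(str(c) for c in missing_codes)
    aff_missing = frozenset(str(c) for c in affection_missing_codes)
    df = raw_records
    required = {"id", "dadid", "momid", "sex"}
    absent = sorted(required - set(df.columns))
    if absent:
        raise ValueError(f"normalize: missing required columns: {absent}")

    if affection_columns is None:
        affection_columns = list(df.attrs.get("affection_columns", ()))
    report = ValidationReport()

    rows = []
    for i in range(len(df)):
        r = df.iloc[i]
        famid = _clean(r["famid"]) if "famid" in df.columns else ""
        famid = famid if famid and famid not in missing else "1"
        iid = _clean(r["id"])
        dad = _clean(r["dadid"])
        mom = _clean(r["momid"])
        rows.append({
            "famid": famid,
            "id": iid,
            "dadid": None if dad in missing else dad,
            "momid": None if mom in missing else mom,
            "sex": coerce_sex(_clean(r["sex"])),
            "status": _parse_status(_clean(r["status"])) if "status" in df.columns else Status.UNKNOWN,
            "avail": _parse_bool(_clean(r["avail"])) if "avail" in df.columns else False,
            "proband": _parse_bool(_clean(r["proband"])) if "proband" in df.columns else False,
            "affections": tuple(
                _parse_affection(_clean(r[c]), aff_missing) for c in affection_columns
            ),
        })

    # duplicate ids within a family
    seen = {}
    for row in rows:
        key = (row["famid"], row["id"])
        if not row["id"]:
            report.errors.append(ValidationIssue(
                "empty-id", key, "individual id must be a non-empty token"))
            continue
        if key in seen:
            report.errors.append(ValidationIssue(
                "duplicate-id", key, f"id {row['id']!r} duplicated in family {row['famid']!r}"))
        seen[key] = row

    # parental roles per family
    dads_by_fam: dict = {}
    moms_by_fam: dict = {}
    for row in rows:
        if row["dadid"] is not None:
            dads_by_fam.setdefault(row["famid"], set()).add(row["dadid"])
        if row["momid"] is not None:
            moms_by_fam.setdefault(row["famid"], set()).add(row["momid"])

    n_affections = len(affection_columns)
    for row in rows:
        fam, iid = row["famid"], row["id"]
        as_dad = iid in dads_by_fam.get(fam, ())
        as_mom = iid in moms_by_fam.get(fam, ())
        if as_dad and as_mom:
            report.errors.append(ValidationIssue(
                "unresolvable-sex", (fam, iid),
                f"{iid!r} appears both as a father and as a mother"))
            continue
        if as_dad and row["sex"] is not Sex.MALE:
            if row["sex"] is Sex.FEMALE:
                report.corrections.append(Correction(
                    "mis-sexed parent", (fam, iid), "female", "male"))
            row["sex"] = Sex.MALE
        elif as_mom and row["sex"] is not Sex.FEMALE:
            if row["sex"] is Sex.MALE:
                report.corrections.append(Correction(
                    "mis-sexed parent", (fam, iid), "male", "female"))
            row["sex"] = Sex.FEMALE

    # create founder records for parents referenced but absent from the table
    existing = {(row["famid"], row["id"]) for row in rows}
    created = []
    for row in list(rows):
        fam = row["famid"]
        for col, sex in (("dadid", Sex.MALE), ("momid", Sex.FEMALE)):
            pid = row[col]
            if pid is not None and (fam, pid) not in existing:
                created.append({
                    "famid": fam, "id": pid, "dadid": None, "momid": None,
                    "sex": sex, "status": Status.UNKNOWN, "avail": False,
                    "proband": False, "affections": (None,) * n_affections,
                })
                existing.add((fam, pid))
                report.corrections.append(Correction(
                    "added missing parent record", (fam, pid), "absent", "founder"))
    rows.extend(created)

    # both-or-neither parent rule via placeholder founders
    placeholders = []
    for row in rows:
        fam = row["famid"]
        has_dad, has_mom = row["dadid"] is not None, row["momid"] is not None
        if has_dad == has_mom:
            continue
        role = "mother" if has_dad else "father"
        sex = Sex.FEMALE if has_dad else Sex.MALE
        base = f"{row['id']}_{role}"
        pid = base
        for k in itertools.count(2):
            if (fam, pid) not in existing:
                break
            pid = f"{base}_{k}"
        placeholders.append({
            "famid": fam, "id": pid, "dadid": None, "momid": None,
            "sex": sex, "status": Status.UNKNOWN, "avail": False,
            "proband": False, "affections": (None,) * n_affections,
        })
        existing.add((fam, pid))
        row["momid" if has_dad else "dadid"] = pid
        report.corrections.append(Correction(
            "added placeholder parent", (fam, row["id"]),
            f"single known {('father' if has_dad else 'mother')}",
            f"placeholder {role} {pid!r}"))
    rows.extend(placeholders)

    records = [IndividualRecord(
        id=row["id"], dadid=row["dadid"], momid=row["momid"],
        famid=row["famid"], sex=row["sex"], affections=row["affections"],
        status=row["status"], proband=row["proband"], avail=row["avail"],
    ) for row in rows]
    return records, report


# ---------------------------------------------------------------------------
# validation

def validate(records: Sequence[IndividualRecord],
             relationships: Sequence[Relationship] = ()) -> ValidationReport:
    """Check every structural invariant; violations are the report payload.

    Rules: unique ids per family; parent links resolve within the family;
    fathers male and mothers female; no self-parenting and no individual its
    own ancestor (cycle search over the directed parent->child graph); both
    parents present or both absent; relationship members exist in the family,
    twin pairs share parents, and monozygotic twins share sex.
    """
    report = ValidationReport()
    by_key: dict = {}
    for rec in records:
        if rec.key in by_key:
            report.errors.append(ValidationIssue(
                "duplicate-id", rec.key,
                f"id {rec.id!r} duplicated in family {rec.famid!r}"))
        by_key[rec.key] = rec

    for rec in records:
        if (rec.dadid is None) != (rec.momid is None):
            report.errors.append(ValidationIssue(
                "single-parent", rec.key,
                "exactly one parent specified (must be zero or two)"))
        for pid, want, role in ((rec.dadid, Sex.MALE, "father"),
                                (rec.momid, Sex.FEMALE, "mother")):
            if pid is None:
                continue
            if pid == rec.id:
                report.errors.append(ValidationIssue(
                    "self-parent", rec.key, f"{rec.id!r} is its own {role}"))
                continue
            parent = by_key.get((rec.famid, pid))
            if parent is None:
                report.errors.append(ValidationIssue(
                    "parent-missing-record", rec.key,
                    f"{role} {pid!r} has no record in family {rec.famid!r}"))
            elif parent.sex is not want:
                report.errors.append(ValidationIssue(
                    "parent-sex", (rec.famid, pid),
                    f"{role} {pid!r} of {rec.id!r} is not {want.value}"))

    # self-ancestor loops: cycles in the parent->child digraph
    graph = nx.DiGraph()
    graph.add_nodes_from(by_key)
    for rec in records:
        for pid in (rec.dadid, rec.momid):
            if pid is not None and (rec.famid, pid) in by_key:
                graph.add_edge((rec.famid, pid), rec.key)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        members = tuple(sorted({node for edge in cycle for node in edge[:2]}))
        report.errors.append(ValidationIssue(
            "self-ancestor", members,
            "individual is its own ancestor (parent-child cycle: "
            + " -> ".join(i for _, i in members) + ")"))

    seen_pairs = set()
    for rel in relationships:
        keys = ((rel.famid, rel.id1), (rel.famid, rel.id2))
        if rel.id1 == rel.id2:
            report.errors.append(ValidationIssue(
                "rel-self", keys[:1], "relationship links an individual to itself"))
            continue
        missing = [k for k in keys if k not in by_key]
        if missing:
            report.errors.append(ValidationIssue(
                "rel-id-missing", tuple(missing),
                "relationship references individual(s) absent from the pedigree"))
            continue
        if rel.pair in seen_pairs:
            report.errors.append(ValidationIssue(
                "rel-duplicate", keys, "duplicate relationship pair"))
        seen_pairs.add(rel.pair)
        a, b = by_key[keys[0]], by_key[keys[1]]
        if rel.code in _TWIN_CODES and (a.dadid, a.momid) != (b.dadid, b.momid):
            report.errors.append(ValidationIssue(
                "twin-parents", keys, "twins must share both parents"))
        if rel.code is RelCode.MZ_TWIN and a.sex is not b.sex:
            report.errors.append(ValidationIssue(
                "mz-sex", keys, "MZ twins must share the same sex"))
    return report


# ---------------------------------------------------------------------------
# family assignment

def make_famid(records: Sequence[IndividualRecord],
               relationships: Sequence[Relationship] = ()) -> tuple:
    """Assign family ids by connected component.

    Children are linked to their parents, and relationship pairs are linked,
    in an undirected graph; each component (including singletons) becomes one
    family, numbered "1", "2", ... in order of first appearance.  Existing
    famid values are ignored, so ids must be unique across the whole input.
    Returns ``(records, relationships)`` relabelled.
    """
    graph = nx.Graph()
    graph.add_nodes_from(rec.id for rec in records)
    for rec in records:
        for pid in (rec.dadid, rec.momid):
            if pid is not None:
                graph.add_edge(rec.id, pid)
    for rel in relationships:
        graph.add_edge(rel.id1, rel.id2)

    label: dict = {}
    counter = itertools.count(1)
    for rec in records:
        if rec.id in label:
            continue
        fam = str(next(counter))
        for node in nx.node_connected_component(graph, rec.id):
            label[node] = fam
    new_records = tuple(replace(rec, famid=label[rec.id]) for rec in records)
    new_rels = tuple(replace(rel, famid=label[rel.id1]) for rel in relationships)
    return new_records, new_rels


# ---------------------------------------------------------------------------
# pedigree container

class Pedigree:
    """A validated pedigree of one or more families.

    Raises :class:`PedigreeError` if any validation rule fails, so every
    constructed instance satisfies all structural invariants.
    """

    def __init__(self, records: Sequence[IndividualRecord],
                 relationships: Sequence[Relationship] = (),
                 scales=None, hints: Optional[Hints] = None):
        report = validate(records, relationships)
        if not report.ok:
            raise PedigreeError(report)
        self.records = tuple(records)
        self.relationships = tuple(relationships)
        self.scales = dict(scales) if scales else {}
        self.hints = hints if hints is not None else Hints()
        self._by_key = {rec.key: rec for rec in self.records}

    @classmethod
    def from_table(cls, raw: pd.DataFrame,
                   relationships: Sequence[Relationship] = (),
                   missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
                   assign_famid: bool = False,
                   **normalize_kwargs) -> "Pedigree":
        """Normalize a raw table and build a pedigree (errors raise)."""
        records, report = normalize(raw, missing_codes, **normalize_kwargs)
        if not report.ok:
            raise PedigreeError(report)
        if assign_famid or "famid" not in raw.columns:
            records, relationships = make_famid(records, relationships)
        return cls(records, relationships)

    # -- lookup helpers ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key) -> bool:
        return self.resolve(key) in self._by_key

    def __getitem__(self, key) -> IndividualRecord:
        return self._by_key[self.resolve(key)]

    def resolve(self, key) -> tuple:
        """Resolve a plain id or a (famid, id) pair to a (famid, id) key."""
        if isinstance(key, tuple):
            return key
        matches = [k for k in self._by_key if k[1] == key]
        if len(matches) > 1:
            raise KeyError(f"id {key!r} is ambiguous across families; "
                           f"use a (famid, id) pair")
        if not matches:
            return ("", key)
        return matches[0]

    @property
    def keys(self) -> tuple:
        return tuple(rec.key for rec in self.records)

    @property
    def famids(self) -> tuple:
        out = []
        for rec in self.records:
            if rec.famid not in out:
                out.append(rec.famid)
        return tuple(out)

    def family(self, famid: str) -> tuple:
        return tuple(rec for rec in self.records if rec.famid == famid)

    def family_relationships(self, famid: str) -> tuple:
        return tuple(rel for rel in self.relationships if rel.famid == famid)

    def parents_of(self, key) -> tuple:
        rec = self[key]
        if rec.is_founder:
            return ()
        return ((rec.famid, rec.dadid), (rec.famid, rec.momid))

    def children_of(self, key) -> tuple:
        fam, iid = self.resolve(key)
        return tuple(rec.key for rec in self.records
                     if rec.famid == fam and iid in (rec.dadid, rec.momid))

    def unions(self, famid: Optional[str] = None) -> tuple:
        """Mating unions as ((dad_key, mom_key), (child_key, ...)) tuples.

        Includes childless-spouse relationship pairs (empty child tuple),
        ordered deterministically by first appearance in the record list.
        """
        out: dict = {}
        for rec in self.records:
            if rec.is_founder:
                continue
            if famid is not None and rec.famid != famid:
                continue
            couple = ((rec.famid, rec.dadid), (rec.famid, rec.momid))
            out.setdefault(couple, []).append(rec.key)
        for rel in self.relationships:
            if rel.code is not RelCode.SPOUSE_NO_CHILD:
                continue
            if famid is not None and rel.famid != famid:
                continue
            a, b = (rel.famid, rel.id1), (rel.famid, rel.id2)
            if self._by_key[a].sex is Sex.FEMALE:
                a, b = b, a
            out.setdefault((a, b), [])
        return tuple((couple, tuple(children)) for couple, children in out.items())

    def n_affections(self) -> int:
        return max((len(rec.affections) for rec in self.records), default=0)

    def affection_values(self, index: int) -> list:
        """Values of one affection column, in record order (None = missing)."""
        return [rec.affections[index] if index < len(rec.affections) else None
                for rec in self.records]

    def affection_is_binary(self, index: int) -> bool:
        vals = {v for v in self.affection_values(index) if v is not None}
        return vals <= {0.0, 1.0}

    def undirected_graph(self, famid: Optional[str] = None) -> nx.Graph:
        """Child-parent and relationship edges as an undirected graph."""
        graph = nx.Graph()
        for rec in self.records:
            if famid is not None and rec.famid != famid:
                continue
            graph.add_node(rec.key)
            for pkey in self.parents_of(rec.key):
                graph.add_edge(rec.key, pkey)
        for rel in self.relationships:
            if famid is not None and rel.famid != famid:
                continue
            graph.add_edge((rel.famid, rel.id1), (rel.famid, rel.id2))
        return graph


def subset(pedigree: Pedigree, keep_ids: Iterable) -> Pedigree:
    """Restrict a pedigree to ``keep_ids`` (plain ids or (famid, id) pairs).

    A parent link survives only if both parents are kept — otherwise both
    links are cleared, so the result satisfies the both-or-neither rule.
    Relationships and hints mentioning a dropped individual are removed.
    """
    keep = {pedigree.resolve(k) for k in keep_ids}
    unknown = keep - set(pedigree.keys)
    if unknown:
        raise KeyError(f"subset: unknown ids {sorted(unknown)}")
    records = []
    for rec in pedigree.records:
        if rec.key not in keep:
            continue
        if not rec.is_founder:
            dad_kept = (rec.famid, rec.dadid) in keep
            mom_kept = (rec.famid, rec.momid) in keep
            if not (dad_kept and mom_kept):
                rec = replace(rec, dadid=None, momid=None)
        records.append(rec)
    rels = tuple(rel for rel in pedigree.relationships
                 if rel.pair <= keep)
    hints = Hints(
        sibling_order={k: v for k, v in pedigree.hints.sibling_order.items()
                       if k in keep},
        spouse_side=[(a, b, s) for a, b, s in pedigree.hints.spouse_side
                     if a in keep and b in keep],
    )
    return Pedigree(records, rels, scales=pedigree.scales, hints=hints)
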