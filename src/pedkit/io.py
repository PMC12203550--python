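"""Reading and writing pedigree tables.

Two on-disk representations are supported:

* the classic LINKAGE/PED pre-makeped text format — whitespace-delimited,
  no header, columns famid, id, dadid, momid, sex (1/2/0) followed by any
  number of phenotype columns;
* delimited files (CSV/TSV, or XLSX read-only) with a header row and a
  :class:`ColumnMapping` that names the source column for each canonical
  field; unmapped columns are preserved as annotations.

Readers return a raw string table (pandas DataFrame with canonical column
names) suitable for :func:`pedkit.model.normalize`; they never silently
drop rows.  Writers round-trip: reading a written file reconstructs the
same records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import Pedigree, RelCode, Relationship, Sex, Status

__all__ = [
    "ColumnMapping",
    "PedigreeParseError",
    "read_linkage",
    "write_linkage",
    "read_delimited",
    "write_delimited",
    "read_relationships",
    "write_relationships",
    "load_linkage",
]

_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
LINKAGE_COLUMNS = ("famid", "id", "dadid", "momid", "sex")


class PedigreeParseError(ValueError):
    pass


@dataclass
class ColumnMapping:
    """Names of the source columns holding each canonical field.

    ``id``, ``dadid``, ``momid`` and ``sex`` are required; ``affections``
    lists phenotype columns in display order.  ``delimiter`` applies to
    text files (ignored for XLSX); ``missing_codes`` is carried through for
    the normalization step.
    """

    id: str = "id"
    dadid: str = "dadid"
    momid: str = "momid"
    sex: str = "sex"
    famid: Optional[str] = None
    status: Optional[str] = None
    avail: Optional[str] = None
    proband: Optional[str] = None
    affections: Sequence[str] = ()
    delimiter: str = ","
    missing_codes: tuple = ("0", "", "NA")

    def required(self) -> dict:
        return {"id": self.id, "dadid": self.dadid,
                "momid": self.momid, "sex": self.sex}

    def optional(self) -> dict:
        out = {}
        for name in ("famid", "status", "avail", "proband"):
            source = getattr(self, name)
            if source is not None:
                out[name] = source
        return out


def read_linkage(path) -> pd.DataFrame:
    """Read a LINKAGE/PED file into a raw canonical table.

    Sex codes 1/2/0 become male/female/unknown tokens; phenotype columns
    become affection columns named ``pheno1``, ``pheno2``, ...  A row with
    fewer than five fields raises :class:`PedigreeParseError` naming the
    offending line.
    """
    rows = []
    n_pheno = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 5:
                raise PedigreeParseError(
                    f"{path}: line {lineno}: expected >= 5 whitespace-"
                    f"delimited fields (famid id dadid momid sex), "
                    f"got {len(fields)}")
            rows.append(fields)
            n_pheno = max(n_pheno, len(fields) - 5)
    pheno_cols = [f"pheno{i + 1}" for i in range(n_pheno)]
    columns = list(LINKAGE_COLUMNS) + pheno_cols
    padded = [row + [""] * (len(columns) - len(row)) for row in rows]
    df = pd.DataFrame(padded, columns=columns, dtype=str)
    sex_map = {"1": "male", "2": "female"}
    df["sex"] = df["sex"].map(lambda s: sex_map.get(s, "unknown"))
    df.attrs["affection_columns"] = pheno_cols
    return df


def write_linkage(pedigree: Pedigree, path) -> None:
    """Write a pedigree in LINKAGE/PED format.

    Sex is written 1/2/0, missing parents as 0, missing phenotype values
    as -9.  Placeholder parents created during normalization serialize like
    any other founder.
    """
    n_aff = pedigree.n_affections()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in pedigree.records:
            fields = [rec.famid, rec.id, rec.dadid or "0", rec.momid or "0",
                      _SEX_OUT[rec.sex]]
            for i in range(n_aff):
                v = rec.affections[i] if i < len(rec.affections) else None
                fields.append("-9" if v is None else f"{v:g}")
            fh.write(" ".join(fields) + "\n")


def load_linkage(path, rel_path=None, **normalize_kwargs) -> Pedigree:
    """Read, normalize and validate a LINKAGE file in one step.

    ``rel_path`` optionally names a relationship table (see
    :func:`read_relationships`) holding twin codes and childless spouses.
    """
    rels = read_relationships(rel_path) if rel_path is not None else ()
    return Pedigree.from_table(read_linkage(path), relationships=rels,
                               **normalize_kwargs)


#: numeric twin/spouse codes, as used by the classic R pedigree packages
_REL_CODES = {
    "1": RelCode.MZ_TWIN, "2": RelCode.DZ_TWIN,
    "3": RelCode.UZ_TWIN, "4": RelCode.SPOUSE_NO_CHILD,
}
_REL_NAMES = {code.value.lower(): code for code in RelCode}
_REL_OUT = {code: num for num, code in _REL_CODES.items()}


def read_relationships(path) -> tuple:
    """Read a relationship table: TSV/CSV with id1, id2, code [, famid].

    Codes may be numeric (1 MZ, 2 DZ, 3 UZ, 4 childless spouse) or the
    names ``MZ_twin``/``DZ_twin``/``UZ_twin``/``spouse_no_child``.
    """
    sep = "\t" if str(path).lower().endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in ("id1", "id2", "code") if c not in df.columns]
    if missing:
        raise PedigreeParseError(
            f"{path}: missing column(s): {', '.join(missing)}")
    rels = []
    for i in range(len(df)):
        row = df.iloc[i]
        token = str(row["code"]).strip()
        code = _REL_CODES.get(token) or _REL_NAMES.get(token.lower())
        if code is None:
            raise PedigreeParseError(
                f"{path}: row {i + 1}: unknown relationship code {token!r}")
        famid = str(row["famid"]) if "famid" in df.columns else "1"
        rels.append(Relationship(str(row["id1"]), str(row["id2"]),
                                 code, famid=famid or "1"))
    return tuple(rels)


def write_relationships(pedigree: Pedigree, path) -> None:
    """Write the pedigree's relationship rows as a TSV (numeric codes)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("famid\tid1\tid2\tcode\n")
        for rel in pedigree.relationships:
            fh.write(f"{rel.famid}\t{rel.id1}\t{rel.id2}\t"
                     f"{_REL_OUT[rel.code]}\n")


def _frame_from_source(path, mapping: ColumnMapping) -> pd.DataFrame:
    text = str(path)
    if text.lower().endswith((".xlsx", ".xlsm")):
        return pd.read_excel(path, dtype=str).fillna("")
    return pd.read_csv(path, sep=mapping.delimiter, dtype=str,
                       keep_default_na=False)


def read_delimited(path, mapping: ColumnMapping) -> pd.DataFrame:
    """Read a delimited (or XLSX) file through a column mapping.

    Mapped columns are renamed to their canonical names; affection columns
    keep their source names and are listed in ``attrs['affection_columns']``;
    every other column is preserved untouched as an annotation.  Mapped
    names absent from the header raise an error listing them.
    """
    df = _frame_from_source(path, mapping)
    wanted = {**mapping.required(), **mapping.optional()}
    sources = list(wanted.values()) + list(mapping.affections)
    missing = [c for c in sources if c not in df.columns]
    if missing:
        raise PedigreeParseError(
            f"{path}: missing column(s): {', '.join(missing)}")
    rename = {source: canon for canon, source in wanted.items()
              if source != canon}
    out = df.rename(columns=rename)
    out.attrs["affection_columns"] = list(mapping.affections)
    return out


_STATUS_OUT = {Status.DEAD: "1", Status.ALIVE: "0", Status.UNKNOWN: ""}


def pedigree_to_frame(pedigree: Pedigree) -> pd.DataFrame:
    """Canonical tabular view of a pedigree (strings, missing = "")."""
    n_aff = pedigree.n_affections()
    aff_cols = [f"affection{i + 1}" for i in range(n_aff)]
    rows = []
    for rec in pedigree.records:
        row = {
            "famid": rec.famid, "id": rec.id,
            "dadid": rec.dadid or "", "momid": rec.momid or "",
            "sex": rec.sex.value, "status": _STATUS_OUT[rec.status],
            "avail": "1" if rec.avail else "0",
            "proband": "1" if rec.proband else "0",
        }
        for i, col in enumerate(aff_cols):
            v = rec.affections[i] if i < len(rec.affections) else None
            row[col] = "" if v is None else f"{v:g}"
        rows.append(row)
    columns = ["famid", "id", "dadid", "momid", "sex",
               "status", "avail", "proband"] + aff_cols
    return pd.DataFrame(rows, columns=columns, dtype=str)


def write_delimited(pedigree: Pedigree, path,
                    mapping: Optional[ColumnMapping] = None) -> None:
    """Write a pedigree as a delimited text file.

    Column order is deterministic: canonical fields first, then affection
    columns.  With a mapping, canonical columns are renamed back to the
    mapped source names and the mapping's delimiter is used.
    """
    df = pedigree_to_frame(pedigree)
    delimiter = ","
    if mapping is not None:
        delimiter = mapping.delimiter
        wanted = {**mapping.required(), **mapping.optional()}
        df = df.rename(columns={canon: source
                                for canon, source in wanted.items()})
        aff_cols = [c for c in df.columns if c.startswith("affection")]
        for col, source in zip(aff_cols, mapping.affections):
            df = df.rename(columns={col: source})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep=delimiter, index=False, lineterminator="\n")
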