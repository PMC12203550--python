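"""Kinship coefficient matrices on pedigrees.

The kinship coefficient K(i, j) is the probability that an allele drawn at
random from i and one drawn from j at the same autosomal locus are identical
by descent.  It is computed by the classical recursion over a pedigree in
which parents are evaluated before children:

* founders: K(i, i) = 1/2, K(i, j) = 0 for distinct founders;
* K(i, i) = 1/2 * (1 + K(father_i, mother_i));
* for i not a descendant of j: K(i, j) = 1/2 * (K(father_i, j) + K(mother_i, j)),
  a missing parent contributing 0.

The X-linked variant accounts for male hemizygosity: a male carries a single
X, so his self-kinship is 1 and his kinship with anyone else equals his
mother's.

Monozygotic twins are genetically one individual; they are handled by
collapsing each MZ group to a single node, running the recursion on the
collapsed pedigree, and expanding the resulting rows and columns back.

A multi-family pedigree yields a sparse block-diagonal matrix: one dense
block per family, exact zeros across families.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import Pedigree, RelCode, Sex

__all__ = [
    "KinshipMatrix",
    "kinship",
    "kinship_autosomal",
    "kinship_x",
    "apply_mz_twins",
    "assemble_block_diagonal",
    "kinship_to_distance",
    "generation_order",
]


def generation_order(pedigree: Pedigree, famid: str) -> list:
    """Keys of one family ordered so parents always precede children.

    Ordering is by generation depth (longest path from a founder), ties
    broken by record order; deterministic.
    """
    records = pedigree.family(famid)
    depth: dict = {}

    def _depth(key) -> int:
        if key in depth:
            return depth[key]
        parents = pedigree.parents_of(key)
        depth[key] = 0 if not parents else 1 + max(_depth(p) for p in parents)
        return depth[key]

    keys = [rec.key for rec in records]
    for key in keys:
        _depth(key)
    index = {key: i for i, key in enumerate(keys)}
    return sorted(keys, key=lambda k: (depth[k], index[k]))


class KinshipMatrix:
    """Symmetric kinship coefficients, block-diagonal over families.

    ``ids`` is the ordered list of (famid, id) keys; ``matrix`` is a sparse
    CSR matrix whose nonzero structure is one dense block per family.
    ``mode`` is "autosome" or "X".
    """

    def __init__(self, ids: Sequence[tuple], matrix: sp.spmatrix, mode: str):
        self.ids = tuple(ids)
        self.matrix = sp.csr_matrix(matrix)
        self.mode = mode
        self._index = {key: i for i, key in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate (famid, id) keys in kinship matrix")

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.matrix[self._index[self._resolve(i)],
                                 self._index[self._resolve(j)]])

    def _resolve(self, key) -> tuple:
        if isinstance(key, tuple):
            return key
        matches = [k for k in self._index if k[1] == key]
        if len(matches) != 1:
            raise KeyError(key)
        return matches[0]

    @property
    def shape(self) -> tuple:
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def family_block(self, famid: str) -> tuple:
        """(keys, dense block) for one family."""
        idx = [i for i, key in enumerate(self.ids) if key[0] == famid]
        keys = [self.ids[i] for i in idx]
        return keys, self.matrix[np.ix_(idx, idx)].toarray()

    def to_long(self) -> pd.DataFrame:
        """Long-format table of within-family pairs (id1 <= id2 positions)."""
        coo = sp.triu(self.matrix).tocoo()
        rows = [{"famid1": self.ids[i][0], "id1": self.ids[i][1],
                 "famid2": self.ids[j][0], "id2": self.ids[j][1],
                 "kinship": v}
                for i, j, v in zip(coo.row, coo.col, coo.data)]
        return pd.DataFrame(rows, columns=["famid1", "id1", "famid2", "id2", "kinship"])


def _family_kinship(pedigree: Pedigree, famid: str, mode: str) -> tuple:
    order = generation_order(pedigree, famid)
    pos = {key: i for i, key in enumerate(order)}
    n = len(order)
    K = np.zeros((n, n))
    for key in order:
        i = pos[key]
        rec = pedigree[key]
        parents = pedigree.parents_of(key)
        fi = pos[parents[0]] if parents else None
        mi = pos[parents[1]] if parents else None
        if mode == "autosome":
            if parents:
                K[i, :i] = 0.5 * (K[fi, :i] + K[mi, :i])
                K[i, i] = 0.5 * (1.0 + K[fi, mi])
            else:
                K[i, i] = 0.5
        else:  # X-linked
            if rec.sex is Sex.UNKNOWN:
                raise ValueError(
                    f"X-linked kinship requires known sex: individual "
                    f"{key[1]!r} in family {key[0]!r} has unknown sex")
            if rec.sex is Sex.MALE:
                if mi is not None:
                    K[i, :i] = K[mi, :i]
                K[i, i] = 1.0
            else:
                if parents:
                    K[i, :i] = 0.5 * (K[fi, :i] + K[mi, :i])
                    K[i, i] = 0.5 * (1.0 + K[fi, mi])
                else:
                    K[i, i] = 0.5
        K[:i, i] = K[i, :i]
    # reorder back to record order within the family
    record_keys = [rec.key for rec in pedigree.family(famid)]
    perm = [pos[key] for key in record_keys]
    return record_keys, K[np.ix_(perm, perm)]


def _mz_groups(pedigree: Pedigree, famid: str) -> list:
    """MZ twin groups (lists of keys, record order) within one family."""
    parent: dict = {}

    def find(x):
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    members = set()
    for rel in pedigree.family_relationships(famid):
        if rel.code is RelCode.MZ_TWIN:
            a, b = (rel.famid, rel.id1), (rel.famid, rel.id2)
            members.update((a, b))
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    groups: dict = {}
    for rec in pedigree.family(famid):
        if rec.key in members:
            groups.setdefault(find(rec.key), []).append(rec.key)
    return [g for g in groups.values() if len(g) > 1]


def _collapse_family(pedigree: Pedigree, famid: str) -> tuple:
    """Collapse each MZ group of one family to its first-listed member.

    Returns (collapsed Pedigree of that family, map key -> representative).
    Twin-group members must share parents (guaranteed by validation).
    """
    rep: dict = {}
    for group in _mz_groups(pedigree, famid):
        for key in group:
            rep[key] = group[0]
    records = []
    for rec in pedigree.family(famid):
        if rec.key in rep and rep[rec.key] != rec.key:
            continue
        dad = rec.dadid
        mom = rec.momid
        if dad is not None:
            dad = rep.get((rec.famid, dad), (rec.famid, dad))[1]
            mom = rep.get((rec.famid, mom), (rec.famid, mom))[1]
        records.append(replace(rec, dadid=dad, momid=mom))
    kept = {r.key for r in records}
    rels = [rel for rel in pedigree.family_relationships(famid)
            if rel.code is not RelCode.MZ_TWIN and rel.pair <= kept]
    return Pedigree(records, rels), rep


def _family_kinship_mz(pedigree: Pedigree, famid: str, mode: str) -> tuple:
    """Per-family kinship with MZ groups treated as one genetic individual."""
    if not _mz_groups(pedigree, famid):
        return _family_kinship(pedigree, famid, mode)
    collapsed, rep = _collapse_family(pedigree, famid)
    ckeys, cK = _family_kinship(collapsed, famid, mode)
    cpos = {key: i for i, key in enumerate(ckeys)}
    record_keys = [rec.key for rec in pedigree.family(famid)]
    idx = [cpos[rep.get(key, key)] for key in record_keys]
    return record_keys, cK[np.ix_(idx, idx)]


def kinship(pedigree: Pedigree, mode: str = "autosome",
            mz_adjust: bool = True) -> KinshipMatrix:
    """Kinship matrix of a (possibly multi-family) pedigree.

    Parameters
    ----------
    mode : "autosome" or "X".
    mz_adjust : treat monozygotic twin groups as a single genetic
        individual (on by default; dizygotic and unknown-zygosity twins are
        ordinary siblings and never adjusted).
    """
    if mode not in ("autosome", "X"):
        raise ValueError(f"unknown kinship mode {mode!r}")
    blocks = []
    ids: list = []
    for famid in pedigree.famids:
        compute = _family_kinship_mz if mz_adjust else _family_kinship
        keys, block = compute(pedigree, famid, mode)
        ids.extend(keys)
        blocks.append(sp.csr_matrix(block))
    return assemble_block_diagonal_raw(ids, blocks, mode)


def kinship_autosomal(pedigree: Pedigree, mz_adjust: bool = True) -> KinshipMatrix:
    """Autosomal kinship matrix (see :func:`kinship`)."""
    return kinship(pedigree, "autosome", mz_adjust=mz_adjust)


def kinship_x(pedigree: Pedigree, mz_adjust: bool = True) -> KinshipMatrix:
    """X-linked kinship matrix; every individual must have known sex."""
    return kinship(pedigree, "X", mz_adjust=mz_adjust)


def apply_mz_twins(matrix: KinshipMatrix, pedigree: Pedigree) -> KinshipMatrix:
    """Adjust a kinship matrix for the pedigree's monozygotic twin pairs.

    Each MZ group becomes one genetic individual: within a group all pairwise
    and self entries are equal, and every member has identical kinship with
    any third party.  The values are those of the recursion run on the
    pedigree with each group collapsed to a single node, expanded back to
    one row/column per member (a simple row copy of the uncollapsed matrix
    would be wrong whenever a third party descends from two different group
    members).  The matrix argument fixes the mode and the id order.
    """
    adjusted = kinship(pedigree, matrix.mode, mz_adjust=True)
    perm = [adjusted._index[key] for key in matrix.ids]
    return KinshipMatrix(matrix.ids,
                         adjusted.matrix[np.ix_(perm, perm)], matrix.mode)


def assemble_block_diagonal_raw(ids: Sequence[tuple],
                                blocks: Sequence[sp.spmatrix],
                                mode: str) -> KinshipMatrix:
    matrix = sp.block_diag(blocks, format="csr") if blocks else sp.csr_matrix((0, 0))
    return KinshipMatrix(ids, matrix, mode)


def assemble_block_diagonal(per_family: Sequence[KinshipMatrix]) -> KinshipMatrix:
    """Stack per-family kinship matrices into one block-diagonal matrix.

    Id order is family order then within-family order; cross-family entries
    are exact (structural) zeros.  Duplicate (famid, id) keys raise.
    """
    if not per_family:
        raise ValueError("no matrices to assemble")
    modes = {m.mode for m in per_family}
    if len(modes) != 1:
        raise ValueError(f"mixed kinship modes: {sorted(modes)}")
    ids: list = []
    for m in per_family:
        ids.extend(m.ids)
    return assemble_block_diagonal_raw(
        ids, [m.matrix for m in per_family], per_family[0].mode)


def kinship_to_distance(k):
    """Kinship-based distance D = log2(1/K); D = +inf for K = 0.

    Expresses relatedness as intuitive meiotic steps: full siblings
    (K = 0.25) are at distance 2, first cousins (K = 0.0625) at distance 4.
    Accepts scalars or arrays; values outside [0, 1] raise.
    """
    arr = np.asarray(k, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("kinship coefficients must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        dist = -np.log2(arr)
    dist = np.where(arr == 0, np.inf, dist)
    if np.isscalar(k) or np.ndim(k) == 0:
        return float(dist)
    return dist
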