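"""Pedigree layout: generations and horizontal positions.

This is step 1 of the two-step drawing pipeline: a :class:`Pedigree` is
converted into a :class:`LayoutTable` holding one entry per drawn symbol
(an individual may be drawn more than once when a consanguinity loop is
broken by duplication) plus the mating-union placements the renderer needs
to draw connectors.

The algorithm is layered and hint-driven:

1. generations by longest path from the founders, with married-in founders
   pulled down to their mate's level; a child always sits exactly one level
   below its lower parent's level (max of the two parents + 1);
2. a deterministic depth-first traversal over mating unions produces the
   left-to-right order of every level, placing spouses adjacent, hanging
   sibships under their parent couple, and duplicating an individual when a
   loop cannot be drawn otherwise (both copies share a ``dup_group``);
3. horizontal coordinates by iterative smoothing: children are centred
   under their parent couple and couples over their children, subject to the
   fixed order and a minimum gap of one symbol width, solved each pass by
   pool-adjacent-violators.

Matings between individuals of different generations cannot satisfy the
"spouses adjacent on the same level" rule; with
``bypass_spouse_alignment=True`` the mating line is routed between levels
instead, otherwise :func:`align` refuses the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import Hints, Pedigree

__all__ = [
    "LayoutError",
    "LayoutEntry",
    "UnionPlacement",
    "GenerationAssignment",
    "LayoutTable",
    "assign_generations",
    "auto_hints",
    "align",
]


class LayoutError(ValueError):
    pass


@dataclass
class LayoutEntry:
    key: tuple                      # (famid, id)
    copy_index: int                 # 0 for the primary copy
    generation: int
    x: float = 0.0
    spouse_link: Optional[tuple] = None
    dup_group: Optional[str] = None


@dataclass
class UnionPlacement:
    dad_key: tuple
    mom_key: tuple
    dad_entry: int                  # indices into LayoutTable.entries
    mom_entry: int
    children_entries: list = field(default_factory=list)
    same_generation: bool = True


@dataclass
class GenerationAssignment:
    generation: dict                # key -> level (0 = top)
    uneven_couples: list            # [(dad_key, mom_key), ...] flagged


@dataclass
class LayoutTable:
    entries: list
    unions: list
    rows: dict                      # generation -> [entry index, ...] in order

    def entries_for(self, key) -> list:
        return [e for e in self.entries if e.key == key]

    def to_frame(self) -> pd.DataFrame:
        """Tabular export for inspection and hand-tuning."""
        return pd.DataFrame([{
            "famid": e.key[0], "id": e.key[1], "copy": e.copy_index,
            "generation": e.generation, "x": e.x,
            "spouse": e.spouse_link[1] if e.spouse_link else "",
            "dup_group": e.dup_group or "",
        } for e in self.entries])


# ---------------------------------------------------------------------------
# generations

def assign_generations(pedigree: Pedigree) -> GenerationAssignment:
    """Assign a drawing level to every individual.

    Founders start minimal (longest-path layering), married-in founders are
    pulled down to the lowest of their mates' levels, and every child sits
    at max(parent levels) + 1.  Couples left on different levels (both
    members have parents, so neither can move) are flagged as uneven.
    """
    from .kinship import generation_order

    gen: dict = {}
    for famid in pedigree.famids:
        order = generation_order(pedigree, famid)
        for key in order:
            parents = pedigree.parents_of(key)
            gen[key] = 0 if not parents else 1 + max(gen[p] for p in parents)
        couples = [c for c, _ in pedigree.unions(famid)]
        for _ in range(len(order) + 2):
            changed = False
            for key in order:
                if pedigree.parents_of(key):
                    continue
                partner_gens = [gen[mom] for dad, mom in couples if dad == key]
                partner_gens += [gen[dad] for dad, mom in couples if mom == key]
                if partner_gens and min(partner_gens) > gen[key]:
                    gen[key] = min(partner_gens)
                    changed = True
            for key in order:
                parents = pedigree.parents_of(key)
                if parents:
                    want = 1 + max(gen[p] for p in parents)
                    if gen[key] != want:
                        gen[key] = want
                        changed = True
            if not changed:
                break
    uneven = [couple for couple, _ in pedigree.unions()
              if gen[couple[0]] != gen[couple[1]]]
    return GenerationAssignment(gen, uneven)


# ---------------------------------------------------------------------------
# hints

def auto_hints(pedigree: Pedigree) -> Hints:
    """Derive sibling-order hints; user-provided hints pass through.

    Siblings keep their record order except that a child who mates another
    child of the same sibship is moved next to its mate, keeping the
    consanguineous connecting path short.  Deterministic for a given input.
    """
    if pedigree.hints.sibling_order or pedigree.hints.spouse_side:
        return pedigree.hints
    sibling_order: dict = {}
    for famid in pedigree.famids:
        unions = pedigree.unions(famid)
        parent_couple = {}
        for couple, children in unions:
            for c in children:
                parent_couple[c] = couple
        for couple, children in unions:
            order = list(children)
            # pull within-sibship mates together
            for (dad, mom), _ in unions:
                if (parent_couple.get(dad) == couple
                        and parent_couple.get(mom) == couple):
                    i, j = order.index(dad), order.index(mom)
                    lo, hi = min(i, j), max(i, j)
                    moved = order.pop(hi)
                    order.insert(lo + 1, moved)
            for rank, key in enumerate(order, start=1):
                sibling_order[key] = rank
    return Hints(sibling_order=sibling_order)


# ---------------------------------------------------------------------------
# alignment

def _pava_spaced(desired: list) -> list:
    """Least-squares positions closest to ``desired`` with fixed order and
    a minimum gap of 1 between neighbours (pool-adjacent-violators)."""
    y = [d - i for i, d in enumerate(desired)]
    blocks: list = []
    for v in y:
        blocks.append([v, 1])
        while len(blocks) > 1 and (blocks[-2][0] / blocks[-2][1]
                                   >= blocks[-1][0] / blocks[-1][1]):
            s, c = blocks.pop()
            blocks[-1][0] += s
            blocks[-1][1] += c
    out: list = []
    for s, c in blocks:
        out.extend([s / c] * c)
    return [v + i for i, v in enumerate(out)]


def align(pedigree: Pedigree, hints: Optional[Hints] = None,
          bypass_spouse_alignment: bool = False,
          smoothing_passes: int = 12) -> LayoutTable:
    """Produce the full layout table (step 1 of the drawing pipeline).

    Raises :class:`LayoutError` for a pedigree with cross-generational
    matings unless ``bypass_spouse_alignment`` is set, in which case the
    mating line is routed between levels instead of the spouses being
    placed adjacent.
    """
    gens = assign_generations(pedigree)
    if gens.uneven_couples and not bypass_spouse_alignment:
        pairs = ", ".join(f"{d[1]}x{m[1]}" for d, m in gens.uneven_couples)
        raise LayoutError(
            f"cross-generational mating(s) {pairs} cannot satisfy spouse "
            f"alignment; re-run with bypass_spouse_alignment=True")
    if hints is None:
        hints = auto_hints(pedigree)

    entries: list = []
    unions: list = []
    rows: dict = {}
    fam_rows: dict = {}

    for famid in pedigree.famids:
        fam_entries, fam_unions, frows = _order_family(
            pedigree, famid, gens.generation, hints)
        offset_e = len(entries)
        for u in fam_unions:
            u.dad_entry += offset_e
            u.mom_entry += offset_e
            u.children_entries = [c + offset_e for c in u.children_entries]
        entries.extend(fam_entries)
        unions.extend(fam_unions)
        fam_rows[famid] = {g: [i + offset_e for i in idxs]
                           for g, idxs in frows.items()}

    # coordinates per family, then families side by side
    x_offset = 0.0
    for famid in pedigree.famids:
        frows = fam_rows[famid]
        _smooth_family(entries, unions, frows, smoothing_passes)
        min_x = min(entries[i].x for idxs in frows.values() for i in idxs)
        max_x = min_x
        for idxs in frows.values():
            for i in idxs:
                entries[i].x += x_offset - min_x
                max_x = max(max_x, entries[i].x)
        x_offset = max_x + 3.0
        for g, idxs in frows.items():
            rows.setdefault(g, []).extend(idxs)

    return LayoutTable(entries=entries, unions=unions, rows=rows)


def _order_family(pedigree: Pedigree, famid: str, gen: dict, hints: Hints):
    """Left-to-right ordering of one family's levels (relative indices)."""
    unions = pedigree.unions(famid)
    unions_of: dict = {}
    parent_couple: dict = {}
    children_of: dict = {}
    for couple, children in unions:
        order = sorted(children,
                       key=lambda c: (hints.sibling_order.get(c, 10**9),
                                      children.index(c)))
        children_of[couple] = order
        for c in children:
            parent_couple[c] = couple
        for member in couple:
            unions_of.setdefault(member, []).append(couple)

    entries: list = []
    rows: dict = {}
    copies: dict = {}
    placements: dict = {}
    visited: set = set()
    processed: set = set()
    placed_via: dict = {}
    union_list: list = []

    def new_entry(key, after: Optional[int] = None) -> int:
        idx = len(entries)
        copy_index = len(copies.setdefault(key, []))
        entries.append(LayoutEntry(key=key, copy_index=copy_index,
                                   generation=gen[key]))
        copies[key].append(idx)
        row = rows.setdefault(gen[key], [])
        if after is not None and after in row:
            row.insert(row.index(after) + 1, idx)
        else:
            row.append(idx)
        return idx

    def mark_duplicate(key, new_idx):
        group = f"{key[0]}:{key[1]}"
        for idx in copies[key]:
            entries[idx].dup_group = group

    def place_individual(key) -> int:
        visited.add(key)
        idx = new_entry(key)
        for couple in unions_of.get(key, ()):  # deterministic union order
            place_union(couple, key, idx)
        return idx

    def place_union(couple, anchor_key, anchor_idx):
        if couple in processed:
            return
        dad, mom = couple
        spouse = mom if anchor_key == dad else dad
        if spouse not in visited and spouse in parent_couple:
            # the spouse will be hung as a child of its own parent couple
            # later; process this union once both partners are placed
            return
        processed.add(couple)
        left = any(a == anchor_key and b == spouse and s == "left"
                   for a, b, s in hints.spouse_side)
        spouse_unions: list = []
        if spouse not in visited:
            # married-in founder: place adjacent to the anchor
            visited.add(spouse)
            placed_via[spouse] = couple
            if gen[spouse] != gen[anchor_key]:
                sp_idx = new_entry(spouse)  # routed mating line (bypass)
            elif left:
                row = rows.setdefault(gen[spouse], [])
                sp_idx = len(entries)
                copy_index = len(copies.setdefault(spouse, []))
                entries.append(LayoutEntry(key=spouse, copy_index=copy_index,
                                           generation=gen[spouse]))
                copies[spouse].append(sp_idx)
                row.insert(row.index(anchor_idx), sp_idx)
            else:
                sp_idx = new_entry(spouse, after=anchor_idx)
            spouse_unions = [c for c in unions_of.get(spouse, ())
                             if c not in processed]
        elif gen[spouse] != gen[anchor_key] or \
                (parent_couple.get(spouse) is not None
                 and parent_couple.get(spouse) == parent_couple.get(anchor_key)):
            # cross-generation mating (routed line) or within-sibship
            # mating: reuse the already-placed primary copy
            sp_idx = copies[spouse][0]
        else:
            # loop closure elsewhere on the level: duplicate the spouse
            sp_idx = new_entry(spouse, after=anchor_idx)
            mark_duplicate(spouse, sp_idx)
        if entries[anchor_idx].spouse_link is None:
            entries[anchor_idx].spouse_link = spouse
        if entries[sp_idx].spouse_link is None:
            entries[sp_idx].spouse_link = anchor_key
        placement = UnionPlacement(
            dad_key=dad, mom_key=mom,
            dad_entry=anchor_idx if anchor_key == dad else sp_idx,
            mom_entry=sp_idx if anchor_key == dad else anchor_idx,
            same_generation=(gen[dad] == gen[mom]))
        placements[couple] = placement
        union_list.append(placement)
        for child in children_of[couple]:
            if child not in visited:
                placed_via[child] = None
                c_idx = place_individual(child)
            else:
                # loop closure: the child is already drawn elsewhere
                c_idx = new_entry(child)
                mark_duplicate(child, c_idx)
            placement.children_entries.append(c_idx)
        # descend into the spouse's other unions after the children
        for c in spouse_unions:
            place_union(c, spouse, sp_idx)

    fam_keys = [rec.key for rec in pedigree.family(famid)]
    index = {key: i for i, key in enumerate(fam_keys)}
    for key in sorted(fam_keys, key=lambda k: (gen[k], index[k])):
        if key not in visited:
            place_individual(key)
    return entries, union_list, rows


def _smooth_family(entries, unions, rows, passes: int):
    """Iterative centring of children under parents and parents over
    children, keeping order and a unit gap (PAVA each pass)."""
    by_gen = sorted(rows)
    for g in by_gen:
        for slot, idx in enumerate(rows[g]):
            entries[idx].x = float(slot)
    parent_union: dict = {}
    for u in unions:
        for c in u.children_entries:
            parent_union[c] = u
    fam_union_idx = {id(u) for u in unions}

    for _ in range(passes):
        # down: children centred under their parent couple midpoint
        for g in by_gen:
            desired = []
            for idx in rows[g]:
                u = parent_union.get(idx)
                if u is not None and id(u) in fam_union_idx:
                    mid = 0.5 * (entries[u.dad_entry].x + entries[u.mom_entry].x)
                    desired.append(mid)
                else:
                    desired.append(entries[idx].x)
            fitted = _pava_spaced(desired)
            for idx, x in zip(rows[g], fitted):
                entries[idx].x = x
        # up: couples centred over their children
        for g in reversed(by_gen):
            targets: dict = {}
            for u in unions:
                if not u.children_entries:
                    continue
                mean = sum(entries[c].x for c in u.children_entries) \
                    / len(u.children_entries)
                d_idx, m_idx = u.dad_entry, u.mom_entry
                if entries[d_idx].generation != g and \
                        entries[m_idx].generation != g:
                    continue
                if entries[d_idx].x <= entries[m_idx].x:
                    first, second = d_idx, m_idx
                else:
                    first, second = m_idx, d_idx
                if u.same_generation:
                    targets.setdefault(first, []).append(mean - 0.5)
                    targets.setdefault(second, []).append(mean + 0.5)
                else:
                    for idx in (d_idx, m_idx):
                        if entries[idx].generation == g:
                            targets.setdefault(idx, []).append(mean)
            desired = []
            for idx in rows[g]:
                if idx in targets:
                    desired.append(sum(targets[idx]) / len(targets[idx]))
                else:
                    desired.append(entries[idx].x)
            fitted = _pava_spaced(desired)
            for idx, x in zip(rows[g], fitted):
                entries[idx].x = x
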