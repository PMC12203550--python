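"""Kinship-distance trimming of large pedigrees.

Large pedigrees are refined by keeping only individuals within a maximum
kinship-based distance D = log2(1/K) of the probands, plus the minimal set
of connecting relatives (typically parent couples) needed so that every
originally-connected pair of informative individuals stays connected in the
trimmed pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

from .kinship import kinship, kinship_to_distance
from .model import Pedigree, subset

__all__ = ["TrimResult", "min_distance_to_probands", "useful_inds", "trim"]


@dataclass
class TrimResult:
    """Outcome of :func:`useful_inds`.

    ``kept_ids`` is the full set of retained (famid, id) keys;
    ``distance`` maps every individual to its minimum distance to a proband
    (+inf when unrelated); ``structural_ids`` are the members of
    ``kept_ids`` beyond the distance threshold, retained only to preserve
    connectivity.
    """

    kept_ids: set
    distance: dict
    structural_ids: set
    probands: set
    max_dist: float


def min_distance_to_probands(pedigree: Pedigree, probands: Iterable,
                             mode: str = "autosome") -> dict:
    """Minimum kinship distance from each individual to any proband.

    D(i) = min over probands p of log2(1 / K(i, p)); a proband's own
    distance is log2(1 / K(p, p)) (= 1 when non-inbred); individuals
    unrelated to every proband (including all other families) get +inf.
    """
    pkeys = [pedigree.resolve(p) for p in probands]
    if not pkeys:
        raise ValueError("at least one proband is required")
    unknown = [k for k in pkeys if k not in set(pedigree.keys)]
    if unknown:
        raise KeyError(f"unknown proband ids: {unknown}")
    matrix = kinship(pedigree, mode)
    out = {}
    for key in pedigree.keys:
        k_max = max(matrix[key, p] for p in pkeys)
        out[key] = kinship_to_distance(k_max)
    return out


def useful_inds(pedigree: Pedigree, probands: Iterable, max_dist: float,
                mode: str = "autosome",
                require_avail: bool = False,
                affected_only: Optional[int] = None) -> TrimResult:
    """Select informative individuals within ``max_dist`` of the probands.

    The core set is every individual whose distance is <= ``max_dist``
    (ties kept), plus the probands themselves.  Optional filters restrict
    the core to available individuals (``require_avail``) or to individuals
    affected for a given affection column (``affected_only``); probands are
    never filtered out.  A structural closure then reconnects the core:
    whenever two core individuals were connected in the original family but
    are not in the kept set, the individuals on a shortest connecting path
    are added, and parent couples are completed (a child's parent link only
    survives trimming if both parents are kept).  Additions beyond the
    threshold are reported as ``structural_ids``.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    pkeys = {pedigree.resolve(p) for p in probands}
    distance = min_distance_to_probands(pedigree, pkeys, mode)

    core = {k for k, d in distance.items() if d <= max_dist} | pkeys
    if require_avail:
        core = {k for k in core if pedigree[k].avail} | pkeys
    if affected_only is not None:
        def _affected(key):
            aff = pedigree[key].affections
            return affected_only < len(aff) and aff[affected_only] == 1.0
        core = {k for k in core if _affected(k)} | pkeys

    graph = pedigree.undirected_graph()
    kept = set(core)
    changed = True
    while changed:
        changed = False
        # reconnect core components split by the trim
        induced = graph.subgraph(kept)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(induced)):
            for node in comp:
                comp_of[node] = ci
        for comp in nx.connected_components(graph):
            anchors = sorted(k for k in comp if k in core)
            while len({comp_of[a] for a in anchors}) > 1:
                first = comp_of[anchors[0]]
                sources = [a for a in anchors if comp_of[a] == first]
                targets = {a for a in anchors if comp_of[a] != first}
                # deterministic multi-source BFS to the nearest other anchor
                prev = {s: None for s in sources}
                frontier = list(sources)
                hit = None
                while frontier and hit is None:
                    nxt = []
                    for node in frontier:
                        for nb in sorted(graph.neighbors(node)):
                            if nb in prev:
                                continue
                            prev[nb] = node
                            if nb in targets:
                                hit = nb
                                break
                            nxt.append(nb)
                        if hit:
                            break
                    frontier = nxt
                node = hit
                while node is not None:
                    if node not in kept:
                        kept.add(node)
                        changed = True
                    node = prev[node]
                induced = graph.subgraph(kept)
                comp_of = {}
                for ci, c in enumerate(nx.connected_components(induced)):
                    for n in c:
                        comp_of[n] = ci
        # complete parent couples: a kept child keeps its parent link only
        # if both parents are kept
        for key in sorted(kept):
            parents = pedigree.parents_of(key)
            if not parents:
                continue
            present = [p in kept for p in parents]
            if any(present) and not all(present):
                for p in parents:
                    if p not in kept:
                        kept.add(p)
                        changed = True
    return TrimResult(kept_ids=kept, distance=distance,
                      structural_ids=kept - core, probands=pkeys,
                      max_dist=max_dist)


def trim(pedigree: Pedigree, result: TrimResult) -> Pedigree:
    """Restrict the pedigree to ``result.kept_ids`` (validates cleanly)."""
    return subset(pedigree, result.kept_ids)
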