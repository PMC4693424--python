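"""Branch-and-bound subgraph isomorphism on line graphs, plus family search.

The searcher walks the residue's line-graph nodes in the order chosen by the
index, mapping each query bond onto a compatible polymer bond. Atom origins
are tracked throughout, so two query bonds sharing an atom must map to polymer
bonds sharing the corresponding atom — this is what distinguishes, e.g.,
cyclopropane from isobutane. Any partial assignment violating the matching
predicate or atom injectivity is pruned immediately. The enumeration is
complete: every embedding of the query is found, under any valid connected
order (the order changes speed, never results).

Family search exploits the residue DAG: the smallest residue (root) is
searched globally; a larger residue is searched only inside the neighbourhoods
of its already-found smaller descendants, because a residue is totally
included in each of its parents — if a residue is absent, none of its parents
can be present.

Matches are reported as atom sets (embeddings differing only by residue
automorphism collapse to one), which is what the tiling step consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .markov_index import MarkovIndex
from .molgraph import (
    LineGraph,
    MolecularGraph,
    atom_compatible,
    to_line_graph,
)
from .residues import Residue, ResidueFamily

__all__ = ["MatchSet", "search_root", "search_family", "search_local", "MatchCapWarning"]

DEFAULT_MATCH_CAP = 10_000


class MatchCapWarning(UserWarning):
    """Raised (as a warning) when a residue exceeds the per-residue match cap."""


@dataclass(frozen=True)
class MatchSet:
    """One occurrence of a residue in a polymer: an injective atom map and the
    covered atom set (the tiler's currency)."""

    residue: Optional[Residue]
    polymer: MolecularGraph
    atom_map: tuple[tuple[int, int], ...]  # (query atom, polymer atom), sorted
    covered_atoms: frozenset[int]
    mode: str

    @property
    def size(self) -> int:
        return len(self.covered_atoms)


def _bfs_index(graph: MolecularGraph) -> MarkovIndex:
    """A valid connected order without frequency information (results are
    order-independent; this is used where no learned index is at hand)."""
    if graph.n_bonds == 0:
        return MarkovIndex(graph=graph, line_graph=None, order=(), connectivity=(),
                           expected_cost=0.0)
    lg = to_line_graph(graph)
    remaining = set(n.node_id for n in lg.nodes)
    order: list[int] = []
    while remaining:
        start = min(remaining)
        order.append(start)
        remaining.discard(start)
        frontier = set(lg.adjacency[start]) & remaining
        while frontier:
            v = min(frontier)
            order.append(v)
            remaining.discard(v)
            frontier |= lg.adjacency[v] & remaining
            frontier -= set(order)
    connectivity = tuple(
        tuple(j for j in range(k) if order[j] in lg.adjacency[node])
        for k, node in enumerate(order)
    )
    return MarkovIndex(graph=graph, line_graph=lg, order=tuple(order),
                       connectivity=connectivity, expected_cost=float(len(order)))


def _bond_mode_ok(q_order: str, t_order: str, mode: str) -> bool:
    return mode == "light" or q_order == t_order


def _enumerate(
    index: MarkovIndex,
    polymer_lg: LineGraph,
    mode: str,
    allowed_atoms: Optional[frozenset[int]],
    max_matches: int,
) -> list[dict[int, int]]:
    """All embeddings (query-atom → polymer-atom maps) of index.graph."""
    qg = index.graph
    pg = polymer_lg.parent

    def atom_ok(q_atom: int, p_atom: int) -> bool:
        if allowed_atoms is not None and p_atom not in allowed_atoms:
            return False
        return atom_compatible(qg.atoms[q_atom], pg.atoms[p_atom], mode)

    results: list[dict[int, int]] = []
    capped = False

    isolated = [a.atom_id for a in qg.atoms if qg.degree(a.atom_id) == 0]

    def assign_isolated(i: int, amap: dict[int, int], used: set[int]) -> bool:
        nonlocal capped
        if i == len(isolated):
            results.append(dict(amap))
            return len(results) < max_matches
        qa = isolated[i]
        for atom in pg.atoms:
            pa = atom.atom_id
            if pa in used or not atom_ok(qa, pa):
                continue
            amap[qa] = pa
            used.add(pa)
            ok = assign_isolated(i + 1, amap, used)
            del amap[qa]
            used.discard(pa)
            if not ok:
                capped = True
                return False
        return True

    if index.n_nodes == 0:
        assign_isolated(0, {}, set())
        if capped:
            warnings.warn("match cap reached; results truncated", MatchCapWarning)
        return results

    order = index.order
    conn = index.connectivity
    qlg = index.line_graph
    assert qlg is not None
    q_bonds = [qlg.nodes[node].bond_ref for node in order]

    def extend(k: int, amap: dict[int, int], used: set[int]) -> bool:
        nonlocal capped
        if k == len(order):
            return assign_isolated(0, amap, used)
        qb = q_bonds[k]
        qa, qb2 = qb.a1, qb.a2
        ma, mb = amap.get(qa), amap.get(qb2)

        if ma is not None and mb is not None:
            tb = next((b for b in pg.bonds_at(ma) if b.other(ma) == mb), None)
            if tb is None or not _bond_mode_ok(qb.order, tb.order, mode):
                return True
            return extend(k + 1, amap, used)

        candidates: Iterable
        if ma is not None or mb is not None:
            anchor_q, free_q = (qa, qb2) if ma is not None else (qb2, qa)
            anchor_p = amap[anchor_q]
            candidates = pg.bonds_at(anchor_p)
            for tb in candidates:
                if not _bond_mode_ok(qb.order, tb.order, mode):
                    continue
                free_p = tb.other(anchor_p)
                if free_p in used or not atom_ok(free_q, free_p):
                    continue
                amap[free_q] = free_p
                used.add(free_p)
                ok = extend(k + 1, amap, used)
                del amap[free_q]
                used.discard(free_p)
                if not ok:
                    return False
            return True

        # neither endpoint mapped: this position starts a new component
        for tb in pg.bonds:
            if not _bond_mode_ok(qb.order, tb.order, mode):
                continue
            for (x_q, x_p), (y_q, y_p) in (
                ((qa, tb.a1), (qb2, tb.a2)),
                ((qa, tb.a2), (qb2, tb.a1)),
            ):
                if x_p in used or y_p in used:
                    continue
                if not atom_ok(x_q, x_p) or not atom_ok(y_q, y_p):
                    continue
                amap[x_q] = x_p
                amap[y_q] = y_p
                used.add(x_p)
                used.add(y_p)
                ok = extend(k + 1, amap, used)
                del amap[x_q]
                del amap[y_q]
                used.discard(x_p)
                used.discard(y_p)
                if not ok:
                    return False
        return True

    if not extend(0, {}, set()):
        capped = True
    if capped:
        warnings.warn("match cap reached; results truncated", MatchCapWarning)
    return results


def _collapse(
    maps: Sequence[dict[int, int]],
    residue: Optional[Residue],
    polymer: MolecularGraph,
    mode: str,
) -> list[MatchSet]:
    """Automorphism collapse: one MatchSet per distinct covered atom set."""
    by_set: dict[frozenset[int], dict[int, int]] = {}
    for amap in maps:
        covered = frozenset(amap.values())
        by_set.setdefault(covered, amap)
    out = []
    for covered in sorted(by_set, key=lambda s: tuple(sorted(s))):
        amap = by_set[covered]
        out.append(
            MatchSet(
                residue=residue,
                polymer=polymer,
                atom_map=tuple(sorted(amap.items())),
                covered_atoms=covered,
                mode=mode,
            )
        )
    return out


def search_root(
    index: MarkovIndex,
    polymer_lg: LineGraph,
    mode: str = "strict",
    *,
    residue: Optional[Residue] = None,
    region: Optional[frozenset[int]] = None,
    max_matches: int = DEFAULT_MATCH_CAP,
) -> list[MatchSet]:
    """Complete enumeration of a residue's occurrences in the polymer.

    Returns one :class:`MatchSet` per distinct covered atom set; empty list
    when absent. ``region`` restricts embeddings to the given polymer atoms.
    """
    if mode not in ("strict", "light"):
        raise ValueError(f"unknown mode {mode!r}")
    maps = _enumerate(index, polymer_lg, mode, region, max_matches)
    return _collapse(maps, residue, polymer_lg.parent, mode)


def _graph_connected(g: MolecularGraph) -> bool:
    if g.n_atoms <= 1:
        return True
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for w in g.neighbors(v):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == g.n_atoms


def _ball(pg: MolecularGraph, seed: frozenset[int], radius: int) -> frozenset[int]:
    cur = set(seed)
    frontier = set(seed)
    for _ in range(radius):
        nxt = set()
        for a in frontier:
            for w in pg.neighbors(a):
                if w not in cur:
                    nxt.add(w)
        if not nxt:
            break
        cur |= nxt
        frontier = nxt
    return frozenset(cur)


def search_family(
    family: ResidueFamily,
    index: Optional[MarkovIndex],
    polymer_lg: LineGraph,
    mode: str = "strict",
    *,
    region: Optional[frozenset[int]] = None,
    max_matches: int = DEFAULT_MATCH_CAP,
) -> list[MatchSet]:
    """Search every residue of a family, using the DAG to prune and localise.

    The root is searched with the given index (a plain connected order is used
    if ``index`` is None). A residue with children is searched only inside the
    dilated neighbourhoods of its children's matches, and skipped outright if
    any child is absent. Residues with no children (local DAG minima other
    than the root) are searched in full.
    """
    if family.is_empty:
        return []
    pg = polymer_lg.parent
    results: dict[str, list[MatchSet]] = {}
    out: list[MatchSet] = []

    by_level = sorted(family.residues, key=lambda r: (-r.level, r.residue_id))
    for r in by_level:
        children = family.children_of(r.residue_id)
        if r is family.root or not children:
            idx = index if (r is family.root and index is not None) else _bfs_index(r.graph)
            found = search_root(idx, polymer_lg, mode, residue=r, region=region,
                                max_matches=max_matches)
        else:
            if any(not results[c.residue_id] for c in children):
                results[r.residue_id] = []
                continue
            if not _graph_connected(r.graph):
                found = search_root(_bfs_index(r.graph), polymer_lg, mode, residue=r,
                                    region=region, max_matches=max_matches)
            else:
                allowed: Optional[frozenset[int]] = None
                for c in children:
                    radius = r.graph.n_atoms - c.graph.n_atoms
                    union: set[int] = set()
                    for m in results[c.residue_id]:
                        union |= _ball(pg, m.covered_atoms, radius)
                    allowed = frozenset(union) if allowed is None else allowed & frozenset(union)
                if region is not None:
                    allowed = (allowed or frozenset()) & region
                if not allowed:
                    results[r.residue_id] = []
                    continue
                found = search_root(_bfs_index(r.graph), polymer_lg, mode, residue=r,
                                    region=allowed, max_matches=max_matches)
        results[r.residue_id] = found
        out.extend(found)
    return out


def search_local(
    family: ResidueFamily,
    polymer_lg: LineGraph,
    region: frozenset[int],
    mode: str = "light",
    *,
    max_matches: int = DEFAULT_MATCH_CAP,
) -> list[MatchSet]:
    """Family search restricted to a polymer region (used by modulation)."""
    if not region:
        raise ValueError("region must be non-empty")
    return search_family(family, None, polymer_lg, mode, region=frozenset(region),
                         max_matches=max_matches)
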