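"""Independent oracles for the test suite.

Everything here is deliberately naive and structurally independent of the
package's search path: plain atom-level backtracking (no line graphs, no
indexes), exhaustive enumeration for tilings and index orders, and a small
random-molecule generator with explicit valence bookkeeping.
"""

from __future__ import annotations

import itertools
import random
from typing import Optional, Sequence

from monomerizer.molgraph import AtomNode, Bond, MolecularGraph

VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}
ORDER_WEIGHT = {"single": 1, "double": 2, "triple": 3}


def naive_matches(
    query: MolecularGraph,
    target: MolecularGraph,
    mode: str,
    region: Optional[frozenset[int]] = None,
) -> set[frozenset[int]]:
    """All embeddings of query in target as covered atom sets, by brute-force
    atom-by-atom backtracking. Strict: elements equal, bond orders equal,
    query hydrogen count a lower bound; light: elements only."""

    def atom_ok(qa: int, ta: int) -> bool:
        q, t = query.atoms[qa], target.atoms[ta]
        if region is not None and ta not in region:
            return False
        if q.element != t.element:
            return False
        return mode == "light" or t.h_count >= q.h_count

    def bonds_ok(amap: dict[int, int]) -> bool:
        for b in query.bonds:
            if b.a1 in amap and b.a2 in amap:
                tb = None
                for cand in target.bonds_at(amap[b.a1]):
                    if cand.other(amap[b.a1]) == amap[b.a2]:
                        tb = cand
                        break
                if tb is None:
                    return False
                if mode == "strict" and tb.order != b.order:
                    return False
        return True

    results: set[frozenset[int]] = set()
    n = query.n_atoms

    def backtrack(qa: int, amap: dict[int, int], used: set[int]) -> None:
        if qa == n:
            results.add(frozenset(amap.values()))
            return
        for ta in range(target.n_atoms):
            if ta in used or not atom_ok(qa, ta):
                continue
            amap[qa] = ta
            used.add(ta)
            if bonds_ok(amap):
                backtrack(qa + 1, amap, used)
            del amap[qa]
            used.discard(ta)

    backtrack(0, {}, set())
    return results


def brute_line_graph(g: MolecularGraph) -> tuple[int, set[frozenset[int]]]:
    """Line-graph structure by definition: node per bond, edge per pair of
    bonds sharing an atom. Returns (node count, set of adjacent bond-id pairs)."""
    edges = set()
    for b1, b2 in itertools.combinations(g.bonds, 2):
        if b1.endpoints & b2.endpoints:
            edges.add(frozenset((b1.bond_id, b2.bond_id)))
    return g.n_bonds, edges


def best_tiling_exhaustive(tiles: Sequence, rank_key) -> tuple[int, tuple]:
    """Max-coverage disjoint subset over ≤~15 tiles by full enumeration.
    Returns (covered atoms, sorted rank keys of the best subset)."""
    best_cov = -1
    best_key: tuple = ()
    for r in range(len(tiles) + 1):
        for combo in itertools.combinations(tiles, r):
            covered: set[int] = set()
            ok = True
            for t in combo:
                if covered & t.covered_atoms:
                    ok = False
                    break
                covered |= t.covered_atoms
            if not ok:
                continue
            key = tuple(sorted(rank_key(t) for t in combo))
            if len(covered) > best_cov or (len(covered) == best_cov and key < best_key):
                best_cov, best_key = len(covered), key
    return best_cov, best_key


def min_connected_order_cost(labels, adjacency, probability) -> float:
    """Minimum index cost over every connected enumeration order (≤~7 nodes)."""
    nodes = sorted(adjacency)
    best = float("inf")
    for perm in itertools.permutations(nodes):
        ok = True
        for k, v in enumerate(perm):
            if k > 0 and not any(perm[j] in adjacency[v] for j in range(k)):
                ok = False
                break
        if not ok:
            continue
        cost, prod = 0.0, 1.0
        for v in perm:
            prod *= probability(labels[v])
            cost += prod
        best = min(best, cost)
    return best


def random_molecule(
    rng: random.Random,
    n_atoms: int,
    elements: str = "CCCCNNOS",
    ring_prob: float = 0.3,
    multi_prob: float = 0.2,
) -> MolecularGraph:
    """A random chemically consistent molecule: random tree plus occasional
    ring closure, bond orders upgraded where valence budgets allow, remaining
    valence expressed as hydrogens."""
    elems = [rng.choice(elements) for _ in range(n_atoms)]
    budget = [VALENCE[e] for e in elems]
    bonds: list[tuple[int, int, str]] = []

    def degree_load(i: int) -> int:
        return sum(ORDER_WEIGHT[o] for a, b, o in bonds if i in (a, b))

    for i in range(1, n_atoms):
        parents = [j for j in range(i) if budget[j] - degree_load(j) >= 1]
        if not parents:
            parents = [i - 1]  # degenerate; hydrogens absorb the slack below
        j = rng.choice(parents)
        bonds.append((j, i, "single"))
    if n_atoms >= 3 and rng.random() < ring_prob:
        free = [i for i in range(n_atoms) if budget[i] - degree_load(i) >= 1]
        rng.shuffle(free)
        for a, b in itertools.combinations(free, 2):
            if abs(a - b) > 1 and not any({a, b} == {x, y} for x, y, _ in bonds):
                bonds.append((min(a, b), max(a, b), "single"))
                break
    upgraded = []
    for (a, b, o) in bonds:
        if rng.random() < multi_prob and budget[a] - degree_load(a) >= 1 and budget[b] - degree_load(b) >= 1:
            o = "double"
        upgraded.append((a, b, o))
    bonds = upgraded
    atoms = []
    for i, e in enumerate(elems):
        h = max(0, budget[i] - degree_load(i))
        atoms.append(AtomNode(atom_id=i, element=e, h_count=h))
    return MolecularGraph(
        atoms,
        [Bond(bond_id=k, a1=a, a2=b, order=o) for k, (a, b, o) in enumerate(bonds)],
    )


def random_connected_query(
    rng: random.Random, target: MolecularGraph, n_atoms: int, truncate_h: bool = True
) -> MolecularGraph:
    """An induced connected subgraph of the target, with some hydrogen counts
    lowered — the shape of a residue, guaranteeing occurrences exist."""
    start = rng.randrange(target.n_atoms)
    chosen = [start]
    frontier = set(target.neighbors(start))
    while len(chosen) < n_atoms and frontier:
        nxt = rng.choice(sorted(frontier))
        chosen.append(nxt)
        frontier |= set(target.neighbors(nxt))
        frontier -= set(chosen)
    old_to_new = {old: i for i, old in enumerate(chosen)}
    atoms = []
    for old in chosen:
        a = target.atoms[old]
        h = a.h_count
        if truncate_h and h > 0 and rng.random() < 0.3:
            h -= 1
        atoms.append(AtomNode(atom_id=old_to_new[old], element=a.element, h_count=h,
                              aromatic=a.aromatic, charge=a.charge))
    bonds = []
    for b in target.bonds:
        if b.a1 in old_to_new and b.a2 in old_to_new:
            bonds.append(Bond(bond_id=len(bonds), a1=old_to_new[b.a1],
                              a2=old_to_new[b.a2], order=b.order))
    return MolecularGraph(atoms, bonds)
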