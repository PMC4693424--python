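"""Monomer tiling: choose non-overlapping residue matches covering the polymer.

The search step produces many overlapping residue matches (puzzle tiles); the
tiling step selects a pairwise-disjoint subset maximising atom coverage.
Exact maximisation is a set-packing problem, so the pipeline approximates:

1. **Greedy tiling** — tiles ranked by Occam's-razor criteria (larger first;
   then fewer attachment points; then more frequent bond chemistry; then a
   deterministic canonical key) are accepted whenever disjoint from everything
   already accepted.
2. **Modulation** — when coverage is partial, tiles bordering uncovered
   regions are removed (they often sit there by chance), a tolerant (light)
   family search is run on the enlarged uncovered region, and the greedy
   tiling is repeated over retained + newly found tiles; the better of the
   two tilings is kept.
3. **Local refinement** — an exact branch-and-bound over the candidate tiles
   of a still-uncovered neighbourhood, under a node budget, with tiles outside
   the region frozen.

Disjointness is maintained after every stage and coverage never decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .isosearch import MatchSet, search_local
from .molgraph import MolecularGraph, to_line_graph, LineGraph
from .residues import ResidueFamily

__all__ = [
    "Tile",
    "Tiling",
    "make_tile",
    "rank_key",
    "rank_tiles",
    "greedy_tile",
    "modulate",
    "modulate_with_tiles",
    "refine_local",
    "BudgetExhaustedWarning",
    "DEFAULT_NODE_BUDGET",
]

DEFAULT_NODE_BUDGET = 100_000


class BudgetExhaustedWarning(UserWarning):
    """Refinement hit its node budget; the best tiling found so far is kept."""


@dataclass(frozen=True)
class Tile:
    """A selected (or selectable) residue match."""

    match: MatchSet
    size: int
    n_attachments: int
    bond_priority: float

    @property
    def covered_atoms(self) -> frozenset[int]:
        return self.match.covered_atoms

    @property
    def monomer_name(self) -> str:
        return self.match.residue.monomer_name if self.match.residue else ""

    @property
    def level(self) -> int:
        return self.match.residue.level if self.match.residue else 0

    def key(self) -> tuple:
        return (self.monomer_name, tuple(sorted(self.covered_atoms)), self.level)


def make_tile(match: MatchSet) -> Tile:
    r = match.residue
    return Tile(
        match=match,
        size=len(match.covered_atoms),
        n_attachments=r.n_attachments if r else 0,
        bond_priority=r.bond_priority if r else 0.0,
    )


def rank_key(tile: Tile) -> tuple:
    """Total order: size desc, attachments asc, bond priority desc, then a
    deterministic canonical key so the whole pipeline is reproducible."""
    return (
        -tile.size,
        tile.n_attachments,
        -tile.bond_priority,
        tile.monomer_name,
        tuple(sorted(tile.covered_atoms)),
        tile.level,
    )


def rank_tiles(tiles: Sequence[Tile]) -> list[Tile]:
    return sorted(tiles, key=rank_key)


@dataclass(frozen=True)
class Tiling:
    """A pairwise-disjoint tile selection and the coverage it achieves."""

    selected: tuple[Tile, ...]
    polymer: MolecularGraph

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for t in self.selected:
            if seen & t.covered_atoms:
                raise ValueError("tiles overlap")
            seen |= t.covered_atoms

    @property
    def covered(self) -> frozenset[int]:
        out: set[int] = set()
        for t in self.selected:
            out |= t.covered_atoms
        return frozenset(out)

    @property
    def coverage_rate(self) -> float:
        if self.polymer.n_atoms == 0:
            return 0.0
        return len(self.covered) / self.polymer.n_atoms

    @property
    def uncovered(self) -> frozenset[int]:
        return frozenset(range(self.polymer.n_atoms)) - self.covered

    def rank_score(self) -> tuple:
        """Sorted rank keys of the selected tiles; lexicographically smaller is
        better (used to break coverage ties between tilings)."""
        return tuple(sorted(rank_key(t) for t in self.selected))


def _better(a: Tiling, b: Tiling) -> Tiling:
    """The better of two tilings: more coverage, then smaller rank-score."""
    ca, cb = len(a.covered), len(b.covered)
    if ca != cb:
        return a if ca > cb else b
    ka = tuple(sorted(rank_key(t) for t in a.selected))
    kb = tuple(sorted(rank_key(t) for t in b.selected))
    return a if ka <= kb else b


def greedy_tile(tiles: Sequence[Tile], polymer: MolecularGraph) -> Tiling:
    """Scan tiles in rank order, accepting each tile disjoint from all accepted."""
    accepted: list[Tile] = []
    covered: set[int] = set()
    for t in rank_tiles(tiles):
        if covered & t.covered_atoms:
            continue
        accepted.append(t)
        covered |= t.covered_atoms
    return Tiling(tuple(accepted), polymer)


def _polymer_lg(polymer: MolecularGraph) -> LineGraph:
    if polymer.n_bonds == 0:
        return LineGraph((), {}, polymer)
    return to_line_graph(polymer)


def modulate_with_tiles(
    tiling: Tiling,
    families: Sequence[ResidueFamily],
    polymer: MolecularGraph,
    *,
    mode: str = "light",
) -> tuple[Tiling, list[Tile]]:
    """Modulation step; also returns the tiles discovered by the local search
    so later refinement can reuse them."""
    uncovered = tiling.uncovered
    if not uncovered:
        return tiling, []
    border = {a for u in uncovered for a in polymer.neighbors(u)}
    removed = [t for t in tiling.selected if t.covered_atoms & border]
    retained = [t for t in tiling.selected if not (t.covered_atoms & border)]
    region = frozenset(uncovered | {a for t in removed for a in t.covered_atoms})
    plg = _polymer_lg(polymer)
    new_tiles: list[Tile] = []
    seen_keys = {t.key() for t in retained}
    for fam in families:
        if fam.is_empty:
            continue
        for m in search_local(fam, plg, region, mode):
            t = make_tile(m)
            if t.key() not in seen_keys:
                seen_keys.add(t.key())
                new_tiles.append(t)
    candidate = greedy_tile(retained + new_tiles, polymer)
    return _better(candidate, tiling), new_tiles


def modulate(
    tiling: Tiling,
    families: Sequence[ResidueFamily],
    polymer: MolecularGraph,
) -> Tiling:
    """Remove tiles bordering uncovered regions, re-search there with light
    matching, re-tile, and keep the better of before/after (no-op when the
    polymer is already fully covered)."""
    out, _ = modulate_with_tiles(tiling, families, polymer)
    return out


def refine_local(
    tiling: Tiling,
    candidate_tiles: Sequence[Tile],
    region: frozenset[int],
    budget: int = DEFAULT_NODE_BUDGET,
) -> Tiling:
    """Exact branch-and-bound over tile subsets inside ``region``.

    Tiles of the current tiling that do not touch the region are frozen; every
    candidate (plus the currently selected tiles inside the region) may be
    chosen as long as selections stay pairwise disjoint and clear of the
    frozen atoms. Objective: covered-atom count, ties broken by the greedy
    rank-score. The search stops at ``budget`` explored nodes and keeps the
    best solution found so far.
    """
    region = frozenset(region)
    frozen = [t for t in tiling.selected if not (t.covered_atoms & region)]
    frozen_atoms: set[int] = set()
    for t in frozen:
        frozen_atoms |= t.covered_atoms
    inside = [t for t in tiling.selected if t.covered_atoms & region]

    pool: dict[tuple, Tile] = {}
    for t in list(candidate_tiles) + inside:
        if not (t.covered_atoms & region):
            continue
        if t.covered_atoms & frozen_atoms:
            continue
        pool.setdefault(t.key(), t)
    cands = rank_tiles(pool.values())

    best_sel: list[Tile] = list(inside)
    best_cov = sum(t.size for t in inside)
    best_key = tuple(sorted(rank_key(t) for t in inside))
    suffix_size = [0] * (len(cands) + 1)
    for i in range(len(cands) - 1, -1, -1):
        suffix_size[i] = suffix_size[i + 1] + cands[i].size

    nodes = 0
    exhausted = False

    def dfs(i: int, chosen: list[Tile], covered: set[int]) -> None:
        nonlocal best_sel, best_cov, best_key, nodes, exhausted
        nodes += 1
        if nodes > budget:
            exhausted = True
            return
        cov = len(covered)
        key = tuple(sorted(rank_key(t) for t in chosen))
        if cov > best_cov or (cov == best_cov and key < best_key):
            best_sel, best_cov, best_key = list(chosen), cov, key
        if i == len(cands) or exhausted:
            return
        if cov + suffix_size[i] < best_cov:
            return  # optimistic bound cannot beat the incumbent
        t = cands[i]
        if not (covered & t.covered_atoms):
            chosen.append(t)
            dfs(i + 1, chosen, covered | t.covered_atoms)
            chosen.pop()
        if not exhausted:
            dfs(i + 1, chosen, covered)

    dfs(0, [], set())
    if exhausted:
        warnings.warn("refinement node budget exhausted; keeping best found",
                      BudgetExhaustedWarning)
    candidate = Tiling(tuple(frozen) + tuple(best_sel), tiling.polymer)
    return _better(candidate, tiling)
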