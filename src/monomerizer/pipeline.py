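"""End-to-end annotation: monomer database → families → indexes → tiling.

:class:`Annotator` is the main user-facing object. Built once from a monomer
database, the reaction rules and (optionally) a learning set of polymers, it
precomputes every residue family and a selectivity-ordered index per root
residue, then annotates any number of target polymers:

1. strict family search of every monomer (root first, DAG extension upward);
2. greedy tiling of the matches;
3. if coverage is partial: modulation (light local re-search + re-tiling);
4. if still partial: exact local branch-and-bound refinement per uncovered
   neighbourhood, under a node budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .evalkit import load_monomers
from .isosearch import MatchSet, search_family
from .markov_index import FrequencyModel, MarkovIndex, build_index, learn_frequencies
from .molgraph import LineGraph, MolecularGraph, parse_smiles, to_line_graph
from .residues import ReactionRule, ResidueFamily, build_family, load_rules
from .tiler import (
    DEFAULT_NODE_BUDGET,
    Tile,
    Tiling,
    greedy_tile,
    make_tile,
    modulate_with_tiles,
    refine_local,
)

__all__ = ["AnnotationConfig", "AnnotationResult", "Annotator"]


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunables of the annotation pipeline.

    ``max_matches`` caps matches per residue (pathological symmetry guard);
    ``node_budget`` bounds the refinement branch-and-bound;
    ``modulation_rounds`` is 1 by default — one round solves most partial
    coverings — but may be raised; ``light_fallback`` controls whether
    modulation may use the tolerant matching mode at all.
    """

    max_matches: int = 10_000
    node_budget: int = DEFAULT_NODE_BUDGET
    modulation_rounds: int = 1
    light_fallback: bool = True


@dataclass
class AnnotationResult:
    """Final tiling of one polymer plus summary quantities."""

    polymer: MolecularGraph
    tiling: Tiling
    n_matches: int
    polymer_name: Optional[str] = None

    @property
    def coverage_rate(self) -> float:
        return self.tiling.coverage_rate

    @property
    def uncovered_atoms(self) -> tuple[int, ...]:
        return tuple(sorted(self.tiling.uncovered))

    def to_dict(self) -> dict:
        return {
            "polymer": self.polymer_name or self.polymer.source_smiles or "",
            "tiles": [
                {
                    "monomer": t.monomer_name,
                    "residue_level": t.level,
                    "atoms": sorted(t.covered_atoms),
                    "mode": t.match.mode,
                }
                for t in self.tiling.selected
            ],
            "coverage_rate": self.coverage_rate,
            "uncovered_atoms": list(self.uncovered_atoms),
        }


def _polymer_lg(polymer: MolecularGraph) -> LineGraph:
    if polymer.n_bonds == 0:
        return LineGraph((), {}, polymer)
    return to_line_graph(polymer)


def _uncovered_neighbourhoods(tiling: Tiling) -> list[frozenset[int]]:
    """Connected components of uncovered atoms, each dilated by the atoms of
    the selected tiles adjacent to it (those tiles become revisable)."""
    pg = tiling.polymer
    uncovered = set(tiling.uncovered)
    comps: list[set[int]] = []
    seen: set[int] = set()
    for a in sorted(uncovered):
        if a in seen:
            continue
        comp = {a}
        stack = [a]
        seen.add(a)
        while stack:
            v = stack.pop()
            for w in pg.neighbors(v):
                if w in uncovered and w not in seen:
                    seen.add(w)
                    comp.add(w)
                    stack.append(w)
        comps.append(comp)
    out = []
    for comp in comps:
        border = {w for v in comp for w in pg.neighbors(v)}
        region = set(comp)
        for t in tiling.selected:
            if t.covered_atoms & border:
                region |= t.covered_atoms
        out.append(frozenset(region))
    return out


class Annotator:
    """Precomputed families + indexes over a monomer database; call
    :meth:`annotate` per target polymer."""

    def __init__(
        self,
        monomers: Mapping[str, MolecularGraph],
        rules: Sequence[ReactionRule],
        frequencies: Optional[FrequencyModel] = None,
        config: Optional[AnnotationConfig] = None,
    ) -> None:
        self.monomers = dict(monomers)
        self.rules = list(rules)
        self.frequencies = frequencies or FrequencyModel.uniform()
        self.config = config or AnnotationConfig()
        self.families: dict[str, ResidueFamily] = {}
        self.indexes: dict[str, MarkovIndex] = {}
        for name in sorted(self.monomers):
            fam = build_family(self.monomers[name], self.rules, monomer_name=name)
            self.families[name] = fam
            if not fam.is_empty:
                self.indexes[name] = build_index(fam.root, self.frequencies)

    @classmethod
    def from_files(
        cls,
        monomers_path: Union[str, Path],
        rules_path: Union[str, Path],
        learning_path: Optional[Union[str, Path]] = None,
        config: Optional[AnnotationConfig] = None,
        smoothing: float = 1.0,
    ) -> "Annotator":
        monomers = load_monomers(monomers_path)
        rules = load_rules(rules_path)
        freq = None
        if learning_path is not None:
            with open(learning_path) as fh:
                records = json.load(fh)
            polymers = [parse_smiles(r["smiles"] if isinstance(r, dict) else r)
                        for r in records]
            freq = learn_frequencies(polymers, smoothing=smoothing)
        return cls(monomers, rules, frequencies=freq, config=config)

    @property
    def unreactive_monomers(self) -> list[str]:
        """Monomers matching no rule: they can never be bonded into a polymer."""
        return sorted(n for n, f in self.families.items() if f.is_empty)

    def search_all(self, polymer: MolecularGraph, mode: str = "strict") -> list[MatchSet]:
        plg = _polymer_lg(polymer)
        out: list[MatchSet] = []
        for name in sorted(self.families):
            fam = self.families[name]
            if fam.is_empty:
                continue
            out.extend(
                search_family(fam, self.indexes.get(name), plg, mode,
                              max_matches=self.config.max_matches)
            )
        return out

    def annotate(
        self,
        polymer: Union[str, MolecularGraph],
        name: Optional[str] = None,
    ) -> AnnotationResult:
        if isinstance(polymer, str):
            polymer = parse_smiles(polymer)
        matches = self.search_all(polymer, "strict")
        tiles = [make_tile(m) for m in matches]
        tiling = greedy_tile(tiles, polymer)

        extra_tiles: list[Tile] = []
        families = [f for f in self.families.values() if not f.is_empty]
        if self.config.light_fallback:
            for _ in range(self.config.modulation_rounds):
                if not tiling.uncovered:
                    break
                tiling, new_tiles = modulate_with_tiles(tiling, families, polymer)
                extra_tiles.extend(new_tiles)

        if tiling.uncovered:
            pool = tiles + extra_tiles
            for region in _uncovered_neighbourhoods(tiling):
                cands = [t for t in pool if t.covered_atoms & region]
                tiling = refine_local(tiling, cands, region, budget=self.config.node_budget)

        return AnnotationResult(
            polymer=polymer,
            tiling=tiling,
            n_matches=len(matches),
            polymer_name=name,
        )
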