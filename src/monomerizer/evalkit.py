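"""Synthetic polymers with known ground truth, and evaluation metrics.

Curated polymer databases with manual monomeric annotations require external
downloads, so benchmarking here rests on a generator that assembles polymers
from a monomer database by actually executing the reaction rules: each bond
deletes the atoms the rules say are lost and joins the two attachment atoms.
The surviving atoms of each unit are recorded as ground-truth tiles, giving an
internally consistent test bed where the correct answer is known exactly.

Metrics follow the coverage/correctness convention for annotated polymers:

* coverage rate   — atoms inside any predicted tile / total heavy atoms;
* correctness rate — atoms inside a predicted tile that exactly agrees with a
  curated tile (same monomer, same atom set) / total heavy atoms;
* per-polymer classes: TP (coverage 1, correctness 1), FP (coverage 1,
  correctness < 1), FN (coverage < 1); recall = TP/(TP+FN),
  precision = TP/(TP+FP).

All counts are over heavy atoms; hydrogens are folded into atom labels.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .molgraph import AtomNode, Bond, MolecularGraph, parse_smiles, to_smiles
from .residues import ReactionRule, Site, apply_sites, find_sites
from .tiler import Tiling

__all__ = [
    "GroundTruthPolymer",
    "EvalRecord",
    "ClassificationReport",
    "generate_polymer",
    "coverage_rate",
    "correctness_rate",
    "evaluate",
    "classify",
    "load_monomers",
    "dump_monomers",
]


@dataclass(frozen=True)
class GroundTruthPolymer:
    """A polymer graph plus its curated/generated monomeric structure."""

    graph: MolecularGraph
    truth_tiles: tuple[tuple[str, frozenset[int]], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for _, atoms in self.truth_tiles:
            if seen & atoms:
                raise ValueError("truth tiles must be pairwise disjoint")
            seen |= atoms

    @property
    def monomer_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.truth_tiles)

    def to_smiles(self) -> str:
        return to_smiles(self.graph)


@dataclass(frozen=True)
class EvalRecord:
    """Coverage/correctness of one annotated polymer and its class."""

    coverage_rate: float
    correctness_rate: float
    cls: str  # "TP" | "FP" | "FN"

    def __post_init__(self) -> None:
        if self.correctness_rate > self.coverage_rate + 1e-12:
            raise ValueError("correctness cannot exceed coverage")
        if self.cls not in ("TP", "FP", "FN"):
            raise ValueError(f"unknown class {self.cls!r}")


@dataclass(frozen=True)
class ClassificationReport:
    tp: int
    fp: int
    fn: int
    recall: Optional[float]
    precision: Optional[float]
    recall_undefined: bool = False
    precision_undefined: bool = False


def _free_sites(all_sites: Sequence[Site], used: Sequence[Site],
                monomer: MolecularGraph) -> list[Site]:
    """Sites still applicable alongside the already-chosen ones."""
    from .residues import _compatible_with

    return [s for s in all_sites if s not in used and _compatible_with(used, s, monomer)]


def _default_pairings(rules: Sequence[ReactionRule]) -> list[tuple[str, str]]:
    """Without an explicit pairing table: every ordered pair of standalone
    rules can form a bond, and each non-standalone rule pairs with itself
    (disulfide-style symmetric bonds)."""
    names = sorted(r.name for r in rules if r.standalone)
    pairs = [(a, b) for a in names for b in names]
    pairs += [(r.name, r.name) for r in sorted(rules, key=lambda r: r.name) if not r.standalone]
    return pairs


def generate_polymer(
    monomers: Mapping[str, MolecularGraph],
    rules: Sequence[ReactionRule],
    n_units: int,
    topology: str = "linear",
    seed: int = 0,
    pairings: Optional[Sequence[tuple[str, str]]] = None,
    max_retries: int = 50,
) -> GroundTruthPolymer:
    """Assemble ``n_units`` randomly drawn monomers into one polymer.

    Each inter-monomer bond picks a rule pairing, applies both rules (deleting
    the lost atoms) and joins the attachment atoms with a single bond. The
    same seed always yields the identical polymer and truth tiles.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if topology not in ("linear", "branched", "cyclic"):
        raise ValueError(f"unknown topology {topology!r}")
    if topology == "cyclic" and n_units < 3:
        raise ValueError("cyclic topology needs at least 3 units")
    rng = random.Random(seed)
    names = sorted(monomers)
    if not names:
        raise ValueError("empty monomer database")
    rule_by_name = {r.name: r for r in rules}
    if pairings is None:
        pairings = _default_pairings(rules)
    pairings = [p for p in pairings if p[0] in rule_by_name and p[1] in rule_by_name]
    if not pairings and n_units > 1:
        raise ValueError("no usable rule pairings")

    site_cache: dict[str, list[Site]] = {}

    def sites_of(name: str) -> list[Site]:
        if name not in site_cache:
            out: list[Site] = []
            for r in rules:
                out.extend(find_sites(monomers[name], r))
            site_cache[name] = out
        return site_cache[name]

    for _attempt in range(max_retries):
        units = [rng.choice(names) for _ in range(n_units)]
        used: list[list[Site]] = [[] for _ in range(n_units)]
        # bond plan: (donor unit, acceptor unit); None = any unit with a free site
        plan: list[tuple[Optional[int], int]]
        if topology == "branched" and n_units > 2:
            plan = [(None, i) for i in range(1, n_units)]
        else:
            plan = [(i, i + 1) for i in range(n_units - 1)]
        if topology == "cyclic":
            plan.append((n_units - 1, 0))
        bonds: list[tuple[int, Site, int, Site]] = []
        ok = True
        for (donor, j) in plan:
            donors = [donor] if donor is not None else list(range(j))
            options = []
            for i in donors:
                if i == j:
                    continue
                for (ra, rb) in pairings:
                    fa = [s for s in _free_sites(sites_of(units[i]), used[i], monomers[units[i]])
                          if s.rule.name == ra]
                    fb = [s for s in _free_sites(sites_of(units[j]), used[j], monomers[units[j]])
                          if s.rule.name == rb]
                    for sa in fa:
                        for sb in fb:
                            options.append((i, sa, sb))
            if not options:
                ok = False
                break
            i, sa, sb = rng.choice(options)
            used[i].append(sa)
            used[j].append(sb)
            bonds.append((i, sa, j, sb))
        if not ok:
            continue

        atoms: list[AtomNode] = []
        graph_bonds: list[Bond] = []
        offsets: list[int] = []
        maps: list[dict[int, int]] = []
        tiles: list[tuple[str, frozenset[int]]] = []
        for u, name in enumerate(units):
            g, o2n = apply_sites(monomers[name], used[u])
            off = len(atoms)
            offsets.append(off)
            maps.append(o2n)
            for a in g.atoms:
                atoms.append(AtomNode(atom_id=off + a.atom_id, element=a.element,
                                      h_count=a.h_count, aromatic=a.aromatic, charge=a.charge))
            for b in g.bonds:
                graph_bonds.append(Bond(bond_id=len(graph_bonds), a1=off + b.a1,
                                        a2=off + b.a2, order=b.order))
            tiles.append((name, frozenset(off + i for i in range(g.n_atoms))))
        for (i, sa, j, sb) in bonds:
            a1 = offsets[i] + maps[i][sa.attachment_atom]
            a2 = offsets[j] + maps[j][sb.attachment_atom]
            graph_bonds.append(Bond(bond_id=len(graph_bonds), a1=a1, a2=a2, order="single"))
        graph = MolecularGraph(atoms, graph_bonds)
        return GroundTruthPolymer(graph=graph, truth_tiles=tuple(tiles))
    raise RuntimeError(
        f"could not assemble a polymer from the given monomers/rules after {max_retries} tries"
    )


def coverage_rate(predicted: Tiling) -> float:
    return predicted.coverage_rate


def correctness_rate(predicted: Tiling, truth: GroundTruthPolymer) -> float:
    """Fraction of heavy atoms lying in a predicted tile that exactly agrees
    with a curated tile (same monomer name, same atom set)."""
    if predicted.polymer.n_atoms != truth.graph.n_atoms:
        raise ValueError("prediction and truth refer to different polymers")
    truth_set = {(name, atoms) for name, atoms in truth.truth_tiles}
    correct = 0
    for t in predicted.selected:
        if (t.monomer_name, t.covered_atoms) in truth_set:
            correct += len(t.covered_atoms)
    return correct / truth.graph.n_atoms if truth.graph.n_atoms else 0.0


def evaluate(predicted: Tiling, truth: GroundTruthPolymer) -> EvalRecord:
    cov = coverage_rate(predicted)
    corr = correctness_rate(predicted, truth)
    if cov == 1.0 and corr == 1.0:
        cls = "TP"
    elif cov == 1.0:
        cls = "FP"
    else:
        cls = "FN"
    return EvalRecord(coverage_rate=cov, correctness_rate=corr, cls=cls)


def classify(records: Union[Sequence[EvalRecord], Mapping[str, int]]) -> ClassificationReport:
    """Counts per class and recall/precision.

    Accepts either a list of :class:`EvalRecord` or a mapping of precomputed
    counts ``{"TP": ..., "FP": ..., "FN": ...}``. Zero denominators yield a
    flagged ``None`` rather than a propagating NaN.
    """
    if isinstance(records, Mapping):
        tp = int(records.get("TP", 0))
        fp = int(records.get("FP", 0))
        fn = int(records.get("FN", 0))
    else:
        tp = sum(1 for r in records if r.cls == "TP")
        fp = sum(1 for r in records if r.cls == "FP")
        fn = sum(1 for r in records if r.cls == "FN")
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    return ClassificationReport(
        tp=tp, fp=fp, fn=fn, recall=recall, precision=precision,
        recall_undefined=recall is None, precision_undefined=precision is None,
    )


def export_ground_truth(gt: GroundTruthPolymer, name: str) -> dict:
    """JSON record for a generated polymer, with truth tiles re-indexed to the
    atom order of the emitted canonical SMILES (so that re-parsing the SMILES
    puts every atom back at the index the tiles refer to)."""
    from rdkit import Chem

    from .molgraph import to_rdkit

    mol = to_rdkit(gt.graph)
    smi = Chem.MolToSmiles(mol)
    order = json.loads(mol.GetProp("_smilesAtomOutputOrder").replace(",]", "]"))
    old_to_new = {old: i for i, old in enumerate(order)}
    return {
        "name": name,
        "smiles": smi,
        "truth_tiles": [
            {"monomer": nm, "atoms": sorted(old_to_new[a] for a in atoms)}
            for nm, atoms in gt.truth_tiles
        ],
    }


def load_monomers(source: Union[str, Path, Sequence[dict]]) -> dict[str, MolecularGraph]:
    """Monomer database: JSON records ``{"name": ..., "smiles": ...}``."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            records = json.load(fh)
    else:
        records = list(source)
    out: dict[str, MolecularGraph] = {}
    for r in records:
        if r["name"] in out:
            raise ValueError(f"duplicate monomer name {r['name']!r}")
        out[r["name"]] = parse_smiles(r["smiles"])
    return out


def dump_monomers(monomers: Mapping[str, MolecularGraph]) -> list[dict]:
    """Serialize a monomer database back to JSON records (canonical order)."""
    return [
        {"name": name, "smiles": monomers[name].source_smiles or to_smiles(monomers[name])}
        for name in sorted(monomers)
    ]
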