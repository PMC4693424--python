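"""Chemical reaction rules and residue-family generation.

A *residue* is a monomer truncated of the atoms it loses when a bond-forming
reaction incorporates it into a polymer (e.g. a carboxylic acid loses its OH
in a peptide bond, an amine loses one hydrogen). A reaction rule names the
functional group involved (a SMARTS pattern), the pattern atoms lost, and the
atom that becomes the link point.

All residues derivable from one monomer form a *family*, organised as a DAG:
level-1 residues have one rule applied, children add one more application, and
the unique smallest residue — every compatible application made — is the
*root*. Because a deeper residue is totally included in each of its parents,
the root can be searched first and its absence prunes the whole family.

Families are generated by enumerating every pairwise-compatible subset of
(rule, site) applications found on the intact monomer; subsets whose every
application is non-standalone are dropped (such bonds never occur alone, so
the corresponding level-1 residues do not exist and nothing above them is
reachable). Residues reached by different application orders are merged by
graph isomorphism, which is what makes the family a DAG rather than a tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from networkx.algorithms import isomorphism as nxiso
from rdkit import Chem

from .molgraph import AtomNode, Bond, MolecularGraph, to_networkx, to_rdkit

__all__ = [
    "ReactionRule",
    "Site",
    "SiteInvalidError",
    "Residue",
    "ResidueFamily",
    "load_rules",
    "find_sites",
    "apply_rule",
    "apply_sites",
    "build_family",
    "graphs_isomorphic",
]


class SiteInvalidError(ValueError):
    """A site no longer applies (its atoms were already removed)."""


@dataclass(frozen=True)
class ReactionRule:
    """A bond-forming reaction: the functional group it needs and what it deletes.

    ``pattern`` is a SMARTS string whose atoms carry map numbers; ``delete``
    lists the map numbers of atoms lost on bond formation (hydrogens in the
    pattern become hydrogen-count decrements on their heavy neighbour);
    ``attach`` is the map number of the atom that becomes the link point.
    ``standalone`` marks whether this bond type can be the only bond a monomer
    forms; ``priority`` ranks bond types by how frequently they occur in the
    target polymer class (higher = more frequent).
    """

    name: str
    pattern: str
    delete: tuple[int, ...]
    attach: int
    standalone: bool = True
    priority: float = 1.0

    def __post_init__(self) -> None:
        if not self.delete:
            raise ValueError(f"rule {self.name!r}: delete must be non-empty")
        q = self.query_mol  # validates the SMARTS
        maps = {a.GetAtomMapNum() for a in q.GetAtoms() if a.GetAtomMapNum()}
        missing = set(self.delete) - maps
        if missing:
            raise ValueError(f"rule {self.name!r}: delete maps {sorted(missing)} not in pattern")
        if self.attach not in maps:
            raise ValueError(f"rule {self.name!r}: attach map {self.attach} not in pattern")
        if self.priority <= 0:
            raise ValueError(f"rule {self.name!r}: priority must be positive")

    @property
    def query_mol(self) -> "Chem.Mol":
        q = Chem.MolFromSmarts(self.pattern)
        if q is None:
            raise ValueError(f"rule {self.name!r}: invalid SMARTS {self.pattern!r}")
        return q


def load_rules(source: Union[str, Path, Sequence[dict]]) -> list[ReactionRule]:
    """Load reaction rules from a JSON file path or a sequence of records."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            records = json.load(fh)
    else:
        records = list(source)
    return [
        ReactionRule(
            name=r["name"],
            pattern=r["pattern"],
            delete=tuple(r["delete"]),
            attach=r["attach"],
            standalone=bool(r.get("standalone", True)),
            priority=float(r.get("priority", 1.0)),
        )
        for r in records
    ]


@dataclass(frozen=True)
class Site:
    """One concrete application of a rule on a monomer, reduced to its effect:
    heavy atoms deleted, hydrogen decrements, and the surviving link atom.
    Embeddings that differ only by pattern automorphism collapse to one site."""

    rule: ReactionRule
    heavy_deleted: frozenset[int]
    h_losses: tuple[tuple[int, int], ...]  # (atom_id, n_hydrogens) sorted
    attachment_atom: int

    @property
    def signature(self) -> tuple:
        return (self.rule.name, tuple(sorted(self.heavy_deleted)), self.h_losses,
                self.attachment_atom)


def find_sites(monomer: MolecularGraph, rule: ReactionRule) -> list[Site]:
    """All embeddings of the rule's functional group on the monomer, collapsed
    by effect (so the two hydrogens of an NH2 count as one site)."""
    mol = to_rdkit(monomer)
    molh = Chem.AddHs(mol)  # heavy-atom indices are preserved; Hs appended
    query = rule.query_mol
    map_to_pidx = {a.GetAtomMapNum(): a.GetIdx() for a in query.GetAtoms() if a.GetAtomMapNum()}
    n_heavy = monomer.n_atoms
    sites: dict[tuple, Site] = {}
    for match in molh.GetSubstructMatches(query, uniquify=True, maxMatches=10000):
        heavy_del: set[int] = set()
        h_loss: dict[int, int] = {}
        ok = True
        for m in rule.delete:
            t = match[map_to_pidx[m]]
            if t < n_heavy:
                heavy_del.add(t)
            else:
                nb = molh.GetAtomWithIdx(t).GetNeighbors()[0].GetIdx()
                if nb >= n_heavy:
                    ok = False  # H bonded to H: not meaningful here
                    break
                h_loss[nb] = h_loss.get(nb, 0) + 1
        if not ok:
            continue
        # hydrogen losses on atoms that are themselves deleted are moot
        h_loss = {a: n for a, n in h_loss.items() if a not in heavy_del}
        attach = match[map_to_pidx[rule.attach]]
        if attach >= n_heavy or attach in heavy_del:
            continue
        site = Site(
            rule=rule,
            heavy_deleted=frozenset(heavy_del),
            h_losses=tuple(sorted(h_loss.items())),
            attachment_atom=attach,
        )
        key = site.signature
        sites.setdefault(key, site)
    return [sites[k] for k in sorted(sites)]


def _check_site(graph: MolecularGraph, site: Site) -> None:
    n = graph.n_atoms
    for a in site.heavy_deleted:
        if a >= n:
            raise SiteInvalidError(f"deleted atom {a} not in graph")
    for a, k in site.h_losses:
        if a >= n:
            raise SiteInvalidError(f"atom {a} not in graph")
        if graph.atoms[a].h_count < k:
            raise SiteInvalidError(f"atom {a} lacks {k} hydrogens to remove")
    if site.attachment_atom >= n or site.attachment_atom in site.heavy_deleted:
        raise SiteInvalidError("attachment atom missing")


def apply_sites(graph: MolecularGraph, sites: Sequence[Site]) -> tuple[MolecularGraph, dict[int, int]]:
    """Apply several compatible sites at once; returns the truncated graph and
    the old→new atom-id mapping."""
    heavy_del: set[int] = set()
    h_loss: dict[int, int] = {}
    for s in sites:
        _check_site(graph, s)
        if heavy_del & s.heavy_deleted:
            raise SiteInvalidError("sites delete overlapping atoms")
        heavy_del |= s.heavy_deleted
        for a, k in s.h_losses:
            h_loss[a] = h_loss.get(a, 0) + k
    for s in sites:
        if s.attachment_atom in heavy_del:
            raise SiteInvalidError("attachment atom deleted by another site")
    for a, k in h_loss.items():
        if a in heavy_del:
            continue
        if graph.atoms[a].h_count < k:
            raise SiteInvalidError(f"atom {a} lacks {k} hydrogens in combination")
    keep = [a.atom_id for a in graph.atoms if a.atom_id not in heavy_del]
    old_to_new = {old: new for new, old in enumerate(keep)}
    atoms = []
    for old in keep:
        a = graph.atoms[old]
        atoms.append(
            AtomNode(
                atom_id=old_to_new[old],
                element=a.element,
                h_count=a.h_count - h_loss.get(old, 0),
                aromatic=a.aromatic,
                charge=a.charge,
            )
        )
    bonds = []
    for b in graph.bonds:
        if b.a1 in heavy_del or b.a2 in heavy_del:
            continue
        bonds.append(Bond(bond_id=len(bonds), a1=old_to_new[b.a1], a2=old_to_new[b.a2], order=b.order))
    return MolecularGraph(atoms, bonds), old_to_new


def apply_rule(graph: MolecularGraph, rule: ReactionRule, site: Site) -> MolecularGraph:
    """Apply one rule at one site; raises :class:`SiteInvalidError` on stale sites."""
    if site.rule.name != rule.name:
        raise ValueError("site does not belong to this rule")
    out, _ = apply_sites(graph, [site])
    return out


@dataclass(frozen=True)
class Residue:
    """A truncated monomer. ``monomer_atoms[i]`` is the monomer atom id behind
    residue atom ``i``, which is what lets a small residue's match be extended
    to its larger parents."""

    residue_id: str
    monomer_name: str
    graph: MolecularGraph
    applied: tuple[Site, ...]
    level: int
    attachment_points: tuple[int, ...]
    monomer_atoms: tuple[int, ...]

    @property
    def n_attachments(self) -> int:
        return len(self.applied)

    @property
    def bond_priority(self) -> float:
        return sum(s.rule.priority for s in self.applied)

    def total_h(self) -> int:
        return sum(a.h_count for a in self.graph.atoms)


@dataclass
class ResidueFamily:
    """The DAG of residues of one monomer. Edges point parent → child, where
    the child has one more rule applied (and so strictly fewer atoms)."""

    monomer_name: str
    monomer: MolecularGraph
    residues: list[Residue]
    dag_edges: list[tuple[str, str]]
    root: Optional[Residue]
    _by_id: dict[str, Residue] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {r.residue_id: r for r in self.residues}

    @property
    def is_empty(self) -> bool:
        return not self.residues

    def by_id(self, residue_id: str) -> Residue:
        return self._by_id[residue_id]

    def parents_of(self, residue_id: str) -> list[Residue]:
        return [self._by_id[p] for p, c in self.dag_edges if c == residue_id]

    def children_of(self, residue_id: str) -> list[Residue]:
        return [self._by_id[c] for p, c in self.dag_edges if p == residue_id]

    def levels(self) -> dict[int, list[Residue]]:
        out: dict[int, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.level, []).append(r)
        return out


def graphs_isomorphic(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    """Exact label-preserving graph isomorphism (elements, hydrogen counts,
    aromaticity, charge, bond orders)."""
    if g1.n_atoms != g2.n_atoms or g1.n_bonds != g2.n_bonds:
        return False
    gm = nxiso.GraphMatcher(
        to_networkx(g1),
        to_networkx(g2),
        node_match=nxiso.categorical_node_match(
            ["element", "h_count", "aromatic", "charge"], [None, None, None, None]
        ),
        edge_match=nxiso.categorical_edge_match("order", None),
    )
    return gm.is_isomorphic()


def _compatible_with(chosen: Sequence[Site], cand: Site, monomer: MolecularGraph) -> bool:
    heavy = set()
    h_loss: dict[int, int] = {}
    for s in list(chosen) + [cand]:
        if heavy & s.heavy_deleted:
            return False
        heavy |= s.heavy_deleted
        for a, k in s.h_losses:
            h_loss[a] = h_loss.get(a, 0) + k
    for s in list(chosen) + [cand]:
        if s.attachment_atom in heavy:
            return False
    for a, k in h_loss.items():
        if a not in heavy and monomer.atoms[a].h_count < k:
            return False
    return True


def build_family(
    monomer: MolecularGraph,
    rules: Iterable[ReactionRule],
    monomer_name: str = "monomer",
) -> ResidueFamily:
    """Generate the residue family of a monomer under the given rules.

    Output is independent of the order of ``rules`` (set semantics): sites are
    canonically sorted before subset enumeration and residue ids are assigned
    from the sorted order.
    """
    sites: list[Site] = []
    for rule in rules:
        sites.extend(find_sites(monomer, rule))
    sites.sort(key=lambda s: s.signature)
    if not sites or not any(s.rule.standalone for s in sites):
        return ResidueFamily(monomer_name, monomer, [], [], None)

    # depth-first enumeration of compatible subsets, pruning on the prefix
    subsets: list[tuple[int, ...]] = []

    def grow(prefix: list[int], start: int) -> None:
        for i in range(start, len(sites)):
            if _compatible_with([sites[j] for j in prefix], sites[i], monomer):
                cur = prefix + [i]
                subsets.append(tuple(cur))
                grow(cur, i + 1)

    grow([], 0)
    subsets = [s for s in subsets if any(sites[i].rule.standalone for i in s)]

    # merge subsets whose truncated graphs are isomorphic
    built: list[tuple[tuple[int, ...], MolecularGraph, dict[int, int]]] = []
    for sub in subsets:
        g, o2n = apply_sites(monomer, [sites[i] for i in sub])
        built.append((sub, g, o2n))
    groups: list[list[int]] = []  # indices into `built`
    for idx, (sub, g, _) in enumerate(built):
        placed = False
        for grp in groups:
            s0, g0, _ = built[grp[0]]
            if len(built[grp[0]][0]) == len(sub) and graphs_isomorphic(g0, g):
                grp.append(idx)
                placed = True
                break
        if not placed:
            groups.append([idx])

    # deterministic residue ids: sort groups by (level, representative signature)
    def group_key(grp: list[int]) -> tuple:
        sub = built[grp[0]][0]
        return (len(sub), tuple(sites[i].signature for i in sub))

    groups.sort(key=group_key)
    residues: list[Residue] = []
    subset_to_rid: dict[tuple[int, ...], str] = {}
    per_level_counter: dict[int, int] = {}
    for grp in groups:
        sub, g, o2n = built[grp[0]]
        level = len(sub)
        k = per_level_counter.get(level, 0)
        per_level_counter[level] = k + 1
        rid = f"{monomer_name}/L{level}.{k}"
        applied = tuple(sites[i] for i in sub)
        attach = tuple(sorted({o2n[s.attachment_atom] for s in applied}))
        keep_old = sorted(o2n, key=o2n.get)
        residues.append(
            Residue(
                residue_id=rid,
                monomer_name=monomer_name,
                graph=g,
                applied=applied,
                level=level,
                attachment_points=attach,
                monomer_atoms=tuple(keep_old),
            )
        )
        for m in grp:
            subset_to_rid[built[m][0]] = rid

    edges: set[tuple[str, str]] = set()
    for sub in subset_to_rid:
        sset = set(sub)
        for drop in sub:
            parent = tuple(i for i in sub if i != drop)
            if parent and parent in subset_to_rid:
                edges.add((subset_to_rid[parent], subset_to_rid[sub]))

    root = min(residues, key=lambda r: (r.graph.n_atoms, r.total_h(), r.residue_id))
    return ResidueFamily(monomer_name, monomer, residues,
                         sorted(edges), root)
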