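"""Molecular graphs, line (bond) graphs and the strict/light bond predicates.

Molecules are hydrogen-suppressed: only heavy atoms are nodes, hydrogens are
folded into per-atom counts. The search machinery operates on the *line graph*
(one node per covalent bond, nodes adjacent when the bonds share an atom),
which carries far more label diversity than the handful of element symbols
found in natural organic molecules and therefore makes every comparison more
selective.

Two bond-comparison predicates are provided:

* **strict** — element pair, bond multiplicity (aromatic is its own
  multiplicity) and hydrogen counts must all be compatible; a query hydrogen
  count is a *minimum* requirement on the target atom, because residues are
  truncated monomers and the polymer atom may have lost further hydrogens to
  other bonds only in the query, never gained them.
* **light** — element pair only; multiplicity, aromaticity and hydrogens are
  ignored, which tolerates tautomeric proton/electron moves.

Every strict match is also a light match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "AtomNode",
    "Bond",
    "MolecularGraph",
    "BondNode",
    "LineGraph",
    "SmilesParseError",
    "parse_smiles",
    "to_smiles",
    "to_rdkit",
    "to_line_graph",
    "match_strict",
    "match_light",
    "atom_compatible",
    "BOND_ORDERS",
]

BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_TO_RDKIT_ORDER = {v: k for k, v in _RDKIT_ORDER.items()}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class AtomNode:
    """A heavy atom: element symbol, folded hydrogen count, aromatic flag, charge."""

    atom_id: int
    element: str
    h_count: int
    aromatic: bool = False
    charge: int = 0

    def __post_init__(self) -> None:
        if self.element == "H":
            raise ValueError("hydrogens are folded into h_count, never explicit atoms")
        if self.h_count < 0:
            raise ValueError("h_count must be non-negative")


@dataclass(frozen=True)
class Bond:
    """A covalent bond between two heavy atoms."""

    bond_id: int
    a1: int
    a2: int
    order: str

    def __post_init__(self) -> None:
        if self.a1 == self.a2:
            raise ValueError("bond endpoints must be distinct")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")

    @property
    def endpoints(self) -> frozenset[int]:
        return frozenset((self.a1, self.a2))

    def other(self, atom_id: int) -> int:
        if atom_id == self.a1:
            return self.a2
        if atom_id == self.a2:
            return self.a1
        raise KeyError(atom_id)


class MolecularGraph:
    """Heavy-atom molecular graph.

    Atom ids are a contiguous 0-based range; at most one bond joins a given
    atom pair. Adjacency structures are precomputed on construction.
    """

    def __init__(
        self,
        atoms: Iterable[AtomNode],
        bonds: Iterable[Bond],
        source_smiles: Optional[str] = None,
    ) -> None:
        self.atoms: tuple[AtomNode, ...] = tuple(atoms)
        self.bonds: tuple[Bond, ...] = tuple(bonds)
        self.source_smiles = source_smiles
        if [a.atom_id for a in self.atoms] != list(range(len(self.atoms))):
            raise ValueError("atom_ids must be contiguous and 0-based")
        if [b.bond_id for b in self.bonds] != list(range(len(self.bonds))):
            raise ValueError("bond_ids must be contiguous and 0-based")
        seen_pairs: set[frozenset[int]] = set()
        self._bonds_at: dict[int, list[Bond]] = {a.atom_id: [] for a in self.atoms}
        for b in self.bonds:
            if b.a1 >= len(self.atoms) or b.a2 >= len(self.atoms):
                raise ValueError("bond endpoint outside atom range")
            if b.endpoints in seen_pairs:
                raise ValueError("duplicate bond between the same atom pair")
            seen_pairs.add(b.endpoints)
            self._bonds_at[b.a1].append(b)
            self._bonds_at[b.a2].append(b)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def bonds_at(self, atom_id: int) -> list[Bond]:
        return self._bonds_at[atom_id]

    def neighbors(self, atom_id: int) -> list[int]:
        return [b.other(atom_id) for b in self._bonds_at[atom_id]]

    def degree(self, atom_id: int) -> int:
        return len(self._bonds_at[atom_id])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularGraph):
            return NotImplemented
        return self.atoms == other.atoms and self.bonds == other.bonds

    def __hash__(self) -> int:
        return hash((self.atoms, self.bonds))

    def __repr__(self) -> str:
        return f"MolecularGraph(n_atoms={self.n_atoms}, n_bonds={self.n_bonds})"


@dataclass(frozen=True)
class BondNode:
    """A line-graph node: one covalent bond, with the origins of its atoms kept
    so that matches remain unambiguous at the atom level."""

    node_id: int
    bond_ref: Bond
    label_strict: tuple
    label_light: tuple

    @property
    def origin_atoms(self) -> frozenset[int]:
        return self.bond_ref.endpoints


@dataclass
class LineGraph:
    """Graph of bonds: nodes are bonds of ``parent``, adjacent iff they share an atom."""

    nodes: tuple[BondNode, ...]
    adjacency: dict[int, frozenset[int]]
    parent: MolecularGraph = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed :class:`MolecularGraph`.

    Aromaticity is perceived by RDKit; hydrogens (implicit and explicit) are
    folded into per-atom counts. Atom order follows the input string, so the
    same string always yields the identical graph and matches are reported in
    input coordinates.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return from_rdkit(mol, source_smiles=smiles)


def from_rdkit(mol: "Chem.Mol", source_smiles: Optional[str] = None) -> MolecularGraph:
    """Convert an RDKit molecule (hydrogen-suppressed) to a MolecularGraph."""
    atoms = []
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 1:
            raise ValueError("explicit hydrogen atoms are not supported; remove them first")
        atoms.append(
            AtomNode(
                atom_id=a.GetIdx(),
                element=a.GetSymbol(),
                h_count=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
                charge=a.GetFormalCharge(),
            )
        )
    bonds = []
    for i, b in enumerate(mol.GetBonds()):
        order = _RDKIT_ORDER.get(b.GetBondType())
        if order is None:
            raise ValueError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(Bond(bond_id=i, a1=b.GetBeginAtomIdx(), a2=b.GetEndAtomIdx(), order=order))
    return MolecularGraph(atoms, bonds, source_smiles=source_smiles)


def to_rdkit(g: MolecularGraph, sanitize: bool = True) -> "Chem.Mol":
    """Build an RDKit molecule from a graph, with explicit hydrogen counts.

    Residue graphs may carry open valences (atoms lost to bond formation);
    RDKit represents these as radical centres, which is adequate for SMILES
    output and substructure matching.
    """
    rw = Chem.RWMol()
    for a in g.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.charge)
        ra.SetNumExplicitHs(a.h_count)
        ra.SetNoImplicit(True)
        ra.SetIsAromatic(a.aromatic)
        rw.AddAtom(ra)
    for b in g.bonds:
        rw.AddBond(b.a1, b.a2, _TO_RDKIT_ORDER[b.order])
        if b.order == "aromatic":
            rw.GetBondBetweenAtoms(b.a1, b.a2).SetIsAromatic(True)
    mol = rw.GetMol()
    if sanitize:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
        )
    return mol


def to_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES for a graph (residues may contain radical centres)."""
    return Chem.MolToSmiles(to_rdkit(g))


def _strict_label(g: MolecularGraph, b: Bond) -> tuple:
    e1, e2 = g.atoms[b.a1], g.atoms[b.a2]
    p1 = (e1.element, e1.h_count)
    p2 = (e2.element, e2.h_count)
    lo, hi = sorted((p1, p2))
    return (lo[0], hi[0], b.order, lo[1], hi[1])


def _light_label(g: MolecularGraph, b: Bond) -> tuple:
    lo, hi = sorted((g.atoms[b.a1].element, g.atoms[b.a2].element))
    return (lo, hi)


def to_line_graph(g: MolecularGraph) -> LineGraph:
    """Transform a molecular graph into its graph of bonds (line graph)."""
    if g.n_bonds == 0:
        raise ValueError("no-bond molecule has an empty line graph; match atoms directly")
    nodes = tuple(
        BondNode(
            node_id=b.bond_id,
            bond_ref=b,
            label_strict=_strict_label(g, b),
            label_light=_light_label(g, b),
        )
        for b in g.bonds
    )
    adjacency: dict[int, set[int]] = {n.node_id: set() for n in nodes}
    for atom in g.atoms:
        incident = g.bonds_at(atom.atom_id)
        for i in range(len(incident)):
            for j in range(i + 1, len(incident)):
                adjacency[incident[i].bond_id].add(incident[j].bond_id)
                adjacency[incident[j].bond_id].add(incident[i].bond_id)
    return LineGraph(
        nodes=nodes,
        adjacency={k: frozenset(v) for k, v in adjacency.items()},
        parent=g,
    )


def to_networkx(g: MolecularGraph):
    """networkx view with full atom/bond labels, for isomorphism-based dedup."""
    import networkx as nx

    G = nx.Graph()
    for a in g.atoms:
        G.add_node(a.atom_id, element=a.element, h_count=a.h_count,
                   aromatic=a.aromatic, charge=a.charge)
    for b in g.bonds:
        G.add_edge(b.a1, b.a2, order=b.order)
    return G


def atom_compatible(query: AtomNode, target: AtomNode, mode: str) -> bool:
    """Endpoint compatibility. In strict mode the query hydrogen count is a
    lower bound on the target's; in light mode only the element matters."""
    if query.element != target.element:
        return False
    if mode == "light":
        return True
    return target.h_count >= query.h_count


def _orientations(query: BondNode, target: BondNode, qg: MolecularGraph,
                  tg: MolecularGraph, mode: str) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Atom-level pairings under which query bond maps onto target bond."""
    if mode == "strict" and query.bond_ref.order != target.bond_ref.order:
        return []
    qa, qb = query.bond_ref.a1, query.bond_ref.a2
    ta, tb = target.bond_ref.a1, target.bond_ref.a2
    out = []
    for (x, y) in (((qa, ta), (qb, tb)), ((qa, tb), (qb, ta))):
        if atom_compatible(qg.atoms[x[0]], tg.atoms[x[1]], mode) and atom_compatible(
            qg.atoms[y[0]], tg.atoms[y[1]], mode
        ):
            out.append((x, y))
    return out


def match_strict(query: BondNode, target: BondNode,
                 query_graph: MolecularGraph, target_graph: MolecularGraph) -> bool:
    """True iff elements, bond multiplicity and hydrogen requirements are all
    simultaneously compatible under some endpoint pairing."""
    return bool(_orientations(query, target, query_graph, target_graph, "strict"))


def match_light(query: BondNode, target: BondNode,
                query_graph: MolecularGraph, target_graph: MolecularGraph) -> bool:
    """True iff the element pairs agree; multiplicity and hydrogens ignored."""
    return query.label_light == target.label_light
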