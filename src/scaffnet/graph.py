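"""Universal molecular graph carrier.

A :class:`MolecularGraph` holds a simple, undirected, heavy-atom graph in
which atom labels may be a concrete element symbol or the :data:`ANY`
wildcard, and bond orders may be 1, 2, 3, aromatic (``"ar"``) or :data:`ANY`.
The same container carries standardized molecules, scaffolds, frameworks,
wireframes and fragments; abstraction is expressed purely through wildcard
labels, never through a separate class hierarchy.

Canonical identity is delegated to RDKit: a graph is converted to an RDKit
molecule (wildcards become dummy atoms, wildcard bonds become unspecified
bonds) and keyed by its canonical SMILES.  Ring perception is done with
networkx so that graph surgery never has to round-trip through chemistry
sanitization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import networkx as nx
from rdkit import Chem
from rdkit.Chem import GetPeriodicTable

__all__ = ["ANY", "MolecularGraph", "BondOrder"]


class _Any:
    """Singleton wildcard for atom labels and bond orders."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ANY"

    def __reduce__(self):
        return (_Any, ())


ANY = _Any()

#: a bond order: 1, 2, 3, "ar" (aromatic) or ANY
BondOrder = object

_RD_ORDER = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    "ar": Chem.BondType.AROMATIC,
}
_FROM_RD_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}

_PT = GetPeriodicTable()


@dataclass
class MolecularGraph:
    """Element-or-wildcard labelled atoms with order-or-wildcard bonds.

    Parameters
    ----------
    labels
        One entry per atom: an element symbol (``"C"``, ``"N"``, ...) or
        :data:`ANY`.
    bonds
        Mapping ``(i, j) -> order`` with ``i < j``; order is 1, 2, 3,
        ``"ar"`` or :data:`ANY`.
    charges
        Formal charges, one per atom (wildcard atoms carry 0).
    ranks
        Canonical atom ranks inherited from the standardized parent
        molecule; used only as a reproducible tie-break (e.g. the
        "first identified" longest side chain).  Preserved by
        :meth:`subgraph`.
    """

    labels: list
    bonds: dict
    charges: list = field(default_factory=list)
    ranks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not self.charges:
            self.charges = [0] * n
        if not self.ranks:
            self.ranks = list(range(n))
        for (i, j), order in self.bonds.items():
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references missing atom")
            if i > j:
                raise ValueError("bond indices must be stored as (i<j)")
            if order not in (1, 2, 3, "ar") and order is not ANY:
                raise ValueError(f"invalid bond order {order!r}")

    # ------------------------------------------------------------------ #
    # basic accessors
    # ------------------------------------------------------------------ #
    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @cached_property
    def adjacency(self) -> list:
        adj: list = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def neighbors(self, i: int) -> list:
        return self.adjacency[i]

    def degree(self, i: int) -> int:
        return len(self.adjacency[i])

    def bond_order(self, i: int, j: int):
        return self.bonds[(i, j) if i < j else (j, i)]

    def is_abstract(self) -> bool:
        """True if any label or order is a wildcard."""
        return any(lb is ANY for lb in self.labels) or any(
            o is ANY for o in self.bonds.values()
        )

    # ------------------------------------------------------------------ #
    # ring perception (networkx; no chemistry involved)
    # ------------------------------------------------------------------ #
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, lb in enumerate(self.labels):
            g.add_node(i, label=lb, charge=self.charges[i])
        for (i, j), order in self.bonds.items():
            g.add_edge(i, j, order=order)
        return g

    @cached_property
    def _nx(self) -> nx.Graph:
        return self.to_networkx()

    @cached_property
    def ring_bonds(self) -> frozenset:
        """Bonds that lie on at least one cycle (non-bridge edges)."""
        g = self._nx
        bridges = {frozenset(e) for e in nx.bridges(g)} if g.number_of_edges() else set()
        return frozenset(
            (i, j) for (i, j) in self.bonds if frozenset((i, j)) not in bridges
        )

    @cached_property
    def ring_atoms(self) -> frozenset:
        return frozenset(i for b in self.ring_bonds for i in b)

    @cached_property
    def sssr(self) -> tuple:
        """Smallest set of smallest rings, as tuples of atom indices."""
        cycles = nx.minimum_cycle_basis(self._nx)
        return tuple(tuple(sorted(c)) for c in sorted(cycles, key=lambda c: (len(c), sorted(c))))

    @property
    def ring_count(self) -> int:
        return len(self.sssr)

    def connected_components(self) -> list:
        return [sorted(c) for c in nx.connected_components(self._nx)]

    # ------------------------------------------------------------------ #
    # surgery
    # ------------------------------------------------------------------ #
    def subgraph(self, atoms: Iterable) -> "MolecularGraph":
        """Induced subgraph on ``atoms`` (original order preserved)."""
        keep = sorted(set(atoms))
        remap = {old: new for new, old in enumerate(keep)}
        bonds = {
            (remap[i], remap[j]): order
            for (i, j), order in self.bonds.items()
            if i in remap and j in remap
        }
        return MolecularGraph(
            labels=[self.labels[i] for i in keep],
            bonds=bonds,
            charges=[self.charges[i] for i in keep],
            ranks=[self.ranks[i] for i in keep],
        )

    def remove_atoms(self, atoms: Iterable) -> "MolecularGraph":
        drop = set(atoms)
        return self.subgraph(i for i in range(self.n_atoms) if i not in drop)

    def remove_bond(self, i: int, j: int) -> "MolecularGraph":
        key = (i, j) if i < j else (j, i)
        bonds = {b: o for b, o in self.bonds.items() if b != key}
        return MolecularGraph(
            labels=list(self.labels),
            bonds=bonds,
            charges=list(self.charges),
            ranks=list(self.ranks),
        )

    # ------------------------------------------------------------------ #
    # RDKit conversion and canonical identity
    # ------------------------------------------------------------------ #
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, ranks: Sequence | None = None) -> "MolecularGraph":
        labels = []
        charges = []
        for atom in mol.GetAtoms():
            labels.append(ANY if atom.GetAtomicNum() == 0 else atom.GetSymbol())
            charges.append(atom.GetFormalCharge())
        bonds = {}
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i > j:
                i, j = j, i
            bt = bond.GetBondType()
            bonds[(i, j)] = ANY if bt == Chem.BondType.UNSPECIFIED else _FROM_RD_ORDER[bt]
        if ranks is None:
            ranks = list(Chem.CanonicalRankAtoms(mol))
        return cls(labels=labels, bonds=bonds, charges=charges, ranks=list(ranks))

    def to_rdkit(self) -> Chem.Mol:
        """Heavy-atom RDKit molecule; wildcards become dummies/unspecified.

        Implicit hydrogens are disabled so that identity depends only on
        the explicit graph, never on valence models (pruned scaffolds are
        not required to be valence-valid molecules).
        """
        rw = Chem.RWMol()
        aromatic_atoms = set()
        for (i, j), order in self.bonds.items():
            if order == "ar":
                aromatic_atoms.add(i)
                aromatic_atoms.add(j)
        for idx, lb in enumerate(self.labels):
            atom = Chem.Atom(0 if lb is ANY else lb)
            atom.SetFormalCharge(self.charges[idx])
            atom.SetNoImplicit(True)
            if idx in aromatic_atoms and lb is not ANY:
                atom.SetIsAromatic(True)
            elif idx in aromatic_atoms:
                atom.SetIsAromatic(True)
            rw.AddAtom(atom)
        for (i, j), order in self.bonds.items():
            bt = Chem.BondType.UNSPECIFIED if order is ANY else _RD_ORDER[order]
            rw.AddBond(i, j, bt)
            if order == "ar":
                rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
        mol = rw.GetMol()
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
        return mol

    def key(self) -> str:
        """Canonical string key: equal for isomorphic graphs.

        Concrete and abstracted graphs share one keying scheme — the
        RDKit canonical SMILES of the heavy-atom graph (wildcard atoms
        written as ``*``, wildcard bonds as ``~``) — so a benzene
        wireframe and a cyclohexane wireframe collapse to the same key
        while their frameworks stay distinct.
        """
        if self.n_atoms == 0:
            return ""
        return Chem.MolToSmiles(self.to_rdkit())

    # ------------------------------------------------------------------ #
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularGraph):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())
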