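"""Generic (any-atom / any-bond) substructure matching.

Abstracted representations double as wildcard substructure queries: a
wildcard atom matches any element, a wildcard bond matches any order, a
concrete label must match exactly.  One extra constraint keeps skeleton
queries meaningful: a query bond that lies in a ring must map onto a ring
bond of the target, so a six-membered cyclic skeleton retrieves rings and
never hexyl chains.

Matching is performed by RDKit's substructure engine on heavy-atom
graphs; queries are assembled programmatically from SMARTS atom and bond
primitives.
"""

from __future__ import annotations

from rdkit import Chem

from .graph import ANY, MolecularGraph

__all__ = ["generic_match", "match_set", "to_smarts"]

_ORDER_SMARTS = {1: "-", 2: "=", 3: "#", "ar": ":"}


def _query_mol(query: MolecularGraph) -> Chem.Mol:
    rw = Chem.RWMol()
    for idx, label in enumerate(query.labels):
        if label is ANY:
            rw.AddAtom(Chem.AtomFromSmarts("*"))
        else:
            num = Chem.GetPeriodicTable().GetAtomicNumber(label)
            rw.AddAtom(Chem.AtomFromSmarts(f"[#{num}]"))
    ring_bonds = query.ring_bonds
    for (i, j), order in query.bonds.items():
        rw.AddBond(i, j, Chem.BondType.SINGLE)
        token = "~" if order is ANY else _ORDER_SMARTS[order]
        if (i, j) in ring_bonds and order != "ar":  # ':' already implies a ring
            token = f"{token}&@"
        rw.ReplaceBond(rw.GetMol().GetNumBonds() - 1, Chem.BondFromSmarts(token))
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def to_smarts(query: MolecularGraph) -> str:
    """SMARTS export of a wildcard query (``*`` atoms, ``~`` bonds)."""
    return Chem.MolToSmarts(_query_mol(query))


def _target_mol(target) -> Chem.Mol:
    if isinstance(target, MolecularGraph):
        return target.to_rdkit()
    graph = getattr(target, "graph", None)
    if graph is not None:
        return graph.to_rdkit()
    return target  # assume an RDKit mol


def generic_match(query: MolecularGraph, target):
    """Test whether ``query`` generically embeds into ``target``.

    ``target`` may be a :class:`MolecularGraph`, a Compound or an RDKit
    molecule.  Returns ``(matched, embedding)`` where ``embedding`` maps
    query atom index -> target atom index for the first witness found
    (``None`` when there is no match).
    """
    q = _query_mol(query)
    t = _target_mol(target)
    hit = t.GetSubstructMatch(q)
    if not hit and q.GetNumAtoms() > 0:
        return False, None
    return True, dict(enumerate(hit))


def match_set(query: MolecularGraph, compounds):
    """Ids of all compounds generically matched, in stable input order."""
    out = []
    for comp in compounds:
        ok, _ = generic_match(query, comp)
        if ok:
            out.append(comp.compound_id)
    return out
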