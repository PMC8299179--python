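"""Exhaustive, progressive fragmentation of scaffold-level graphs.

Three unbiased rules disassemble any representation (scaffold, framework
or wireframe alike — the rules are pure graph surgery):

* chain removal — every acyclic linker between ring systems is deleted
  (its internal atoms removed, its bridge bonds cut) and each remaining
  ring-containing component becomes a child;
* fused-ring opening — for every ring of a multi-ring system, the atoms
  exclusive to that ring are deleted, opening the system; shared atoms
  and bonds are retained (spiro systems are handled identically, the
  shared atom surviving);
* internal-ring removal — a whole ring system whose deletion splits the
  remainder into two or more ring-containing pieces is removed, dangling
  linker stubs pruned back to the nearest ring.

Applied progressively (children of children) the rules produce a closed,
deduplicated fragment set; every child has strictly fewer atoms than its
originator, so the closure terminates.  Fragments keep at least one ring:
pure-chain leftovers carry no clustering information and are discarded.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .graph import ANY, MolecularGraph

__all__ = [
    "FragmentationRule",
    "FragmentRecord",
    "remove_internal_chains",
    "open_fused_rings",
    "remove_internal_rings",
    "enumerate_fragments",
]


class FragmentationRule(Enum):
    CHAIN_REMOVAL = "chain_removal"
    FUSED_RING_OPENING = "fused_ring_opening"
    INTERNAL_RING_REMOVAL = "internal_ring_removal"


@dataclass(frozen=True)
class FragmentRecord:
    """A fragment, its generating rule, depth and immediate originator."""

    graph: MolecularGraph = field(compare=False)
    key: str
    rule: FragmentationRule = field(compare=False)
    depth: int = field(compare=False)
    originator_key: str = field(compare=False)


def _has_ring(graph: MolecularGraph) -> bool:
    return bool(graph.ring_bonds)


def _ring_components(graph: MolecularGraph, atoms=None):
    """Connected components (of the induced subgraph) that contain a ring."""
    sub = graph if atoms is None else graph.subgraph(atoms)
    out = []
    for comp in sub.connected_components():
        piece = sub.subgraph(comp)
        if _has_ring(piece):
            out.append(piece)
    return out


def _prune_stubs(graph: MolecularGraph) -> MolecularGraph:
    """Prune dangling order-1/wildcard terminals back to the nearest ring.

    Terminal atoms held by a bond of order > 1 are decorations, not linker
    stubs, and survive.
    """
    kept = set(range(graph.n_atoms))
    changed = True
    while changed:
        changed = False
        for i in sorted(kept):
            nbrs = [j for j in graph.neighbors(i) if j in kept]
            if len(nbrs) == 1 and graph.bond_order(i, nbrs[0]) in (1, ANY):
                kept.discard(i)
                changed = True
            elif len(nbrs) == 0 and len(kept) > 1:
                kept.discard(i)
                changed = True
    return graph.subgraph(kept)


# ---------------------------------------------------------------------- #
# rule 1: internal chain removal
# ---------------------------------------------------------------------- #
def _linkers(graph: MolecularGraph):
    """Internal chains: each is (atom set to delete, bond set to cut).

    A linker is either a connected set of non-ring atoms whose removal
    separates at least two ring-containing pieces, or a direct non-ring
    bond between two ring atoms.
    """
    ring_atoms = graph.ring_atoms
    out = []
    non_ring = [i for i in range(graph.n_atoms) if i not in ring_atoms]
    g = graph.to_networkx()
    for comp in nx.connected_components(g.subgraph(non_ring)) if non_ring else []:
        comp = set(comp)
        rest = [i for i in range(graph.n_atoms) if i not in comp]
        pieces = _ring_components(graph, rest)
        if len(pieces) >= 2:
            out.append((comp, set()))
    for (i, j), order in graph.bonds.items():
        if (i, j) not in graph.ring_bonds and i in ring_atoms and j in ring_atoms:
            out.append((set(), {(i, j)}))
    return out


def remove_internal_chains(graph: MolecularGraph):
    """Children obtained by deleting one internal linker at a time."""
    children = {}
    for atoms, cut_bonds in _linkers(graph):
        g = graph
        for (i, j) in cut_bonds:
            g = g.remove_bond(i, j)
        if atoms:
            g = g.remove_atoms(atoms)
        for piece in _ring_components(g):
            children[piece.key()] = piece
    return set(children.values())


# ---------------------------------------------------------------------- #
# rule 2: fused ring opening
# ---------------------------------------------------------------------- #
def _ring_systems(graph: MolecularGraph):
    """Groups of SSSR rings sharing at least one atom (fused or spiro)."""
    rings = [set(r) for r in graph.sssr]
    systems = []
    for ring in rings:
        merged = [ring]
        rest = []
        for sys_ in systems:
            if any(ring & r for r in sys_):
                merged.extend(sys_)
            else:
                rest.append(sys_)
        systems = rest + [merged]
    return systems


def open_fused_rings(graph: MolecularGraph):
    """Children obtained by deleting one ring's exclusive atoms."""
    children = {}
    for system in _ring_systems(graph):
        if len(system) < 2:
            continue
        for k, ring in enumerate(system):
            others = set().union(*(r for m, r in enumerate(system) if m != k))
            exclusive = ring - others
            if not exclusive:
                continue
            g = graph.remove_atoms(exclusive)
            for piece in _ring_components(g):
                piece = _prune_stubs(piece)
                if _has_ring(piece):
                    children[piece.key()] = piece
    return set(children.values())


# ---------------------------------------------------------------------- #
# rule 3: internal ring removal
# ---------------------------------------------------------------------- #
def remove_internal_rings(graph: MolecularGraph):
    """Children obtained by deleting a whole internal ring system."""
    children = {}
    for system in _ring_systems(graph):
        atoms = set().union(*system)
        g = graph.remove_atoms(atoms)
        pieces = [_prune_stubs(p) for p in _ring_components(g)]
        pieces = [p for p in pieces if _has_ring(p)]
        if len(pieces) >= 2:
            for piece in pieces:
                children[piece.key()] = piece
    return set(children.values())


_RULES = (
    (FragmentationRule.CHAIN_REMOVAL, remove_internal_chains),
    (FragmentationRule.FUSED_RING_OPENING, open_fused_rings),
    (FragmentationRule.INTERNAL_RING_REMOVAL, remove_internal_rings),
)


@dataclass
class FragmentationResult:
    """Closure of the three rules; ``truncated`` flags a hit size cap."""

    records: list
    truncated: bool = False

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def enumerate_fragments(
    graph: MolecularGraph,
    max_depth: int | None = None,
    max_fragments: int = 10000,
) -> FragmentationResult:
    """Breadth-first closure of the three rules up to ``max_depth``.

    ``max_depth`` defaults to the ring count of the input (full closure
    for ordinary scaffolds; a finite cap for pathological fused cages).
    Children are deduplicated by canonical key; each record keeps the
    rule, depth and immediate originator key of its first discovery.
    """
    if max_depth is None:
        max_depth = max(graph.ring_count, 1)
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    seen = {graph.key()}
    records = []
    truncated = False
    frontier = deque([(graph, 0)])
    while frontier:
        parent, depth = frontier.popleft()
        if depth >= max_depth:
            continue
        for rule, fn in _RULES:
            for child in fn(parent):
                key = child.key()
                if key in seen:
                    continue
                if len(records) >= max_fragments:
                    truncated = True
                    continue
                seen.add(key)
                rec = FragmentRecord(
                    graph=child,
                    key=key,
                    rule=rule,
                    depth=depth + 1,
                    originator_key=parent.key(),
                )
                records.append(rec)
                frontier.append((child, depth + 1))
    return FragmentationResult(records=records, truncated=truncated)
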