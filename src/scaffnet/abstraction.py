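"""The nine correlated molecular representations.

Two orthogonal axes span a 3x3 grid of representations:

* decoration — how much side-chain context is kept on the ring system:
  ``basic`` (none: iteratively prune every terminal atom), ``decorated``
  (terminal atoms attached by a bond of order > 1, e.g. carbonyl or
  sulfonyl oxygens, are protected) and ``augmented`` (additionally the
  single longest carbon-terminated side chain is retained);
* abstraction — how much chemistry is kept on that pruned graph:
  ``scaffold`` (elements and bond orders), ``framework`` (any-atom,
  bond orders kept) and ``wireframe`` (any-atom, any-bond: the cyclic
  skeleton).

The grid commutes: the wireframe of a framework equals the wireframe of
the scaffold it came from, and every abstraction step is a deterministic
function of the less abstract representation, so molecules that share a
key at one grid point share keys at every more abstract point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .graph import ANY, MolecularGraph

__all__ = [
    "Decoration",
    "Abstraction",
    "RepresentationKind",
    "NINE_KINDS",
    "RepresentationSet",
    "NoRingError",
    "basic_scaffold",
    "decorated_scaffold",
    "augmented_scaffold",
    "to_framework",
    "to_wireframe",
    "nine_representations",
    "ring_count",
]


class NoRingError(ValueError):
    """The molecule is acyclic: no scaffold representation exists."""


class Decoration(Enum):
    # enumeration order = increasing abstraction (more pruning)
    AUGMENTED = 0
    DECORATED = 1
    BASIC = 2


class Abstraction(Enum):
    SCAFFOLD = 0
    FRAMEWORK = 1
    WIREFRAME = 2


@dataclass(frozen=True, order=True)
class RepresentationKind:
    """One coordinate of the 3x3 grid.

    ``abstractness_rank`` totally orders the grid for "least abstract"
    tie-breaking: the abstraction axis dominates (it destroys element and
    bond information) and the decoration axis refines (it only prunes
    side-chain context).
    """

    decoration: Decoration = field(compare=False)
    abstraction: Abstraction = field(compare=False)
    abstractness_rank: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "abstractness_rank",
            self.abstraction.value * 3 + self.decoration.value,
        )

    @property
    def column_name(self) -> str:
        return f"{self.decoration.name.lower()}_{self.abstraction.name.lower()}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.column_name


NINE_KINDS = tuple(
    sorted(
        (RepresentationKind(d, a) for a in Abstraction for d in Decoration),
        key=lambda k: k.abstractness_rank,
    )
)
_KIND_BY_NAME = {k.column_name: k for k in NINE_KINDS}


def kind_by_name(name: str) -> RepresentationKind:
    return _KIND_BY_NAME[name]


# ---------------------------------------------------------------------- #
# pruning primitives (operate on kept-index sets of one graph)
# ---------------------------------------------------------------------- #
def _prune_terminals(graph: MolecularGraph, removable) -> set:
    """Iteratively delete degree-1 atoms for which ``removable`` is true.

    Returns the set of kept atom indices.  ``removable(atom, neighbor)``
    decides whether a currently-terminal atom may be pruned.
    """
    kept = set(range(graph.n_atoms))
    changed = True
    while changed:
        changed = False
        for i in sorted(kept):
            nbrs = [j for j in graph.neighbors(i) if j in kept]
            if len(nbrs) == 1 and removable(i, nbrs[0]):
                kept.discard(i)
                changed = True
            elif len(nbrs) == 0 and graph.n_atoms > 1 and removable(i, None):
                # isolated leftover of a fully pruned branch
                kept.discard(i)
                changed = True
    return kept


def _basic_keep(graph: MolecularGraph) -> set:
    return _prune_terminals(graph, lambda i, j: True)


def _decorated_keep(graph: MolecularGraph) -> set:
    def removable(i, j):
        if j is None:
            return True
        return graph.bond_order(i, j) in (1, ANY)

    return _prune_terminals(graph, removable)


def _require_rings(graph: MolecularGraph) -> None:
    if not graph.ring_bonds:
        raise NoRingError("graph contains no ring")


def basic_scaffold(graph: MolecularGraph) -> MolecularGraph:
    """Bemis-Murcko scaffold: iteratively delete every terminal atom.

    What remains is exactly the ring systems and the acyclic linkers
    connecting them.
    """
    _require_rings(graph)
    return graph.subgraph(_basic_keep(graph))


def decorated_scaffold(graph: MolecularGraph) -> MolecularGraph:
    """Scaffold in which terminal atoms bonded by order > 1 survive.

    Pruning of order-1 terminals iterates to a fixpoint, so a protected
    terminal (e.g. a sulfonyl oxygen) also anchors the atoms on the path
    back to the ring system.
    """
    _require_rings(graph)
    return graph.subgraph(_decorated_keep(graph))


def _augmented_keep(graph: MolecularGraph) -> set:
    # step 1: iteratively remove terminal non-carbon atoms bonded by order 1
    def removable(i, j):
        if graph.labels[i] == "C":
            return False
        if j is None:
            return True
        return graph.bond_order(i, j) in (1, ANY)

    step1 = _prune_terminals(graph, removable)

    # decorated baseline within the step-1 graph (indices unchanged)
    decorated = _decorated_keep_within(graph, step1)
    side = step1 - decorated
    if not side:
        return decorated

    # candidate chains: simple paths inside a side-chain component, starting
    # at an atom attached to the decorated baseline and ending on a carbon
    best = None  # (length, rank_sequence, path_atoms)
    adj = {i: [j for j in graph.neighbors(i) if j in side] for i in side}
    attach = [i for i in side if any(j in decorated for j in graph.neighbors(i))]

    def extend(path, visited):
        nonlocal best
        last = path[-1]
        if graph.labels[last] == "C":
            ranks = tuple(graph.ranks[a] for a in path)
            cand = (-len(path), ranks, tuple(path))
            if best is None or cand < best:
                best = cand
        for nxt in sorted(adj[last], key=lambda a: graph.ranks[a]):
            if nxt not in visited:
                extend(path + [nxt], visited | {nxt})

    for start in sorted(attach, key=lambda a: graph.ranks[a]):
        extend([start], {start})

    if best is None:
        return decorated
    return decorated | set(best[2])


def _decorated_keep_within(graph: MolecularGraph, allowed: set) -> set:
    kept = set(allowed)
    changed = True
    while changed:
        changed = False
        for i in sorted(kept):
            nbrs = [j for j in graph.neighbors(i) if j in kept]
            if len(nbrs) == 1 and graph.bond_order(i, nbrs[0]) in (1, ANY):
                kept.discard(i)
                changed = True
            elif len(nbrs) == 0 and len(allowed) > 1:
                kept.discard(i)
                changed = True
    return kept


def augmented_scaffold(graph: MolecularGraph) -> MolecularGraph:
    """Decorated scaffold plus the single longest retained side chain.

    Step 1 iteratively removes terminal non-carbon atoms attached by an
    order-1 bond.  Step 2 enumerates, over what remains outside the
    decorated baseline, every simple side-chain path that starts at an
    attachment point and ends on a carbon atom; the longest is retained.
    Equal-length candidates are broken by the lexicographically smallest
    canonical-rank sequence ("first identified" made order-independent).
    If step 1 leaves no side-chain atoms, decorated and augmented
    coincide.
    """
    _require_rings(graph)
    return graph.subgraph(_augmented_keep(graph))


# ---------------------------------------------------------------------- #
# abstraction axis
# ---------------------------------------------------------------------- #
def to_framework(graph: MolecularGraph) -> MolecularGraph:
    """Replace every atom label by the wildcard; bond orders kept."""
    return MolecularGraph(
        labels=[ANY] * graph.n_atoms,
        bonds=dict(graph.bonds),
        charges=[0] * graph.n_atoms,
        ranks=list(graph.ranks),
    )


def strip_bond_orders(graph: MolecularGraph) -> MolecularGraph:
    """Keep element labels, wildcard every bond order.

    Not part of the 3x3 grid: it is the complementary single-axis
    abstraction (atom type retained, bond type dropped) used when
    benchmarking cluster counts of the classical representations.
    """
    return MolecularGraph(
        labels=list(graph.labels),
        bonds={b: ANY for b in graph.bonds},
        charges=list(graph.charges),
        ranks=list(graph.ranks),
    )


def to_wireframe(graph: MolecularGraph) -> MolecularGraph:
    """Cyclic skeleton: wildcard atoms *and* wildcard bonds."""
    return MolecularGraph(
        labels=[ANY] * graph.n_atoms,
        bonds={b: ANY for b in graph.bonds},
        charges=[0] * graph.n_atoms,
        ranks=list(graph.ranks),
    )


def ring_count(graph: MolecularGraph) -> int:
    """Number of smallest rings (SSSR cardinality)."""
    return graph.ring_count


_SCAFFOLD_FN = {
    Decoration.BASIC: basic_scaffold,
    Decoration.DECORATED: decorated_scaffold,
    Decoration.AUGMENTED: augmented_scaffold,
}
_ABSTRACT_FN = {
    Abstraction.SCAFFOLD: lambda g: g,
    Abstraction.FRAMEWORK: to_framework,
    Abstraction.WIREFRAME: to_wireframe,
}


@dataclass
class RepresentationSet:
    """All nine representations (graph + key) of one molecule."""

    compound_id: str
    graphs: dict
    keys: dict
    ring_count: int

    def kinds(self):
        return NINE_KINDS

    def key_at(self, decoration: Decoration, abstraction: Abstraction) -> str:
        return self.keys[RepresentationKind(decoration, abstraction)]


def nine_representations(compound) -> RepresentationSet:
    """Compute the full 3x3 grid for a standardized compound.

    Raises :class:`NoRingError` (naming the compound) on acyclic input.
    """
    graph = compound.graph
    try:
        _require_rings(graph)
    except NoRingError:
        raise NoRingError(f"compound {compound.compound_id!r} contains no ring") from None
    graphs = {}
    keys = {}
    scaffolds = {d: fn(graph) for d, fn in _SCAFFOLD_FN.items()}
    for d, scaf in scaffolds.items():
        for a, fn in _ABSTRACT_FN.items():
            kind = RepresentationKind(d, a)
            g = fn(scaf)
            graphs[kind] = g
            keys[kind] = g.key()
    return RepresentationSet(
        compound_id=compound.compound_id,
        graphs=graphs,
        keys=keys,
        ring_count=scaffolds[Decoration.BASIC].ring_count,
    )
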