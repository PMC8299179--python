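"""Oriented framework network construction.

Nodes are molecules, deduplicated frameworks (one node per unique
canonical key, labelled with the least abstract representation kind that
produced it) and, optionally, fragments.  Edges point in the direction of
increasing abstraction along the 3x3 representation grid (adjacent steps
on each axis, collapsed whenever the two adjacent representations share a
key), from a molecule to its least abstract representation (membership),
and from an originator to its fragments.  The non-membership subgraph is
a DAG: every edge strictly abstracts or strictly shrinks.

Tables are plain pandas DataFrames in the dialect Cytoscape's table
import expects (``source,target,interaction`` for edges, attributes keyed
on ``key``).
"""

from __future__ import annotations

from collections import defaultdict

import networkx as nx
import pandas as pd

from .abstraction import Abstraction, Decoration, NINE_KINDS, RepresentationKind

__all__ = [
    "NODE_COLUMNS",
    "EDGE_COLUMNS",
    "build_framework_network",
    "connected_components",
    "extend_with_fragments",
    "membership_table",
]

NODE_COLUMNS = [
    "key",
    "node_class",
    "kind",
    "structure",
    "n_molecules",
    "molecule_ids",
]
EDGE_COLUMNS = ["source", "target", "edge_class"]

# grid adjacency: one abstraction step along a single axis
_GRID_STEPS = []
for d in Decoration:
    for a in Abstraction:
        if a.value < 2:
            _GRID_STEPS.append(
                (RepresentationKind(d, a), RepresentationKind(d, Abstraction(a.value + 1)))
            )
        if d.value < 2:
            _GRID_STEPS.append(
                (RepresentationKind(d, a), RepresentationKind(Decoration(d.value + 1), a))
            )


def build_framework_network(rep_sets, dense_membership: bool = False):
    """Assemble (NodeTable, EdgeTable) from per-molecule representations.

    One MOLECULE node per compound (keyed by compound id), one FRAMEWORK
    node per unique structure key.  With ``dense_membership`` every
    distinct representation of a molecule receives a membership edge
    instead of only the least abstract one.
    """
    frame_kind = {}  # key -> least abstract RepresentationKind
    frame_struct = {}
    members = defaultdict(set)  # key -> compound ids
    edges = set()
    mol_rows = []
    for rs in rep_sets:
        distinct = {}  # key -> least abstract kind for this molecule
        for kind in NINE_KINDS:  # ordered by increasing abstractness
            key = rs.keys[kind]
            members[key].add(rs.compound_id)
            if key not in frame_kind or kind.abstractness_rank < frame_kind[key].abstractness_rank:
                frame_kind[key] = kind
                frame_struct[key] = key
            if key not in distinct:
                distinct[key] = kind
        for src_kind, dst_kind in _GRID_STEPS:
            s, t = rs.keys[src_kind], rs.keys[dst_kind]
            if s != t:
                edges.add((s, t, "ABSTRACTION"))
        mol_rows.append(
            {
                "key": rs.compound_id,
                "node_class": "MOLECULE",
                "kind": "molecule",
                "structure": "",
                "n_molecules": 1,
                "molecule_ids": (rs.compound_id,),
            }
        )
        if dense_membership:
            for key in distinct:
                edges.add((rs.compound_id, key, "MEMBERSHIP"))
        else:
            least = min(distinct.items(), key=lambda kv: kv[1].abstractness_rank)[0]
            edges.add((rs.compound_id, least, "MEMBERSHIP"))

    frame_rows = [
        {
            "key": key,
            "node_class": "FRAMEWORK",
            "kind": frame_kind[key].column_name,
            "structure": frame_struct[key],
            "n_molecules": len(members[key]),
            "molecule_ids": tuple(sorted(members[key])),
        }
        for key in sorted(frame_kind)
    ]
    nodes = pd.DataFrame(mol_rows + frame_rows, columns=NODE_COLUMNS)
    edge_rows = sorted(edges)
    edge_df = pd.DataFrame(edge_rows, columns=EDGE_COLUMNS)
    return nodes, edge_df


def membership_table(rep_sets) -> pd.DataFrame:
    """Long (compound_id, representation_kind, key) table."""
    rows = [
        {
            "compound_id": rs.compound_id,
            "representation_kind": kind.column_name,
            "key": rs.keys[kind],
        }
        for rs in rep_sets
        for kind in NINE_KINDS
    ]
    return pd.DataFrame(rows, columns=["compound_id", "representation_kind", "key"])


def _as_nx(nodes: pd.DataFrame, edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes["key"])
    g.add_edges_from(zip(edges["source"], edges["target"]))
    return g


def connected_components(nodes: pd.DataFrame, edges: pd.DataFrame):
    """Undirected component count and per-node labels over all edges."""
    g = _as_nx(nodes, edges)
    labels = {}
    for idx, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            labels[node] = idx
    return len(set(labels.values())), labels


def extend_with_fragments(nodes: pd.DataFrame, edges: pd.DataFrame, fragment_records):
    """Merge fragment records into the network.

    A fragment whose key equals an existing framework node reuses that
    node; otherwise a FRAGMENT node is created.  FRAGMENTATION edges run
    originator -> fragment.  Fragment-only nodes inherit, transitively,
    the union of the molecule memberships of every superframework (every
    node from which they can be reached by fragmentation edges), which is
    the molecule set their enrichment is computed on.
    """
    known = set(nodes["key"])
    frag_edges = set()
    frag_nodes = {}
    for rec in fragment_records:
        if rec.originator_key not in known and rec.originator_key not in frag_nodes:
            raise KeyError(
                f"fragment originator {rec.originator_key!r} is not a network node"
            )
        if rec.key not in known and rec.key not in frag_nodes:
            frag_nodes[rec.key] = {
                "key": rec.key,
                "node_class": "FRAGMENT",
                "kind": rec.rule.value,
                "structure": rec.key,
                "n_molecules": 0,
                "molecule_ids": (),
            }
        if rec.key != rec.originator_key:
            frag_edges.add((rec.originator_key, rec.key, "FRAGMENTATION"))

    new_nodes = pd.concat(
        [nodes, pd.DataFrame(list(frag_nodes.values()), columns=NODE_COLUMNS)],
        ignore_index=True,
    )
    new_edges = pd.concat(
        [edges, pd.DataFrame(sorted(frag_edges), columns=EDGE_COLUMNS)],
        ignore_index=True,
    ).drop_duplicates(ignore_index=True)

    # propagate molecule memberships originator -> fragment, transitively
    dg = nx.DiGraph()
    dg.add_nodes_from(new_nodes["key"])
    for s, t, c in new_edges.itertuples(index=False):
        if c == "FRAGMENTATION":
            dg.add_edge(s, t)
    mols = {
        row.key: set(row.molecule_ids)
        for row in new_nodes.itertuples(index=False)
    }
    for node in nx.topological_sort(dg):
        for succ in dg.successors(node):
            mols[succ] |= mols[node]
    new_nodes = new_nodes.assign(
        molecule_ids=[tuple(sorted(mols[k])) for k in new_nodes["key"]],
    )
    new_nodes["n_molecules"] = new_nodes["molecule_ids"].map(len)
    return new_nodes, new_edges
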