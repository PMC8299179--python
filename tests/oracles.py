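"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and built on networkx primitives,
never on the code paths under test.
"""

from __future__ import annotations

import networkx as nx

from scaffnet.graph import ANY, MolecularGraph


def graphs_isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Exact isomorphism under (label, charge) / order equality."""
    def n_match(x, y):
        lx, ly = x["label"], y["label"]
        same_label = (lx is ANY and ly is ANY) or (lx is not ANY and lx == ly)
        return same_label and x["charge"] == y["charge"]

    def e_match(x, y):
        ox, oy = x["order"], y["order"]
        return (ox is ANY and oy is ANY) or (ox is not ANY and ox == oy)

    return nx.is_isomorphic(a.to_networkx(), b.to_networkx(),
                            node_match=n_match, edge_match=e_match)


def generic_embeds(query: MolecularGraph, target: MolecularGraph) -> bool:
    """Wildcard subgraph monomorphism with the ring-bond constraint.

    A query wildcard matches anything; a concrete query label/order must
    equal the target's; a query bond on a cycle must map to a target bond
    on a cycle.
    """
    qg, tg = query.to_networkx(), target.to_networkx()
    q_ring = {frozenset(b) for b in query.ring_bonds}
    t_ring = {frozenset(b) for b in target.ring_bonds}
    for e in qg.edges:
        qg.edges[e]["in_ring"] = frozenset(e) in q_ring
    for e in tg.edges:
        tg.edges[e]["in_ring"] = frozenset(e) in t_ring

    def n_match(t, q):  # GraphMatcher passes (target_attrs, query_attrs)
        return q["label"] is ANY or q["label"] == t["label"]

    def e_match(t, q):
        order_ok = q["order"] is ANY or q["order"] == t["order"]
        ring_ok = (not q["in_ring"]) or t["in_ring"]
        return order_ok and ring_ok

    gm = nx.algorithms.isomorphism.GraphMatcher(
        tg, qg, node_match=n_match, edge_match=e_match
    )
    return gm.subgraph_is_monomorphic()


def component_count_union_find(node_keys, edge_pairs) -> int:
    """Classic union-find, independent of networkx components."""
    parent = {k: k for k in node_keys}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edge_pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(k) for k in node_keys})


def ef_recount(molecule_ids, activity_map):
    """Direct evaluation of the enrichment-factor formula."""
    ids = set(molecule_ids)
    mf_a = sum(1 for i in ids if activity_map.get(i) is True)
    mf_i = sum(1 for i in ids if activity_map.get(i) is False)
    t_a = sum(1 for v in activity_map.values() if v is True)
    t_i = sum(1 for v in activity_map.values() if v is False)
    if mf_a + mf_i == 0:
        return 0.0
    return (mf_a / (mf_a + mf_i)) / (t_a / (t_a + t_i))


def closure_by_random_order(graph: MolecularGraph, rules, rng, max_depth: int):
    """Fragment closure recomputed with rules applied in shuffled order.

    Deduplication is done by brute-force isomorphism, not canonical keys.
    """
    classes = []  # representatives

    def seen(g):
        return any(graphs_isomorphic(g, rep) for rep in classes)

    frontier = [(graph, 0)]
    while frontier:
        parent, depth = frontier.pop(rng.randrange(len(frontier)))
        if depth >= max_depth:
            continue
        shuffled = list(rules)
        rng.shuffle(shuffled)
        for rule in shuffled:
            children = list(rule(parent))
            rng.shuffle(children)
            for child in children:
                if graphs_isomorphic(child, graph) or seen(child):
                    continue
                classes.append(child)
                frontier.append((child, depth + 1))
    return classes
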