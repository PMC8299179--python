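"""Activity classification and enrichment factors.

A node's enrichment factor compares the active fraction among the
molecules carrying that framework with the active fraction of the whole
library::

    EF = MF_ratio / Total_ratio
    MF_ratio    = MF_actives / (MF_actives + MF_inactives)
    Total_ratio = Total_actives / (Total_actives + Total_inactives)

EF > 1 marks an activity-enriched chemotype; EF is bounded above by
1 / Total_ratio.  Percent-inhibition values are bucketed into five
classes (inactive / weak / moderate / strong / very strong); a molecule
is *active* when it falls in the moderate class or above.  When the same
structure key is reached from several representation kinds, the highest
per-kind EF is retained on the deduplicated node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ActivityScheme",
    "DEFAULT_SCHEME",
    "EnrichmentResult",
    "NoActivesError",
    "classify",
    "activity_map_from_compounds",
    "enrichment_factor",
    "annotate_nodes",
    "filter_ef_zero",
    "superframework_ef",
]


class NoActivesError(ValueError):
    """Total_ratio is zero: EF (active fraction quotient) is undefined."""


@dataclass(frozen=True)
class ActivityScheme:
    """Percent-inhibition class boundaries.

    Boundaries are assigned upward (a value on a boundary joins the upper
    class) except the last one: "very strong" is strictly above its
    boundary, as conventionally printed (> 80).
    """

    boundaries: tuple = (19.0, 33.0, 50.0, 80.0)
    labels: tuple = ("inactive", "weak", "moderate", "strong", "very strong")
    active_classes: frozenset = frozenset({"moderate", "strong", "very strong"})

    def __post_init__(self):
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need one more label than boundaries")


DEFAULT_SCHEME = ActivityScheme()


def classify(activity_value, scheme: ActivityScheme = DEFAULT_SCHEME):
    """Bucket a percent-inhibition value; returns ``(label, is_active)``.

    ``None``/NaN values are unclassified: ``(None, None)``; they are
    excluded from every enrichment denominator.
    """
    if activity_value is None or (
        isinstance(activity_value, float) and math.isnan(activity_value)
    ):
        return None, None
    v = float(activity_value)
    *upward, last = scheme.boundaries
    if v > last:
        label = scheme.labels[-1]
    else:
        label = scheme.labels[0]
        for k, b in enumerate(upward):
            if v >= b:
                label = scheme.labels[k + 1]
    return label, label in scheme.active_classes


def activity_map_from_compounds(compounds, scheme: ActivityScheme = DEFAULT_SCHEME):
    """``compound_id -> True/False/None`` from flags or percent values.

    An explicit binary flag wins; otherwise the percent-inhibition value
    is classified with ``scheme``; molecules with neither stay ``None``.
    """
    amap = {}
    for c in compounds:
        if c.is_active is not None:
            amap[c.compound_id] = bool(c.is_active)
        else:
            _, active = classify(c.activity_value, scheme)
            amap[c.compound_id] = active
    return amap


@dataclass(frozen=True)
class EnrichmentResult:
    mf_actives: int
    mf_inactives: int
    total_actives: int
    total_inactives: int

    @property
    def mf_ratio(self) -> float:
        n = self.mf_actives + self.mf_inactives
        return self.mf_actives / n if n else 0.0

    @property
    def total_ratio(self) -> float:
        n = self.total_actives + self.total_inactives
        return self.total_actives / n if n else 0.0

    @property
    def ef(self) -> float:
        return self.mf_ratio / self.total_ratio


def _totals(activity_map):
    total_actives = sum(1 for v in activity_map.values() if v is True)
    total_inactives = sum(1 for v in activity_map.values() if v is False)
    return total_actives, total_inactives


def enrichment_factor(node_molecule_ids, activity_map) -> EnrichmentResult:
    """EF of one node's molecule set; each molecule counted once."""
    total_actives, total_inactives = _totals(activity_map)
    if total_actives == 0:
        raise NoActivesError(
            "no active molecules in the library: Total_ratio = 0 and EF is undefined"
        )
    ids = set(node_molecule_ids)
    mf_actives = sum(1 for i in ids if activity_map.get(i) is True)
    mf_inactives = sum(1 for i in ids if activity_map.get(i) is False)
    return EnrichmentResult(mf_actives, mf_inactives, total_actives, total_inactives)


def annotate_nodes(
    nodes: pd.DataFrame,
    activity_map,
    memberships: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach n_actives and EF columns to a node table.

    Framework nodes that were reached from several representation kinds
    keep the *maximum* per-kind EF (``memberships`` supplies the long
    molecule x kind x key table); without it, EF is computed on the
    node's deduplicated molecule union.  Molecule nodes carry their own
    activity (EF of a single molecule: 0 or 1/Total_ratio).
    """
    total_actives, total_inactives = _totals(activity_map)
    if total_actives == 0:
        raise NoActivesError(
            "no active molecules in the library: Total_ratio = 0 and EF is undefined"
        )

    per_kind_ef = {}
    if memberships is not None:
        grouped = memberships.groupby(["key", "representation_kind"])["compound_id"]
        for (key, _kind), ids in grouped:
            res = enrichment_factor(ids, activity_map)
            per_kind_ef[key] = max(per_kind_ef.get(key, 0.0), res.ef)

    n_actives = []
    efs = []
    for row in nodes.itertuples(index=False):
        res = enrichment_factor(row.molecule_ids, activity_map)
        n_actives.append(res.mf_actives)
        if row.node_class == "FRAMEWORK" and row.key in per_kind_ef:
            efs.append(per_kind_ef[row.key])
        else:
            efs.append(res.ef)
    out = nodes.copy()
    out["n_actives"] = n_actives
    out["ef"] = efs
    return out


def filter_ef_zero(nodes: pd.DataFrame, edges: pd.DataFrame, activity_map=None):
    """Drop EF = 0 framework/fragment nodes and inactive molecule nodes.

    Never removes a node lying on a directed path from an active
    molecule: any framework containing an active molecule has EF > 0.
    """
    if "ef" not in nodes.columns:
        raise ValueError("nodes must be annotated before filtering")
    keep = []
    for row in nodes.itertuples(index=False):
        if row.node_class == "MOLECULE":
            active = (
                activity_map.get(row.key)
                if activity_map is not None
                else row.n_actives > 0
            )
            keep.append(bool(active))
        else:
            keep.append(row.ef > 0)
    out_nodes = nodes[pd.Series(keep, index=nodes.index)].reset_index(drop=True)
    kept_keys = set(out_nodes["key"])
    out_edges = edges[
        edges["source"].isin(kept_keys) & edges["target"].isin(kept_keys)
    ].reset_index(drop=True)
    return out_nodes, out_edges


def superframework_ef(fragment_key, nodes, edges, activity_map) -> EnrichmentResult:
    """EF of a fragment over the union of all its superframeworks.

    Superframeworks are every node from which the fragment is reachable
    along FRAGMENTATION edges; each molecule is counted once even when it
    appears in several superframeworks.
    """
    import networkx as nx

    if fragment_key not in set(nodes["key"]):
        raise KeyError(f"fragment {fragment_key!r} is not in the network")
    dg = nx.DiGraph()
    dg.add_nodes_from(nodes["key"])
    for s, t, c in edges[["source", "target", "edge_class"]].itertuples(index=False):
        if c == "FRAGMENTATION":
            dg.add_edge(s, t)
    ancestors = nx.ancestors(dg, fragment_key) | {fragment_key}
    own = {
        row.key: row.molecule_ids
        for row in nodes.itertuples(index=False)
        if row.key in ancestors and row.node_class != "MOLECULE"
    }
    union = set()
    for ids in own.values():
        union.update(ids)
    return enrichment_factor(union, activity_map)
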