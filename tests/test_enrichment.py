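"""Activity classes, enrichment factors, EF-zero filtering."""

import math
import random

import pandas as pd
import pytest

from scaffnet import (
    DEFAULT_SCHEME,
    NoActivesError,
    activity_map_from_compounds,
    annotate_nodes,
    build_framework_network,
    classify,
    enrichment_factor,
    extend_with_fragments,
    enumerate_fragments,
    filter_ef_zero,
    membership_table,
    nine_representations,
    standardize,
    superframework_ef,
)
from scaffnet.abstraction import Abstraction, Decoration, RepresentationKind

from oracles import ef_recount

BASIC_WF = RepresentationKind(Decoration.BASIC, Abstraction.WIREFRAME)


class TestClassify:
    @pytest.mark.parametrize(
        "value,label,active",
        [
            (10, "inactive", False),
            (18.9, "inactive", False),
            (19, "weak", False),       # boundary joins the upper class
            (32.9, "weak", False),
            (33, "moderate", True),
            (45, "moderate", True),
            (50, "strong", True),
            (80, "strong", True),      # very strong is strictly > 80
            (80.1, "very strong", True),
            (95, "very strong", True),
        ],
    )
    def test_buckets(self, value, label, active):
        got_label, got_active = classify(value)
        assert (got_label, got_active) == (label, active)

    def test_missing_value_unclassified(self):
        assert classify(None) == (None, None)
        assert classify(float("nan")) == (None, None)

    def test_classes_partition_the_line(self):
        rng = random.Random(5)
        for _ in range(200):
            v = rng.uniform(-10, 120)
            label, _ = classify(v)
            assert label in DEFAULT_SCHEME.labels

    def test_bad_scheme_rejected(self):
        from scaffnet import ActivityScheme

        with pytest.raises(ValueError):
            ActivityScheme(boundaries=(50.0, 19.0, 33.0, 80.0))


class TestEnrichmentFactor:
    def _amap(self, n_active, n_inactive):
        amap = {f"a{i}": True for i in range(n_active)}
        amap.update({f"i{i}": False for i in range(n_inactive)})
        return amap

    def test_direct_formula(self):
        amap = self._amap(10, 90)
        node = ["a0", "a1", "a2", "i0"]
        res = enrichment_factor(node, amap)
        assert res.mf_ratio == 0.75
        assert res.total_ratio == 0.10
        assert res.ef == 7.5

    def test_whole_library_node_has_unit_ef(self):
        amap = self._amap(7, 13)
        res = enrichment_factor(list(amap), amap)
        assert res.ef == 1.0

    def test_all_inactive_node(self):
        amap = self._amap(5, 5)
        assert enrichment_factor(["i0", "i1"], amap).ef == 0.0

    def test_ef_bounds(self):
        amap = self._amap(4, 16)
        rng = random.Random(3)
        ids = list(amap)
        for _ in range(50):
            node = rng.sample(ids, rng.randint(1, len(ids)))
            res = enrichment_factor(node, amap)
            assert 0.0 <= res.mf_ratio <= 1.0
            assert 0.0 <= res.ef <= 1.0 / res.total_ratio + 1e-12

    def test_no_actives_is_an_error(self):
        with pytest.raises(NoActivesError):
            enrichment_factor(["i0"], {"i0": False, "i1": False})

    def test_molecules_counted_once(self):
        amap = self._amap(2, 2)
        res = enrichment_factor(["a0", "a0", "i0"], amap)
        assert (res.mf_actives, res.mf_inactives) == (1, 1)


def _library(actives_by_scaffold):
    """Tiny library: dict scaffold_smiles -> (n_active, n_inactive)."""
    compounds = []
    k = 0
    for smiles, (na, ni) in actives_by_scaffold.items():
        for _ in range(na):
            compounds.append(standardize(smiles, f"m{k}", is_active=True))
            k += 1
        for _ in range(ni):
            compounds.append(standardize(smiles, f"m{k}", is_active=False))
            k += 1
    return compounds


class TestAnnotate:
    def test_ef_matches_recount_oracle(self, small_library, library_rep_sets):
        amap = activity_map_from_compounds(small_library.compounds)
        nodes, _ = build_framework_network(library_rep_sets)
        ann = annotate_nodes(nodes, amap)
        for row in ann.itertuples(index=False):
            assert row.ef == pytest.approx(ef_recount(row.molecule_ids, amap))

    def test_collision_keeps_max_per_kind_ef(self):
        # benzene (active) and toluene (inactive) collide on the benzene
        # scaffold node: as toluene's basic scaffold its EF is 1/total_ratio
        # *only* at kinds where the set is {benzene}; the node keeps the max
        compounds = _library({"c1ccccc1": (1, 0), "Cc1ccccc1": (0, 1)})
        rep_sets = [nine_representations(c) for c in compounds]
        amap = activity_map_from_compounds(compounds)
        nodes, _ = build_framework_network(rep_sets)
        memb = membership_table(rep_sets)
        ann = annotate_nodes(nodes, amap, memberships=memb)
        bz_key = standardize("c1ccccc1").graph.key()
        row = ann[ann["key"] == bz_key].iloc[0]
        # union EF would be (1/2)/(1/2) = 1; per-kind max is 2
        assert row["ef"] == pytest.approx(2.0)
        assert row["n_molecules"] == 2 and row["n_actives"] == 1

    def test_all_classified_finite(self, small_library, library_rep_sets):
        amap = activity_map_from_compounds(small_library.compounds)
        nodes, _ = build_framework_network(library_rep_sets)
        ann = annotate_nodes(nodes, amap)
        assert ann["ef"].map(math.isfinite).all()

    def test_activity_conserved_through_tables(self, small_library, library_rep_sets):
        amap = activity_map_from_compounds(small_library.compounds)
        nodes, _ = build_framework_network(library_rep_sets)
        ann = annotate_nodes(nodes, amap)
        mols = ann[ann["node_class"] == "MOLECULE"]
        assert mols["n_actives"].sum() == sum(1 for v in amap.values() if v)

    def test_no_actives_raises(self):
        compounds = _library({"c1ccccc1": (0, 2)})
        rep_sets = [nine_representations(c) for c in compounds]
        nodes, _ = build_framework_network(rep_sets)
        with pytest.raises(NoActivesError, match="Total_ratio"):
            annotate_nodes(nodes, activity_map_from_compounds(compounds))


class TestFilterEfZero:
    def _annotated(self, compounds):
        rep_sets = [nine_representations(c) for c in compounds]
        amap = activity_map_from_compounds(compounds)
        nodes, edges = build_framework_network(rep_sets)
        ann = annotate_nodes(nodes, amap, memberships=membership_table(rep_sets))
        return ann, edges, amap

    def test_inactive_branch_removed_active_paths_intact(self):
        compounds = _library({"c1ccccc1": (2, 0), "C1CCNCC1": (0, 2)})
        ann, edges, amap = self._annotated(compounds)
        out_nodes, out_edges = filter_ef_zero(ann, edges, amap)
        # the piperidine branch disappears entirely
        pip_scaffold = standardize("C1CCNCC1").graph.key()
        assert pip_scaffold not in set(out_nodes["key"])
        # the active benzene path is intact
        bz = standardize("c1ccccc1").graph.key()
        assert bz in set(out_nodes["key"])
        assert not out_edges["source"].isin([pip_scaffold]).any()

    def test_all_active_library_identity(self):
        compounds = _library({"c1ccccc1": (2, 0), "C1CCNCC1": (1, 0)})
        ann, edges, amap = self._annotated(compounds)
        out_nodes, out_edges = filter_ef_zero(ann, edges, amap)
        assert len(out_nodes) == len(ann)
        assert len(out_edges) == len(edges)

    def test_kept_count_equals_positive_ef_count(self):
        compounds = _library(
            {"c1ccccc1": (2, 1), "C1CCNCC1": (0, 2), "c1ccc2ccccc2c1": (1, 1)}
        )
        ann, edges, amap = self._annotated(compounds)
        out_nodes, _ = filter_ef_zero(ann, edges, amap)
        frameworks = ann[ann["node_class"] == "FRAMEWORK"]
        expect = (frameworks["ef"] > 0).sum()
        assert (out_nodes["node_class"] == "FRAMEWORK").sum() == expect

    def test_never_removes_active_ancestry(self):
        compounds = _library({"c1ccccc1": (1, 3), "C1CCNCC1": (0, 2)})
        ann, edges, amap = self._annotated(compounds)
        out_nodes, _ = filter_ef_zero(ann, edges, amap)
        kept = set(out_nodes["key"])
        # every framework containing the active molecule survives
        active_id = next(c.compound_id for c in compounds if c.is_active)
        rs = nine_representations(next(c for c in compounds if c.is_active))
        for key in rs.keys.values():
            assert key in kept

    def test_requires_annotation(self, sample_rep_sets):
        nodes, edges = build_framework_network(sample_rep_sets)
        with pytest.raises(ValueError, match="annotated"):
            filter_ef_zero(nodes, edges)


class TestSuperframeworkEf:
    def _extended(self, compounds):
        rep_sets = [nine_representations(c) for c in compounds]
        amap = activity_map_from_compounds(compounds)
        nodes, edges = build_framework_network(rep_sets)
        graphs = {}
        for rs in rep_sets:
            graphs.setdefault(rs.keys[BASIC_WF], rs.graphs[BASIC_WF])
        records = []
        for g in graphs.values():
            records.extend(enumerate_fragments(g))
        nodes, edges = extend_with_fragments(nodes, edges, records)
        return nodes, edges, amap

    def test_single_superframework_equals_its_ef(self):
        # naphthalene cluster only: the 6-ring fragment's EF equals the
        # (sole) originator's EF
        compounds = _library({"c1ccc2ccccc2c1": (1, 1), "CCCC1CCNC1C": (1, 0)})
        # the second scaffold is a lone 5-ring: it fragments nothing and its
        # skeleton differs from the 6-ring fragment under test
        nodes, edges, amap = self._extended(compounds)
        from scaffnet import standardize as std, to_wireframe

        frag6 = to_wireframe(std("C1CCCCC1").graph).key()
        res = superframework_ef(frag6, nodes, edges, amap)
        base = enrichment_factor(["m0", "m1"], amap)
        assert res.ef == pytest.approx(base.ef)

    def test_union_strictly_between_extremes(self):
        # one all-active and one all-inactive cluster of equal size share
        # the 6-ring skeleton fragment
        compounds = _library(
            {"c1ccc2ccccc2c1": (2, 0), "c1ccc(-c2ccccc2)cc1": (0, 2)}
        )
        nodes, edges, amap = self._extended(compounds)
        from scaffnet import standardize as std, to_wireframe

        frag6 = to_wireframe(std("C1CCCCC1").graph).key()
        res = superframework_ef(frag6, nodes, edges, amap)
        lo = enrichment_factor(["m2", "m3"], amap).ef
        hi = enrichment_factor(["m0", "m1"], amap).ef
        assert lo < res.ef < hi

    def test_matches_union_recount_oracle(self, small_library, library_rep_sets):
        amap = activity_map_from_compounds(small_library.compounds)
        nodes, edges = build_framework_network(library_rep_sets)
        graphs = {}
        for rs in library_rep_sets:
            graphs.setdefault(rs.keys[BASIC_WF], rs.graphs[BASIC_WF])
        records = []
        for g in graphs.values():
            records.extend(enumerate_fragments(g))
        nodes, edges = extend_with_fragments(nodes, edges, records)
        frag_keys = nodes[nodes["node_class"] == "FRAGMENT"]["key"]
        mols_of = dict(zip(nodes["key"], nodes["molecule_ids"]))
        import networkx as nx

        dg = nx.DiGraph()
        dg.add_nodes_from(nodes["key"])
        frag_edges = edges[edges["edge_class"] == "FRAGMENTATION"]
        dg.add_edges_from(zip(frag_edges["source"], frag_edges["target"]))
        for fk in frag_keys:
            res = superframework_ef(fk, nodes, edges, amap)
            union = set()
            for anc in nx.ancestors(dg, fk) | {fk}:
                if anc in mols_of:
                    union |= set(mols_of[anc])
            union -= {r for r in union if r not in amap}
            assert res.ef == pytest.approx(ef_recount(union, amap))

    def test_unknown_fragment_rejected(self, small_library, library_rep_sets):
        amap = activity_map_from_compounds(small_library.compounds)
        nodes, edges = build_framework_network(library_rep_sets)
        with pytest.raises(KeyError):
            superframework_ef("nonexistent", nodes, edges, amap)
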