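# scaffnet

Multi-dimensional hierarchical scaffold networks for structure–activity
analysis of screening libraries.

High-throughput screening triage and library design both hinge on grouping
molecules into chemically meaningful series. Classical scaffold clustering
uses a *single* representation — most often the Bemis–Murcko scaffold — and
fails in two familiar ways: prune too little and every analogue is its own
cluster; prune too much and unrelated chemotypes collapse together. There is
no single best abstraction level: it depends on the dataset.

`scaffnet` sidesteps the choice by computing **nine correlated
representations per molecule**, arranged on a 3×3 grid:

|                 | scaffold (atoms + bonds) | framework (any-atom) | wireframe (any-atom, any-bond) |
|-----------------|--------------------------|----------------------|--------------------------------|
| **basic**       | Bemis–Murcko scaffold    | bond orders only     | cyclic skeleton                |
| **decorated**   | + terminal atoms with bond order > 1 (C=O, S(=O)₂ …) | ″ | ″ |
| **augmented**   | + the longest carbon-terminated side chain | ″ | ″ |

All representations of all molecules are deduplicated into one **oriented
network**: edges run from each molecule to its representations and between
adjacent grid points in the direction of increasing abstraction. Three
unbiased fragmentation rules (internal-chain removal, fused-ring opening,
internal-ring removal) are applied progressively to any representation,
adding originator→fragment edges that interconnect otherwise disjoint
clusters — small shared fragments such as a plain six-ring skeleton stitch
the whole library into one navigable graph.

For screening data, every node carries an **enrichment factor**

```
EF = MF_ratio / Total_ratio
MF_ratio    = MF_actives / (MF_actives + MF_inactives)
Total_ratio = Total_actives / (Total_actives + Total_inactives)
```

where *MF actives* counts the active molecules carrying that framework.
EF > 1 marks an activity-enriched chemotype; filtering EF = 0 nodes prunes
the network down to its SAR-relevant paths, and a fragment's EF aggregates
the molecules of every framework containing it (its superframeworks).

Percent-inhibition data are bucketed as inactive < 19, weak 19–33, moderate
33–50, strong 50–80, very strong > 80 (moderate and above count as active);
binary active flags are accepted directly.

## Worked example

The bundled sample (`scaffnet.fixtures.load_cox2_sample()`) holds fourteen
anti-inflammatory agents with synthetic activity values. Polmacoxib's basic
wireframe — three fused-free rings, 6-5-6, used as an any-atom/any-bond
query — retrieves exactly the diaryl-heterocycle COX-2 inhibitors:

```python
from scaffnet import basic_scaffold, match_set, to_wireframe
from scaffnet.fixtures import load_cox2_sample, worked_examples

sample = load_cox2_sample()
pol = worked_examples()["polmacoxib"]
query = to_wireframe(basic_scaffold(pol.graph))
print(match_set(query, sample))
```

```
['polmacoxib', 'celecoxib', 'valdecoxib', 'rofecoxib', 'parecoxib',
 'deracoxib', 'mavacoxib']
```

Seven hits out of fourteen: the coxibs share Polmacoxib's cyclic skeleton
while etoricoxib (central six-ring), the diaryl-amine/ether NSAIDs and the
single-ring profens do not. The command line produces the four standard
tables (per-molecule wide table, long molecule × representation table, node
attribute file, edge file — directly importable by Cytoscape):

```
$ scaffnet enrich src/scaffnet/data/cox2_sample_synthetic.csv -o out/
parsed 14 records: 14 with scaffolds, 0 acyclic, 0 unparseable
EF   1.4  n=7    basic_wireframe        *1~*~*~*(~*2~*~*~*~*~2~*2~*~*~*~*~*~2)~*~*~1
EF   1.4  n=5    basic_framework        *1:*:*:*(*2:*:*:*:*:2*2:*:*:*:*:*:2):*:*:1
EF   1.4  n=4    decorated_framework    *=*(=*)*1:*:*:*(*2:*:*:*:*:2*2:*:*:*:*:*:2):*:*:1
...
```

The top node is the shared coxib cyclic skeleton itself (all seven carriers
are active), refined below it by frameworks that add bond orders and
decorations. An EF of 1.4 is this library's maximum: 10 of 14 molecules are
active, so 1/Total_ratio = 14/10 = 1.4, reached only by all-active nodes.

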