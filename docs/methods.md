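# Methods

## The representation grid

Every standardized molecule with at least one ring is mapped to nine
representations, the cross product of a *decoration* axis and an
*abstraction* axis.

**Decoration** controls how much side-chain context survives on the ring
system:

* *basic* — iteratively delete every degree-1 atom. What remains is the
  ring systems plus the acyclic linkers between them (the Bemis–Murcko
  scaffold). Note that exocyclic double-bonded atoms are terminals too and
  are pruned here; library implementations of the Murcko scaffold often
  retain them, which is exactly the behaviour reserved for the next level.
* *decorated* — identical pruning, except a terminal atom held by a bond of
  order greater than one (carbonyl or sulfonyl oxygens, exocyclic imines) is
  protected. Protection is transitive in effect: the pruning loop can never
  reach an atom that lies between the ring and a protected terminal, so a
  chain capped by a C=O survives whole.
* *augmented* — two steps. First, terminal non-carbon atoms attached by an
  order-1 bond are removed iteratively (hydroxyls, halogens, amines fall
  off; ether oxygens and protected oxygens stay). Second, among the atoms
  left outside the decorated baseline, every simple path that starts at a
  side-chain attachment point and ends on a carbon is enumerated, and the
  single longest path in the whole molecule is retained; everything else is
  pruned to the decorated baseline. Paths may traverse internal heteroatoms
  (an O–CH3 chain is a valid two-atom candidate) but must end on carbon.

Ties between equal-longest paths are broken by the lexicographically
smallest sequence of canonical atom ranks, with ranks computed once on the
standardized molecule and inherited by every derived graph. This makes the
"first identified" choice a pure function of the molecular structure: the
same molecule written with any atom ordering yields the same augmented
scaffold (property-tested).

**Abstraction** controls how much chemistry the pruned graph keeps: the
*scaffold* keeps element labels and bond orders; the *framework* replaces
every element by an any-atom wildcard but keeps bond orders (aromatic bonds
are preserved as their own order, never kekulized, so aromatic and aliphatic
rings of equal size remain distinct frameworks); the *wireframe* wildcards
bond orders too, leaving the bare cyclic skeleton. A tenth, off-grid
transform (`strip_bond_orders`: elements kept, orders dropped) exists only
for benchmarking cluster counts of the classical single-axis abstractions.

The grid commutes — each abstraction step is a deterministic function of the
less abstract representation — which yields the sharing-monotonicity
property the network relies on: molecules with equal keys at one grid point
have equal keys at every more abstract point.

## Identity and keys

All graphs live in one container (`MolecularGraph`) whose atoms are element
symbols or wildcards and whose bonds are orders 1/2/3/aromatic or wildcards.
Identity is the RDKit canonical SMILES of the heavy-atom graph with implicit
hydrogens disabled; wildcard atoms serialize as `*`, wildcard bonds as `~`,
so a framework (`*1:*:...`) can never collide with a wireframe (`*1~*~...`).
One scheme covers concrete and abstracted graphs alike. InChIKeys are
computed for standardized input molecules as a conventional registration
identifier but are deliberately **not** the dedup key: InChI's tautomer
normalization can merge distinct heavy-atom graphs, and pruned scaffolds
need not be valence-valid molecules at all (a sulfonyl sulfur that lost its
methyl has no sensible valence model). Key equality is verified equivalent
to brute-force graph isomorphism on small random graphs.

Ring perception (ring bonds = non-bridge edges, ring count = SSSR
cardinality via a minimum cycle basis) runs on networkx, so graph surgery
never round-trips through chemistry sanitization.

## Fragmentation

Three rules apply to any representation, since they are pure graph surgery:

1. **Internal-chain removal.** A linker is a connected set of non-ring atoms
   whose removal separates at least two ring-containing pieces, or a direct
   non-ring bond between two ring atoms (the zero-length case — without it,
   biphenyl-type scaffolds would be irreducible). One child per linker per
   remaining ring-containing component.
2. **Fused-ring opening.** Ring systems are SSSR rings grouped by shared
   atoms; for each ring of a multi-ring system, the atoms exclusive to that
   ring are deleted and shared atoms/bonds retained. Spiro systems are
   handled by the same rule, the shared atom surviving. Dangling linker
   stubs left by the deletion are pruned back to the nearest ring.
3. **Internal-ring removal.** A whole ring system is deleted; if the pruned
   remainder holds two or more ring-containing pieces, each is a child.

Children are deduplicated by canonical key; the closure applies the rules
breadth-first to a default depth equal to the input's ring count (a full
closure for ordinary scaffolds) with a global size cap that sets a
truncation flag rather than failing. Every child is strictly smaller than
its originator, so termination is structural. The closure is independent of
rule application order (tested against a shuffled-order brute-force closure
that deduplicates by isomorphism instead of keys), and every fragment
generically embeds into its originator (tested against a networkx
monomorphism oracle).

Fragments must contain at least one ring: pure-chain leftovers carry no
clustering information and would flood the network. One consequence is that
at the wireframe level, where bond orders are wildcards, protected
decorations are indistinguishable from linker stubs and are pruned with
them; decoration-aware fragments are obtained by fragmenting the scaffold-
or framework-level representations instead.

## Network and enrichment

The network holds one node per molecule, one per unique representation key
(labelled with the least abstract kind that produced it, ordering the grid
abstraction-axis-first: scaffold < framework < wireframe, then augmented <
decorated < basic), and optionally one per fragment. Edges: molecule → its
least abstract representation (all nine with `--dense-membership`), adjacent
grid steps oriented toward abstraction (collapsed when the two points share
a key), and originator → fragment. The non-membership subgraph is acyclic by
construction. Without fragments, the undirected component count provably
equals the number of unique basic wireframes; fragments merge components,
typically into a single connected network.

Enrichment uses EF = MF_ratio / Total_ratio on each node's molecule set.
Molecules without activity data are excluded from numerators and
denominators; a library without a single active raises an error naming the
undefined denominator rather than emitting EF = 0 everywhere. Percent
inhibition is bucketed at 19/33/50/80 with boundary values joining the upper
class, except that "very strong" is strictly above 80 (the printed
convention); actives are moderate and above. When one key is reached from
several representation kinds, the deduplicated node keeps the **maximum**
per-kind EF (computed from the long molecule × kind table) while its
molecule counts report the union. Fragment nodes aggregate the molecule
union of all their superframeworks — every node that fragments into them,
transitively — and `superframework_ef` recomputes that union on demand.
EF = 0 filtering drops frameworks with no active carrier and inactive
molecules; it can never disconnect an active molecule from its
representations, because any framework containing an active molecule has a
positive EF.

## Wildcard queries

Abstracted representations double as substructure queries: wildcard atoms
match any element, wildcard bonds any order, and — one constraint beyond
plain monomorphism — a query bond on a ring must map to a target ring bond,
so a six-ring skeleton retrieves rings, never hexyl chains. Queries are
assembled programmatically from SMARTS primitives (`*`, `~`, `@`) and run on
RDKit's substructure engine; agreement with an independent networkx
monomorphism oracle is part of the test suite.

## Standardization

Inputs are parsed from SMILES; the largest covalent component is kept (ties
broken by molecular weight), trivially charged atoms are neutralized,
stereochemistry and isotope labels are removed. These defaults are declared
choices following screening-library convention, not derived rules. No
tautomer enumeration or protonation modelling is attempted.

## Synthetic data

`fixtures.synthetic_library` emulates a screening deck with a known answer:
ten template scaffolds with pairwise-distinct cyclic skeletons (verified by
test) each spawn decorated variants via 1–3 short random side chains that
never alter the underlying scaffold; one planted scaffold's members are
active with probability 0.8 against a 0.05 background, and actives draw
percent inhibition in 35–95 (moderate or better) versus 0–15 for inactives.
Defaults are 10 scaffolds × 10 molecules. What passing tests on this
generator demonstrate is the bookkeeping — EF arithmetic, deduplication,
component structure, ranking — under ideal conditions: one clean series per
skeleton, no assay noise beyond the activity flip, no promiscuous
chemotypes, no scaffold overlap between series. Real decks violate all of
these, so recovery rates here say nothing about screening performance on
real data; reference-scale distributional statistics are exercised
separately by the (externally supplied) 816-molecule COX-2 table.

The bundled fourteen-molecule COX-2 sample is a synthetic stand-in fixture
(public structures, invented activity values) for worked examples and CLI
tests; it is not the published reference set.

## Problem sizes and numerics

The default test suite and the acceptance script run on the 14-molecule
sample, libraries of 48–100 synthetic molecules, and 20 seeds of the
planted-recovery check — sizes chosen so the full run completes in seconds
while still exercising every code path; all algorithms are polynomial in
molecule size except candidate-path enumeration in the augmented scaffold
(exponential only in side-chain branching, which is tiny in practice) and
subgraph matching (delegated to RDKit's VF2-style engine). Degenerate
inputs: acyclic molecules raise a ring error naming the compound;
single-ring molecules fragment to nothing; the empty graph has an empty key
and matches everything reflexively.
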