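"""Programmatic test fixtures: worked examples and synthetic libraries.

``worked_examples`` ships the structures that exercise every rule edge
case — a bundled miniature COX-2 inhibitor sample (a synthetic stand-in
table: public structures with invented activity values, as the filename
says) plus hand-built topologies for the longest-side-chain tie-breaks
and the three fragmentation rules.

``synthetic_library`` plants a known activity enrichment on chosen
template scaffolds, so every pipeline-level statistic the package
computes (top-EF scaffold, component counts, cluster counts) can be
compared against values known by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

from rdkit import Chem

from .chem_io import Compound, read_compounds, standardize

__all__ = [
    "FixtureError",
    "sample_path",
    "load_cox2_sample",
    "load_cox2_reference",
    "worked_examples",
    "synthetic_library",
    "SyntheticLibrary",
]


class FixtureError(FileNotFoundError):
    """A bundled fixture file is missing."""


_SAMPLE_NAME = "cox2_sample_synthetic.csv"
_REFERENCE_NAME = "cox2_816_reference.csv"


def _data_path(name: str):
    path = resources.files("scaffnet.data") / name
    if not path.is_file():
        raise FixtureError(f"bundled fixture {name!r} is missing")
    return path


def sample_path():
    """Path to the bundled synthetic COX-2 sample table."""
    return _data_path(_SAMPLE_NAME)


def load_cox2_sample():
    """Load the bundled miniature COX-2 sample (synthetic stand-in).

    Fourteen public anti-inflammatory structures with synthetic
    percent-inhibition values: seven diaryl-five-membered-ring COX-2
    inhibitors sharing Polmacoxib's cyclic skeleton, plus structurally
    unrelated comparators.
    """
    compounds, _ = read_compounds(sample_path())
    return compounds


def load_cox2_reference():
    """Load the 816-molecule COX-2 reference table, if provided.

    The published reference set is distributed as supplementary material
    of the originating study and is not redistributable inside this
    package; place it at ``scaffnet/data/cox2_816_reference.csv`` (columns
    ``compound_id,smiles``) to run the reference-scale checks.
    """
    path = _data_path(_REFERENCE_NAME)
    compounds, _ = read_compounds(path)
    return compounds


# ---------------------------------------------------------------------- #
# worked-example topologies
# ---------------------------------------------------------------------- #
def worked_examples():
    """Named compounds covering each rule's edge cases.

    Keys
    ----
    polmacoxib
        From the bundled sample: three rings, sulfonamide decoration,
        gem-dimethyl side chains.
    chain_three_paths
        A ring with one branched side chain offering three candidate
        paths of different lengths (a unique longest exists).
    chain_tied_paths
        A branched side chain with two equal longest paths (exercises the
        canonical-rank tie-break).
    chain_single_path
        One unbranched side chain.
    linker_pair
        Two rings joined by a two-atom internal chain.
    fused_pair / fused_hetero
        Naphthalene and indole: bond-fused ring pairs.
    internal_ring_chain
        Terphenyl: the middle ring is internal (its removal leaves two
        separate rings).
    spiro_pair
        Two rings sharing exactly one atom.
    """
    by_id = {c.compound_id: c for c in load_cox2_sample()}
    examples = {
        "polmacoxib": by_id["polmacoxib"],
        "chain_three_paths": standardize("CCCC(CC)Cc1ccccc1", "chain_three_paths"),
        "chain_tied_paths": standardize("CCC(CC)Cc1ccccc1", "chain_tied_paths"),
        "chain_single_path": standardize("CCCCc1ccccc1", "chain_single_path"),
        "linker_pair": standardize("c1ccc(CCc2ccccc2)cc1", "linker_pair"),
        "fused_pair": standardize("c1ccc2ccccc2c1", "fused_pair"),
        "fused_hetero": standardize("c1ccc2[nH]ccc2c1", "fused_hetero"),
        "internal_ring_chain": standardize(
            "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1", "internal_ring_chain"
        ),
        "spiro_pair": standardize("C1CCC2(CC1)CCCC2", "spiro_pair"),
    }
    return examples


# ---------------------------------------------------------------------- #
# synthetic screening library
# ---------------------------------------------------------------------- #
# Template scaffolds with pairwise-distinct cyclic skeletons, so that each
# planted series is its own basic-wireframe cluster.
TEMPLATE_SCAFFOLDS = (
    "c1ccc(-c2ccccc2)cc1",          # two 6-rings, direct bond
    "c1ccc2ccccc2c1",               # fused 6-6
    "C(c1ccccc1)c1ccccc1",          # two 6-rings, 1-atom linker
    "C1Cc2ccccc2C1",                # fused 5-6
    "c1ccccc1",                     # single 6-ring
    "C1CCNC1",                      # single 5-ring
    "c1ccc(CCc2ccccc2)cc1",         # two 6-rings, 2-atom linker
    "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",  # 6-6-6 chain
    "C1CCC(c2ccccc2)C1",            # 5-6, direct bond
    "c1ccc2c(c1)oc1ccccc12",        # fused 6-5-6
)

_SUBSTITUENT_ELEMENTS = ("C", "N", "O")
_TERMINAL_ELEMENTS = ("C", "F", "Cl", "O", "N")


def _decorate(template: str, rng: random.Random) -> str:
    """Attach 1-3 short random side chains to a template scaffold."""
    mol = Chem.RWMol(Chem.MolFromSmiles(template))
    n_subs = rng.randint(1, 3)
    for _ in range(n_subs):
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetTotalNumHs() >= 1 and a.GetAtomicNum() in (6, 7)
        ]
        if not sites:
            break
        before = Chem.RWMol(mol)
        anchor = rng.choice(sites)
        length = rng.randint(1, 3)
        prev = anchor
        for pos in range(length):
            sym = (
                rng.choice(_TERMINAL_ELEMENTS)
                if pos == length - 1
                else rng.choice(_SUBSTITUENT_ELEMENTS)
            )
            idx = mol.AddAtom(Chem.Atom(sym))
            mol.AddBond(prev, idx, Chem.BondType.SINGLE)
            prev = idx
        try:
            probe = mol.GetMol()
            Chem.SanitizeMol(probe)
            mol = Chem.RWMol(probe)
        except Exception:
            mol = before
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


@dataclass
class SyntheticLibrary:
    """A generated library with its planted ground truth."""

    compounds: list
    scaffold_of: dict           # compound_id -> template SMILES
    enriched_scaffolds: tuple   # template SMILES planted as active series
    seed: int

    @property
    def n_actives(self) -> int:
        return sum(1 for c in self.compounds if c.is_active)


def synthetic_library(
    n_scaffolds: int = 10,
    n_per_scaffold: int = 10,
    active_scaffold_fraction: float = 0.1,
    seed: int = 0,
    p_active_enriched: float = 0.8,
    p_active_background: float = 0.05,
) -> SyntheticLibrary:
    """Generate a screening library with planted scaffold enrichment.

    ``n_scaffolds`` template scaffolds (cyclic skeletons pairwise
    distinct) each spawn ``n_per_scaffold`` decorated variants.  A
    fraction of the scaffolds is planted as enriched: their members are
    active with probability ``p_active_enriched`` versus
    ``p_active_background`` elsewhere.  Actives draw a percent-inhibition
    value in the moderate-to-very-strong range (35-95), inactives in
    0-15.  Fully reproducible per seed.
    """
    if n_scaffolds > len(TEMPLATE_SCAFFOLDS):
        raise ValueError(f"at most {len(TEMPLATE_SCAFFOLDS)} template scaffolds")
    rng = random.Random(seed)
    templates = list(TEMPLATE_SCAFFOLDS[:n_scaffolds])
    n_enriched = max(1, round(n_scaffolds * active_scaffold_fraction))
    enriched = tuple(rng.sample(templates, n_enriched))
    compounds = []
    scaffold_of = {}
    for si, template in enumerate(templates):
        p_active = p_active_enriched if template in enriched else p_active_background
        for mi in range(n_per_scaffold):
            smiles = _decorate(template, rng)
            cid = f"S{si:02d}M{mi:02d}"
            active = rng.random() < p_active
            value = rng.uniform(35.0, 95.0) if active else rng.uniform(0.0, 15.0)
            compounds.append(
                standardize(smiles, cid, activity_value=value, is_active=active)
            )
            scaffold_of[cid] = template
    return SyntheticLibrary(
        compounds=compounds,
        scaffold_of=scaffold_of,
        enriched_scaffolds=enriched,
        seed=seed,
    )
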