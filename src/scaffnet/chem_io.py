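"""Reading, standardizing and keying molecules; tabular input/output.

Input is a plain text file (one SMILES per line) or a delimited table with
``smiles`` plus optional ``id`` and activity columns.  Standardization keeps
the largest covalent component, neutralizes trivially charged atoms, and
strips stereochemistry and isotopes — screening-library conventions for
scaffold work, where salt forms and chirality are noise.

Output mirrors the four tables a network viewer (Cytoscape) imports: a wide
per-molecule table, a long (molecule x representation) table, a node
attribute file and an edge file.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .graph import MolecularGraph

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Compound",
    "ParseError",
    "EmptyInputError",
    "standardize",
    "structure_key",
    "read_compounds",
    "write_wide_table",
    "write_long_table",
    "write_attribute_table",
    "write_network_table",
]


class ParseError(ValueError):
    """A SMILES record could not be parsed."""


class EmptyInputError(ValueError):
    """No molecule was supplied."""


@dataclass
class Compound:
    """One standardized screening-library molecule.

    ``structure_key`` is the canonical graph key used for all
    deduplication; ``inchikey`` is carried alongside as the conventional
    registration identifier (it is *not* used as the dedup key because
    InChI's tautomer normalization can merge distinct heavy-atom graphs).
    """

    compound_id: str
    input_smiles: str
    graph: MolecularGraph
    canonical_smiles: str
    structure_key: str
    inchikey: str = ""
    activity_value: Optional[float] = None
    is_active: Optional[bool] = None


def _largest_component(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    # largest by heavy-atom count; ties broken by molecular weight
    return max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m)))


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(
    smiles: str,
    compound_id: str = "",
    activity_value: Optional[float] = None,
    is_active: Optional[bool] = None,
) -> Compound:
    """Parse and standardize one SMILES record into a :class:`Compound`.

    Keeps the largest covalent component, neutralizes chemically trivial
    charges, removes stereo marks and isotope labels, and computes the
    canonical SMILES and structure key.

    Raises
    ------
    ParseError
        If the SMILES does not parse (the message names the record).
    EmptyInputError
        If the input string is empty/blank.
    """
    if smiles is None or not str(smiles).strip():
        raise EmptyInputError(f"empty SMILES for record {compound_id!r}")
    mol = Chem.MolFromSmiles(str(smiles).strip())
    if mol is None:
        raise ParseError(f"unparseable SMILES {smiles!r} (record {compound_id!r})")
    mol = _largest_component(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    if mol is None:  # pragma: no cover - standardization never invalidates
        raise ParseError(f"standardization failed for {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    graph = MolecularGraph.from_rdkit(mol)
    try:
        ik = Chem.MolToInchiKey(mol)
    except Exception:  # pragma: no cover - InChI unavailable for exotic mols
        ik = ""
    return Compound(
        compound_id=str(compound_id) if compound_id else canonical,
        input_smiles=str(smiles),
        graph=graph,
        canonical_smiles=canonical,
        structure_key=graph.key(),
        inchikey=ik,
        activity_value=activity_value,
        is_active=is_active,
    )


def structure_key(graph: MolecularGraph) -> str:
    """Canonical key of any graph: isomorphic graphs share one key."""
    return graph.key()


# ---------------------------------------------------------------------- #
# tabular input
# ---------------------------------------------------------------------- #
_HEADER_NAMES = {
    "smiles",
    "canonical_smiles",
    "structure",
    "id",
    "compound_id",
    "name",
    "identifier",
    "activity",
    "percent_inhibition",
    "inhibition",
    "active",
    "is_active",
}


def _sniff_delimiter(sample: str) -> str:
    # auto-detect is restricted to comma/tab
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def _looks_like_header(row: Sequence[str]) -> bool:
    return any(str(c).strip().lower() in _HEADER_NAMES for c in row)


def read_compounds(
    path,
    smiles_col: Optional[str] = None,
    id_col: Optional[str] = None,
    activity_col: Optional[str] = None,
    active_col: Optional[str] = None,
    delimiter: Optional[str] = None,
    on_error: str = "raise",
):
    """Read compounds from a SMILES list or a CSV/TSV table.

    Column resolution: an explicit ``smiles_col`` wins; otherwise a header
    column named like ``smiles`` is used; otherwise the first column.
    ``activity_col`` holds percent inhibition; ``active_col`` holds a
    binary active flag (0/1, true/false).

    Returns ``(compounds, skipped)`` where ``skipped`` lists
    ``(record_id, reason)`` for unparseable rows when ``on_error="skip"``.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise EmptyInputError(f"input file {path} is empty")
    delim = delimiter or _sniff_delimiter(text.splitlines()[0])
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [r for r in rows if any(str(c).strip() for c in r)]
    header = None
    if _looks_like_header(rows[0]):
        header = [str(c).strip().lower() for c in rows[0]]
        rows = rows[1:]

    def col_index(name, fallbacks):
        if name is not None:
            if header is None or name.lower() not in header:
                raise ValueError(f"column {name!r} not found in header {header}")
            return header.index(name.lower())
        if header is not None:
            for fb in fallbacks:
                if fb in header:
                    return header.index(fb)
        return None

    smi_idx = col_index(smiles_col, ["smiles", "canonical_smiles", "structure"])
    if smi_idx is None:
        smi_idx = 0
    id_idx = col_index(id_col, ["id", "compound_id", "name", "identifier"])
    act_idx = col_index(activity_col, ["activity", "percent_inhibition", "inhibition"])
    flag_idx = col_index(active_col, ["active", "is_active"])
    if header is None and len(rows[0]) > 1 and id_idx is None:
        id_idx = 1
    if header is None and len(rows[0]) > 2 and act_idx is None and activity_col is None:
        act_idx = 2

    compounds = []
    skipped = []
    for n, row in enumerate(rows, start=1):
        rid = row[id_idx].strip() if id_idx is not None and id_idx < len(row) else f"mol{n}"
        if not rid:
            rid = f"mol{n}"
        smi = row[smi_idx].strip() if smi_idx < len(row) else ""
        value = None
        flag = None
        if act_idx is not None and act_idx < len(row) and str(row[act_idx]).strip():
            value = float(row[act_idx])
        if flag_idx is not None and flag_idx < len(row) and str(row[flag_idx]).strip():
            flag = str(row[flag_idx]).strip().lower() in ("1", "true", "yes", "active")
        try:
            compounds.append(standardize(smi, rid, activity_value=value, is_active=flag))
        except (ParseError, EmptyInputError) as exc:
            if on_error == "skip":
                skipped.append((rid, str(exc)))
            else:
                raise
    return compounds, skipped


# ---------------------------------------------------------------------- #
# tabular output (Cytoscape-compatible CSV dialects)
# ---------------------------------------------------------------------- #
def write_wide_table(rep_sets, compounds, path) -> pd.DataFrame:
    """Per-molecule wide table: one row, nine representation columns."""
    by_id = {c.compound_id: c for c in compounds}
    records = []
    for rs in rep_sets:
        comp = by_id[rs.compound_id]
        row = {
            "compound_id": rs.compound_id,
            "smiles": comp.canonical_smiles,
            "inchikey": comp.inchikey,
        }
        for kind in rs.kinds():
            row[kind.column_name] = rs.keys[kind]
        records.append(row)
    df = pd.DataFrame(records)
    df.to_csv(path, index=False)
    return df


def write_long_table(rep_sets, path) -> pd.DataFrame:
    """Long table: one row per molecule x representation."""
    records = []
    for rs in rep_sets:
        for kind in rs.kinds():
            records.append(
                {
                    "compound_id": rs.compound_id,
                    "representation_kind": kind.column_name,
                    "structure": rs.keys[kind],
                    "key": rs.keys[kind],
                }
            )
    df = pd.DataFrame(records)
    df.to_csv(path, index=False)
    return df


def write_attribute_table(nodes: pd.DataFrame, path) -> pd.DataFrame:
    """Node attribute file keyed on ``key`` (Cytoscape table import)."""
    cols = [c for c in nodes.columns if c != "molecule_ids"]
    df = nodes[cols].copy()
    if "ef" in df.columns:
        df["ef_display"] = df["ef"].map(
            lambda v: "" if pd.isna(v) else f"{v:.1f}"
        )
    df.to_csv(path, index=False)
    return df


def write_network_table(edges: pd.DataFrame, path) -> pd.DataFrame:
    """Edge file with source,target,interaction columns."""
    df = edges.rename(columns={"edge_class": "interaction"})[
        ["source", "target", "interaction"]
    ]
    df.to_csv(path, index=False)
    return df
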