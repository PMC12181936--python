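"""Structural categorization: primary classes, perfluorinated chain length,
and chain-length secondary categories.

Primary classes follow the OECD-style vocabulary (perfluoroalkyl acids and
their precursors, polyfluoroalkyl acids, and a residual "Other PFASs" branch
subdivided into aromatic, silicon, alkane, hydrofluorocarbon and telomer
subclasses). The classification-tree internals of the public subgroup tools
are not published, so the rules here are an ordered, editable table of
structural predicates approximating that vocabulary: most specific first,
first match wins.

The secondary level bins each substance by the length of its longest
contiguous run of perfluorinated carbons, thresholded at 7 (``gte7``/``lt7``),
the conventional "long chain" boundary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from rdkit import Chem

from .registry import Registry, matches_pfas_definition

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryAssignment",
    "max_cf2_chain_length",
    "assign_primary_class",
    "apply_hybrid_rule",
    "assign_secondary",
    "categorize_registry",
    "CHAIN_THRESHOLD",
    "HYBRID_MEMBERSHIP_THRESHOLD",
]

CHAIN_THRESHOLD = 7
HYBRID_MEMBERSHIP_THRESHOLD = 300
MIN_SECONDARY_COUNT = 5  # second classes rarer than this collapse to "others"

UNCLASSIFIED = "unclassified"
NOT_PFAS = "Not PFAS"

# second class -> first (broad) class
_FIRST_CLASS_OF = {
    "PFAAs": "PFAAs",
    "PFAA precursors": "PFAA precursors",
    "PASF-based substances": "PFAA precursors",
    "n:2 fluorotelomer-based substances": "PFAA precursors",
    "HFCs": "PFAA precursors",
    "Polyfluoroalkyl acids": "Polyfluoroalkyl acids",
    "PolyFCA derivatives": "Polyfluoroalkyl acids",
    "Other PFASs": "Other PFASs",
    "Aromatic PFASs": "Other PFASs",
    "Si PFASs": "Other PFASs",
    "Polyfluoroalkanes": "Other PFASs",
    "others": "Other PFASs",
}

# first classes that have a ", cyclic" variant in the category vocabulary
_CYCLIC_CAPABLE = {"PFAAs", "PFAA precursors", "Polyfluoroalkyl acids",
                   "Other PFASs", "others"}


@dataclass
class CategoryAssignment:
    substance_id: str
    first_class: str
    second_class: str
    primary_category: str = ""
    chain_length: int = 0
    chain_bin: str = ""
    secondary_category: str = ""


# --- chain length ------------------------------------------------------------

def _qualifying_carbons(mol, strict_cf2: bool) -> list[int]:
    idxs = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetTotalNumHs() != 0:
            continue
        n_f = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 9)
        if strict_cf2 and n_f != 2:
            continue
        if n_f >= 2:
            idxs.append(atom.GetIdx())
    return idxs


def max_cf2_chain_length(qsar_ready_smiles: str, max_chain: int = 30,
                         strict_cf2: bool = False) -> int:
    """Length of the longest contiguous run of perfluorinated carbons.

    A carbon qualifies when it bears at least two fluorines and no hydrogens,
    so a terminal CF3 extends the run (PFOA scores 7, PFOS 8). The length is
    the longest simple path through bonded qualifying carbons; 0 when none
    qualify. ``strict_cf2=True`` restricts to carbons with exactly two
    fluorines. Lengths beyond ``max_chain`` are still computed exactly, with
    a warning.
    """
    mol = Chem.MolFromSmiles(qsar_ready_smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {qsar_ready_smiles!r}")
    nodes = _qualifying_carbons(mol, strict_cf2)
    if not nodes:
        return 0
    node_set = set(nodes)
    adj: dict[int, list[int]] = {i: [] for i in nodes}
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in node_set and b in node_set:
            adj[a].append(b)
            adj[b].append(a)

    best = 1

    def dfs(node: int, visited: set[int], depth: int) -> None:
        nonlocal best
        best = max(best, depth)
        for nb in adj[node]:
            if nb not in visited:
                visited.add(nb)
                dfs(nb, visited, depth + 1)
                visited.remove(nb)

    for start in nodes:
        dfs(start, {start}, 1)
    if best > max_chain:
        logger.warning("chain length %d exceeds configured maximum %d",
                       best, max_chain)
    return best


# --- primary class rules -----------------------------------------------------

_ACID_HEAD = Chem.MolFromSmarts(
    "[$([CX3](=O)[OX2H1]),$([CX3](=O)[OX1-]),"
    "$([SX4](=O)(=O)[OX2H1]),$([SX4](=O)(=O)[OX1-]),"
    "$([PX4](=O)([OX2H1])[OX2H1])]")
_PF_CARBON = Chem.MolFromSmarts("[CX4;H0](F)F")
_PASF = Chem.MolFromSmarts("[CX4](F)(F)[SX4](=O)(=O)[F,N]")
_TELOMER = Chem.MolFromSmarts("[CX4](F)(F)[CX4H2][CX4H2]")
_PFCA_DERIV = Chem.MolFromSmarts(
    "[CX4](F)(F)[CX3](=O)[$([OX2][#6]),$([NX3])]")
# cyclic = fluorinated saturated ring carbon; aromatic ring fluorines stay
# with the aromatic class rather than spawning a cyclic variant
_FLUORINATED_RING_C = Chem.MolFromSmarts("[C;R]F")


def _is_perfluoroalkyl_acid(mol) -> bool:
    """All carbons outside the acid head are perfluorinated and acyclic."""
    heads = mol.GetSubstructMatches(_ACID_HEAD)
    if not heads:
        return False
    head_atoms = {i for match in heads for i in match}
    attached = False
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIdx() in head_atoms:
            continue
        n_f = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 9)
        ok = (atom.GetTotalNumHs() == 0 and n_f >= 1 and not atom.GetIsAromatic()
              and all(nb.GetAtomicNum() in (6, 9, 8, 16, 15)
                      for nb in atom.GetNeighbors()))
        if not ok:
            return False
        if any(nb.GetIdx() in head_atoms for nb in atom.GetNeighbors()):
            attached = True
    return attached


def _second_class(mol) -> str:
    """Ordered structural rules, most specific first."""
    if _is_perfluoroalkyl_acid(mol):
        return "PFAAs"
    if mol.HasSubstructMatch(_PASF):
        return "PASF-based substances"
    if mol.HasSubstructMatch(_ACID_HEAD) and mol.HasSubstructMatch(_PF_CARBON):
        return "Polyfluoroalkyl acids"
    if mol.HasSubstructMatch(_PFCA_DERIV):
        return "PolyFCA derivatives"
    if mol.HasSubstructMatch(_TELOMER):
        return "n:2 fluorotelomer-based substances"
    elements = {a.GetAtomicNum() for a in mol.GetAtoms()}
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        return "Aromatic PFASs"
    if 14 in elements:
        return "Si PFASs"
    n_carbons = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    if elements <= {6, 9, 1}:
        # hydrofluorocarbons are the small refrigerant-like members
        return "HFCs" if n_carbons <= 3 else "Polyfluoroalkanes"
    return "others"


def assign_primary_class(qsar_ready_smiles: Optional[str],
                         ) -> tuple[str, str]:
    """Assign (first_class, second_class) from the ordered rule table.

    Substances without a resolvable structure map to ``unclassified``;
    structures failing the PFAS definition map to ``Not PFAS`` (later
    reassigned to ``unclassified`` by the hybrid rule).
    """
    if qsar_ready_smiles is None:
        return UNCLASSIFIED, UNCLASSIFIED
    mol = Chem.MolFromSmiles(qsar_ready_smiles)
    if mol is None:
        return UNCLASSIFIED, UNCLASSIFIED
    try:
        if not matches_pfas_definition(qsar_ready_smiles):
            return NOT_PFAS, NOT_PFAS
    except ValueError:
        return UNCLASSIFIED, UNCLASSIFIED
    second = _second_class(mol)
    first = _FIRST_CLASS_OF[second]
    if mol.HasSubstructMatch(_FLUORINATED_RING_C):
        # cyclic variants exist only at the broad-class level; fine classes
        # collapse onto their cyclic first class to keep the vocabulary closed
        first = f"{first}, cyclic"
        second = (f"{second}, cyclic" if second in _CYCLIC_CAPABLE else first)
    return first, second


# --- hybrid rule and secondary categories ------------------------------------

def apply_hybrid_rule(assignments: list[CategoryAssignment],
                      membership_threshold: int = HYBRID_MEMBERSHIP_THRESHOLD,
                      min_secondary_count: int = MIN_SECONDARY_COUNT,
                      ) -> None:
    """Resolve each substance's primary category in place.

    The broad first class is kept unless its landscape membership exceeds
    ``membership_threshold`` (default 300), in which case the finer second
    class is used. Second classes with very low counts fall back to the
    residual bucket of their branch. ``Not PFAS`` and unresolvable
    substances become ``unclassified``.
    """
    first_counts = Counter(a.first_class for a in assignments)
    provisional = []
    for a in assignments:
        if a.first_class in (NOT_PFAS, UNCLASSIFIED):
            provisional.append(UNCLASSIFIED)
        elif first_counts[a.first_class] > membership_threshold:
            provisional.append(a.second_class)
        else:
            provisional.append(a.first_class)
    primary_counts = Counter(provisional)
    for a, label in zip(assignments, provisional):
        if (label != UNCLASSIFIED and label != a.first_class
                and primary_counts[label] < min_secondary_count):
            base = _FIRST_CLASS_OF.get(label.replace(", cyclic", ""),
                                       "Other PFASs")
            if base == "Other PFASs":
                base = "others"
            label = f"{base}, cyclic" if label.endswith(", cyclic") else base
        a.primary_category = label


def assign_secondary(primary_category: str, chain_length: int,
                     threshold: int = CHAIN_THRESHOLD) -> tuple[str, str]:
    """Return (chain_bin, secondary_category) for a substance."""
    chain_bin = "gte7" if chain_length >= threshold else "lt7"
    return chain_bin, f"{primary_category}, {chain_bin}"


def categorize_registry(registry: Registry,
                        membership_threshold: int = HYBRID_MEMBERSHIP_THRESHOLD,
                        chain_threshold: int = CHAIN_THRESHOLD,
                        max_chain: int = 30,
                        ) -> list[CategoryAssignment]:
    """Run the full primary/secondary categorization over a registry."""
    assignments = []
    for rec in registry:
        first, second = assign_primary_class(rec.qsar_ready_smiles)
        chain = 0
        if rec.qsar_ready_smiles is not None:
            try:
                chain = max_cf2_chain_length(rec.qsar_ready_smiles,
                                             max_chain=max_chain)
            except ValueError:
                chain = 0
        assignments.append(CategoryAssignment(
            substance_id=rec.substance_id,
            first_class=first, second_class=second, chain_length=chain))
    apply_hybrid_rule(assignments, membership_threshold)
    for a in assignments:
        a.chain_bin, a.secondary_category = assign_secondary(
            a.primary_category, a.chain_length, chain_threshold)
    return assignments


def assignments_to_frame(assignments: list[CategoryAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "substance_id": a.substance_id,
            "first_class": a.first_class,
            "second_class": a.second_class,
            "primary_category": a.primary_category,
            "chain_length": a.chain_length,
            "chain_bin": a.chain_bin,
            "secondary_category": a.secondary_category,
        } for a in assignments]
    )
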