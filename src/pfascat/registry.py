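"""Substance registry: ingestion, structure standardization, PFAS filtering,
and merging of predicted degradation products.

A registry is an ordered collection of :class:`SubstanceRecord`. Structures
are standardized to "QSAR-ready" form (largest organic fragment, charges
neutralized, stereochemistry stripped) and keyed by the full 27-character
InChIKey so constitutional duplicates collapse regardless of how the SMILES
was written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "SubstanceRecord",
    "DegradantPrediction",
    "Registry",
    "MergeReport",
    "load_substances",
    "standardize_structure",
    "structure_key",
    "matches_pfas_definition",
    "merge_degradants",
    "PFAS_DEFINITION_SMARTS",
]


@dataclass
class SubstanceRecord:
    """One chemical substance in the landscape.

    ``origin`` distinguishes source substances from simulated degradation
    products; degradants carry the id of their parent and follow the
    ``<parent_id>_m_<rank>`` naming scheme.
    """

    substance_id: str
    smiles: str
    qsar_ready_smiles: Optional[str] = None
    structure_key: Optional[str] = None
    name: Optional[str] = None
    casrn: Optional[str] = None
    origin: str = "source"  # "source" | "degradant"
    parent_id: Optional[str] = None


@dataclass(frozen=True)
class DegradantPrediction:
    """A predicted degradation product listed for a parent substance."""

    parent_id: str
    degradant_smiles: str
    rank: int  # 1-based position in the parent's prediction list

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")


@dataclass
class MergeReport:
    """Bookkeeping for a degradant merge.

    ``predicted = unique + intra-set duplicates`` and
    ``added = unique - non_pfas_removed - duplicate_removed``.
    """

    predicted: int = 0
    unique: int = 0
    non_pfas_removed: int = 0
    duplicate_removed: int = 0
    added: int = 0

    def to_dict(self) -> dict:
        return {
            "predicted": self.predicted,
            "unique": self.unique,
            "non_pfas_removed": self.non_pfas_removed,
            "duplicate_removed": self.duplicate_removed,
            "added": self.added,
        }


class Registry:
    """Ordered collection of substance records with unique ids."""

    def __init__(self, records: Iterable[SubstanceRecord] = ()):
        self._records: dict[str, SubstanceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SubstanceRecord) -> None:
        if rec.substance_id in self._records:
            raise ValueError(f"duplicate substance_id: {rec.substance_id!r}")
        self._records[rec.substance_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, substance_id: str) -> bool:
        return substance_id in self._records

    def __getitem__(self, substance_id: str) -> SubstanceRecord:
        return self._records[substance_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def structure_keys(self) -> set[str]:
        return {r.structure_key for r in self if r.structure_key is not None}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "substance_id": r.substance_id,
                    "smiles": r.smiles,
                    "qsar_ready_smiles": r.qsar_ready_smiles,
                    "structure_key": r.structure_key,
                    "name": r.name,
                    "casrn": r.casrn,
                    "origin": r.origin,
                    "parent_id": r.parent_id,
                }
                for r in self
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# --- standardization ---------------------------------------------------------

_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str) -> Optional[str]:
    """Return the QSAR-ready SMILES for ``smiles``, or None if unparseable.

    Keeps the largest organic component, neutralizes charges where chemically
    valid, strips stereochemistry and emits the RDKit canonical SMILES. The
    operation is idempotent.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        mol = _LARGEST_FRAGMENT.choose(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.RemoveStereochemistry(mol)
        return Chem.MolToSmiles(mol)
    except Exception:  # pragma: no cover - defensive against rdkit edge cases
        logger.warning("standardization failed for %r", smiles)
        return None


def structure_key(qsar_ready_smiles: str) -> Optional[str]:
    """Full 27-character InChIKey of a standardized structure, or None."""
    mol = Chem.MolFromSmiles(qsar_ready_smiles)
    if mol is None:
        return None
    key = Chem.MolToInchiKey(mol)
    return key or None


# --- PFAS structural definition ---------------------------------------------

#: The three definitional substructures, as SMARTS with saturation (sp3,
#: four-connected) constraints on the specified carbons:
#:   1. R-(CF2)-CF(R')R''  — adjacent saturated CF2 and CF carbons
#:   2. R-CF2-O-CF2-R'     — perfluoro ether bridge, R,R' in {F, O, saturated C}
#:   3. CF3-C(CF3)R'R''    — gem-bis(trifluoromethyl), R',R'' in {F, saturated C}
#: The list is module-level so an alternative definition (e.g. the broader
#: single -CF2-/-CF3 rule) can be swapped in.
PFAS_DEFINITION_SMARTS: list[str] = [
    "[CX4](F)(F)[CX4]F",
    "[F,O,CX4][CX4](F)(F)O[CX4](F)(F)[F,O,CX4]",
    "FC(F)(F)[CX4H0](C(F)(F)F)([F,CX4])[F,CX4]",
]

_PFAS_PATTERNS = [Chem.MolFromSmarts(s) for s in PFAS_DEFINITION_SMARTS]


def matches_pfas_definition(qsar_ready_smiles: str,
                            patterns: Optional[list[str]] = None) -> bool:
    """True iff the structure contains any of the definitional substructures.

    Raises ValueError on unparseable input (distinct from a negative match).
    """
    mol = Chem.MolFromSmiles(qsar_ready_smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {qsar_ready_smiles!r}")
    pats = (_PFAS_PATTERNS if patterns is None
            else [Chem.MolFromSmarts(p) for p in patterns])
    return any(mol.HasSubstructMatch(p) for p in pats)


# --- ingestion ---------------------------------------------------------------

def _finalize(rec: SubstanceRecord) -> SubstanceRecord:
    rec.qsar_ready_smiles = standardize_structure(rec.smiles)
    if rec.qsar_ready_smiles is None:
        logger.warning("could not parse structure for %s: %r",
                       rec.substance_id, rec.smiles)
        rec.structure_key = None
    else:
        rec.structure_key = structure_key(rec.qsar_ready_smiles)
    return rec


def load_substances(path, id_column: str = "substance_id",
                    smiles_column: str = "smiles",
                    name_column: Optional[str] = None,
                    casrn_column: Optional[str] = None,
                    sep: str = ",") -> Registry:
    """Load a substance table (CSV/TSV) into a registry.

    Unparseable structures are retained with ``structure_key`` absent so they
    can later be reported as unclassifiable rather than silently dropped.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in (id_column, smiles_column) if c not in df.columns]
    if missing:
        raise KeyError(f"missing required columns {missing} in {path}")
    registry = Registry()
    for _, row in df.iterrows():
        rec = SubstanceRecord(
            substance_id=str(row[id_column]),
            smiles="" if pd.isna(row[smiles_column]) else str(row[smiles_column]),
            name=(str(row[name_column])
                  if name_column and not pd.isna(row.get(name_column)) else None),
            casrn=(str(row[casrn_column])
                   if casrn_column and not pd.isna(row.get(casrn_column)) else None),
        )
        registry.add(_finalize(rec))
    return registry


def make_record(substance_id: str, smiles: str, **kwargs) -> SubstanceRecord:
    """Build a fully standardized record from an id and a SMILES."""
    return _finalize(SubstanceRecord(substance_id=substance_id, smiles=smiles,
                                     **kwargs))


# --- degradant merge ---------------------------------------------------------

def merge_degradants(registry: Registry,
                     predictions: Iterable[DegradantPrediction],
                     ) -> tuple[Registry, MergeReport]:
    """Merge predicted degradation products into the registry.

    Degradants are grouped by structure key across all parents (the first
    listing wins), filtered to those meeting the PFAS definition, and
    cross-matched against the existing landscape so that structures already
    present are not added twice. Survivors enter with
    ``substance_id = <parent_id>_m_<rank>`` and ``origin="degradant"``.
    """
    predictions = list(predictions)
    report = MergeReport(predicted=len(predictions))
    for p in predictions:
        if p.parent_id not in registry:
            raise KeyError(f"unknown parent_id: {p.parent_id!r}")

    # Group by structure key; keep first occurrence per unique structure.
    seen: dict[str, DegradantPrediction] = {}
    unkeyed: list[DegradantPrediction] = []
    for p in predictions:
        qrs = standardize_structure(p.degradant_smiles)
        key = structure_key(qrs) if qrs is not None else None
        if key is None:
            logger.warning("unparseable degradant for parent %s rank %d",
                           p.parent_id, p.rank)
            unkeyed.append(p)
            continue
        seen.setdefault(key, p)
    report.unique = len(seen)

    existing = registry.structure_keys()
    merged = Registry(list(registry))
    for key, p in seen.items():
        qrs = standardize_structure(p.degradant_smiles)
        try:
            is_pfas = matches_pfas_definition(qrs)
        except ValueError:
            is_pfas = False
        if not is_pfas:
            report.non_pfas_removed += 1
            continue
        if key in existing:
            report.duplicate_removed += 1
            continue
        rec = SubstanceRecord(
            substance_id=f"{p.parent_id}_m_{p.rank}",
            smiles=p.degradant_smiles,
            qsar_ready_smiles=qrs,
            structure_key=key,
            origin="degradant",
            parent_id=p.parent_id,
        )
        merged.add(rec)
        existing.add(key)
        report.added += 1
    return merged, report
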