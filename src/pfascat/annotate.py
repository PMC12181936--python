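"""Exposure, physicochemical and data-availability annotation, plus the
category triage workflow that nominates data-collection candidates.

Physical state is assigned at 25 °C from predicted melting and boiling
points; solubility/volatility cutoffs (water solubility 0.5 mg/L, vapour
pressure 75 mmHg, Henry's law constant 0.1 atm·m³/mol) combine with state
into four designations A–D. Inventory status, production-volume bins and
monitoring-list tags feed a triage that focuses on data-poor categories with
inventory overlap and monitoring evidence, then nominates representative
substances that are actually procurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .select import SelectionResult, select_category
from .similarity import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PropertyRecord",
    "AnnotationRecord",
    "TriageResult",
    "physical_state",
    "assign_designation",
    "bin_production_volume",
    "tag_lists",
    "data_availability_matrix",
    "data_poor_categories",
    "select_candidates",
    "PV_BINS",
]

STATE_TEMPERATURE_C = 25.0
WS_SOLUBLE_MGL = 0.5
VP_VOLATILE_MMHG = 75.0
HLC_HIGHLY_VOLATILE = 0.1

QUALIFYING_EFFECT_TYPES = {"NOAEL", "LOAEL", "LOEL", "NOEL", "NEL", "LEL"}
QUALIFYING_ROUTES = {"oral", "inhalation"}


@dataclass
class PropertyRecord:
    """Predicted physicochemical properties; units are fixed:
    melting/boiling point °C, water solubility mg/L, vapour pressure mmHg,
    Henry's law constant atm·m³/mol."""

    substance_id: str
    melting_point: Optional[float] = None
    boiling_point: Optional[float] = None
    water_solubility: Optional[float] = None
    vapour_pressure: Optional[float] = None
    henrys_law: Optional[float] = None


@dataclass
class AnnotationRecord:
    substance_id: str
    physical_state: str = "unknown"
    designation: str = "not determined"
    inventory_status: str = "unclassified"  # active | inactive | unclassified
    pv_bin: Optional[str] = None
    list_tags: set[str] = field(default_factory=set)
    has_tox_data_by_study_type: dict[str, bool] = field(default_factory=dict)


@dataclass
class TriageResult:
    terminal_label: str
    data_poor: bool
    on_tsca: bool
    on_tsca_active: bool
    on_monitoring_lists: bool
    nominated_candidates: list[tuple[str, str]] = field(default_factory=list)
    # (substance_id, rationale) pairs; empty when no branch produced one

    @property
    def triaged(self) -> bool:
        return self.data_poor and self.on_tsca and self.on_monitoring_lists


# --- physical state and designation ------------------------------------------

def physical_state(rec: PropertyRecord) -> str:
    """Gas: bp < 25 °C. Solid: mp >= 25 °C. Liquid: mp < 25 and bp >= 25."""
    mp, bp = rec.melting_point, rec.boiling_point
    if bp is not None and bp < STATE_TEMPERATURE_C:
        return "gas"
    if mp is not None and mp >= STATE_TEMPERATURE_C:
        return "solid"
    if mp is not None and bp is not None and bp >= STATE_TEMPERATURE_C:
        return "liquid"
    return "unknown"


def assign_designation(rec: PropertyRecord,
                       soluble_ge: bool = True) -> str:
    """Physical state + physicochemical designation A–D.

    A: insoluble solid. B: soluble solid, or soluble non-volatile liquid.
    C: soluble volatile liquid, insoluble liquid, or soluble gas.
    D: insoluble gas or highly volatile gas (D wins when a gas is both
    soluble and highly volatile). Anything else: "not determined".
    Comparisons use >= on the soluble/volatile side by default.
    """
    state = physical_state(rec)
    ws, vp, hlc = rec.water_solubility, rec.vapour_pressure, rec.henrys_law

    def ge(v, cutoff):
        return v >= cutoff if soluble_ge else v > cutoff

    soluble = None if ws is None else ge(ws, WS_SOLUBLE_MGL)
    volatile = None if vp is None else ge(vp, VP_VOLATILE_MMHG)
    highly_volatile = None if hlc is None else ge(hlc, HLC_HIGHLY_VOLATILE)

    if state == "solid" and soluble is not None:
        return "B" if soluble else "A"
    if state == "liquid" and soluble is not None:
        if not soluble:
            return "C"
        if volatile is None:
            return "not determined"
        return "C" if volatile else "B"
    if state == "gas":
        if highly_volatile:
            return "D"
        if soluble is None:
            return "not determined"
        return "C" if soluble else "D"
    return "not determined"


# --- production volume bins ---------------------------------------------------

#: The ten reporting ranges, in pounds. Some printed ranges overlap because
#: they mirror heterogeneous source range strings; numeric values are mapped
#: through the most-specific (narrowest) ladder below.
PV_BINS: list[str] = [
    "<25,000 lbs",
    "25,000–<100,000 lbs",
    "100,000–<500,000 lbs",
    "500,000–<1,000,000 lbs",
    "<1,000,000 lbs",
    "1,000,000–<10,000,000 lbs",
    "1,000,000–<20,000,000 lbs",
    "20,000,000–<100,000,000 lbs",
    "50,000,000–<100,000,000 lbs",
    "100,000,000–<1,000,000,000 lbs",
]

_NUMERIC_LADDER = [
    (25_000, "<25,000 lbs"),
    (100_000, "25,000–<100,000 lbs"),
    (500_000, "100,000–<500,000 lbs"),
    (1_000_000, "500,000–<1,000,000 lbs"),
    (10_000_000, "1,000,000–<10,000,000 lbs"),
    (20_000_000, "1,000,000–<20,000,000 lbs"),
    (50_000_000, "20,000,000–<100,000,000 lbs"),
    (100_000_000, "50,000,000–<100,000,000 lbs"),
    (1_000_000_000, "100,000,000–<1,000,000,000 lbs"),
]


def bin_production_volume(value) -> Optional[str]:
    """Map a numeric pounds value or a source range string to one PV bin.

    Boundary values fall into the bin whose lower bound they equal.
    Unparseable input yields None with a warning.
    """
    if isinstance(value, str):
        text = value.strip().replace("-", "–")
        if not text.endswith("lbs"):
            text = text + " lbs"
        if text in PV_BINS:
            return text
        try:
            value = float(value.replace(",", ""))
        except (ValueError, AttributeError):
            logger.warning("unparseable production volume %r", value)
            return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        logger.warning("unparseable production volume %r", value)
        return None
    if not np.isfinite(v) or v < 0:
        logger.warning("unusable production volume %r", value)
        return None
    for upper, label in _NUMERIC_LADDER:
        if v < upper:
            return label
    logger.warning("production volume %r above the largest range", value)
    return None


# --- list tagging -------------------------------------------------------------

def tag_lists(registry, list_members: dict[str, Iterable[str]],
              inventory_active: Iterable[str] = (),
              inventory_inactive: Iterable[str] = (),
              ) -> dict[str, AnnotationRecord]:
    """Tag registry records with monitoring-list membership and inventory
    status. Identifiers match on substance_id first, then structure_key.
    Unmatched list identifiers are logged, not fatal."""
    by_id = {r.substance_id: r for r in registry}
    by_key = {}
    for r in registry:
        if r.structure_key is not None:
            by_key.setdefault(r.structure_key, []).append(r)

    annotations = {r.substance_id: AnnotationRecord(r.substance_id)
                   for r in registry}

    def resolve(ident: str):
        if ident in by_id:
            return [by_id[ident]]
        if ident in by_key:
            return by_key[ident]
        return []

    active = set(inventory_active)
    inactive = set(inventory_inactive)
    for r in registry:
        matched_active = r.substance_id in active or (
            r.structure_key is not None and r.structure_key in active)
        matched_inactive = r.substance_id in inactive or (
            r.structure_key is not None and r.structure_key in inactive)
        if matched_active:
            annotations[r.substance_id].inventory_status = "active"
        elif matched_inactive:
            annotations[r.substance_id].inventory_status = "inactive"

    for list_name, members in list_members.items():
        for ident in members:
            recs = resolve(ident)
            if not recs:
                logger.info("list %s identifier %r not in registry",
                            list_name, ident)
            for rec in recs:
                annotations[rec.substance_id].list_tags.add(list_name)
    return annotations


def data_availability_matrix(members_by_terminal: dict[str, list[str]],
                             tox_records: pd.DataFrame,
                             annotations: dict[str, AnnotationRecord],
                             ) -> pd.DataFrame:
    """0/1 heatmap matrix: terminal categories × (study types + lists).

    A cell is 1 when any category member has a record of that study type
    (oral/inhalation routes) or sits on that monitoring list.
    """
    study_types = (sorted(tox_records["study_type"].dropna().unique())
                   if "study_type" in tox_records.columns else [])
    list_names = sorted({tag for ann in annotations.values()
                         for tag in ann.list_tags})
    rows = {}
    for label, members in sorted(members_by_terminal.items()):
        member_set = set(members)
        row = {}
        for st in study_types:
            sub = tox_records[
                (tox_records["study_type"] == st)
                & tox_records["route"].isin(QUALIFYING_ROUTES)]
            row[f"study:{st}"] = int(bool(member_set
                                          & set(sub["substance_id"])))
        for name in list_names:
            row[f"list:{name}"] = int(any(
                name in annotations[s].list_tags
                for s in members if s in annotations))
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# --- data-poor gate and triage ------------------------------------------------

def data_poor_categories(members_by_terminal: dict[str, list[str]],
                         tox_records: pd.DataFrame) -> set[str]:
    """Terminal categories with no member holding a qualifying repeated-dose
    record (oral or inhalation route, effect type among
    NOAEL/LOAEL/LOEL/NOEL/NEL/LEL)."""
    if len(tox_records):
        qualifying = tox_records[
            tox_records["route"].isin(QUALIFYING_ROUTES)
            & tox_records["effect_type"].isin(QUALIFYING_EFFECT_TYPES)]
        covered = set(qualifying["substance_id"])
    else:
        covered = set()
    return {label for label, members in members_by_terminal.items()
            if not any(s in covered for s in members)}


def select_candidates(members_by_terminal: dict[str, list[str]],
                      selections: dict[str, SelectionResult],
                      distances: DistanceMatrix,
                      annotations: dict[str, AnnotationRecord],
                      data_poor: set[str],
                      require_active: bool = False,
                      maxmin_k: int = 3,
                      ) -> dict[str, TriageResult]:
    """Triage workflow over terminal categories.

    Gates: the category must be data-poor, contain inventory members
    (active members when ``require_active``), and contain members on at
    least one monitoring list. For gated categories, candidates come from:
    (1) existing centroid/MaxMin picks on the inventory; (2) the inventory
    member nearest the centroid; (3) centroid/MaxMin recomputed on the
    inventory-constrained category.
    """
    def status(sid: str) -> str:
        ann = annotations.get(sid)
        return ann.inventory_status if ann else "unclassified"

    def on_inventory(sid: str) -> bool:
        s = status(sid)
        return s == "active" if require_active else s in ("active", "inactive")

    results: dict[str, TriageResult] = {}
    for label, members in members_by_terminal.items():
        inv_members = [s for s in members if on_inventory(s)]
        on_tsca = any(status(s) in ("active", "inactive") for s in members)
        on_active = any(status(s) == "active" for s in members)
        on_lists = any(annotations.get(s) and annotations[s].list_tags
                       for s in members)
        res = TriageResult(
            terminal_label=label,
            data_poor=label in data_poor,
            on_tsca=on_tsca,
            on_tsca_active=on_active,
            on_monitoring_lists=on_lists,
        )
        results[label] = res
        gate_inventory = on_active if require_active else on_tsca
        if not (res.data_poor and gate_inventory and on_lists):
            continue

        sel = selections.get(label)
        if sel is not None:
            direct = [s for s in sel.picks if on_inventory(s)]
            if direct:
                res.nominated_candidates = [
                    (s, "centroid on inventory" if s == sel.centroid_id
                     else "maxmin pick on inventory") for s in direct]
                continue
        # fallback 1: is the next-closest member to the centroid on the
        # inventory? (ties to lowest index)
        if sel is not None and len(members) > 1:
            sub = distances.subset(members)
            index = {s: i for i, s in enumerate(sub.substance_ids)}
            ci = index[sel.centroid_id]
            others = [s for s in sub.substance_ids if s != sel.centroid_id]
            next_closest = min(others, key=lambda s: (sub.d[ci, index[s]],
                                                      index[s]))
            if on_inventory(next_closest):
                res.nominated_candidates = [
                    (next_closest, "next-closest member to centroid on inventory")]
                continue
        # fallback 2: recompute selection on the constrained category
        if inv_members:
            constrained = select_category(distances.subset(inv_members),
                                          label, k=maxmin_k)
            res.nominated_candidates = [
                (s, "constrained-landscape centroid" if j == 0
                 else "constrained-landscape maxmin pick")
                for j, s in enumerate(constrained.picks)]
        else:
            logger.info("category %r has no inventory members to nominate",
                        label)
    return results
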