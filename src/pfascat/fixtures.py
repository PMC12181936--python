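"""Synthetic chemical landscapes with known ground truth.

Every pipeline stage is testable without external downloads: structures are
built from homologous-series templates (perfluorocarboxylic and -sulfonic
acids, fluorotelomer alcohols, perfluoroalkane sulfonyl fluorides, aromatic
and ether-bridged perfluoro compounds, plus non-PFAS decoys), so the
intended chain length, family and PFAS-definition status of each substance
are known by construction. Companion generators emit physicochemical
property tables, ToxVal-style toxicity records with a planted POD model,
inventory/monitoring lists and NAM flag tables with a planted feature–flag
odds ratio. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import pod as podmod
from .registry import Registry, make_record

__all__ = [
    "FixtureSpec",
    "generate_landscape",
    "generate_property_table",
    "generate_tox_records",
    "generate_flag_table",
    "generate_list_files",
    "generate_bundle",
    "FAMILIES",
]

FAMILIES = ("PFCA", "PFSA", "fluorotelomer alcohol", "PASF",
            "aromatic PFAS", "ether PFAS", "non-PFAS decoys")

_DECOYS = ["CCO", "c1ccccc1", "CC(F)(F)F", "CCCCCC", "CC(=O)O",
           "c1ccncc1", "CCN", "CCOC(C)=O", "CC(C)O", "CCCCO"]

_AROMATIC_DECOR = ["", "C", "CC", "O", "Cl", "OC", "C(C)C", "CCC"]
_TELOMER_HEADS = ["OCC", "COCC", "CCOCC", "OCCOCC"]
_ETHER_CAPS = ["FC(F)(F)O", "CO", "CCO", "COCCO"]


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic landscape.

    ``n_series`` is the number of decorated variants per family and chain
    length (families without chemically safe decorations emit one series).
    ``planted_gte7_pod_shift`` multiplies the true POD median of long-chain
    substances (0.1 plants a 10-fold lower POD for the gte7 bin);
    ``planted_flag_or`` is the target feature–flag odds ratio for the NAM
    flag generator.
    """

    n_series: int = 2
    chain_min: int = 3
    chain_max: int = 10
    families: tuple[str, ...] = FAMILIES
    seed: int = 0
    planted_gte7_pod_shift: float = 0.1
    planted_flag_or: float = 10.0

    def __post_init__(self):
        if not self.families:
            raise ValueError("empty family list")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")


def _family_smiles(family: str, n: int, variant: int) -> Optional[str]:
    chain = "C(F)(F)" * n
    if family == "PFCA":
        return f"OC(=O){chain}F" if variant == 0 else None
    if family == "PFSA":
        return f"OS(=O)(=O){chain}F" if variant == 0 else None
    if family == "PASF":
        return f"FS(=O)(=O){chain}F" if variant == 0 else None
    if family == "fluorotelomer alcohol":
        heads = _TELOMER_HEADS
        if variant >= len(heads):
            return None
        return f"{heads[variant]}{chain}F"
    if family == "aromatic PFAS":
        decs = _AROMATIC_DECOR
        if variant >= len(decs):
            return None
        dec = decs[variant]
        ring = f"c1ccc({dec})cc1" if dec else "c1ccccc1"
        return f"{ring}{chain}F"
    if family == "ether PFAS":
        caps = _ETHER_CAPS
        if variant >= len(caps):
            return None
        return f"{caps[variant]}{chain}F"
    raise AssertionError(family)


def generate_landscape(spec: FixtureSpec) -> tuple[Registry, pd.DataFrame]:
    """Build the registry and its truth table.

    The truth table records, per substance, the family, the intended
    maximum contiguous perfluorinated chain length, and whether the
    structure meets the PFAS structural definition.
    """
    registry = Registry()
    truth_rows = []
    counter = 0
    for family in spec.families:
        if family == "non-PFAS decoys":
            for smi in _DECOYS[: max(len(_DECOYS) // 2,
                                     spec.n_series * 2)]:
                counter += 1
                sid = f"SYN{counter:05d}"
                registry.add(make_record(sid, smi))
                truth_rows.append({"substance_id": sid, "family": family,
                                   "true_chain_length": 0 if "F" not in smi
                                   else 1,
                                   "is_pfas": False})
            continue
        for n in range(spec.chain_min, spec.chain_max + 1):
            for variant in range(spec.n_series):
                smi = _family_smiles(family, n, variant)
                if smi is None:
                    continue
                counter += 1
                sid = f"SYN{counter:05d}"
                registry.add(make_record(sid, smi))
                truth_rows.append({"substance_id": sid, "family": family,
                                   "true_chain_length": n,
                                   "is_pfas": n >= 2})
    truth = pd.DataFrame(truth_rows)
    return registry, truth


# --- companion tables ---------------------------------------------------------

def generate_property_table(registry: Registry, seed: int = 0,
                            missing_rate: float = 0.05) -> pd.DataFrame:
    """Predicted-property table spanning all physical states and designations."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in registry:
        state = rng.choice(["solid", "liquid", "gas"], p=[0.45, 0.4, 0.15])
        if state == "gas":
            mp, bp = rng.uniform(-150, -60), rng.uniform(-120, 20)
        elif state == "solid":
            mp, bp = rng.uniform(30, 250), rng.uniform(150, 400)
        else:
            mp, bp = rng.uniform(-100, 20), rng.uniform(40, 250)
        row = {
            "substance_id": rec.substance_id,
            "melting_point": mp,
            "boiling_point": bp,
            "water_solubility": float(10 ** rng.uniform(-4, 4)),
            "vapour_pressure": float(10 ** rng.uniform(-6, 3)),
            "henrys_law": float(10 ** rng.uniform(-8, 0.5)),
        }
        for col in ("melting_point", "boiling_point", "water_solubility",
                    "vapour_pressure", "henrys_law"):
            if rng.random() < missing_rate:
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def generate_tox_records(truth: pd.DataFrame, seed: int = 0,
                         base_median: float = 10.0,
                         gsd: float = 2.0,
                         gte7_shift: float = 0.1,
                         records_per_substance: int = 6,
                         chain_threshold: int = 7,
                         data_fraction: float = 1.0,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ToxVal-style records sampled from a planted per-substance POD model.

    Each covered substance gets a true lognormal BMDh distribution with
    median ``base_median`` mg/kg-bw/day (multiplied by ``gte7_shift`` for
    long-chain substances) and geometric sd ``gsd``. Reported effect values
    are back-multiplied through the harmonization factors so running the
    harmonization chain recovers samples from the true distribution.
    ``gsd=1`` produces zero-noise records. Returns (records, truth) where
    the second frame carries each substance's true median and sd.
    """
    rng = np.random.default_rng(seed)
    conv = podmod.species_conversion_factors()
    species_pool = sorted(conv)
    study_pool = sorted(podmod.DURATION_CLASS)
    effect_pool = ["NOAEL", "NOEL", "LOAEL", "LOEL"]
    mean_mult = float(np.mean(podmod.CONCEPTUAL_MODEL_MULTIPLIERS["noncancer"]))

    rec_rows, truth_rows = [], []
    for _, row in truth.iterrows():
        if not row["is_pfas"] or rng.random() > data_fraction:
            continue
        median = base_median
        if row["true_chain_length"] >= chain_threshold:
            median *= gte7_shift
        sigma = float(np.log(gsd))
        truth_rows.append({"substance_id": row["substance_id"],
                           "true_median_bmdh": median, "true_log_sd": sigma})
        for _ in range(records_per_substance):
            true_bmdh = float(median * np.exp(sigma * rng.standard_normal()))
            species = str(rng.choice(species_pool))
            study = str(rng.choice(study_pool))
            effect = str(rng.choice(effect_pool))
            value = true_bmdh / mean_mult  # undo conceptual-model mean
            value *= conv[species]         # undo human-equivalence scaling
            value *= podmod.DURATION_FACTORS[podmod.DURATION_CLASS[study]]
            if effect in podmod.LOAEL_LIKE:
                value *= podmod.LOAEL_TO_NOAEL
            rec_rows.append({
                "substance_id": row["substance_id"], "route": "oral",
                "study_type": study, "effect_type": effect,
                "value": value, "units": "mg/kg-bw/day",
                "species": species, "effect_class": "noncancer"})
    return pd.DataFrame(rec_rows), pd.DataFrame(truth_rows)


def generate_flag_table(substance_ids: Sequence[str],
                        feature: Sequence[int],
                        seed: int = 0,
                        target_or: float = 10.0,
                        base_rate: float = 0.2,
                        qc_fail_rate: float = 0.1,
                        flag_name: str = "NR_flag") -> pd.DataFrame:
    """Flag table with a planted feature–flag odds ratio (in expectation).

    The flag positive probability is ``base_rate`` for feature-negative
    substances and the odds-ratio-shifted rate for feature-positive ones;
    positive flags are reported as level 1 or 2. Raises when the target
    odds ratio is infeasible for the base rate.
    """
    odds0 = base_rate / (1.0 - base_rate)
    odds1 = target_or * odds0
    p1 = odds1 / (1.0 + odds1)
    if not 0.0 < p1 < 1.0:
        raise ValueError(f"odds ratio {target_or} infeasible for base rate "
                         f"{base_rate}")
    rng = np.random.default_rng(seed)
    feature = np.asarray(feature, dtype=int)
    if feature.shape[0] != len(substance_ids):
        raise ValueError("feature vector must align with substance_ids")
    rows = []
    for sid, f in zip(substance_ids, feature):
        p = p1 if f else base_rate
        positive = rng.random() < p
        level = int(rng.integers(1, 3)) if positive else 0
        rows.append({"substance_id": sid, flag_name: level,
                     "qc_pass": bool(rng.random() >= qc_fail_rate)})
    return pd.DataFrame(rows).set_index("substance_id")


def generate_list_files(registry: Registry, seed: int = 0,
                        active_fraction: float = 0.15,
                        inactive_fraction: float = 0.2,
                        n_lists: int = 4,
                        list_fraction: float = 0.1,
                        ) -> dict[str, list[str]]:
    """Inventory (active/inactive) and monitoring-list memberships."""
    rng = np.random.default_rng(seed)
    ids = registry.ids
    n = len(ids)
    shuffled = list(ids)
    rng.shuffle(shuffled)
    n_active = int(round(active_fraction * n))
    n_inactive = int(round(inactive_fraction * n))
    out = {"inventory_active": sorted(shuffled[:n_active]),
           "inventory_inactive": sorted(shuffled[n_active:
                                                 n_active + n_inactive])}
    for i in range(n_lists):
        members = [s for s in ids if rng.random() < list_fraction]
        out[f"monitoring_list_{i + 1}"] = members
    return out


def generate_bundle(spec: FixtureSpec, outdir) -> dict:
    """Emit a complete fixture bundle (registry, truth, properties, tox
    records, flags, lists) into a directory with a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry, truth = generate_landscape(spec)
    registry.to_csv(outdir / "registry.csv")
    truth.to_csv(outdir / "truth.csv", index=False)
    props = generate_property_table(registry, seed=spec.seed + 1)
    props.to_csv(outdir / "properties.csv", index=False)
    tox, tox_truth = generate_tox_records(
        truth, seed=spec.seed + 2, gte7_shift=spec.planted_gte7_pod_shift)
    tox.to_csv(outdir / "tox_records.csv", index=False)
    tox_truth.to_csv(outdir / "tox_truth.csv", index=False)
    feature = truth["family"].eq("PASF").astype(int).to_numpy()
    flags = generate_flag_table(truth["substance_id"].tolist(), feature,
                                seed=spec.seed + 3,
                                target_or=spec.planted_flag_or)
    flags.to_csv(outdir / "flags.csv")
    lists = generate_list_files(registry, seed=spec.seed + 4)
    for name, members in lists.items():
        pd.DataFrame({"substance_id": members}).to_csv(
            outdir / f"{name}.csv", index=False)
    manifest = {
        "spec": {"n_series": spec.n_series, "chain_min": spec.chain_min,
                 "chain_max": spec.chain_max,
                 "families": list(spec.families), "seed": spec.seed,
                 "planted_gte7_pod_shift": spec.planted_gte7_pod_shift,
                 "planted_flag_or": spec.planted_flag_or},
        "n_substances": len(registry),
        "files": sorted(p.name for p in outdir.iterdir() if p.is_file()
                        and p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
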