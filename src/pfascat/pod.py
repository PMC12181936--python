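"""Harmonization of in vivo effect levels to human-equivalent benchmark
doses (BMDh) and per-substance points of departure (PODs).

The chain follows the harmonization framework of Aurisano and colleagues:

1. filter to oral repeated-dose records with listed effect-level types,
   study types and dose units;
2. extrapolate the effect level to a chronic NOAEL equivalent
   (LOAEL-type values ÷ 3; subchronic ÷ 2; subacute ÷ 5);
3. scale to a human-equivalent dose by a species body-weight conversion
   factor (quarter-power allometry by default);
4. convert the NOAEL equivalent to a BMDh as the mean of two conceptual-
   model multiples;
5. summarize each substance's BMDh records as the 25th percentile of a
   lognormal fitted by moment matching, substituting the global median sd
   when fewer than 5 records are available.

Every factor application is logged on the record so the input/output ratio
can be reconstructed exactly from the audit trail.

The species conversion factors and conceptual-model multipliers are not
published with the categorization study; the defaults below are
reconstructions from the cited framework and are fully configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "ToxRecord",
    "BMDhRecord",
    "CategoryPodSummary",
    "filter_records",
    "harmonize_effect_level",
    "to_human_equivalent",
    "to_bmdh",
    "harmonize_records",
    "substance_pod_p25",
    "substance_pods",
    "category_pod_summary",
    "SPECIES_BW_KG",
    "species_conversion_factors",
    "CONCEPTUAL_MODEL_MULTIPLIERS",
]

RETAINED_ROUTES = {"oral"}
RETAINED_EFFECT_TYPES = {"NOEL", "NOAEL", "NEL", "NOAEC",
                         "LOAEL", "LOEL", "LOAEC", "LEL"}
LOAEL_LIKE = {"LOAEL", "LOEL", "LOAEC", "LEL"}
RETAINED_STUDY_TYPES = {"short-term", "subchronic", "chronic", "developmental",
                        "reproduction", "reproduction developmental", "28-day"}
RETAINED_UNITS = {"mg/kg-bw/day", "mg/kg"}
STANDARD_SPECIES = {"rat", "mouse", "rabbit", "dog", "hamster", "guinea pig"}

LOAEL_TO_NOAEL = 3.0
#: study type -> duration class; subacute covers short-term and 28-day
DURATION_CLASS = {
    "short-term": "subacute",
    "28-day": "subacute",
    "subchronic": "subchronic",
    "chronic": "chronic",
    "developmental": "chronic",
    "reproduction": "chronic",
    "reproduction developmental": "chronic",
}
DURATION_FACTORS = {"subacute": 5.0, "subchronic": 2.0, "chronic": 1.0}

#: average body weights (kg) used for allometric human-equivalence scaling
SPECIES_BW_KG = {"human": 70.0, "rat": 0.25, "mouse": 0.03, "rabbit": 2.0,
                 "dog": 10.0, "hamster": 0.1, "guinea pig": 0.5}


def species_conversion_factors(bw: Optional[dict[str, float]] = None,
                               exponent: float = 0.25) -> dict[str, float]:
    """Divisors (bw_human/bw_species)**exponent per species (rat ≈ 4.1)."""
    bw = dict(SPECIES_BW_KG if bw is None else bw)
    human = bw.pop("human")
    return {sp: (human / w) ** exponent for sp, w in bw.items()}


#: effect class -> the two conceptual-model NOAEL→BMD multipliers
CONCEPTUAL_MODEL_MULTIPLIERS = {
    "noncancer": (1.0 / 3.0, 2.0 / 3.0),
    "repro_dev": (1.0 / 3.0, 2.0 / 3.0),
}

Z_P25 = float(norm.ppf(0.25))  # -0.67449...


@dataclass
class ToxRecord:
    substance_id: str
    route: str
    study_type: str
    effect_type: str
    value: float
    units: str = "mg/kg-bw/day"
    species: str = "rat"
    effect_class: str = "noncancer"  # noncancer | repro_dev


@dataclass
class BMDhRecord:
    substance_id: str
    effect_class: str
    input_value: float
    chronic_noael_equiv: float
    human_equiv: float
    bmdh: float
    factors_applied: list[tuple[str, float]] = field(default_factory=list)

    def reconstructed_ratio(self) -> float:
        """Product of logged factors; equals bmdh / input_value."""
        out = 1.0
        for _, f in self.factors_applied:
            out *= f
        return out


# --- filtering ----------------------------------------------------------------

def filter_records(raw: Sequence[ToxRecord]) -> list[ToxRecord]:
    """Retain oral records with listed effect types, study types, units and
    standardizable species. Filtering is the contract: nothing here errors."""
    out = []
    for r in raw:
        if r.route not in RETAINED_ROUTES:
            continue
        if r.effect_type not in RETAINED_EFFECT_TYPES:
            continue
        if r.study_type not in RETAINED_STUDY_TYPES:
            continue
        if r.units not in RETAINED_UNITS:
            continue
        if r.species not in STANDARD_SPECIES:
            continue
        if not (r.value > 0):
            continue
        out.append(r)
    return out


# --- harmonization chain ------------------------------------------------------

def harmonize_effect_level(record: ToxRecord,
                           ) -> Optional[tuple[float, list[tuple[str, float]]]]:
    """Extrapolate an effect level to a chronic NOAEL equivalent.

    LOAEL-type values are divided by 3; subchronic studies by 2; subacute
    (short-term/28-day) by 5. Returns (value, factor audit) or None for an
    unmapped study type.
    """
    duration = DURATION_CLASS.get(record.study_type)
    if duration is None:
        logger.warning("unknown study type %r; record skipped",
                       record.study_type)
        return None
    factors: list[tuple[str, float]] = []
    value = record.value
    if record.effect_type in LOAEL_LIKE:
        value /= LOAEL_TO_NOAEL
        factors.append(("loael_to_noael", 1.0 / LOAEL_TO_NOAEL))
    dur_factor = DURATION_FACTORS[duration]
    if dur_factor != 1.0:
        value /= dur_factor
        factors.append((f"{duration}_to_chronic", 1.0 / dur_factor))
    return value, factors


def to_human_equivalent(chronic_noael_equiv: float, species: str,
                        conversion_factors: Optional[dict[str, float]] = None,
                        ) -> Optional[tuple[float, tuple[str, float]]]:
    """Divide by the species' body-weight conversion factor."""
    table = (species_conversion_factors() if conversion_factors is None
             else conversion_factors)
    factor = table.get(species)
    if factor is None:
        logger.warning("no conversion factor for species %r; record skipped",
                       species)
        return None
    return chronic_noael_equiv / factor, (f"bw_{species}", 1.0 / factor)


def to_bmdh(human_equiv: float, effect_class: str,
            multipliers: Optional[dict[str, tuple[float, float]]] = None,
            ) -> Optional[tuple[float, tuple[str, float]]]:
    """Mean of the two conceptual-model multiples of the human equivalent."""
    table = CONCEPTUAL_MODEL_MULTIPLIERS if multipliers is None else multipliers
    pair = table.get(effect_class)
    if pair is None:
        logger.warning("no conceptual models for effect class %r; skipped",
                       effect_class)
        return None
    m1, m2 = pair
    mean_mult = (m1 + m2) / 2.0
    return human_equiv * mean_mult, ("conceptual_models_mean", mean_mult)


def harmonize_records(records: Sequence[ToxRecord],
                      conversion_factors: Optional[dict[str, float]] = None,
                      multipliers: Optional[dict[str, tuple[float, float]]] = None,
                      ) -> list[BMDhRecord]:
    """Run the full chain over filtered records."""
    out = []
    for r in records:
        step1 = harmonize_effect_level(r)
        if step1 is None:
            continue
        chronic, audit = step1
        step2 = to_human_equivalent(chronic, r.species, conversion_factors)
        if step2 is None:
            continue
        human, f2 = step2
        step3 = to_bmdh(human, r.effect_class, multipliers)
        if step3 is None:
            continue
        bmdh, f3 = step3
        out.append(BMDhRecord(
            substance_id=r.substance_id, effect_class=r.effect_class,
            input_value=r.value, chronic_noael_equiv=chronic,
            human_equiv=human, bmdh=bmdh,
            factors_applied=audit + [f2, f3]))
    return out


# --- per-substance POD --------------------------------------------------------

def substance_pod_p25(values: Sequence[float],
                      global_median_sd: Optional[float] = None,
                      min_records_for_own_sd: int = 5) -> float:
    """25th percentile of a lognormal moment-matched to the BMDh sample.

    σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2, pod = exp(μ + z₀.₂₅ σ).
    With fewer than ``min_records_for_own_sd`` records the sample sd is
    replaced by ``global_median_sd``. A zero sd degenerates to the mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no records for substance")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if v.size < min_records_for_own_sd and global_median_sd is not None:
        sd = float(global_median_sd)
    if sd <= 0 or mean <= 0:
        return mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return math.exp(mu + Z_P25 * math.sqrt(sigma2))


def substance_pods(bmdh_records: Sequence[BMDhRecord],
                   effect_class: str = "noncancer",
                   min_records_for_own_sd: int = 5) -> pd.DataFrame:
    """Per-substance PODs for one effect class, with the median-sd fallback.

    Returns a frame with substance_id, n_records, mean, sd, pod.
    """
    grouped: dict[str, list[float]] = {}
    for r in bmdh_records:
        if r.effect_class == effect_class:
            grouped.setdefault(r.substance_id, []).append(r.bmdh)
    if not grouped:
        return pd.DataFrame(columns=["substance_id", "n_records",
                                     "mean_bmdh", "sd_bmdh", "pod_p25"])
    sds = [float(np.std(v, ddof=1)) for v in grouped.values() if len(v) > 1]
    global_median_sd = float(np.median(sds)) if sds else 0.0
    rows = []
    for sid, v in sorted(grouped.items()):
        arr = np.asarray(v, dtype=float)
        pod = substance_pod_p25(arr, global_median_sd, min_records_for_own_sd)
        rows.append({"substance_id": sid, "n_records": len(v),
                     "mean_bmdh": float(arr.mean()),
                     "sd_bmdh": float(arr.std(ddof=1)) if len(v) > 1 else 0.0,
                     "pod_p25": pod})
    return pd.DataFrame(rows)


# --- category summaries -------------------------------------------------------

@dataclass
class CategoryPodSummary:
    terminal_label: str
    effect_class: str
    n_substances: int
    log10_pods: np.ndarray
    median: float
    q1: float
    q3: float
    iqr: float
    lo: float
    hi: float


def category_pod_summary(pods: pd.DataFrame,
                         terminal_of: dict[str, str],
                         effect_class: str = "noncancer",
                         ) -> list[CategoryPodSummary]:
    """log10 POD distribution per terminal category (quartiles, IQR, range)."""
    out = []
    df = pods.copy()
    df["terminal_label"] = df["substance_id"].map(terminal_of)
    df = df.dropna(subset=["terminal_label"])
    for label, grp in df.groupby("terminal_label", sort=True):
        logs = np.log10(grp["pod_p25"].to_numpy(dtype=float))
        q1, med, q3 = np.percentile(logs, [25, 50, 75])
        out.append(CategoryPodSummary(
            terminal_label=str(label), effect_class=effect_class,
            n_substances=len(grp), log10_pods=logs,
            median=float(med), q1=float(q1), q3=float(q3),
            iqr=float(q3 - q1), lo=float(logs.min()), hi=float(logs.max())))
    return out


def pod_boxplot(summaries: list[CategoryPodSummary], path) -> None:
    """Box-and-whisker export of category POD distributions (log10 scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [s.terminal_label for s in summaries]
    data = [s.log10_pods for s in summaries]
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(labels)), 4))
    ax.boxplot(data, tick_labels=labels, whis=1.5)
    ax.set_ylabel("log10 POD (mg/kg-bw/day)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
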