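"""Enrichment of binary structural features against qualitative NAM flags.

Flags take values 0 (low concern), 1 (medium confidence) and 2 (high
confidence); the immune flag is binary (0/1). Only substances passing
analytical QC are carried forward. Each feature × flag combination is
scored with a one-sided Fisher's exact test on its 2×2 contingency table;
a feature is *enriched* when the odds ratio is at least 3, the one-sided
p-value (probability of the odds ratio exceeding 1) is below 0.05, and
there are at least 3 true positives. Enriched features then act as simple
structural alerts: a substance is predicted flag-positive when it carries
any enriched feature for that flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "filter_by_qc",
    "binarize_flags",
    "binarize_tk_bins",
    "fisher_one_sided_p",
    "odds_ratio",
    "enrich_features",
    "predict_flags",
    "performance_metrics",
    "EXCLUDED_FLAGS",
    "OR_THRESHOLD",
    "P_THRESHOLD",
    "TP_THRESHOLD",
]

OR_THRESHOLD = 3.0
P_THRESHOLD = 0.05
TP_THRESHOLD = 3
#: flags whose information comes from the half-life model, not assays
EXCLUDED_FLAGS = ("TK_Metab", "TK_Struc_Endo")
DEFAULT_POSITIVE_LEVELS = (1, 2)


@dataclass
class EnrichmentResult:
    feature_name: str
    flag_name: str
    a: int  # feature present, flag positive (true positives)
    b: int  # feature present, flag negative
    c: int  # feature absent, flag positive
    d: int  # feature absent, flag negative
    odds_ratio: float
    p_value: float
    enriched: bool

    @property
    def true_positives(self) -> int:
        return self.a


def filter_by_qc(flags: pd.DataFrame, qc_column: str = "qc_pass",
                 ) -> pd.DataFrame:
    """Drop substances that failed analytical QC."""
    if qc_column not in flags.columns:
        raise KeyError(f"missing QC column {qc_column!r}")
    kept = flags[flags[qc_column].astype(bool)].drop(columns=[qc_column])
    if kept.empty:
        logger.warning("no substances passed QC")
    return kept


def binarize_flags(flags: pd.DataFrame,
                   positive_levels: Sequence[int] = DEFAULT_POSITIVE_LEVELS,
                   ) -> pd.DataFrame:
    """Convert 0/1/2 confidence levels to a binary scale.

    ``positive_levels`` selects which levels count as positive (medium+high
    by default, high-only via ``(2,)``). Missing values stay missing and are
    excluded from contingency tables downstream.
    """
    pos = set(positive_levels)
    return flags.apply(
        lambda col: col.map(lambda v: (np.nan if pd.isna(v)
                                       else int(int(v) in pos))))


def binarize_tk_bins(bins) -> "int | pd.Series":
    """Half-life bin 4 (≥ 2 months) maps to 1; bins 1–3 map to 0."""
    def one(v: int) -> int:
        v = int(v)
        if not 1 <= v <= 4:
            raise ValueError(f"TK half-life bin out of range: {v}")
        return int(v == 4)

    if isinstance(bins, pd.Series):
        return bins.map(one)
    if np.isscalar(bins):
        return one(bins)
    return pd.Series([one(v) for v in bins])


# --- Fisher machinery ---------------------------------------------------------

def fisher_one_sided_p(a, b, c, d) -> np.ndarray:
    """One-sided Fisher exact p-value, direction P(OR > 1); vectorized.

    This is the hypergeometric upper tail P(X >= a) with population
    n = a+b+c+d, a+b draws and a+c successes.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    n = a + b + c + d
    p = hypergeom.sf(a - 1, n, a + c, a + b)
    return np.clip(p, 0.0, 1.0)


def odds_ratio(a, b, c, d, haldane: bool = True) -> float:
    """ad/bc, with the Haldane–Anscombe +0.5 correction on zero cells.

    With ``haldane=False`` a zero denominator yields inf (or nan for 0/0).
    """
    a, b, c, d = float(a), float(b), float(c), float(d)
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return float("nan") if a * d == 0 else float("inf")
    return (a * d) / (b * c)


def enrich_features(features: pd.DataFrame, flag: pd.Series,
                    flag_name: str = "",
                    or_threshold: float = OR_THRESHOLD,
                    p_threshold: float = P_THRESHOLD,
                    tp_threshold: int = TP_THRESHOLD,
                    haldane: bool = True) -> list[EnrichmentResult]:
    """Score every binary feature column against one binary flag.

    Substances with a missing flag are excluded. Constant features or a
    constant flag give p = 1 and are never enriched.
    """
    flag = flag.reindex(features.index)
    mask = flag.notna()
    flag_v = flag[mask].astype(int).to_numpy()
    feats = features.loc[mask]
    results = []
    for name in feats.columns:
        f = feats[name].astype(int).to_numpy()
        a = int(np.sum((f == 1) & (flag_v == 1)))
        b = int(np.sum((f == 1) & (flag_v == 0)))
        c = int(np.sum((f == 0) & (flag_v == 1)))
        d = int(np.sum((f == 0) & (flag_v == 0)))
        if (a + b == 0 or c + d == 0  # constant feature
                or a + c == 0 or b + d == 0):  # constant flag
            p, orat = 1.0, float("nan")
        else:
            p = float(fisher_one_sided_p(a, b, c, d))
            orat = odds_ratio(a, b, c, d, haldane=haldane)
        enriched = (not np.isnan(orat) and orat >= or_threshold
                    and p < p_threshold and a >= tp_threshold)
        results.append(EnrichmentResult(name, flag_name, a, b, c, d,
                                        orat, p, enriched))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature_name, "flag": r.flag_name,
        "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "odds_ratio": r.odds_ratio, "p_value": r.p_value,
        "enriched": r.enriched,
    } for r in results])


def predict_flags(landscape_features: pd.DataFrame,
                  enriched_features: dict[str, list[str]],
                  ) -> pd.DataFrame:
    """Predict binary flags across a landscape from enriched features.

    A substance is predicted positive for a flag when it carries at least
    one of that flag's enriched features; a flag with no enriched features
    predicts all-negative (with a note).
    """
    out = {}
    for flag_name, feat_names in enriched_features.items():
        present = [f for f in feat_names if f in landscape_features.columns]
        if not present:
            logger.info("flag %r has no enriched features; predicting 0",
                        flag_name)
            out[flag_name] = np.zeros(len(landscape_features), dtype=int)
        else:
            out[flag_name] = (landscape_features[present].astype(int)
                              .sum(axis=1) > 0).astype(int).to_numpy()
    return pd.DataFrame(out, index=landscape_features.index)


def performance_metrics(actual, predicted) -> dict[str, Optional[float]]:
    """Sensitivity, specificity and (balanced-accuracy) AUC for hard binary
    predictions. AUC is undefined and reported as None when the actuals
    contain a single class."""
    y = np.asarray(actual, dtype=int)
    yhat = np.asarray(predicted, dtype=int)
    if y.shape != yhat.shape:
        raise ValueError("actual and predicted must align")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    auc = (sens + spec) / 2.0 if (sens is not None and spec is not None) else None
    return {"sensitivity": sens, "specificity": spec, "roc_auc": auc}
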