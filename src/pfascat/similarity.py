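"""Fingerprint similarity, the objective distance threshold, and iterative
Ward subcategorization down to terminal categories.

Categories are compared through Morgan (circular) fingerprints, radius 3,
1024 bits, under the Jaccard distance d = 1 - |A∩B|/|A∪B|. A secondary
category is split when the median of its within-category pairwise distances
exceeds an objective threshold τ derived from the landscape itself: τ is the
15th percentile of the distribution of median *between*-category distances,
taken over all pairs of secondary categories that do not share a primary
root. Splitting uses Ward agglomeration on the precomputed distance matrix,
cut at the first-generation level, and recurses at most twice.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintMatrix",
    "DistanceMatrix",
    "ThresholdReport",
    "morgan_fingerprints",
    "jaccard_distance_matrix",
    "within_category_medians",
    "between_category_pairs",
    "between_category_medians",
    "objective_threshold",
    "ecdf",
    "ward_subcategorize",
    "derive_terminal_categories",
    "terminal_frame",
    "DEFAULT_PERCENTILE",
    "MAX_GENERATIONS",
]

DEFAULT_PERCENTILE = 15.0
MAX_GENERATIONS = 2
FIRST_GENERATION_CUT = 0.7  # fraction of max merge height defining gen-1 clusters

_FP_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=1024)


@dataclass
class FingerprintMatrix:
    substance_ids: list[str]
    bits: np.ndarray  # (n, 1024) uint8

    def subset(self, ids: Sequence[str]) -> "FingerprintMatrix":
        index = {s: i for i, s in enumerate(self.substance_ids)}
        rows = [index[s] for s in ids]
        return FingerprintMatrix(list(ids), self.bits[rows])


@dataclass
class DistanceMatrix:
    substance_ids: list[str]
    d: np.ndarray  # (n, n) symmetric, zero diagonal

    def __len__(self) -> int:
        return len(self.substance_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.substance_ids)}
        rows = np.array([index[s] for s in ids], dtype=int)
        return DistanceMatrix(list(ids), self.d[np.ix_(rows, rows)])


@dataclass
class ThresholdReport:
    within_medians: dict[str, float]
    between_medians: dict[tuple[str, str], float]
    threshold: float
    percentile: float = DEFAULT_PERCENTILE
    excluded_singletons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "percentile": self.percentile,
            "threshold": self.threshold,
            "within_medians": dict(self.within_medians),
            "between_medians": {" | ".join(k): v
                                for k, v in self.between_medians.items()},
            "excluded_singletons": list(self.excluded_singletons),
        }


# --- fingerprints and distances ---------------------------------------------

def morgan_fingerprints(registry_subset) -> FingerprintMatrix:
    """Morgan fingerprints (radius 3, 1024 bits) for parseable structures.

    Accepts an iterable of records with ``substance_id`` and
    ``qsar_ready_smiles`` attributes, or ``(id, smiles)`` pairs.
    Unparseable rows are omitted with a warning.
    """
    ids, rows = [], []
    for item in registry_subset:
        if hasattr(item, "substance_id"):
            sid, smi = item.substance_id, item.qsar_ready_smiles
        else:
            sid, smi = item
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is None:
            logger.warning("omitting unparseable structure %s", sid)
            continue
        fp = _FP_GENERATOR.GetFingerprintAsNumPy(mol)
        ids.append(sid)
        rows.append(fp.astype(np.uint8))
    bits = (np.vstack(rows) if rows
            else np.empty((0, 1024), dtype=np.uint8))
    return FingerprintMatrix(ids, bits)


def _jaccard(bits_a: np.ndarray, bits_b: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances between two binary row blocks."""
    a = bits_a.astype(np.float64)
    b = bits_b.astype(np.float64)
    inter = a @ b.T
    union = a.sum(1)[:, None] + b.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0  # two empty bit sets: zero distance by convention
    return d


def jaccard_distance_matrix(fps: FingerprintMatrix) -> DistanceMatrix:
    """Symmetric Jaccard distance matrix over a fingerprint set."""
    d = _jaccard(fps.bits, fps.bits)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(list(fps.substance_ids), d)


# --- threshold derivation ----------------------------------------------------

def primary_root(secondary_label: str) -> str:
    """Strip the chain-bin suffix from a secondary category label."""
    for suffix in (", gte7", ", lt7"):
        if secondary_label.endswith(suffix):
            return secondary_label[: -len(suffix)]
    return secondary_label


def within_category_medians(members_by_category: dict[str, list[str]],
                            distances: DistanceMatrix,
                            ) -> tuple[dict[str, float], list[str]]:
    """Median upper-triangle pairwise distance per category.

    Singleton categories carry no pairwise distances and are excluded;
    their labels are returned separately.
    """
    medians: dict[str, float] = {}
    singletons: list[str] = []
    for cat, members in members_by_category.items():
        if len(members) < 2:
            singletons.append(cat)
            logger.info("category %r is a singleton; excluded from medians", cat)
            continue
        sub = distances.subset(members)
        medians[cat] = float(np.median(sub.condensed()))
    return medians, singletons


def between_category_pairs(secondary_labels: Sequence[str],
                           ) -> list[tuple[str, str]]:
    """All unordered pairs of secondary categories with distinct primary roots."""
    return [(a, b)
            for a, b in itertools.combinations(sorted(set(secondary_labels)), 2)
            if primary_root(a) != primary_root(b)]


def between_category_medians(members_by_category: dict[str, list[str]],
                             fps: FingerprintMatrix,
                             ) -> dict[tuple[str, str], float]:
    """Median cross-category Jaccard distance for each qualifying pair."""
    out: dict[tuple[str, str], float] = {}
    for a, b in between_category_pairs(list(members_by_category)):
        fa = fps.subset(members_by_category[a])
        fb = fps.subset(members_by_category[b])
        if len(fa.substance_ids) == 0 or len(fb.substance_ids) == 0:
            continue
        out[(a, b)] = float(np.median(_jaccard(fa.bits, fb.bits)))
    return out


def objective_threshold(between_medians, percentile: float = DEFAULT_PERCENTILE,
                        ) -> float:
    """Stated percentile (linear interpolation) of the between-category medians."""
    values = np.asarray(list(between_medians.values())
                        if isinstance(between_medians, dict)
                        else between_medians, dtype=float)
    if values.size == 0:
        raise ValueError("no between-category medians to take a percentile of")
    return float(np.percentile(values, percentile, method="linear"))


def umap_projection(fps: FingerprintMatrix, seed: int = 0,
                    ) -> pd.DataFrame:  # pragma: no cover - plotting plumbing
    """Optional 2-D projection of a fingerprint set for visualization.

    Plumbing for plots only; no downstream computation consumes it.
    Requires the optional umap-learn dependency.
    """
    import umap  # deferred: heavy optional import

    reducer = umap.UMAP(n_components=2, random_state=seed)
    coords = reducer.fit_transform(fps.bits.astype(float))
    return pd.DataFrame({"substance_id": fps.substance_ids,
                         "x": coords[:, 0], "y": coords[:, 1]})


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF sample points: F(x) = (# values <= x)/n at distinct x."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("ecdf of empty sample")
    x = np.unique(v)
    f = np.searchsorted(v, x, side="right") / v.size
    return x, f


# --- clustering --------------------------------------------------------------

def ward_subcategorize(distances: DistanceMatrix,
                       cut_fraction: float = FIRST_GENERATION_CUT,
                       ) -> np.ndarray:
    """First-generation Ward clusters of a category.

    Ward linkage is computed directly on the condensed Jaccard matrix and the
    dendrogram cut at ``cut_fraction`` of the maximum merge height (the
    conventional dendrogram colouring threshold), which reproduces the
    "first generation" of visually distinct clusters. Labels are 1-based in
    order of first appearance along the input.
    """
    n = len(distances)
    if n < 2:
        raise ValueError("cannot cluster fewer than 2 members")
    link = hierarchy.linkage(distances.condensed(), method="ward")
    cut = cut_fraction * link[:, 2].max()
    raw = hierarchy.fcluster(link, t=cut, criterion="distance")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return labels


@dataclass
class TerminalAssignment:
    substance_id: str
    secondary_category: str
    tertiary: Optional[int] = None
    quaternary: Optional[int] = None

    @property
    def terminal_label(self) -> str:
        parts = [self.secondary_category]
        if self.tertiary is not None:
            parts.append(str(self.tertiary))
        if self.quaternary is not None:
            parts.append(str(self.quaternary))
        return ", ".join(parts)

    @property
    def padded_label(self) -> str:
        """Export form padded with "nan" to two generation slots."""
        parts = [self.secondary_category,
                 "nan" if self.tertiary is None else str(self.tertiary),
                 "nan" if self.quaternary is None else str(self.quaternary)]
        return ", ".join(parts)


def derive_terminal_categories(members_by_category: dict[str, list[str]],
                               distances: DistanceMatrix,
                               threshold: float,
                               max_generations: int = MAX_GENERATIONS,
                               split_on_tie: bool = False,
                               cut_fraction: float = FIRST_GENERATION_CUT,
                               ) -> list[TerminalAssignment]:
    """Iteratively subcategorize secondary categories into terminal ones.

    A category is split when its within-category median distance exceeds the
    threshold (strictly, unless ``split_on_tie``), it has at least two
    members, and the generation budget (default 2) is not exhausted. Children
    of a split are numbered 1, 2, 3, … in order of first appearance.
    """
    results: dict[str, TerminalAssignment] = {}
    for cat, members in members_by_category.items():
        for sid in members:
            results[sid] = TerminalAssignment(sid, cat)

    def median_of(members: list[str]) -> float:
        return float(np.median(distances.subset(members).condensed()))

    def needs_split(members: list[str]) -> bool:
        if len(members) < 2:
            return False
        med = median_of(members)
        return med >= threshold if split_on_tie else med > threshold

    frontier = [(members, 0) for members in members_by_category.values()]
    while frontier:
        members, generation = frontier.pop(0)
        if generation >= max_generations or not needs_split(members):
            continue
        labels = ward_subcategorize(distances.subset(members),
                                    cut_fraction=cut_fraction)
        if labels.max() < 2:
            continue  # degenerate: no structure above the cut
        children: dict[int, list[str]] = {}
        for sid, lab in zip(members, labels):
            ta = results[sid]
            if generation == 0:
                ta.tertiary = int(lab)
            else:
                ta.quaternary = int(lab)
            children.setdefault(int(lab), []).append(sid)
        for child_members in children.values():
            frontier.append((child_members, generation + 1))
    return list(results.values())


def terminal_frame(assignments: list[TerminalAssignment]) -> pd.DataFrame:
    rows = []
    for ta in assignments:
        root = primary_root(ta.secondary_category)
        chain_bin = ta.secondary_category[len(root) + 2:]
        rows.append({
            "substance_id": ta.substance_id,
            "primary": root,
            "chain_bin": chain_bin,
            "tertiary": "nan" if ta.tertiary is None else str(ta.tertiary),
            "quaternary": "nan" if ta.quaternary is None else str(ta.quaternary),
            "terminal_label": ta.terminal_label,
            "padded_label": ta.padded_label,
        })
    return pd.DataFrame(rows)
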