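"""Representative and diverse substance selection within terminal categories.

The *centroid* (technically a medoid) is the member minimizing the sum of
Jaccard distances to all other members. Additional diverse members are
picked greedily by the MaxMin rule: at each step, add the candidate whose
minimum distance to the already-picked set is largest. Structural-diversity
coverage is quantified from the mean minimum distance m(k) of all members to
the first k picks: the coverage fraction c(k) is the normalized cumulative
sum of m over the full pick order, so c is nondecreasing and c(n) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .similarity import DistanceMatrix

__all__ = [
    "SelectionResult",
    "centroid",
    "maxmin_pick",
    "coverage_curve",
    "select_category",
    "select_landscape",
    "MAXMIN_MIN_CATEGORY_SIZE",
    "DEFAULT_MAXMIN_K",
]

#: MaxMin is applied only to categories with more than this many members.
MAXMIN_MIN_CATEGORY_SIZE = 5
#: Default number of diverse picks beyond the centroid.
DEFAULT_MAXMIN_K = 3


@dataclass
class SelectionResult:
    terminal_label: str
    centroid_id: str
    picks: list[str]                       # centroid first
    mean_min_distances: np.ndarray         # m(k), k = 1..n over full ordering
    coverage: np.ndarray                   # c(k), nondecreasing, c(n) = 1
    n_for_target: dict[float, int] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.coverage)


def centroid(distances: DistanceMatrix) -> str:
    """Member with the minimal row sum of distances (ties: lowest index)."""
    n = len(distances)
    if n == 0:
        raise ValueError("empty category has no centroid")
    row_sums = distances.d.sum(axis=1)
    return distances.substance_ids[int(np.argmin(row_sums))]


def maxmin_pick(distances: DistanceMatrix, seed: str, k: int) -> list[str]:
    """Greedy MaxMin diverse picks (excluding the seed), deterministic ties.

    Each step adds the candidate with the greatest minimum distance to the
    already-picked set; ties break to the lowest candidate index. If ``k``
    exceeds the remaining candidates the pick list is truncated.
    """
    ids = distances.substance_ids
    index = {s: i for i, s in enumerate(ids)}
    if seed not in index:
        raise KeyError(f"seed {seed!r} not in category")
    picked = [index[seed]]
    remaining = [i for i in range(len(ids)) if i != picked[0]]
    min_d = distances.d[picked[0]].copy()
    out: list[str] = []
    for _ in range(min(k, len(remaining))):
        best, best_val = None, -1.0
        for i in remaining:
            if min_d[i] > best_val:
                best, best_val = i, min_d[i]
        out.append(ids[best])
        remaining.remove(best)
        np.minimum(min_d, distances.d[best], out=min_d)
    return out


def coverage_curve(distances: DistanceMatrix, ordering: Sequence[str],
                   targets: Sequence[float] = (0.5, 0.8),
                   ) -> tuple[np.ndarray, np.ndarray, dict[float, int]]:
    """m(k), c(k) and minimal pick counts for target coverage fractions.

    ``ordering`` must cover every member (centroid first, then MaxMin picks
    to exhaustion). m(k) is the mean over *all* members of the minimum
    distance to the first k picks; c(k) = Σ_{j<=k} m(j) / Σ_j m(j).
    A singleton (or all-identical) category is fully covered by one pick.
    """
    ids = distances.substance_ids
    if sorted(ordering) != sorted(ids):
        raise ValueError("ordering must enumerate all category members")
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    m = np.empty(n)
    min_d = np.full(n, np.inf)
    for k, sid in enumerate(ordering):
        np.minimum(min_d, distances.d[index[sid]], out=min_d)
        m[k] = min_d.mean()
    total = m.sum()
    if total > 0:
        c = np.cumsum(m) / total
    else:
        c = np.ones(n)  # degenerate: no diversity to cover
    c[-1] = 1.0
    n_for_target = {float(f): int(np.argmax(c >= f) + 1) for f in targets}
    return m, c, n_for_target


def select_category(distances: DistanceMatrix, terminal_label: str = "",
                    k: int = DEFAULT_MAXMIN_K,
                    min_size_for_maxmin: int = MAXMIN_MIN_CATEGORY_SIZE,
                    targets: Sequence[float] = (0.5, 0.8),
                    ) -> SelectionResult:
    """Centroid + MaxMin picks + coverage curve for one terminal category.

    Categories of ``min_size_for_maxmin`` or fewer members yield only the
    centroid; MaxMin is not applied to them.
    """
    c_id = centroid(distances)
    n = len(distances)
    picks = [c_id]
    if n > min_size_for_maxmin:
        picks += maxmin_pick(distances, c_id, k)
    full_ordering = [c_id] + maxmin_pick(distances, c_id, n - 1)
    m, cov, n_for = coverage_curve(distances, full_ordering, targets)
    return SelectionResult(terminal_label, c_id, picks, m, cov, n_for)


def select_landscape(members_by_terminal: dict[str, list[str]],
                     distances: DistanceMatrix,
                     k: int = DEFAULT_MAXMIN_K,
                     min_size_for_maxmin: int = MAXMIN_MIN_CATEGORY_SIZE,
                     targets: Sequence[float] = (0.5, 0.8),
                     constraint: Optional[set[str]] = None,
                     ) -> dict[str, SelectionResult]:
    """Run selection for every terminal category.

    ``constraint`` restricts each category to a subset of substance ids
    (e.g. inventory-active members) before selecting; categories left empty
    by the constraint are skipped.
    """
    out: dict[str, SelectionResult] = {}
    for label, members in members_by_terminal.items():
        if constraint is not None:
            members = [s for s in members if s in constraint]
        if not members:
            continue
        out[label] = select_category(distances.subset(members), label, k,
                                     min_size_for_maxmin, targets)
    return out


def selections_frame(results: dict[str, SelectionResult]) -> pd.DataFrame:
    rows = []
    for label, res in results.items():
        for j, sid in enumerate(res.picks):
            rows.append({"terminal_label": label,
                         "role": "centroid" if j == 0 else f"maxmin_{j}",
                         "substance_id": sid})
    return pd.DataFrame(rows)


def coverage_frame(results: dict[str, SelectionResult]) -> pd.DataFrame:
    rows = []
    for label, res in results.items():
        for k in range(res.n_members):
            rows.append({"terminal_label": label, "k": k + 1,
                         "mean_min_distance": float(res.mean_min_distances[k]),
                         "coverage_fraction": float(res.coverage[k])})
    return pd.DataFrame(rows)
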