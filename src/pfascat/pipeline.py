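"""End-to-end orchestration: registry → categories → terminal clusters →
representative selection, and the downstream triage.

Each stage persists its intermediates; two runs with the same resolved
configuration and inputs produce byte-identical assignment tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .annotate import (AnnotationRecord, TriageResult, data_poor_categories,
                       select_candidates)
from .categorize import CategoryAssignment, assignments_to_frame, \
    categorize_registry
from .config import RunConfig
from .registry import Registry
from .select import SelectionResult, coverage_frame, select_landscape, \
    selections_frame
from .similarity import (DistanceMatrix, FingerprintMatrix, ThresholdReport,
                         TerminalAssignment, between_category_medians,
                         derive_terminal_categories, jaccard_distance_matrix,
                         morgan_fingerprints, objective_threshold,
                         terminal_frame, within_category_medians)

logger = logging.getLogger(__name__)

__all__ = ["CategorizationResult", "run_full_categorization", "run_triage"]


@dataclass
class CategorizationResult:
    registry: Registry
    assignments: list[CategoryAssignment]
    fingerprints: FingerprintMatrix
    distances: DistanceMatrix
    threshold_report: ThresholdReport
    terminal: list[TerminalAssignment]
    selections: dict[str, SelectionResult]

    @property
    def members_by_terminal(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ta in self.terminal:
            out.setdefault(ta.terminal_label, []).append(ta.substance_id)
        return out

    def terminal_label_of(self) -> dict[str, str]:
        return {ta.substance_id: ta.terminal_label for ta in self.terminal}


def run_full_categorization(registry: Registry,
                            config: Optional[RunConfig] = None,
                            outdir=None) -> CategorizationResult:
    """Execute categorization end to end over a registry.

    Stages: primary/secondary categorization, fingerprinting, the objective
    threshold, iterative subcategorization to terminal categories, and
    centroid/MaxMin selection with coverage curves. When ``outdir`` is
    given, all intermediates and the resolved config are persisted there.
    """
    cfg = config or RunConfig()

    logger.info("categorize: %d substances", len(registry))
    assignments = categorize_registry(
        registry, membership_threshold=cfg.hybrid_membership_threshold,
        chain_threshold=cfg.chain_threshold, max_chain=cfg.max_chain)

    fingerprintable = [r for r in registry if r.qsar_ready_smiles]
    fps = morgan_fingerprints(fingerprintable)
    distances = jaccard_distance_matrix(fps)
    fp_ids = set(fps.substance_ids)

    members_by_secondary: dict[str, list[str]] = {}
    for a in assignments:
        if a.substance_id in fp_ids:
            members_by_secondary.setdefault(a.secondary_category,
                                            []).append(a.substance_id)

    within, singletons = within_category_medians(members_by_secondary,
                                                 distances)
    between = between_category_medians(members_by_secondary, fps)
    tau = objective_threshold(between, cfg.percentile)
    report = ThresholdReport(within, between, tau, cfg.percentile, singletons)
    logger.info("objective threshold: %.3f (%d between-category pairs)",
                tau, len(between))

    terminal = derive_terminal_categories(
        members_by_secondary, distances, tau,
        max_generations=cfg.max_generations, split_on_tie=cfg.split_on_tie,
        cut_fraction=cfg.cut_fraction)

    members_by_terminal: dict[str, list[str]] = {}
    for ta in terminal:
        members_by_terminal.setdefault(ta.terminal_label,
                                       []).append(ta.substance_id)
    selections = select_landscape(
        members_by_terminal, distances, k=cfg.maxmin_k,
        min_size_for_maxmin=cfg.min_category_for_maxmin,
        targets=cfg.coverage_targets)

    result = CategorizationResult(registry, assignments, fps, distances,
                                  report, terminal, selections)
    if outdir is not None:
        persist(result, cfg, outdir)
    return result


def persist(result: CategorizationResult, cfg: RunConfig, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    result.registry.to_csv(out / "registry.csv")
    assignments_to_frame(result.assignments).to_csv(
        out / "assignments.csv", index=False)
    terminal_frame(result.terminal).to_csv(out / "terminal.csv", index=False)
    (out / "threshold_report.json").write_text(
        json.dumps(result.threshold_report.to_dict(), indent=2))
    selections_frame(result.selections).to_csv(
        out / "selections.csv", index=False)
    coverage_frame(result.selections).to_csv(out / "coverage.csv", index=False)
    summary = {
        "n_substances": len(result.registry),
        "n_terminal_categories": len(result.members_by_terminal),
        "threshold": result.threshold_report.threshold,
        "n_for_80pct": {label: sel.n_for_target.get(0.8)
                        for label, sel in result.selections.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


def run_triage(result: CategorizationResult,
               annotations: dict[str, AnnotationRecord],
               tox_records: pd.DataFrame,
               require_active: bool = False,
               maxmin_k: int = 3) -> dict[str, TriageResult]:
    """Data-poor / inventory / monitoring triage over terminal categories."""
    members = result.members_by_terminal
    poor = data_poor_categories(members, tox_records)
    return select_candidates(members, result.selections, result.distances,
                             annotations, poor, require_active=require_active,
                             maxmin_k=maxmin_k)
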