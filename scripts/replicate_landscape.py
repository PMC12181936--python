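#!/usr/bin/env python
"""Replicate the full published landscape categorization from the deposited
study dataset.

The landscape-scale results (objective threshold 0.8; 16 secondary
categories above it; 128 terminal categories; 484 MaxMin selections over
121 categories; per-category within-medians) depend on the deposited
dataset of ~15,500 substances, which must be downloaded separately
(figshare DOI 10.23645/epacomptox.26524327; the substance list is also
published on the EPA CompTox Chemicals Dashboard as "PFAS8a7v3"). Point
this script at the downloaded substance table and it runs the complete
pipeline with the study's default thresholds:

    python scripts/replicate_landscape.py --substances path/to/table.csv \
        --id-column DTXSID --smiles-column QSAR_READY_SMILES \
        --outdir results/landscape

Outputs (assignments, terminal categories, threshold report, selections,
coverage, summary) are written under --outdir; summary.json carries the
terminal-category count and the objective threshold for comparison with
the published values. This is a full-landscape computation: expect it to
run for a while on a single CPU.
"""

import argparse
from pathlib import Path

from pfascat.config import RunConfig
from pfascat.pipeline import run_full_categorization
from pfascat.registry import load_substances


def main() -> None:
    parser = argparse.ArgumentParser(
        description=__doc__,
        formatter_class=argparse.RawDescriptionHelpFormatter)
    parser.add_argument("--substances", type=Path, required=True,
                        help="CSV from the deposited dataset (substance id "
                             "+ SMILES columns)")
    parser.add_argument("--id-column", default="DTXSID")
    parser.add_argument("--smiles-column", default="SMILES")
    parser.add_argument("--outdir", type=Path, default=Path("landscape_out"))
    args = parser.parse_args()

    registry = load_substances(args.substances, args.id_column,
                               args.smiles_column)
    cfg = RunConfig()  # study defaults: chain 7, percentile 15, 2 generations
    result = run_full_categorization(registry, cfg, outdir=args.outdir)
    n_terminal = len(result.members_by_terminal)
    print(f"substances: {len(registry)}")
    print(f"objective threshold: {result.threshold_report.threshold:.3f}")
    print(f"terminal categories: {n_terminal}")
    print(f"outputs written to {args.outdir}")


if __name__ == "__main__":
    main()
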