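# pfascat

Hierarchical structural categorization of per- and polyfluoroalkyl
substances (PFAS), for computational toxicologists and risk assessors who
need to organize a large PFAS inventory into read-across-ready chemical
categories and decide which substances to test next.

Only a handful of the many thousands of PFAS have meaningful toxicity
data. A category approach groups structurally similar substances so data
on a few representatives can inform assessment of the rest. `pfascat`
implements that workflow end to end:

1. **Registry** — ingest substance tables (id + SMILES), standardize to
   QSAR-ready structures (largest organic fragment, neutralized, stereo
   stripped), deduplicate by full InChIKey, filter on a three-substructure
   PFAS definition (saturated CF2–CF pair; CF2–O–CF2 ether bridge;
   gem-bis-CF3), and merge externally predicted degradation products under
   `<parent>_m_<rank>` identifiers.
2. **Categorization** — assign each substance a primary structural class
   from an ordered rule table (PFAAs, PFAA precursors, polyfluoroalkyl
   acids, PASF-based substances, fluorotelomers, aromatic/silicon/alkane
   subclasses, ± cyclic), applying a hybrid rule that switches to the
   finer class when a broad class exceeds 300 members; compute the maximum
   contiguous perfluorinated chain length *L* (longest run of carbons with
   ≥ 2 F and no H, so PFOA → 7, PFOS → 8) and bin it at 7
   (`gte7`/`lt7`) into secondary categories.
3. **Similarity** — Morgan fingerprints (radius 3, 1024 bits) and Jaccard
   distances d(i,j) = 1 − |B_i ∩ B_j| / |B_i ∪ B_j|. An objective split
   threshold τ is the 15th percentile of median *between*-category
   distances (over category pairs with distinct primary roots); any
   category whose *within*-median exceeds τ is split by Ward clustering
   on the precomputed distance matrix, recursively for at most two
   generations, giving terminal categories like
   `"Aromatic PFASs, lt7, 4, 1"`.
4. **Selection** — each terminal category's centroid (medoid: argmin of
   distance row sums) plus up to 3 diverse members by greedy MaxMin
   picking; diversity coverage c(k) is the normalized cumulative sum of
   mean minimum distances m(k) over the full pick order.
5. **Annotation & triage** — physical state at 25 °C, solubility /
   volatility designations A–D, inventory status, production-volume bins
   and monitoring-list tags; a triage workflow nominates data-collection
   candidates from categories that are data-poor, inventory-overlapping
   and monitoring-listed.
6. **POD harmonization** — oral repeated-dose effect levels harmonized to
   chronic human-equivalent benchmark doses (LOAEL ÷ 3, subchronic ÷ 2,
   subacute ÷ 5, allometric body-weight scaling, conceptual-model mean),
   then a per-substance POD as the 25th percentile of a moment-matched
   lognormal, with a median-sd fallback below 5 records.
7. **Enrichment** — binary structural features tested against NAM
   (new-approach-method) flags with one-sided Fisher's exact tests;
   features with OR ≥ 3, p < 0.05 and ≥ 3 true positives become
   structural alerts that predict flags across the landscape.
8. **Classifier** — a random forest over fingerprints, chain length and
   primary category assigns new substances to terminal categories
   (balanced accuracy on a stratified 80/20 split, 5-fold CV, randomized
   hyperparameter search).

A synthetic-fixture generator builds landscapes from homologous-series
templates with known chain lengths, planted POD shifts and planted
feature–flag odds ratios, so the whole pipeline is testable offline.

## Worked example

```bash
pfascat simulate-fixtures --outdir bundle --seed 1 --n-series 2
```

```python
from pfascat import RunConfig, run_full_categorization
from pfascat.registry import load_substances

registry = load_substances("bundle/registry.csv")
cfg = RunConfig(hybrid_membership_threshold=10)  # scaled to fixture size
result = run_full_categorization(registry, cfg, outdir="run")
print(f"substances:          {len(registry)}")
print(f"objective threshold: {result.threshold_report.threshold:.3f}")
print(f"terminal categories: {len(result.members_by_terminal)}")
sel = result.selections["PFAAs, gte7"]
print(f"'PFAAs, gte7' centroid: {sel.centroid_id}, picks: {sel.picks[1:]}")
print(f"picks for 80% coverage: {sel.n_for_target[0.8]} of {sel.n_members}")
```

prints

```
substances:          77
objective threshold: 0.704
terminal categories: 15
'PFAAs, gte7' centroid: SYN00005, picks: ['SYN00013', 'SYN00006', 'SYN00007']
picks for 80% coverage: 1 of 8
```

The 77-substance synthetic landscape resolves into 15 terminal
categories. The derived threshold τ = 0.704 means a category is split
only when its members are, at the median, farther apart than the most
similar 15% of unrelated category pairs. In the long-chain
perfluoroalkyl-acid category, `SYN00005` is the medoid (most central
member) and the three MaxMin picks bound the category's structural
diversity; because the homologous series is tight, the centroid alone
already covers 80% of it.

Run directories contain `assignments.csv`, `terminal.csv` (with the
`"…, gte7, nan, nan"` padded labels), `threshold_report.json`,
`selections.csv`, `coverage.csv` and the resolved configuration.

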