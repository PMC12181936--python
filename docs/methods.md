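# Methods

## Scope and model of the problem

`pfascat` organizes a PFAS chemical landscape into a category hierarchy —
primary structural class → chain-length bin → up to two rounds of
similarity-driven subcategorization — and layers decision support on top:
representative/diverse member selection, exposure and data-availability
annotation, harmonized points of departure, structural-alert enrichment,
and a classifier that places new substances into existing terminal
categories. The package assumes each substance is representable by a
single organic structure (SMILES); mixtures, polymers and unresolvable
records are carried as `unclassified` rather than dropped.

## Structure standardization and the PFAS definition

Structures are standardized to QSAR-ready form with RDKit: largest organic
fragment, charge neutralization where chemically valid, stereochemistry
removed, canonical SMILES output. Standardization is idempotent.
Deduplication keys are full 27-character InChIKeys, so constitutional
duplicates collapse while tautomer handling is left to standardization.

The PFAS membership filter encodes three definitional substructures as
SMARTS with explicit saturation constraints (module constant
`PFAS_DEFINITION_SMARTS`, swappable for broader definitions such as the
single −CF2−/−CF3 rule):

1. `[CX4](F)(F)[CX4]F` — adjacent saturated CF2 and CF carbons;
2. `[F,O,CX4][CX4](F)(F)O[CX4](F)(F)[F,O,CX4]` — a CF2–O–CF2 ether bridge
   whose outer substituents are F, O or saturated carbon;
3. `FC(F)(F)[CX4H0](C(F)(F)F)([F,CX4])[F,CX4]` — gem-bis(trifluoromethyl)
   carbon with F/saturated-carbon substituents.

An unparseable structure is an error from this predicate, never `False`.

## Chain length

The chain length *L* is the longest run of contiguous perfluorinated
carbons: carbons bearing ≥ 2 fluorines and no hydrogens, so a terminal CF3
extends the run (PFOA scores 7; PFOS 8). Implementation note: such a
carbon can have at most two heavy non-fluorine neighbours, so the
qualifying-carbon subgraph is always a union of simple paths and rings —
the longest-simple-path search is exact and cheap, and a perfluorinated
ring scores its full size. A `strict_cf2` mode restricts to exactly two
fluorines (excluding CF3 ends). Lengths beyond the configured range cap
(default 30) are still computed exactly, with a warning. The long-chain
boundary is *L* ≥ 7 (`gte7`), the conventional "long chain" threshold.

## Primary classes and the hybrid rule

The public PFAS subgroup classifiers do not publish their internal rule
trees, so `pfascat` ships its own ordered rule table (most specific
first): fully perfluorinated acid → PFAAs; perfluoroalkane sulfonyl
fluoride/amide → PASF-based substances; partially fluorinated acid →
polyfluoroalkyl acids; perfluoroacyl ester/amide → PolyFCA derivatives;
CF2–CH2CH2 segment → n:2 fluorotelomer-based substances; then aromatic,
silicon, hydrofluorocarbon (C/H/F only, ≤ 3 carbons), polyfluoroalkane and
a residual `others` bucket. A fluorinated *saturated* ring triggers the
", cyclic" variant of the broad class; aromatic ring fluorine does not
(otherwise the aromatic class would be absorbed into "cyclic"). Fine
classes collapse onto their cyclic broad class to keep the category
vocabulary closed. These rules approximate the published vocabulary; they
are not a byte-level reproduction of any external tool.

The hybrid rule keeps the broad first class unless its landscape
membership exceeds 300 substances, in which case the finer second class is
used; second classes left with fewer than 5 members (configurable) fall
back to the residual bucket of their branch. Substances without a
QSAR-ready structure, and structures failing the PFAS definition, map to
`unclassified`.

On synthetic fixtures of ~100 substances the 300-member rule would never
fire, so fixture runs scale `hybrid_membership_threshold` down (10 in the
tests) to exercise the branch; the default remains 300.

## Objective threshold and subcategorization

Within each secondary category, pairwise Jaccard distances over Morgan
fingerprints (radius 3, 1024 bits) are summarized by their median;
singleton categories are excluded with a note. Between-category medians
are computed for every unordered pair of secondary categories whose
primary roots differ, using only cross-category pairs. The split threshold
τ is the 15th percentile of the between-category medians, with the linear
interpolation percentile convention (documented because several
conventions exist; `numpy` `method="linear"`).

A category is split when its within-median strictly exceeds τ (a
`split_on_tie` flag switches to ≥, since both readings of "exceeds" are
defensible). Splitting is Ward agglomeration computed directly on the
condensed Jaccard distance matrix — the linkage update operates on those
distances, not on Euclidean coordinates — and the "first generation" of
clusters is the cut at 0.7 × the maximum merge height, the conventional
dendrogram colouring threshold. This reading allows more than two children
per split, which a root bisection would not. A consequence worth stating:
any category that is clustered yields at least two clusters (the root
merge always sits above a fractional cut), so "no split" is decided by the
τ test, not by the dendrogram. With all pairwise distances equal there is
no real structure and the outcome is set by deterministic tie-breaking
(lowest-index merges first, inherited from the linkage implementation's
stable ordering); the tests pin determinism rather than a particular
partition. Recursion stops after two generations below the secondary
level. Terminal labels append child indices (`"others, lt7, 2"`); tabular
exports pad unsplit levels with `"nan"`
(`"Aromatic PFASs, gte7, nan, nan"`).

Distances between empty fingerprint rows (no bits set) are 0 by
convention; fingerprints are deterministic, so identical structures always
coincide.

## Centroids, MaxMin and coverage

The category centroid is the medoid: argmin over members of the summed
distance to all other members, ties to the lowest index. Diverse members
are picked greedily by MaxMin from the centroid seed — each step adds the
candidate whose minimum distance to the picked set is largest, ties to the
lowest index (deterministic, unlike randomized picker implementations).
MaxMin applies only to categories with more than 5 members; the default is
3 picks beyond the centroid.

Coverage is computed from the full diversity ordering (centroid, then
MaxMin to exhaustion): m(k) is the mean over *all* members of the minimum
distance to the first k picks (picked members contribute 0 at and beyond
their own index, so the all-members and unpicked-only variants differ only
by a scale factor; all-members is the default), and
c(k) = Σ_{j≤k} m(j) / Σ_j m(j). c is nondecreasing with c(n) = 1; a
singleton or fully degenerate category (total 0) is defined as fully
covered by one pick. `n_for_target` maps coverage fractions (defaults 0.5
and 0.8 — the 80% figure is illustrative, not normative) to the minimal k.

## Exposure annotation and triage

Physical state at 25 °C: gas if boiling point < 25, solid if melting
point ≥ 25, liquid if melting < 25 and boiling ≥ 25; otherwise unknown.
Cutoffs: soluble ⟺ water solubility ≥ 0.5 mg/L, volatile liquid ⟺ vapour
pressure ≥ 75 mmHg, highly volatile ⟺ Henry's law constant ≥ 0.1
atm·m³/mol (≥ on the soluble/volatile side, config-exposed). Designations:
A insoluble solid; B soluble solid or soluble non-volatile liquid; C
soluble volatile liquid, insoluble liquid or soluble gas; D insoluble or
highly volatile gas — D takes precedence for a gas that is both soluble
and highly volatile, since high volatility dominates the exposure route.
Records with insufficient properties are `not determined`; fully
annotated records always land in exactly one of A–D.

Production volumes map onto the ten reporting ranges; because the printed
ranges mirror heterogeneous source range strings and overlap, numeric
values go through a non-overlapping most-specific-first ladder over the
same boundaries, and source range strings matching a label pass through
verbatim. Boundary values join the bin whose lower bound they equal.

Triage gates a terminal category on: (1) data-poor — no member has an
oral/inhalation record with a NOAEL/LOAEL/LOEL/NOEL/NEL/LEL value; (2)
inventory overlap (active-only under `require_active`); (3) presence on at
least one monitoring list. Candidates then come from the first branch that
succeeds: existing centroid/MaxMin picks on the inventory; else the single
next-closest member to the centroid if it is on the inventory; else
centroid/MaxMin recomputed on the inventory-constrained category (which by
construction returns only constraint members). Adding a qualifying
toxicity record can only remove a category from the nominated set.

## POD harmonization

Retained records: oral route; effect types NOEL/NOAEL/NEL/NOAEC/LOAEL/
LOEL/LOAEC/LEL; study types short-term, subchronic, chronic,
developmental, reproduction, reproduction developmental, 28-day; units
mg/kg-bw/day or mg/kg; species standardized to rat, mouse, rabbit, dog,
hamster or guinea pig. Inhalation records participate only in the
data-availability gates, not in harmonization.

Chain: LOAEL-type ÷ 3 → chronic NOAEL equivalent with subchronic ÷ 2 and
subacute (short-term, 28-day) ÷ 5; developmental/reproduction studies
carry no duration factor. Human equivalence divides by a species
conversion factor; the default table is quarter-power allometry
(70/bw_species)^0.25 over standard body weights (rat 0.25 kg → factor
≈ 4.1). BMDh is the mean of two conceptual-model multiples of the human
equivalent; the default multipliers are (1/3, 2/3) for both the noncancer
and the reproductive/developmental stream. **Both tables are
reconstructions** — the source framework's exact constants are not
printed in the categorization study — and are arguments/config throughout.
Noncancer and repro/developmental records are processed as separate
streams. Every factor application is appended to the record's audit list;
the product of logged factors reconstructs output/input exactly.

Per-substance POD: the 25th percentile of a lognormal moment-matched to
the substance's BMDh sample — σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2,
POD = exp(μ + z₀.₂₅σ) with z₀.₂₅ = −0.67449. Moment matching on the
arithmetic mean/sd (rather than fitting on logs) is deliberate: the
procedure is specified in terms of the mean and sd of the BMDh values.
Below 5 records the sample sd is replaced by the median sd across
substances; sd = 0 degenerates to the mean. Category summaries are
quartiles/IQR/range of log10 PODs with 1.5 × IQR whiskers in the boxplot
export.

## NAM-flag enrichment

Flags take levels 0/1/2 (immune: 0/1). Only QC-passing substances are
carried forward. Binarization treats medium + high as positive by default
(high-only via config) — the level split used originally is not stated, so
both are supported. TK half-life bins 1–4 binarize as bin 4 → 1, else 0.
The `TK_Metab` and `TK_Struc_Endo` flags are excluded from enrichment
(their information comes from the half-life model, not assays).

Each feature × flag 2×2 table gets a one-sided Fisher exact p-value in the
"odds ratio > 1" direction, computed as the hypergeometric upper tail
(vectorizable); the odds ratio is ad/bc with the Haldane–Anscombe +0.5
correction when any cell is zero (raw-infinite convention via config).
Enriched ⟺ OR ≥ 3 ∧ p < 0.05 ∧ a ≥ 3. Constant features or flags score
p = 1. Prediction is alert-style: positive iff the substance carries ≥ 1
enriched feature for the flag. For hard binary predictions the reported
AUC is balanced accuracy, (sensitivity + specificity)/2, which is the ROC
AUC of a single-threshold classifier; it is undefined (reported missing)
for single-class actuals.

## Category classifier

Features: fingerprint bits and chain length standardized, primary category
ordinal-encoded — all fitted inside an sklearn pipeline on training folds
only, so no statistics leak from test data; unseen primaries at predict
time map to a reserved code. Standardizing binary bits before a forest is
unusual but kept as specified (a raw-bit path is a one-line config).
Categories under 10 members pool into `miscellaneous`. Evaluation:
stratified 80/20 split, majority-class dummy baseline, 5-fold stratified
CV, randomized search over a space centred on the reported best
configuration (100–400 trees, min split 2/4, min leaf 1/2, sqrt features,
balanced-subsample weighting), balanced accuracy (= macro recall)
throughout, per-class recall reported, final refit on all data. A single
seed drives split, search and forest, so reports are bit-reproducible.
Single-member classes raise an actionable error pointing at the
aggregation threshold.

## Synthetic fixtures

The generator emulates the *shape* of a real landscape, not its content:
homologous series (perfluorocarboxylic/-sulfonic acids, fluorotelomer
alcohols with varied hydrophilic heads, perfluoroalkane sulfonyl
fluorides, ring-decorated aromatic perfluoroalkyl compounds, ether-capped
perfluoroalkanes) across a chain range (default 3–10, spanning both chain
bins), plus non-PFAS decoys. Chain lengths, family classes and
PFAS-definition status are known by construction and cross-checked
against the categorizer in tests. Companion generators produce property
tables spanning all states/designations, toxicity records back-multiplied
through the harmonization factors from planted per-substance lognormals
(default: median 10 mg/kg-bw/day, geometric sd 2, 6 records per substance,
10-fold lower medians for the gte7 bin), inventory and monitoring lists,
and flag tables with a planted feature–flag odds ratio (default 10)
against a 0.2 base rate. All generators are pure functions of
(spec, seed).

What fixtures do *not* emulate: realistic category-size distributions
(real landscapes are dominated by a few very large categories), realistic
fingerprint density, correlated property/toxicity structure, curation
noise in identifiers, or the deposited landscape's counts. Passing tests
demonstrate algorithmic correctness and statistical behaviour under known
truth, not agreement with the published landscape-scale figures — those
require the deposited dataset via `scripts/replicate_landscape.py`.

## Numerical choices and degenerate inputs

- Percentiles: linear interpolation everywhere.
- Ties: lowest index wins (centroid, MaxMin, cluster relabeling order).
- Jaccard of two empty bit vectors: 0.
- Coverage of a singleton/degenerate category: 1 at k = 1.
- Strict `>` for the split test; `≥` behind `split_on_tie`.
- Ward cut fraction 0.7 of max merge height, config-exposed.
- Zero-cell odds ratios: Haldane–Anscombe 0.5 by default.
- Problem sizes in the test suite (fixture landscape ~77 substances,
  200 substances × 6 records for POD recovery, 200 replicates × n = 150
  for enrichment power, 120-sample classifier fixtures) were chosen so
  each statistical check has adequate power while the whole suite stays
  desk-scale.

## Known limitations

- The primary-class rule table is an approximation of unpublished
  classifier internals; ether-containing perfluoro acids, for example,
  classify as polyfluoroalkyl acids rather than PFAAs.
- The body-weight factors and conceptual-model multipliers are
  reconstructed defaults; absolute BMDh values should not be compared
  against the source study without aligning those tables.
- Study quality is not considered in POD harmonization or the data-poor
  gate; cancer endpoints and dose-response benchmark-dose modelling are
  out of scope.
- UMAP projections are offered for plotting only and carry no validated
  computation.
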