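# Methods

## The statistics

All statistics operate on a per-group (species × season) fish-by-prey
weight matrix built from individual gut contents. With `N` the number of
fish whose guts contain anything, `N_i` the number containing prey *i*,
`S_i` the total weight of prey *i*, `S_t` the total content weight of
all examined guts, and `St_i` the total content weight of only those
guts containing prey *i*:

- **Frequency of occurrence** `F_i = 100 · N_i / N`
- **Relative abundance** `A_i = 100 · S_i / S_t`
- **Prey-specific abundance** `P_i = 100 · S_i / St_i`

`P_i ≥ A_i` always (the denominator shrinks to the sub-population of
guts that contain the prey), with equality exactly when every non-empty
gut contains prey *i*. Fish with empty guts — naturally empty, or
emptied when unidentifiable/parasite categories are stripped — remain
specimens for the length summaries but are excluded from `N`, which by
definition counts fish *with gut contents of any kind*.

**Diet overlap** between two groups with percent-by-weight proportion
vectors *p*, *q* over the union of their prey categories (absent = 0) is
Schoener's `D = 100 − 0.5 · Σ|p_i − q_i|`, identical to `Σ min(p_i,
q_i)` whenever both vectors sum to 100. D is reported on the 0–100
percent scale throughout (the literature sometimes describes the same
index on [0, 1]); the conventional significance threshold is 60%.

**Dietary niche breadth** is Levins' `B = 1 / Σ p_i²` on the fraction
scale: 1 for monophagy, S for uniform use of S prey. The computation is
scale-invariant, so percent and fraction inputs agree.

Both B and D are computed **by weight** (the A_i basis), not by count:
the overlap index is defined on proportions by weight and no count-based
index is used anywhere downstream; `prey_count` is carried through the
I/O layer for extensions but never enters an index.

## Specimen handling

- Unidentifiable material and suspected parasites (cestodes) are removed
  *before* any index — in particular before `S_t`, the denominator of
  `A_i`. An include-in-`S_t` variant is not offered because excluded
  categories are by construction not analyzable diet.
- Juveniles are removed per species by a strict standard-length
  threshold (`length > threshold`; "bigger than" read literally). The
  thresholds for the four gudgeon species ship as `GUDGEON_POLICY`
  (96 / 139 / 79 / 114 mm); both the values and the strictness are
  configurable.
- Standard-error of length for singleton groups is reported as 0 with a
  warning rather than NaN, to keep report tables well-formed.
- Season labels are opaque strings; nothing in the library hard-codes
  "spring"/"autumn".

## The published-table pathway

The raw specimen data of the gudgeon study were never deposited; the
package ships 2-dp transcriptions of its specimen table (8 groups, 936
fish) and its diet-composition table (per-group `F_i`, `A_i`). Printed
`A_i` columns are a legitimate input to D and B because both depend only
on proportions.

Printed columns sum to 99.99–100.01 from rounding. `diet_proportions`
renormalizes to exactly 100 by default (this bounds rounding error and
makes the two algebraic forms of D coincide); the published-table
helpers default to **raw printed columns** instead, because that is the
mode under which the published overlap table's desk-checkable cells
reproduce exactly at 2 dp. Five published overlap cells (all involving
*C. guichenoti*, plus the heterodon–ventralis spring pair's neighbours)
do **not** reproduce from the printed 2-dp columns under either mode
(deviations 0.10–1.15): they were evidently computed from unrounded raw
proportions, and are therefore not desk-reproducible. The test suite
records this honestly — the full-table reproduction test fails on those
cells while the desk-checkable cells pass.

Report rounding is 2 dp, half-up (the convention of the printed
tables), implemented via `decimal` after snapping to 6 dp so binary
float noise cannot flip half-way cases; internal computation is full
precision, and the CLI writes a `*_full.tsv` sidecar at full precision
beside every rounded table.

## Feeding-strategy diagram

Each prey is a point (x = `F_i`, y = `P_i`). The source method is
qualitative and names no numeric boundaries, so the classifier uses
configurable thresholds with plot midpoints (50, 50) as defaults:

- importance: *dominant* = upper-right quadrant, *rare* = lower-left,
  otherwise *intermediate*; a ranking score along the importance
  diagonal is the coordinate mean `(x + y)/2` (a Euclidean projection
  would rank identically up to a constant factor);
- tendency: points in the upper half read as specialization, lower half
  as generalization;
- phenotype component: upper-left = high BPC (different individuals
  specialize on different prey), lower-right = high WPC;
- group label: *specialized* if any prey lies in the upper half,
  *generalized* if all prey lie below — by the method's description
  these two cases are exhaustive, so the reserved *mixed* label is never
  produced by the default classifier.

Points exactly on a threshold line go to the upper/dominant side
(deterministic tie-break). An optional rare-prey frequency threshold of
20% reflects the narrative convention that prey eaten by fewer than a
fifth of individuals are minor; it is not applied by default.

## Synthetic generator

`SpeciesProfile` generates gut contents in three stages per fish: draw a
phenotype from a mixture, draw each prey's presence as an independent
Bernoulli with the phenotype's occupancy probability `f_i`, then draw a
conditional weight from a log-normal `(μ_i, σ_i)`. Choices and caveats:

- **Log-normal weights**: strictly positive and right-skewed, matching
  gut contents weighed to 0.0001 g that mix many small items with
  occasional heavy ones (e.g. crabs). The family is a package choice;
  only proportions matter downstream, so absolute scale is arbitrary
  (defaults put typical items near 0.1 g).
- **Independent presences within a phenotype**: the simplest structure
  that realizes both within-phenotype (every fish takes many prey) and
  between-phenotype (sub-populations specialize on different prey) diet
  variation; real prey co-occurrence (e.g. habitat-driven correlation)
  is not modelled.
- **Empty guts arise naturally** when every Bernoulli fails; there is no
  separate empty-gut parameter, so the empty-gut rate is implied by the
  occupancies.
- Archetypes: *specialist* (one prey at occupancy 0.95 and a 20:1 weight
  ratio at full strength), *generalist* (equal occupancy 0.6, equal
  weights), *bpc_mixture* (two equal sub-phenotypes specializing on
  different prey — moderate F, high P, the diagram's upper-left
  signature).
- The analytic occurrence oracle is
  `E[F_i] = 100 · Σ_k w_k f_ki / Σ_k w_k (1 − Π_j (1 − f_kj))`
  (containing prey *i* implies a non-empty gut); expected A and P have
  no closed form under log-normal weights and are estimated by Monte
  Carlo with batch standard errors.
- The bundled study design mirrors the published sampling frame (8
  groups, 936 fish, published length ranges) and its qualitative
  narrative (shared specialization on the mussel in spring; two species
  diversify, two specialize further in autumn). It makes no attempt to
  infer the study's actual generative parameters — that inverse problem
  is under-determined by the printed tables.

What passing synthetic tests therefore show: the estimators recover
known generative parameters at the study's sample sizes, and the regime
classifiers respond correctly to controlled specialization. What they do
not show: anything about prey identification error, digestion-biased
weights, or co-occurrence structure in real guts.

## Problem sizes and tolerances

Parameter-recovery tests use n = 500 fish per group (comparable to the
larger published groups) with a 3-standard-error acceptance band and a
19/20-profile pass criterion; the Monte-Carlo oracle uses 2,000–20,000
draws in tests and supports ≥10⁵ draws for tighter work. Dual-formula
equivalence is checked to 1e-9 over 1,000 random simplex pairs. Percent
vectors are accepted when their sum is within 0.5 of 100 (printed 2-dp
tables stray by at most a few hundredths).

## Known limitations

- Weight-based indices only; count-based variants (and IRI, Pianka,
  Morisita, rarefaction, bootstrap CIs) are out of scope.
- Gut sections are not modelled; "gut content" is treated generically.
- The published composition table is an input, never a reproduction
  target: per-fish raw data would be required to recompute it.
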