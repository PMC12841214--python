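# Methods

This note documents the models and procedures implemented in `ifra`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Cohort model and splits

A cohort is a subjects × features table with a binary fall label, a
provenance flag (`real` / `synthetic`) and a split assignment. The canonical
design is a 142-subject cohort (88 non-fallers, 39 real + 15 synthetic
fallers) split 93 / 17 / 32 into train (54 non-fallers + 39 fallers),
validation (12 + 5) and test (22 + 10). Synthetic subjects are confined to
the training split by construction and the split assigner enforces this as
an invariant; within that constraint splits are drawn uniformly at random,
stratified by label, from a seed. How the original fixed split of this
design was drawn is not documented anywhere we know of, so the seeded
stratified draw is a reproducible stand-in, not a claim about the original
procedure.

Cohort CSVs carry 17 significant digits and ingest converts values through
Python's correctly-rounded `float()`, so write → read round-trips are
bit-exact (pandas' fast to-numeric path is off by several hundred ulp and is
used only to locate malformed entries). Records with missing feature values
are rejected at ingest by default — the upstream design excluded incomplete
records — with an explicit `drop_incomplete` escape hatch that logs the
dropped count.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure the pipeline assumes,
not any particular biomechanical reality:

* `n_fallers=39`, `n_nonfallers=88`, `n_features=108` by default (the
  real-cohort shape after exclusions); `n_informative=22` defaults to the
  size of the scale the methodology produced on real data.
* informative features carry a group-mean shift of `effect_size` ×
  feature SD (Cohen's d) in a per-feature random direction, recorded as the
  registry's `direction_hint`;
* `within_class_correlation` adds an equicorrelated common factor across the
  informative block; `heavy_tail_fraction` makes a random subset of features
  log-normal (σ = 0.5) to mimic skewed mobility measures;
* null features are exchangeable between groups (verified by Monte-Carlo
  calibration of the rank-sum rejection rate at the nominal α).

What this does **not** model: the covariance structure of real ITUG
sub-task measures (many are near-duplicates of each other), measurement
error correlated within a test session, and age/severity confounding.
Passing selection-recovery tests on these cohorts therefore demonstrates
correctness of the pipeline's mechanics and its behaviour under known
effect sizes — not clinical validity on real patients.

`augment_fallers` implements the minority-class augmentation: `k` distinct
real fallers are drawn without replacement and copied with independent
zero-mean Gaussian noise per feature. The reference population for the
noise SD is the *faller-group* sample SD (augmentation targets the faller
manifold), scaled by `noise_scale`. The source description pins the noise
only to "the variance of each respective feature", so `noise_scale` is a
free parameter; the default 0.1 keeps copies close to their templates while
avoiding duplicates, and no numerical claim in the package depends on it.
Zero-variance features are copied verbatim; values are not clipped, so
nominally nonnegative quantities can go negative in synthetic data.

## Consensus feature selection

Defaults follow the published protocol: 1000 draws (39 fixed fallers + 39
of 54 non-fallers, distinctness enforced by fingerprinting the sorted
non-faller id set with bounded redraws and an up-front combinatorial
feasibility check), a strict `accuracy > 0.80` validation gate, two-group
tests at α = 0.05, consensus at 50%. Choices the protocol leaves open:

* **SVM hyperparameters** are unstated in the source protocol: RBF kernel,
  C = 1, `gamma="scale"` (1 / (n_features × variance)), features
  standardized with the training subset's own mean/SD (zero-SD features
  standardize to zero with a logged warning). All exposed in
  `SelectionConfig`.
* **t-test flavour**: Welch (unequal variances), two-sided — the robust
  default for unequal group spreads.
* **Normality routing**: Shapiro–Wilk per group at α = 0.05 (configurable);
  if *either* group rejects normality (or is constant, where Shapiro–Wilk
  is undefined), the comparison routes to the rank-sum test — the
  conservative reading of "as appropriate".
* **Consensus denominator**: "marked in at least 50% of the iterations" is
  ambiguous between all iterations and the retained (gated) subsets.
  Aggregation is described over successful subsets, so the default
  denominator is `n_retained_subsets`, with `consensus_denominator=
  "iterations"` available in config.
* **Seeding**: one master seed spawns an independent substream per draw
  index, so per-iteration results are independent of execution order and a
  run is bit-for-bit reproducible, including the per-iteration log.

A property worth knowing before interpreting consensus fractions: because
the faller half of every subset is identical and non-faller subsets overlap
heavily, per-feature marking events are strongly correlated across draws.
Under a global null the *mean* marking rate is ≈ α (verified on independent
subsets), but the per-feature marking fraction is close to bimodal: a null
feature whose whole-training-split difference happens to reach α is marked
in most draws and can clear the 50% consensus. The expected number of false
selections is therefore ≈ α × N (≈ 5 of 100), not ≈ 0, whenever any subsets
pass the gate. The `"iterations"` denominator suppresses this when the gate
pass rate is below twice the consensus fraction. Relatedly, under a null
cohort the gate's pass events are governed by the luck of the small fixed
validation split (12 + 5), and observed pass counts vary wildly across
seeds. Both behaviours are measured in the acceptance suite rather than
assumed away.

## Thresholds and stratification

For each selected feature the training values are sorted in risk-increasing
order (ascending for higher-is-riskier). With n values the cut ranks are
k1 = ceil(n/3) and k2 = ceil(2n/3) — ranks 31 and 62 at n = 93, dividing
the ranking into three sets of 31 ("31st and 62nd percentiles" is read as
these ranks precisely because it reproduces the three-sets-of-31 division;
thresholds are always observed training values, never interpolations). The
risk direction comes from the registry hint when present, else from the
sign of the training mean difference (ties default to higher-is-riskier
with a warning; a median-based variant is available).

Stratum membership of a *value* follows the printed-interval convention:
extreme strata are closed, medium is open (lower-is-riskier: low `x ≥ a`,
medium `b < x < a`, high `x ≤ b`). One consequence is intentional and
documented rather than hidden: the rank-k2 subject's value sits exactly on
the closed high boundary, so re-applying the value rule to the training
split yields strata of (31, 30, 32), while the rank division used during
derivation is exactly (31, 31, 31). The rank division is exposed as
`training_rank_strata`; both facts are asserted in the tests. Tied values
spanning a cut are kept as stored thresholds and membership stays
value-based, so boundary-tied subjects share a stratum (logged when
detected).

A patient's overall stratum is the mode of the per-feature strata with ties
resolved upward (three-way ties → high); all features have equal weight. By
default all scale features must be present; `min_features_required` enables
a permissive mode over available features with the count recorded. The
eight clinical comparator rules (Table-style literature thresholds,
multi-level instruments consolidated to three strata by preserving the
extremes) ship as an editable YAML fixture.

## Exact evaluation

The association between fall status and assigned strata is tested with the
Fisher–Freeman–Halton exact test on the 2×3 table: direct recursion
enumerates every margin-consistent table (a few hundred to a few thousand
at these sizes), table probabilities are multivariate hypergeometric
computed with cached log-factorials, and the two-sided p sums tables whose
probability is ≤ the observed one — probability ordering, the convention of
standard exact-test implementations, with a relative tie tolerance of 1e−7
(configurable) and normalisation by the enumerated total so degenerate
margins give exactly 1. The test suite checks the implementation against an
independent exact-Fraction oracle for *every* 2×3 table with grand total
≤ 12 (worst deviation observed ≈ 4e−15) and against the closed-form 2×2
hypergeometric (and scipy's `fisher_exact`) when a column is empty.

`reconstruct_counts` inverts published row percentages into integer counts
by largest-remainder apportionment (equivalently: minimising the maximum
absolute deviation from percentage × n / 100, ties toward the largest
remainder), refusing inputs no integer vector fits within one count. Six of
the eight published comparator rows reproduce their printed p-values to the
printed precision under this reconstruction; the POMA-B and 10 MWT rows do
not, under any count vector consistent with their printed percentages or
any common test variant we tried, and the package reports its computed
values (≈ 0.482 and ≈ 0.166) rather than matching the printed ones. The
printed percentages themselves appear truncated rather than rounded
(21/22 prints as 95.4), which the comparison tolerance accounts for.

## Problem sizes used in the checks

The selection-recovery experiments run at 100 features with 10 planted
informative features (d = 1.2), the canonical 93/17/32 splits and 200
subsampling draws — enough draws for consensus fractions to stabilise while
keeping the full suite fast; the oracle sweep covers all 18,563 tables of
grand total ≤ 12; Monte-Carlo calibrations use 500 replicates with ±2
Monte-Carlo-SE acceptance bands (±3 SE for mean-convergence checks).

## Known limitations

* The synthetic generator's independence-plus-single-factor covariance is a
  deliberate simplification; consensus behaviour on strongly collinear real
  ITUG features will differ (correlated features are selected or rejected
  together).
* The SVM gate's behaviour depends heavily on the small fixed validation
  split; with 17 subjects the gate is a coarse filter, not a calibrated
  accuracy estimate.
* Exact-test enumeration is designed for 2×3 (generic r×c works but scales
  combinatorially); no mid-p or chi-squared variants are provided.
* Thresholds derived from 93 subjects carry substantial sampling noise;
  the package reproduces the methodology and does not certify any specific
  threshold values.
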