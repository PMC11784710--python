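# Methods

## Model and assumptions

The pipeline rests on three assumptions:

1. **Carotid-body chemosensitivity is informative.**  A brief hyperoxic
   stimulus depresses ventilation; in subjects with early metabolic
   dysfunction the post-stimulus HR/RR response is more erratic.  The
   pipeline quantifies that erraticness through cluster-membership changes
   at the three post-stimulus minutes.
2. **Per-subject K-means on (time, value) points yields temporally
   coherent clusters.**  Each subject's series is clustered independently
   on standardized coordinates, so cluster labels are comparable only
   *within* a subject; all downstream logic therefore uses only the
   equality structure of the label triple at minutes 11–13, never raw
   label identities.  The five pattern classes (S, DU, DD, DUD, T) are
   exactly the set partitions of three items, so the naming is total and
   invariant under relabeling.
3. **Glucose severity is a valid training weight.**  Subjects with worse
   glucose trajectories contribute more to the score matrix, so patterns
   common among severely affected subjects accumulate high scores.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| K (clusters) | 6 | – | WCSS elbow on this protocol; configurable |
| K-means seed | 13 | – | fixed for reproducibility; k-means++, 10 restarts |
| post-stimulus window | minutes 11–13 | min | 3 min after the O2 inhalation |
| meal minute | 21 | min | protocol timing |
| t_g, T_g | 34, 55 | min | interval where group glucose means diverge; set by inspection, not estimated |
| severity mode | `as_printed` | – | see below |
| band boundaries | χ/3, 2χ/3 | score | equal thirds of the maximum risk |

**The severity-level denominator.**  The conventional formula divides the
tail-window sum (minutes T_g..80, 26 samples) by T_g − t_g = 21 even though
the window holds 26 samples.  The default `as_printed` mode keeps the
formula literally; `window_mean` divides by the true sample count.  The two
modes differ by a factor 26/21 on the second term; all reference figures
use `as_printed`.

**Band edge conventions.**  Lower bounds are inclusive; the top band also
includes χ.  Scores above χ (possible only when patterns and score matrix
come from different models) clamp to High with a warning.

**Weight range.**  The weight W = SL/100 is nominally between 1 and 10 but
is not enforced: realistic cohorts produce weights around 1.5–2.9, and
rejecting values outside (1, 10) would reject valid data.

## Numerical choices

* Standardization maps zero-variance columns to zeros (a constant signal
  contributes nothing to the distance) — relevant for degenerate inputs
  only, since the time column always varies.
* K-means uses scikit-learn's implementation with k-means++ initialisation
  and `n_init=10`, keeping the lowest-WCSS solution; with a fixed seed the
  whole pipeline is bit-reproducible.
* The WCSS elbow is the K maximizing the discrete second difference of the
  curve, ties broken toward smaller K.
* Printed reference values are truncated to two decimals, so comparisons
  against them use absolute tolerance 0.01 (0.02 for sums).
* The Mann-Whitney comparison uses the exact null distribution when the
  smaller sample has ≤ 8 observations without ties, and the tie-corrected
  normal approximation (with continuity correction) otherwise.

## The synthetic cohort generator

`simulate.generate_cohort` emulates exactly the statistical features the
pipeline consumes:

* AR(1) HR and RR noise (ρ = 0.6) around subject-level baselines — the
  autocorrelation keeps K-means clusters temporally contiguous, which the
  pattern taxonomy presupposes; white noise would fragment them.
* Control RR baseline 17.1 breaths/min (the generator's calibration
  anchor); prediabetes baseline slightly lower.
* A ventilatory dip at minutes 11–13 whose per-minute jitter is much larger
  in the prediabetes group (sd 2.0 vs 0.4 breaths/min) — this single knob
  produces the higher prediabetes cluster variability the method exploits,
  and an HR-mirrored perturbation does the same for the HR and RR×HR
  variables.
* A gamma-shaped postprandial glucose excursion whose height and decay are
  larger/slower for prediabetes, so the group means diverge inside the
  severity window [34, 55].

What it does **not** emulate: circadian drift, measurement artifacts,
missing data, SpO2, or any physiologic coupling between HR and RR beyond
their shared stimulus response.  Passing tests on synthetic cohorts
therefore demonstrate that the pipeline recovers the structure it assumes,
not that real recordings contain that structure.

## The engineered reference cohort

`fixtures.reference_cohort` inverts the published association table: each
subject's glucose is piecewise linear with plateaus chosen so the severity
arithmetic reproduces the printed weight exactly, and the HR/RR series are
piecewise-constant block layouts designed so K-means at K=6 places the
window minutes in clusters realizing the printed pattern triple for all
three variables.  Three layout devices are used: block boundaries at minute
12 or 13 (DD/DU), single-minute excursions with a time-adjacent home block
(DUD), and — for the one subject whose joint pattern cannot arise from
independent HR/RR boundaries — an intermediate-level block after the window
that jointly captures minutes 11 and 13 in the three-dimensional space.
The layouts are frozen in source and verified by the test suite through the
real clustering path; the realization is stable across K-means seeds.

## Validation harness

ADASYN closes the 8-vs-25 class gap with exactly 17 synthetic minority
vectors in the concatenated HR‖RR feature space (160-dim); per-point
budgets follow the adaptive majority-neighbour ratio when majority vectors
are supplied and are uniform otherwise, with largest-remainder rounding so
the count is exact.  Synthetic vectors are convex combinations of minority
pairs and re-enter the pipeline as ordinary subjects.

The four-fold protocol holds out one fixed (or seeded random) pair of
training subjects per round; each round retrains the score matrix from the
six remaining subjects only (held-out data never touches Ψ or χ — asserted
by a bit-exact retraining test).  The default harness generates the
synthetic pool once per run from all eight training subjects, matching the
published counts (17 synthetic + 2 held-out = 19 prediabetes-labelled test
items per round); because that re-uses training-subject geometry in the
test set, a stricter `no_leak` mode generates per-round pools from the
held-out pair only.  Nineteen controls are sampled per round without
replacement, independently across rounds.  Medium-risk calls count as
correct for the subject's true class; averaged metrics are arithmetic means
over the four rounds.

Problem sizes used in the shipped tests: cohorts of 33 subjects (8/25),
ten generator seeds for the variability-ordering property, and single-run
cross-validation — sizes at which the full suite completes in about a
minute.

## Design choices where the design was open

* **DU/DD orientation.**  K-means label indices are arbitrary, so an
  "up/down" reading of raw labels is undefined; the taxonomy is fixed by
  equality structure with (a,a,b) = DU, which reproduces the published
  anchors.  The `pattern_orientation` switch flips the convention should
  the pictorial legend ever be read the other way.
* **Time column standardized together with the value columns**, taken
  literally from the clustering procedure's description.
* **Classification seeding.**  The single-subject K-means reuses the
  model's stored seed, making classification a pure function of
  (HR, RR, model).
* **Rank-sum convenience.**  The published group comparison of
  post-stimulus RR does not specify its exact construction; the package
  provides the general test plus `compare_postoxygen_rr`, which compares
  per-subject mean RR over minutes 11–13 — flagged as one interpretation.

## Limitations

* With eight training subjects the score matrix is sparse; unseen patterns
  score zero and can only lower a subject's band (a conservative failure
  mode).
* t_g/T_g are fixed inputs; no automatic divergence-window detection.
* The method is retrospective: the full 80-minute recording must exist
  before classification (no real-time use).
* Cross-validation on a synthetic cohort measures the harness and the
  achievable separation under the generator's assumptions, not clinical
  performance.
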