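# Methods

## Model

`fuzzycomm` is a fuzzy comprehensive evaluation (FCE) of communication
ability. The indicator set is fixed at nine measurements per subject, in
this canonical order: auditory, visual, memory, comprehension, judgment,
expression, attention (percentages in [0, 100]), average speech energy
(dB, positive), average speech speed (events per minute, positive). The
verdict set is four ordered levels — intact, mild, moderate, severe —
with representative fuzzy values V = (0.90, 0.75, 0.55, 0.25).

The per-subject chain is

1. **Ability scaling** r = 0.5·(x − M)/(H − M) + 0.5, clipped to [0, 1].
2. **Membership grading** of each r against the four levels, giving the
   9×4 relation matrix R.
3. **Composition** B = A∘R with indicator weights A, using the
   weighted-sum operator b_j = Σ_i A_i R_ij.
4. **Defuzzification** u* = Σ_i V_i b_i / Σ_i b_i.
5. **Classification** to the level whose rubric value minimizes
   |u* − V_i|; an exact midpoint resolves to the more severe level.

Assumptions: indicators are interval-scaled and monotone in ability once
the direction flag is applied; the weight vector is nonnegative and sums
to 1, so u* is a bona fide weighted average and always lies in
[min V, max V] = [0.25, 0.90].

### Why weighted-sum composition

The composition operator for A∘R is not uniquely determined by the FCE
framework. Max–min composition discards the weight magnitudes that the
eigen-analysis exists to provide, and the defuzzification step is
explicitly an averaging principle; weighted-sum (M(·,+)) composition is
therefore used. Maximum-membership defuzzification is likewise rejected
in favor of the weighted average: a verdict based only on the single
largest membership throws away the rest of the evidence vector.

### Membership family

The four membership functions are piecewise power functions with
exponent k = 1.2 (configurable): rising segments ((x − a)/(b − a))^k,
plateaus at 1, falling segments ((b − x)/(b − a))^k. Breakpoints:

| level | shape | breakpoints |
| --- | --- | --- |
| intact | ascending shoulder | 0.75, 0.9 |
| mild | trapezoid | 0.55, 0.725, 0.775, 0.9 |
| moderate | trapezoid | 0.25, 0.455, 0.545, 0.75 |
| severe | descending shoulder | 0.25, 0.55 |

The breakpoints are taken as configuration constants, not derived from a
midpoint rule — no single generating rule reproduces all of them. The
mild level's source rubric defines no descending branch; the family
completes it on [0.775, 0.9] by mirror symmetry with the moderate
level's shape, because every level with a superior neighbor otherwise
has one, and without it the function would be discontinuous at its
plateau edge. Segment boundaries are evaluated left-closed; each segment
reaches exactly 0 or 1 at its endpoints so the choice has no numerical
effect (verified to 1e−9 in tests).

With k = 1 every segment degenerates to the straight line between its
endpoints, which the tests use as a closed-form check.

### Ability anchors H and M

H (best reference) and M (normal midpoint) are per-indicator
configuration, not estimated quantities:

| indicator | H | M | rationale |
| --- | --- | --- | --- |
| seven percentage indicators | 100 | 50 | r reduces to pct/100 |
| speech energy | 80 dB | 55 dB | spans the reference table's 56–74 dB spread |
| speech speed | 60 /min | 30 /min | spans the reference table's 13–56 /min spread |

All defaults treat indicators as increasing; a `direction: decreasing`
flag reflects a measurement about M before scaling, so rate-type
indicators where excess is pathological can reuse the same formula. The
energy/speed anchors were calibrated once from the packaged six-subject
reference table and should be overridden per cohort; published
composite scores for subjects other than the fully-worked example depend
on anchors that were never published, so those scores are treated as
qualitative references, not reproduction targets.

## Weight derivation

Weights come from principal components of the indicator correlation
matrix:

- **Standardization** uses the sample (n−1) standard deviation —
  conventional for small cohorts; a constant column is an error.
- **Eigen-decomposition** is of the correlation matrix (equivalently the
  covariance of z-scores), so eigenvalues sum to p = 9. Eigenvectors are
  unit-norm with each column's largest-magnitude entry made positive;
  weights are invariant to this sign fix (tested).
- **Selection** keeps the smallest leading set with every eigenvalue
  > 1.0 (`eigen_min`) and cumulative contribution > 0.85 (`cum_min`).
  When no prefix qualifies the estimator raises rather than silently
  degrading; an explicit `fallback=True` permits one component.
- **Blending**: w_i = Σ_j a_ij c_j / Σ_j c_j over the retained
  components, with individual contribution rates c_j = λ_j / Σλ, then
  unit-sum normalization. The normalization is required for the
  downstream average to be proper; the published weight vector is
  reproduced by exactly this rule. Cumulative rates are also exposed
  since the selection rule is stated in cumulative terms.
- **Loading conversion**: published factor loadings relate to score
  coefficients by loading = coefficient·√λ. When only the two printed
  tables are available, eigenvalues are recovered as the mean of
  (loading/coefficient)² per component, excluding entries with
  |coefficient| < 0.05 — the ratio of two near-zero four-decimal numbers
  is rounding noise (the excluded entries imply per-entry eigenvalues up
  to 15% off; the retained ones agree within ~1%).

## Synthetic cohorts

No cohort pairing the nine indicators with clinician verdicts is
public, so `fuzzycomm.synthetic` generates labeled cohorts:

- each level draws from a truncated multivariate normal (percentages in
  [0, 100], rates positive) with per-level mean vectors; the defaults
  are calibrated from the packaged six-subject reference table and are
  fixture-derived, not population estimates;
- dependence is a single equicorrelation parameter (default ρ = 0.6),
  the simplest generator of the one dominant shared factor that the
  published loading matrix shows (first-component loadings 0.77–0.996
  for all non-speech indicators);
- default severity mix (0.44, 0.30, 0.18, 0.08) follows the published
  50-subject clinical marginals; level counts use deterministic
  largest-remainder allocation so tests can assert exact class sizes;
- truncation is by per-row rejection with bounded retries; a level mean
  outside (or too near) the support raises instead of looping;
- `well_separated_spec(r_sd)` centers each level's ability values
  exactly on the rubric values (0.9/0.75/0.55/0.25) under the default
  anchors, with marginal ability-scale noise `r_sd` converted back to
  raw units per indicator.

What the generator does **not** emulate: measurement floor/ceiling
pile-ups, indicator-specific correlation structure (e.g. the speech-
energy column's weak coupling to the ability factor), rater drift, or
any raw speech/video signal. Passing recovery tests therefore show the
pipeline is internally consistent and separates well-separated level
distributions; they do not validate the rubric against real patients.

## Numerical choices and degenerate inputs

- u* tolerance against the published worked example: 5e−4 absolute,
  matching its three-decimal rounding.
- u* is monotone in any single indicator's ability value up to a
  sub-millipoint ripple (< 1e−3): because u* is a ratio of B-sums, total
  evidence can dip slightly where membership supports overlap. Exact
  monotonicity holds on each membership flank; the property test allows
  the ripple and requires strict overall increase across the full range.
- Zero evidence vectors, H = M anchors, constant indicator columns,
  all-zero eigenvalues, non-positive eigenvalues in loading conversion,
  and infeasible truncation all raise typed exceptions rather than
  returning NaN.
- Agreement reports define per-class accuracy as confusion-diagonal over
  reference row sum, with empty reference classes scored 0.0 (keeps the
  [0, 1] range) rather than erroring.

## Problem sizes

The test suite and acceptance script run at desk scale by design: the
worked-example checks are closed-form; recovery tests use n = 200
subjects (clean r_sd = 0.05 and noisy r_sd = 0.10 variants); the
convergence test for the generator uses one 10,000-subject level. The
whole suite completes in a few seconds on one CPU.

## Known limitations

- The four interior breakpoints (0.455, 0.545, 0.725, 0.775) are adopted
  verbatim; no generating rule is assumed or exposed.
- The default speech-energy/speed anchors are fixture-calibrated from
  six subjects; cohort-specific anchors are strongly recommended.
- Clinician agreement can only be emulated on synthetic labels; the
  published 50-subject comparison is reproducible only at the level of
  its marginal counts.
- Only the printed power-of-k membership family is implemented; no
  triangular/Gaussian alternatives, no factor rotation, and no
  alternative defuzzifiers.
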