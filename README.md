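# fuzzycomm

Quantitative assessment of foreign-language communication ability from
nine clinical/behavioral indicators, for clinicians and researchers who
need a single interpretable severity score instead of nine separate
measurements.

Communication ability after impairment is multi-factorial — auditory,
visual, memory, comprehension, judgment, expression and attention
percentages, plus average speech energy (dB) and average speech speed
(per minute) — and the boundaries between "mild" and "moderate"
dysfunction are inherently fuzzy. `fuzzycomm` implements a fuzzy
comprehensive evaluation that fuses the nine indicators into a composite
ability score u\* ∈ [0, 1] and a four-level verdict (intact, mild,
moderate, severe).

## The model

**Rubric.** The four verdict levels carry fuzzy values
V = (0.90, 0.75, 0.55, 0.25).

**Ability scaling.** Each raw measurement is anchored onto [0, 1] by
r = 0.5·(x − M)/(H − M) + 0.5, where M is the indicator's reference
normal midpoint (→ 0.5) and H its reference best value (→ 1.0); r is
clipped to [0, 1].

**Memberships.** Each ability value is graded against the four levels by
piecewise power functions with exponent k = 1.2: rising segments
((x − a)/(b − a))^k, plateaus at 1, falling segments ((b − x)/(b − a))^k,
with breakpoints {0.75, 0.9}, {0.55, 0.725, 0.775, 0.9},
{0.25, 0.455, 0.545, 0.75} and {0.25, 0.55} for the four levels. A
subject's nine ability values give the 9×4 fuzzy relation matrix R.

**Weights.** Indicator weights A come from an eigen-analysis of the
cohort correlation matrix: retain the leading components with eigenvalue
> 1 whose cumulative variance share exceeds 85%, blend their score
coefficients a\_ij by contribution rates c\_j = λ\_j/p,
w\_i = Σ\_j a\_ij c\_j / Σ\_j c\_j, and normalize A to unit sum. A
published two-component weight vector for the nine indicators ships as
the packaged default.

**Verdict.** B = A∘R by weighted-sum composition (b\_j = Σ\_i A\_i R\_ij),
then u\* = Σ V\_i b\_i / Σ b\_i, and the verdict is the level whose rubric
value is nearest to u\* (midpoint ties go to the more severe level).

## Worked example

```python
>>> import fuzzycomm as fc
>>> B = [0.2119, 0.2440, 0.3916, 0.1371]   # level evidence for one subject
>>> u = fc.defuzzify(B)
>>> round(u, 3)
0.633
>>> fc.classify(u)
(3, 'moderate')
```

The evidence vector weighs moderate (0.3916) most heavily; the weighted
average of the rubric values gives u\* = 0.633, nearest to the moderate
rubric value 0.55, so the subject is rated level 3 of 4.

Cohort-level use goes through the two scikit-learn-style estimators:

```python
>>> est = fc.FuzzyAssessor().fit()              # packaged default weights
>>> cohort = fc.load_reference_cohort()         # six packaged subjects
>>> est.score_samples(cohort).round(3)
array([0.688, 0.815, 0.683, 0.849, 0.842, 0.36 ])
>>> est.predict(cohort)
array([2, 2, 2, 1, 1, 4])
```

The two intact subjects score ≈ 0.85, the severe subject 0.36; fitting
weights from your own cohort instead uses
`fc.FuzzyAssessor(weights="fit").fit(cohort)` or the
`fc.PrincipalComponentWeights` transformer directly.

The same pipeline is scriptable from the shell:

```sh
fuzzycomm simulate -o cohort.csv --n 200 --seed 7 --well-separated
fuzzycomm weights cohort.csv -o model.json
fuzzycomm assess cohort.csv -o results.csv --weights model.json
fuzzycomm evaluate results.csv -o agreement.json
```

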