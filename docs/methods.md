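# Methods

## Model

A measurement of analyte X on subject i at visit j is modelled as

    X_ij = mu_i + t_j + e_ij

* `mu_i ~ N(mu0, sigma0^2)` — the subject's true personal level; `sigma0^2`
  is the between-subject (inter-individual) variance.
* `t_j` — a shared fixed visit effect (e.g. a calibration shift common to
  everyone on sampling day j), constrained to sum to zero.
* `e_ij ~ N(0, sigma^2)` — within-subject noise, the sum of short-term
  biological fluctuation (tau^2) and analytical error (sigma_eps^2).
  With one measurement per subject-visit only the sum
  `sigma^2 = tau^2 + sigma_eps^2` is identifiable, and that is all any
  estimator here consumes.

All computations run on the raw scale: the analytes targeted (serum
transferrin, albumin, retinol-binding protein, transthyretin) are
approximately normal in healthy adults, so the variable-transformation
step of the general recipe is the identity.  A log-transform hook would
slot in ahead of `estimate_components` without API change but is not
implemented.

## Estimators

**Naive (mean ± z·S).**  Treats the n-point sample mean and SD as the
truth.  Its coverage of a fresh draw at n = 5 is ~85%, not 95% — the
motivating defect of the field's habit of applying population-interval
arithmetic to tiny personal samples.

**RCV.**  The reference change value `RCV% = sqrt(2)·z·sqrt(CVa^2+CVi^2)`
converts the analytical CV (`CVa`, an assay-QC constant supplied per
analyte in configuration, not recomputed here) and the within-subject
biological CV (`CVi`) into the smallest relative difference between two
serial results that is statistically meaningful; the personal range is
`mean ± mean·RCV/100`.  By default `CVi` is the subject's own cumulative
CV over their visits so far (available from the second visit); a cohort
value (e.g. the panel mean CV(intra)) can be substituted via the
`cvi_percent` argument when a single per-analyte RCV is wanted.

**Prediction interval (tango).**  `X̄ ± Cn·S` with
`Cn = t_{n-1}(alpha/2)·sqrt((n+1)/n)` is the exact acceptance region of
the one-new-observation t test, i.e. the interval with guaranteed
(1−alpha) coverage of the next measurement at every n.  `Cn(5, .05) =
3.041`, `Cn(2, .05) = 15.56`; the price of honesty about 1–4 df SDs is
width.  The `(n+1)/n` factor sits under the square root — the printed
anchor 3.041 at n = 5 pins this down unambiguously.

**Bayesian shrinkage.**  Conjugate normal–normal posterior of the
personal mean (formulas in the README).  The reported range
`mu_n ± z·sqrt(sigma_n^2 + sigma^2)` is the posterior-predictive-style
interval: remaining uncertainty about the personal mean plus the
irreducible within-subject scatter.  Its width is data-independent given
(n, sigma0^2, sigma^2), strictly decreasing in n, equal to the
population width at n = 0 and bounded below by `2z·sigma`.  `sigma^2`
is treated as known; plugging in a panel estimate ignores its sampling
uncertainty (a deliberate simplification — a hyperprior on the variance
components is out of scope).

## Variance-component estimation

`estimate_components` uses closed-form method-of-moments on a balanced
S × T panel: visit effects are visit means minus the grand mean; on
visit-centered data,

    within_var  = residual SS / ((S-1)(T-1))
    between_var = max(0, (T·var(subject means) - within_var) / T)

The `(S-1)(T-1)` divisor keeps `within_var` unbiased after estimating T
visit means.  In a balanced design this is also the REML solution (the
test-suite cross-checks against an independent mixed-model fit).
Choices:

* **Balanced panels only.**  Every closed form above assumes a common
  visit count; unbalanced panels are rejected rather than approximated.
* **Negative moment estimates** of the between component truncate to 0
  with a warning (standard remedy; happens routinely at S, T ≤ 4 when
  the true between-variance is small).
* **Zero total variance** yields all-zero components with a warning.

## Sequential evaluation

`cumulative_trajectory` re-estimates one subject's interval at every
visit.  *Prospective* mode (default) judges visit k with the interval
built from visits 1..k−1 — the alarm semantics; *retrospective* mode
plots the cumulative estimate through visit k.  At the first visit no
SD exists, so the naive/RCV/prediction methods fall back to the routine
population range (the returned interval is tagged `population` so the
fallback is visible); the Bayesian method needs no fallback — its n = 0
interval *is* the population range implied by the components.  Interval
membership is closed on both ends: a value exactly on a limit is
`within` (reference limits are conventionally inclusive).

## Synthetic data

`generate_panel` draws exactly the model above; `study_like_bundle`
fixes a 20-subject × 5-visit, four-analyte design with components at
realistic serum-marker scales (e.g. transferrin: mu0 280 mg/dL, between
variance 770.96, within 165.95; sex ratio 9 F : 11 M).  For the two
analytes whose within-subject component is not separately tabulated
(ALB, TTR) the generator imputes it as total_sd² − between_var.  Visit
effects default to zero (none are evident at these scales); a nonzero
option exercises the fixed-effect-removal path.  Values are floored at
0 with a warning — at RBP's scale 0 lies 3.2 SDs below the mean, so
roughly one value in a thousand panels truncates; the other analytes
never do.

What the generator does *not* emulate: serial correlation within a
subject (noise is i.i.d.; any true temporal autocorrelation is
unidentifiable from a 5-visit design and is not simulated), sex or age
effects on the mean (sex matters only for population-range lookup),
assay drift, and non-normal tails.  Passing tests therefore demonstrate
correctness of the estimators *under the stated model*, not robustness
to real-data pathologies.

## Numerical conventions

* Sample SDs use the n−1 denominator everywhere; a single observation
  has an undefined (None) SD, never 0.
* CV with a zero mean is undefined-flagged, not infinite.
* Display rounding is half-away-from-zero at the analyte's configured
  decimals and applies only at formatting time; all internal
  computation and all test comparisons use full precision.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; bundle child seeds are spawned with
  `SeedSequence` and kept below 2^31.

## Problem sizes

The test-suite and acceptance script use: 10^5 Monte-Carlo replicates
per n for coverage; 500 subjects × 5 visits (averaged over 20 replicate
panels in the acceptance script) for parameter recovery; 200–500
study-like 20 × 5 seeds for the cohort-level comparisons; 200 random
S, T ≤ 4 panels for oracle equivalence of the moment estimator.

## Known limitations

* The per-subject ordering "naive narrower than Bayes" at 5 visits holds
  in expectation, not surely: a 4-df sample SD exceeds the fixed
  Bayesian width about a third of the time.  Ordering assertions are
  therefore made on subject-averaged widths.
* Under the transferrin-scale components, *all 20* subjects show
  CV(intra) < CV(inter) in roughly 89% of simulated cohorts — it is the
  modal outcome, not a near-certain one; single-cohort findings of
  20/20 should be read accordingly.
* The RCV interval is symmetric on the raw scale; log-normal/asymmetric
  variants for skewed analytes are not provided.
* No multiplicity correction is applied to the per-subject t/F screens
  in `subject_vs_grand_tests`; they are descriptive flags, not
  family-wise inferences.
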