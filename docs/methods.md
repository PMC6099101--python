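# Methods

## Measurement model

Observed scores arise from a fully crossed two-facet random design: every
person (p, the object of measurement) is scored on every item (i) by every
rater (r).  The additive random-effects decomposition is

    X_pir = mu + nu_p + nu_i + nu_r + nu_pi + nu_pr + nu_ir + e_pir,

with mutually independent zero-mean effects.  The three-way interaction is
confounded with residual error in a single-replication design, so seven
variance components are estimable: sigma2(p), sigma2(i), sigma2(r),
sigma2(pi), sigma2(pr), sigma2(ri), sigma2(pir,e).  Persons are random;
items and raters are random facets (exchangeable samples from their
universes).  Task family (Alternative Uses vs. Consequences) is *not* a
modelled facet: the two families use differently anchored scales and are
not interchangeable, so every analysis is run separately within a family's
subtable.  Scores within a family are assumed pre-cleaned (no nonsense
responses) and complete; unbalanced tables are refused rather than
silently accommodated.

## G-study estimation

The estimator is the closed-form expected-mean-squares (Henderson /
ANOVA) method: classical balanced three-way mean squares, then inversion
of their expectations,

    s2(pir,e) = MS_pir
    s2(pi) = (MS_pi - MS_pir) / n_r          (pr, ir symmetric)
    s2(p)  = (MS_p - MS_pi - MS_pr + MS_pir) / (n_i n_r)   (i, r symmetric).

EMS was chosen over REML deliberately: for balanced complete designs it is
exact, closed-form, and testable against independent oracles (a brute-force
sum-of-squares evaluation and a numeric solve of the 7x7 EMS system, both
in the test suite; an lme4 REML fit serves as a third, external
cross-check).  For balanced data with strictly positive solutions REML and
EMS coincide; they differ when a component estimate would be negative and
REML pins it to zero, which also perturbs the remaining components.  Moment
estimates can be negative by sampling error; reported components are
truncated at zero (as published component tables print them) while the raw
solutions are retained on the result object for diagnostics.
Percent-of-variance divides each truncated component by the truncated
total.  Reporting precision is 3 decimals for components and 1 for
percentages; estimation is full precision throughout.

## D-study projection

For a candidate design with n_i items and n_r raters, each component is
divided by the number of conditions it is averaged over (1 for p, n_i for
i and pi, n_r for r and pr, n_i*n_r for ri and the residual).  Relative
error variance sums the person-interaction terms; absolute error variance
adds the facet main effects and ri.  The generalizability coefficient
E-rho2 = s2(p)/(s2(p)+s2_delta) serves rank-order decisions; the
dependability coefficient Phi = s2(p)/(s2(p)+s2_Delta) serves absolute
decisions and never exceeds E-rho2.  Coefficients are computed at full
precision and rounded half-up to 2 decimals only in formatted output;
components round half-up to 3.

`printed_table_mode` reproduces published D-study tables: projected
components are rounded to 3 decimals first and the error variances formed
from the rounded values, because such tables print error variances equal to
the sum of their printed components.  Full precision is the default for
analysis.  Two quirks of the reference values are worth recording.  First,
the reference tables disagree with themselves about the Consequences person
variance (0.067 in the G-study table, 0.068 in the D-study table); each
reference set reproduces its own table, and the worked-example coefficients
(0.52/0.27) follow the D-study table's 0.068.  Second, projecting the
printed (3-decimal) G-study components does not always reproduce the
printed projections — e.g. 0.139/2 = 0.0695 prints as 0.069, not the
half-up 0.070 — because the source evidently projected unrounded REML
estimates.  Related: from the rounded printed components, E-rho2 with 3
raters crosses 0.80 at 5 Alternative Uses items (0.786 at 4), whereas the
source's figure-based recommendation was 4; `minimal_design` reports what
the supplied components imply.  Design search is over integers only, up to
a cap (default 10, matching the coefficient curves).

## Synthetic data generator

`simulate_scores` draws every effect from a zero-mean normal with its
specified variance — the canonical G-theory working model; the source data
carry no distributional statement, so normality is adopted explicitly, not
inferred.  Defaults are the study conditions: 80 persons, 2 items, 3
raters, grand mean 3 (scale centre), reference average-rating Alternative
Uses components as truth, and ~6.5 responses per person-item at response
level (zero-truncated Poisson, matching reported fluency means of about
6.4–6.8 and the constraint that observed fluency is >= 1).  Scores are
continuous by default; averaged ratings are near-continuous and the
estimation theory is moment-based.  `discretize=True` clips to [1, 5] and
rounds to the integer scale, which compresses tails and biases component
recovery — useful for emulating raw snapshot data, not for calibration
checks.

Response-level tables give every response an integer 1–5 rating equal to
the cell's systematic value plus fresh residual noise, rounded and
clipped.  Averaging a rater's ratings therefore shrinks the residual
roughly by the fluency, so response-level pipelines recover the
person-linked components well but not the residual magnitude; exact
recovery claims are always made at score level.  What passing tests show
about real data is correspondingly limited: real ratings are ordinal,
raters drift, and response sets are not exchangeable draws — none of which
the generator emulates.

One integer seed governs every draw; per-replicate seeds in
`parameter_recovery` are derived from it via a seed sequence (kept below
2^31).  Identical spec and seed give byte-identical tables.

## Validity descriptives

Composite person scores (mean over raters per item, optionally averaged
over a family's items) are summarised by mean, sample SD (n-1 denominator
— conventional for descriptives; the source does not state its choice),
and pairwise Pearson correlations on complete cases.  Zero-variance
variables yield undefined correlations, reported as missing with a
warning.  At least 3 persons are required.  Reproducing the source's
actual correlation table would require its archived dataset; the module is
validated against textbook-formula oracles on fixtures and synthetic data.

## Problem sizes

The test suite and analysis scripts use the study-scale design (80 x 2 x 3)
for pipeline runs, a 200-person x 8-item x 8-rater design with 200
replicates for estimator calibration (chosen so the Monte-Carlo standard
error of sigma2(p) is well under the 0.02 bias tolerance), and 1,000
random component/design draws for the coefficient-invariant checks.

## Known limitations

* Balanced, fully crossed, single-replication designs only — no nesting,
  no missing cells, no multivariate extensions.
* EMS estimation only; REML/Bayesian fits are out of scope (lme4 appears
  solely as a test oracle).
* No confidence intervals on coefficients, and no cost-optimal joint
  (n_i, n_r) search beyond the single-facet sweep.
* The generator does not model rater drift, response content, or
  rating-scale ordinality (beyond optional rounding).
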