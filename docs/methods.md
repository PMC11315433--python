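# Methods

## Problem

Direct measurement of the cervical central canal's cross-sectional area on
CT requires freeform tracing by a trained reader. Two linear measurements —
the anteroposterior (AP) diameter and the interpedicular distance (IPD) —
are far cheaper to obtain (and are the kind of measurement automated
readers already do well). This package implements and evaluates closed-form
area approximations built from those two lengths, for the five cervical
disc levels C2-3 … C6-7.

## Shape approximations

Treating the canal cross-section as a simple shape with extents AP and IPD
(mm):

| shape     | area (mm²)            |
|-----------|-----------------------|
| ellipse   | π · (IPD/2) · (AP/2)  |
| triangle  | ½ · IPD · AP          |
| rectangle | IPD · AP              |

All three are positive multiples of the product `P = AP·IPD`, so exactly
`ellipse = (π/4)·rectangle` and `triangle = rectangle/2`, and all three
share a single Pearson correlation with any reference measurement at a
level. Empirically the ellipse underestimates the manual area and the
rectangle overestimates it, which motivates the second-order approximation.

## Second-order approximation (SOA)

The SOA keeps the full ellipse value and adds a small per-level fraction of
the rectangle value:

    soa = ellipse + c(level) · rectangle = (π/4 + c) · AP · IPD

Two estimators of the rectangle weight `c` are provided (ellipse weight
fixed at 1):

- **least_squares** — `argmin_c Σ (measured − ellipse − c·rectangle)²`,
  closed form `c = Σ rect·(measured − ellipse) / Σ rect²`. This is
  regression through the origin of the ellipse residual on the rectangle
  area; its standard error is `sd(resid)/√(Σ rect²)`.
- **mean_match** — `c = mean(measured − ellipse) / mean(rectangle)`. By
  construction the paired mean difference between SOA and measurement is
  exactly zero, so the paired t-statistic is exactly 0 (p = 1) — the
  "statistically indistinguishable from manual measurement" property the
  SOA exists for. Delta-method standard error
  `sd(resid)/(mean(rect)·√n)`.

The package default is `least_squares`. Note a structural fact the test
suite documents: when the correlation between `P` and the measured area is
moderate (r ≈ 0.54–0.70, as in the reference population) while the SDs are
those of the reference tables, the slope of measured on `P` is
`r·s_m/s_P ≈ 0.31–0.40 < π/4`, and through-origin least squares then
assigns a small or even negative weight at the caudal levels. Mean-match
weights, by contrast, stay within the published per-level coefficient range
(0.021–0.071); the built-in coefficients shipped with the package are in
fact numerically close to the mean-match reconstruction from the reference
level means. Use `mean_match` when the goal is the zero-mean-difference
property; use `least_squares` when the goal is squared-error prediction.

Built-in per-level coefficients (dimensionless): C2-3 0.07091,
C3-4 0.046525, C4-5 0.041866, C5-6 0.0329399, C6-7 0.0210019.

## Evaluation statistics

Per level and per approximation: mean and SD of the paired differences
(approximation − manual; sample SD, n−1), a 95% t confidence interval of
the mean difference, percent error, Pearson correlation (banded weak
[0, 0.4), moderate [0.4, 0.7), strong [0.7, 1]), and the two-sided paired
sample t-test (alpha 0.05; no multiplicity correction, matching standard
practice for this kind of descriptive agreement table).

Percent error has two defensible readings, and the package computes both:

- `of_means` (default): `100·(mean(a) − mean(m))/mean(m)` — the definition
  under which the reference per-shape percent-error table is exactly
  recomputable from the reference level means;
- `mean_of_ratios`: mean of per-record `100·(a−m)/m` — larger in magnitude
  when errors covary with 1/m; this is the reading reported (explicitly
  flagged) in the SOA report table, whose of-means value is ≈0 by fit.

Degenerate t-test inputs follow a stated convention: all differences zero →
t = 0, p = 1; zero-variance nonzero differences → t = ±∞, p = 0.

## Synthetic cohort generator

No per-patient data are available, so the generator emulates the reference
population (803 patients per level) from its published level summaries.
Every downstream statistic depends only on the product `P` and the measured
area, which dictates the design:

1. `P ~ lognormal`, moment-matched to the reference rectangle mean/SD
   (`σ² = ln(1+(sd/mean)²)`, `μ = ln(mean) − σ²/2`). Lognormal guarantees
   positivity; the match is exact for any positive moments.
2. `measured = m + r·s·z(P) + √(1−r²)·s·ε`, with (m, s) the reference
   manual mean/SD, `r` the reference correlation, `z(P)` the within-level
   standardized product and `ε` unit normal; truncated below at 1 mm²
   (a test asserts truncation touches <0.1% of draws at defaults). The
   population correlation between `P` and `measured` is exactly `r`.
3. `P` is split into IPD and AP through a lognormal ratio `R = IPD/AP`
   with mean 2.0 and CV 0.10 (cervical canals are wider than deep). The
   reference study reports no AP/IPD summaries, so this convention is
   unverifiable — and deliberately inert: a test asserts the full
   evaluation table is invariant to it.

One global seed spawns one deterministic substream per level
(cranial→caudal), so cohorts are bit-stable for a fixed seed and levels can
be resized independently.

What a green calibration test establishes: realized per-level means/SDs and
correlations converge to their targets (checked at n = 50 000 within 1% /
0.01, and at n = 803 within sampling error). What it does not establish:
anything about real measurement error structure — inter-observer error,
pathology, non-lognormal canal geometry, or AP/IPD marginals are not
modelled.

Sample Pearson r on the heavy-tailed lognormal product runs slightly hot
(≈ +0.01 at n = 803) because high-leverage draws inflate the realized
signal variance; this sits well inside the ±0.05 calibration band and is a
property of sample correlation on skewed regressors, not of the target.

## Numerical choices

- All computation in float64; rounding (2 dp for areas, 3 dp for r,
  `<0.001` style for p) happens only at the report layer.
- Sample SDs use the n−1 denominator throughout.
- Published 2-dp level means carry ±0.005 display rounding; consistency
  checks that pass printed values through π/4 or /2 therefore use a ±0.01
  band (propagated input rounding plus output rounding).
- Fitting requires ≥2 records per level; least squares additionally
  requires non-identical rectangle areas. Errors name the offending level,
  row and field.

## Known limitations

- The SOA is fitted and evaluated on the same cohort (intrinsic validity
  only); no held-out validation is provided.
- The generator reproduces first/second moments and one correlation per
  level — not joint distributions across levels within a patient (levels
  are drawn independently).
- The reference SOA table's caudal-most row is internally inconsistent with
  its own inputs and is excluded from numeric reproduction targets.
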