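# canalarea

Approximation of the cervical central canal's cross-sectional area from two
linear CT measurements — the anteroposterior (AP) diameter and the
interpedicular distance (IPD) — with the full agreement-statistics
machinery needed to judge the approximations against manually traced
areas, and a calibrated synthetic-cohort generator so the whole pipeline
runs without patient data.

**Who it is for.** Researchers in spinal morphometry and developers of
automated (e.g. AI-driven) canal-stenosis screening who need canal area
from linear measurements, per cervical disc level C2-3 … C6-7.

## The model

With AP and IPD in mm, the canal cross-section is approximated as

- ellipse: `π·(IPD/2)·(AP/2)` — consistently underestimates,
- triangle: `½·IPD·AP` — underestimates badly,
- rectangle: `IPD·AP` — consistently overestimates,

and the **second-order approximation (SOA)** bridges the ellipse/rectangle
gap with a small per-level rectangle weight `c`:

    soa = ellipse + c(level)·rectangle = (π/4 + c)·AP·IPD

`c` is fitted per level either by least squares (through-origin regression
of the ellipse residual on the rectangle area) or by mean matching
(`c = mean(measured − ellipse)/mean(rectangle)`), which forces the paired
mean difference to zero so the paired t-test of SOA vs manual measurement
is non-significant by construction. Built-in per-level coefficients from
the 803-patient normative reference cohort are included. Each
approximation is evaluated per level by mean difference ± SD, percent
error, Pearson correlation (weak/moderate/strong banding) and the paired
sample t-test. See `docs/methods.md` for assumptions and estimator choice.

## Worked example

```python
from canalarea import CanalAreaModel

model = CanalAreaModel.simulate(seed=17)   # calibrated synthetic cohort
res = model.fit(method="mean_match")
print(res.summary())
```

```
Cervical canal area approximation
================================================================
Records:   4015    Levels: 5
Provenance: synthetic:seed=17
SOA coefficient source: mean_match

Second-order approximation: soa = ellipse + c * rectangle
             c     stderr
C2-3 0.0812582 0.00725558
C3-4 0.0369868 0.00583304
C4-5 0.0517445 0.00653811
C5-6 0.0438024  0.0059825
C6-7 0.0247252 0.00601852

SOA vs manual measurement
level  mean_diff    sd  pearson_r  p_value
 C2-3  1.274e-15 67.24      0.557        1
 C3-4  2.124e-15 51.88     0.5795        1
 C4-5   9.91e-16 59.18     0.5237        1
 C5-6 -3.256e-15 55.78      0.624        1
 C6-7  1.133e-15  57.5      0.708        1
```

The fitted weights `c` land in the published per-level range (≈0.02–0.08):
a few percent of the rectangle area is enough to offset the ellipse's
underestimate. Mean differences are zero to machine precision (the
mean-match property), the paired-t p-values are 1, and correlations sit at
the calibrated targets (moderate at C2-3…C5-6, strong at C6-7). The pure
ellipse rows of `res.evaluation` show the familiar pattern instead: mean
differences around −8 to −27 mm² (percent error −3% to −9%), significant
at p < 0.001 with n = 803 per level.

The same pipeline runs from a shell:

```sh
canalarea simulate --seed 17 --out cohort.csv
canalarea report --in cohort.csv --soa-coeffs builtin --out-dir report/
```

which writes `table1.csv` (per-level means ± SD), `table2.csv`
(mean differences, p, correlation per shape), `table3.csv` (percent
errors), `table4.csv` (SOA evaluation) and a run log. `canalarea fit-soa`
and `canalarea evaluate` expose the individual steps; measurement CSVs use
the header `patient_id,level,ap_diameter_mm,ipd_mm,measured_area_mm2`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the headline quantities by running the package: the mean SOA
areas at C2-3 and C5-6 obtained by applying the built-in coefficients to
the reference level means (exact by linearity of the SOA), and the
realized rectangle-vs-measured Pearson correlation at C6-7 in a freshly
generated 803-record synthetic cohort at the given seed. Results are
written as JSON keyed by target id.
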