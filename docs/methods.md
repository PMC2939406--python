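# Methods

## Model and assumptions

The package implements a deterministic kinetic model of HbA1c formation
built on three physiological premises:

1. **Linear glycation.** A red cell living at constant mean plasma glucose
   (MPG) accumulates HbA1c linearly with age: zero at birth, and at the end
   of its life exactly twice the steady-state HbA1c that glucose level
   sustains. The per-cell accumulation at age `m` months on a curve with
   steady HbA1c `h` is `h·m/2`.
2. **Uniform age structure.** Erythropoiesis balances destruction, so 1/120
   of the circulating mass is at each integer day of age and the population
   mean is the arithmetic mean of the youngest and oldest cells. The
   lifespan is fixed at 120 days, treated as exactly 4 months of 30 days;
   closed forms take fractional months.
3. **Linear HbA1c↔MPG conversion.** The DCCT regression
   `MPG = 35.6·HbA1c − 77.3` (mg/dl) links steady HbA1c to glucose. The
   canonical mixture algebra runs entirely in Hb-space and is independent of
   this choice; conversions enter only at the input/output boundary.

A step change in glycemic control at time 0 splits the population observed
`m` months later into old-curve survivors (weight `(4−m)/4`) and cells born
after the change (weight `m/4`), yielding the mixed measurement
`Hb_mix = [Hbₓ(8m−m²) + Hb₁(m²−8m+16)]/16` and its closed-form inverse.
The turnover fraction `100·(8m−m²)/16` is endpoint-independent because the
endpoints cancel in `(Hb₁ − Hb_mix)/(Hb₁ − Hbₓ)`.

Deliberately excluded (out of scope by design): inter-individual variation
in glycation rate, variable erythrocyte lifespan (hemoglobinopathies,
reticulocyte dynamics), glycation saturation or reversal, refitting the
DCCT regression, and measurement-uncertainty propagation.

## Parameters and conventions

| Parameter | Default | Meaning |
|---|---|---|
| lifespan | 120 days = 4 months | erythrocyte life, all cells identical |
| month | 30 days | time unit of all closed forms |
| DCCT slope / intercept | 35.6 mg/dl per % / −77.3 mg/dl | forward conversion |
| intercept mode | `paper` | inverse intercept 2.17 (printed) vs 77.3/35.6 (exact) |
| constant mode | `paper` | MPG-space constants 570/1236 (printed) vs composition through the conversion model |
| error-grid mask | implied Hbₓ ∈ [0, 20]% | plausibility envelope for tabulated cells |

Two mode axes exist because the published inverse intercept (2.17) and
MPG-space constants (570, 1236) are roundings of 77.3/35.6, 16×35.6 and
16×35.6×2.17. The `paper` defaults reproduce printed clinical numbers; the
`exact` modes make forward∘inverse an identity to 1e−9 and are what the
self-consistency tests use. The two constant modes agree within
1.5 mg/dl of recovered MPG for m ≥ 1 month over the clinical range
(HbA1c 4–14%, MPG 100–420 mg/dl); at two weeks the `1/(8m−m²)` factor
amplifies the rounding to a worst-case ~1.6 mg/dl at the extreme corner.

The ADAG relationship ships only as tabulated anchors (5–12% HbA1c) with
monotone linear interpolation; no formula is extrapolated. The DCCT table
anchors are stored verbatim; they drift from the regression line by up to
~1 mg/dl (they were evidently derived via the mmol/l column with rounding),
which the tests assert as a bound rather than resolving. Display rounding is
half-away-from-zero; raw operations never round.

## The cohort simulator

The simulator is the package's independent oracle, not a fit: 120 equal-mass
daily cohorts, one-day steps, each day's glycation increment set by that
day's MPG alone (piecewise-constant forcing), the 120-day cohort destroyed
and a newborn cohort created each step. Cohort values are carried at mid-day
ages (age + 0.5 days, the newborn holding half a day's increment) so the
discrete steady-state mean equals the continuous arithmetic-mean result
exactly instead of with O(1/120) bias. With this convention the simulated
step-change mean matches the closed-form mixture to machine precision at
month boundaries; the test tolerance of 0.05 HbA1c points is therefore
conservative. The model has no stochastic component and needs no seed.

The simulator generalises what the closed forms cannot express — arbitrary
daily MPG trajectories and multiple changes within one window — but shares
the model's idealisations: it says nothing about assay noise, lifespan
heterogeneity, or nonlinear glycation, so agreement between the two routes
validates the algebra, not those physiological simplifications.

## Inversion, flags and masking

The inversion is algebraically exact; feeding the recovered `Hbₓ` back
through the forward mixture reproduces the measurement to 1e−9. Recovered
values at or below zero (equivalently MPGₓ ≤ 0) are *flagged*
`non-physiological`, never clamped and never raised: error tabulations
legitimately enter such regimes. `m = 0` is excluded from every inversion
domain (no measurement is "zero months later"); limits as m → 0⁺ are
covered by property tests.

Error grids mask a cell when the implied new-curve HbA1c leaves a
configurable plausibility envelope (default [0, 20]%) or the recovered MPGₓ
is non-positive. Published versions of such tables blank additional
cells under an unstated rule that no constant-mode choice reproduces, so the
package asserts and documents the structural properties instead: near-zero
diagonal (|error| < 0.25 under the rounded constants, exactly 0 under exact
constants), sign determined by which side of the diagonal a cell lies on,
magnitude growing with the |Hb₁ − Hb_mix| mismatch, and three-month errors
uniformly smaller than two-month ones. Diagonal cells are sub-0.25 rounding
residues of the printed constants and are excluded from the decay
comparison, which is a claim about genuine errors.

Similarly, the first- and second-month turnover fractions (43.75% → 44
rounded, 75%) and the 100% endpoint follow from the formula; tabulations of
the third/fourth months sometimes printed elsewhere (17%/8%/92%) are not
consistent with it (the formula gives 18.75%/6.25%/93.75%) and are not
asserted.

## Numerical and design choices

* All closed forms are exact rational expressions in floats; no iteration,
  no tolerance tuning. Comparisons in tests use 1e−9 for algebraic
  identities, 0.05 HbA1c points for simulator-vs-closed-form.
* Scenario inputs given in MPG-space are converted to Hb-space once at
  construction under the active model/mode and kept; no silent
  re-conversions.
* The fixture generator's randomised simulator-vs-closed-form grid draws
  (Hb₁, Hbₓ) uniformly from [4, 14]% — the plausible clinical range the
  error tables also span — and m from {0.5, 1, 2, 3, 4} months, under the
  fixed seed 1729; published-anchor fixtures are deterministic.
* The CLI prints full-precision values; table-display rounding
  (half-away-from-zero) is opt-in and never feeds back into computation.

## Known limitations

The model is a deliberate idealisation: one instantaneous change between two
constant glucose levels, identical cells, exact 120-day lifespan, strictly
linear kinetics. Real HbA1c trajectories include assay noise (~0.1–0.5
points), lifespan dispersion that smooths the sharp 4-month washout corner,
and mild glycation nonlinearity at high glucose. Closed-form inversion is
also ill-conditioned at very small m, where `1/(8m−m²)` amplifies both
measurement error and the rounded published constants — results from
intervals much shorter than two weeks should not be trusted clinically even
though the algebra is exact.
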