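# Methods

## Dose–response model and fitting

Single-agent cytotoxicity is modelled with the median-effect equation
fa/fu = (D/Dm)^m. One model serves both purposes the pipeline needs: the
IC50 of each agent (Dm itself) and the equieffective dose Dx at any effect
level, Dx = Dm·(fa/(1−fa))^(1/m). Percent-of-control viability v maps to
fraction affected as fa = 1 − v/100, clamped to [0, 1]; wells brighter than
control (v > 100%) clamp to fa = 0 with a warning rather than an error,
because real MTT plates routinely overshoot control.

The fit is ordinary least squares on the linearization
log₁₀(fa/fu) = m·log₁₀D − m·log₁₀Dm (base 10 throughout; any base gives the
same Dm and m, base 10 is fixed so intercepts are reproducible). Replicate
wells are averaged to one viability value per dose *before* the transform —
the standard median-effect workflow, where the mean fractional effect per
dose enters the plot. This default also has a statistical rationale: points
with fa ∈ {0, 1} must be excluded (undefined log-odds), and applying that
exclusion to individual noisy wells retains a biased subset at the extreme
doses. Measured on the synthetic plates (1000 seeds, study conditions
below), per-well fitting biases the recovered Dm by about −2.5% while
mean-per-dose fitting is unbiased to within ±0.6%; RMSE is ≈9% either way.
`per_replicate=True` selects the per-well regression when wanted.

Degenerate inputs: fewer than two usable points, or all usable points at a
single dose, or an exactly flat median-effect plot raise a fit error. A
negative slope (effect decreasing with dose) yields a fit flagged
`non_inhibitor` rather than an error, so screening data with inverted
response is surfaced, not silently dropped.

## Combination index and classification

CI = D1/Dx1 + D2/Dx2 + α·D1·D2/(Dx1·Dx2), with α ∈ {0, 1}. The analysis
default is α = 1 (independent modes of action); α = 0 makes CI coincide
with the normalized isobologram coordinate sum for equieffective points.
Equieffective doses come either from the fitted curves (pipeline mode) or
directly from supplied Dx columns (replication mode, for re-scoring a
published table); both paths share one CI evaluation.

Classification rounds CI half-up to one decimal and compares with 1.0 —
the semantics of printed CI tables, where 1.0 is labelled additive. An
explicit band |CI − 1| ≤ tol (including tol = 0 for the exact rule) is
available. When a replication-mode input carries the published CI, any
disagreement at the printed precision is flagged `printed_ci_mismatch` and
the computed value is reported; the flag, not silent agreement, is the
contract. (The published cisplatin/α-mangostin table contains one such row:
(2, 10, 20.7, 13.8) evaluates to 0.891 → 0.9 against a printed 0.8.)

Isobologram placement uses tolerance 0.05 on the coordinate sum by
default, matching the one-decimal CI granularity, so placement and α = 0
classification agree on equieffective points.

## In vivo endpoints

V = (π/6)·width²·length with width the smaller caliper dimension; swapped
inputs are corrected with a warning (the formula is asymmetric and the
smaller-dimension convention is standard for xenografts).
CDT = days/log₂(V_final/V_initial), implemented with natural logs (only
the ratio of logs enters). A shrinking tumor gives a negative CDT, reported
as-is and counted in the group summary's `n_shrinking` column; an exactly
unchanged volume raises an explicit error instead of returning infinity.

The treatment window for CDT is configurable; the default spans each
animal's first to last measurement, and an explicit window uses the first
measurement on/after its start and the last on/before its end, with the
actual day span between those measurements as "days of treatment". Group
summaries report mean ± SD (population SD) of initial volume, final volume
and per-animal CDT; animals are sorted within group before aggregation so
the summary is bit-identical under input reordering.

## Synthetic data generator

The generator emulates the study the pipeline was built for and doubles as
its ground-truth oracle.

**Single-agent plates.** Viability = 100·(1 − fa(D)) + N(0, σ), clamped at
0, with σ = 5 percentage points by default and triplicate wells. Ground
truth: CDDP Dm = 29.7 µM, α-M Dm = 19.1 µM, both with m = 2 (a typical MTT
slope; the emulated study reports only the IC50s). Dose grids are twofold
dilution series from each agent's top tested concentration (CDDP 120 µM,
α-M 80 µM; 6 positive doses plus a control row). The replicate-level
variance is a modelling choice — the emulated study reports none.

**Combination plates.** The generative null is Loewe additivity, the model
the CI/isobologram framework is consistent with: the combined effect F of
(D1, D2) solves D1/Dx1(F) + D2/Dx2(F) = 1 (unique root, bracketed
bisection). A per-scheme deviation factor β multiplies F (clamped to
[0, 1]) before noise: β = 0.7 for coincubation (the protective interaction
seen when both drugs are co-exposed), β = 1.3 for preincubation (the
potentiating sequence), β = 1 for an exactly additive scheme. Default dose
pairs lie on the theoretical additivity isobole at 1/4, 1/2 and 3/4 of the
CDDP IC50 — the emulated study likewise chose its combination
concentrations from the theoretical isobologram, and near the 50% effect
level the CI is least sensitive to well noise (the log-odds derivative
1/(2F(1−F)) is minimal at F = 0.5). Calibration of interaction calls
against the null is done with α = 0, under which the Loewe construction
gives CI = 1 exactly in the noise-free limit; the α = 1 cross term is an
analysis convention, not a generative one, and is strictly positive even
for perfectly additive data.

**Xenograft cohorts.** Four arms (control, CDDP, α-M, CDDP+α-M), 7 animals
each. V0 ~ Normal(mean, SD) truncated at 0, with the per-arm means/SDs on
the reported scale (168±59, 144±41, 143±36, 192±93 mm³); growth is
exponential with rates set from the reported doubling times
(r = ln2/CDT: 3.9, 4.7, 4.9, 8.5 days), multiplicative measurement noise
(1 + ε), ε ~ N(0, 0.05) truncated above −0.9. Calipers are back-derived
from volume at a fixed length = 1.5·width, so the volume formula recovers
V(t) exactly (any fixed aspect ratio preserves this identity).
Measurement days default to 0, 3, 6, 9, 12: the source report's weekly
10-week schedule is arithmetically incompatible with its own volumes and
doubling times (at r = ln2/3.9 per day, 70 days of growth from 168 mm³
would exceed 10⁶ mm³), so the simulated window is chosen to keep volumes
on the reported 150→1100 mm³ scale while preserving the doubling times.
Group CDT table values are therefore structural emulation only, not
quantitative reproduction.

**Determinism.** Every generator draws from
`numpy.random.default_rng([seed, crc32(stream_label)])`, so one seed fixes
all outputs bit-for-bit while streams (per agent, scheme, group) remain
mutually independent.

## What the synthetic data does not emulate

Plate-position and edge effects, correlated replicate error, lognormal or
heteroscedastic OD noise, effect-level-dependent interaction (β is a single
multiplicative knob at all effect levels), tumor growth deceleration
(Gompertzian plateaus), measurement dropout, and animal attrition. Passing
tests demonstrate correctness of the estimators and calls under the stated
noise model, not robustness to these real-data features.

## Numerical choices

- Loewe root: `scipy.optimize.brentq` on [1e-12, 1−1e-12], xtol/rtol 1e-14.
- Linear fit: `scipy.stats.linregress`; r² is the squared correlation of
  the linearized plot.
- Rounding for classification: decimal half-up (ties away from 1.0-band),
  matching how printed tables round, rather than banker's rounding.
- CSV readers use `float_precision="round_trip"` so written reports parse
  back to identical binary floats; all writers emit shortest-repr floats.

## Problem sizes

Stochastic checks use 100 simulated plates per agent for IC50 recovery and
50 simulated combination plates per deviation factor for call calibration
— enough for sub-percent Monte-Carlo error on the measured bias while
keeping the default suite fast.

## Known limitations

- The median-effect linearization weights all usable doses equally;
  no inverse-variance weighting of extreme effect levels is applied.
- Only two-drug combinations at a single effect normalization (50%) are
  supported; dose-matrix designs and response-surface models (Bliss, ZIP,
  HSA) are out of scope.
- CDT for non-monotone trajectories uses only the two bracketing
  measurements of the window; no regression over the full trajectory.
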