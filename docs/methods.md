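# Methods

## The reactive continuum model and its calibration

The extractable Fe(III) pool of a sediment is treated as a continuum of
reactivities. The pool remaining at time `t` of an extraction is

    M(t) = M0 · (a/(a+t))^v

with dissolution rate `J(t) = M0·(v/a)·(M(t)/M0)^(1+1/v) = −dM/dt`, and the
measured cumulative release is `Fe_d(t) = M0 − M(t)`. The model nests
first-order kinetics: holding `k = v/a` fixed and letting `v → ∞`,
`M(t) → M0·e^(−kt)`; finite `v` flattens the decay because the most reactive
material dissolves first. Interpretive parameters: reducibility `v/a` (s⁻¹,
the apparent rate constant), composition `1 + 1/v` (≈1 for a uniform pool,
>1 for a reactivity mixture), lability `(v/a)·M0` (the initial rate).

The naming of `v/a` as *reducibility* and of the initial rate as *lability*
follows the parameter-table convention of the field literature (some prose
passages swap the two labels; the package uses one convention throughout).

**M0 from the plateau, not from the fit.** `M0` is fixed at the maximum
cumulative Fe observed by the end of the extraction (`PlateauRule("max")`,
the default), mirroring how time-course extractions are evaluated in
practice: the experiment is run until the Fe(II) signal is stable, and the
plateau *is* the amount. A stability criterion — unstated in the field
protocols, chosen here once as "last 3 samples within a 5% relative range",
configurable — flags curves that never settled; the estimate is still
returned (never an exception) so downstream tables can carry the flag. An
alternative `tail_mean` rule (mean of the last k points when stable) is
selectable. When the maximum occurs at several times, the earliest is
reported as plateau onset.

Because extractions stop at 32 h, the observed plateau is the truncated
amount `M0·(1−(a/(a+T))^v)`, a few percent below the asymptote for realistic
reducibilities. This is inherent to the plateau definition, not a defect;
parameter-recovery tests therefore distinguish "recovery given the true M0"
(machine precision, noiseless) from "recovery through the plateau rule"
(within the truncation bias).

**Fitting a and v.** With `M0` fixed, `(a, v)` minimize the unweighted sum
of squared deviations between the observed and modelled cumulative release
(`scipy.optimize.least_squares`, trust-region reflective). The fit runs on
log10-transformed parameters for conditioning, with bounds `a ∈ [1, 10⁹] s`,
`v ∈ [10⁻³, 10³]` and defaults `a₀ = median sampling time`, `v₀ = 1`.
Optional relative weighting divides residuals by the observation magnitude.
Non-monotone noisy curves are fitted as-is (no isotonic smoothing, which
would bias residuals). Non-convergence returns the best iterate with
`converged=False`; derived parameters refuse such fits. Standard errors for
`a` and `v` come from the Gauss–Newton covariance on the log scale,
propagated through the log transform. An independent brute-force minimizer
(`grid_search_rcm`, 200×200 log-spaced grid) serves as the oracle in tests;
it is never the production path.

## Wet-chemistry reductions

Colorimetric assays (ferrozine for Fe(II), formaldoxime for Mn) reduce to a
linear calibration: OLS absorbance-vs-concentration, inverted with a
dilution factor; concentrations below the blank clip to zero with a flag.
Vessel concentrations convert to µmol per g dry weight via
`conc · volume / dry_mass`. An optional withdrawal correction applies the
exact mass balance — each point credits the Fe removed in earlier aliquots
and uses the remaining extractant volume — and is off by default because
sampling aliquots are small against the 100 mL vessel volume.

Sequential-HCl speciation is bookkeeping: per step (0.5 M, then 6 M HCl),
Fe(III) = total − Fe(II), clipped at zero with a flag when the Fe(II)
measurement exceeds the total (physical non-negativity, keeps totals
conservative); the pool total sums the step totals. Porosity and water
content come from weight loss on drying a known volume; an implied porosity
above 1 is rejected as inconsistent input. Replicates aggregate as
mean ± sample SD; the uninoculated control of microbial extractions is a
measurement of native iron-reducer activity and is reported alongside,
never subtracted.

## Sulfate reduction rates

`SRR = [SO4]·1000·φ·(a_TRIS/(a_TRIS+a_SO4))·f / t` in nmol cm⁻³ d⁻¹, with
the fractionation correction `f = 1.06` of the cold-chromium distillation
method (configurable). Porosity scaling happens in this formula, not in the
reader. Depth integration is piecewise-constant (rate × thickness), matching
1-cm core slicing; all provided slices are integrated by default, with the
bound configurable, since the appropriate lower bound depends on how deep
the cores were sliced.

## Transect gradients

The exponential spatial model `value(d) = value0·e^(rate·d)` is fitted as
OLS of `ln(value)` on distance (the growth is a straight line on a semi-log
plot), giving the growth rate, R² on the log scale and a two-sided slope
p-value. Log-linear OLS rather than nonlinear fitting on the raw scale keeps
the significance machinery the standard linear-regression t-test. The
significance threshold (default α = 0.05) only flags; the p-value is always
reported. Fold change is farthest/nearest station by distance within the
subset. Per-transect subsets (a maximum distance) support transects whose
gradient breaks down beyond some station; full and truncated fits are
reported side by side.

## The synthetic-data generator

The generator emulates the field design so the pipeline is testable with
known truth: RCM-shaped curves sampled on the field cadence (0, 5, 10, 20,
30 min, hourly to 450 min, then 2-hourly to at most 32 h), triplicate
inoculated + one uninoculated-control microbial vessels, multiplicative
Gaussian noise on concentrations (sd 5% by default — assay error scales with
signal; no error model is stated in field protocols), exponential
head-to-mouth surface gradients, an optional subsurface-peak depth mode, and
tracer count tables built by inverting the rate formula (optional Poisson
counting noise). Everything is byte-deterministic under a fixed seed, and a
truth ledger accompanies every bundle as the oracle for recovery tests.

Default scenario, chosen once as a realistic mid-scale campaign: five
stations over 0–30 km; surface M0 growing ninefold from 5 to 45 µmol g dw⁻¹;
lability growing at the same ninefold rate from 2×10⁻⁴ µmol g dw⁻¹ s⁻¹, i.e.
a constant reducibility of 4×10⁻⁵ s⁻¹ along the transect; heterogeneity
exponent v = 1.5; 0.75 g sediment in 100 mL. Applying one gradient to both
amount and lability means every station shares the same dissolution kinetics
up to scale, so the truncated-plateau fraction is identical everywhere and
the configured fold change and growth rate are recovered exactly by a
noiseless run — the cleanest possible end-to-end oracle. Field transects
with steeper lability than amount gradients (up to ~19-fold vs ninefold) are
one config line (`lability_gradient`); for such scenarios the noiseless
recovered amount fold change deviates from the configured truth by the ratio
of station capture fractions (~8% for the 19-fold case), which is a property
of the plateau-based M0 definition, not of the estimator.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: porewater diffusion and reoxidation of reduced
sulfur, non-Gaussian assay error and drift, vessel-to-vessel heterogeneity
beyond the noise model, correlated depth structure beyond the simple peak
mode, Mössbauer-visible mineralogy, or grain-size effects.

## Numerical choices and degenerate inputs

Seconds are the internal time base throughout; readers convert. Fits are
deterministic given inputs and options. All-zero curves and curves with
fewer than 4 points are rejected before fitting; plateau estimation needs at
least 3 points. Tracer slices with zero total activity, porosities outside
(0, 1), overlapping depth intervals, non-positive gradient values (log
scale) and implied porosities above 1 are rejected with named errors. Result
tables are written with a fixed `%.10g` float format so repeated runs are
byte-identical. Problem sizes in the test suite and acceptance script (24
sampling times per curve, 100 Monte-Carlo seeds, 200 noisy transects, 5-station
demo scenario) were chosen as the smallest sizes at which the statistical
checks are meaningful.

## Known limitations

* The plateau rule inherits the truncation bias of finite-duration
  extractions; `M0` is the operational amount released by 32 h, not the
  asymptotic pool.
* With `M0` fixed below the asymptote, fitted `a` and `v` absorb the
  truncation (≈10–15% bias in each for typical curves) while their ratio-
  and product-derived quantities remain comparable across stations that
  share kinetics; comparisons across very different kinetics should keep
  this in mind.
* Depth integration is rectangle-rule only; no trapezoid option.
* The gradient fit treats stations as independent; no spatial
  autocorrelation structure.
* No scintillation-counter efficiency correction, sulfate diffusion, or
  reoxidation modelling in the tracer rates.
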