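# fjordfe

Quantitative analysis of benthic iron cycling in glacially influenced fjord
sediments: how much potentially bioavailable iron a sediment holds, how fast
it can be reduced, and how those properties change from the fjord head to the
fjord mouth.

The package is aimed at marine geomicrobiologists and sediment
biogeochemists who run time-course iron extractions (chemical, with an
ascorbate buffer, or microbial, with an iron-reducing culture), sequential
HCl leaches, and ³⁵S-radiotracer sulfate-reduction incubations, and want a
tested, reproducible route from raw vessel measurements to interpretable
parameters and transect statistics.

## The model

Dissolution of sedimentary Fe(III) during a time-course extraction follows a
**reactive continuum model**: the extractable pool has a continuous
distribution of reactivities, so the iron remaining in the sediment decays as

```
M(t) = M0 · (a / (a + t))^v
```

with `M0` the total extractable iron (µmol g dw⁻¹), `a` a time scale (s) and
`v` a dimensionless heterogeneity exponent. The dissolution rate is

```
J(t) = M0 · (v/a) · (M(t)/M0)^(1 + 1/v)
```

and the cumulative release `Fe_d(t) = M0 − M(t)` is what the vessels measure.
`M0` is fixed from the observed end-of-extraction plateau; `a` and `v` are
then fitted by nonlinear least squares. Four interpretive parameters result:

| parameter | formula | meaning |
|---|---|---|
| amount | `M0` | size of the extractable pool |
| reducibility | `v/a` (s⁻¹) | apparent rate constant |
| composition | `1 + 1/v` | heterogeneity (≈1 uniform, >1 mixed) |
| lability | `(v/a)·M0` | initial dissolution rate |

Around the kinetic core the package provides sequential-HCl Fe(II)/Fe(III)
speciation (Fe(III) by difference), volumetric sulfate reduction rates from
³⁵S tracer counts with piecewise-constant depth integration, log-linear
(exponential) regression of surface iron quantities against distance from
the fjord head, and a synthetic-data generator that emulates the whole field
design with known truth.

## Worked example

```python
import fjordfe as f

truth = f.RCMParams(m0=30.0, a=5000.0, v=1.5)        # a mid-range pool
sched = f.field_schedule()                            # 5 min … 32 h cadence
tab = f.simulate_dissolution(truth, sched, 0.05, seed=1,
                             dry_mass_g=0.75, volume_l=0.1)
curve = f.build_dissolution_curve(tab.time_s, tab.conc_uM,
                                  volume_l=0.1, dry_mass_g=0.75)
m0, stable = f.estimate_m0(curve)
fit = f.fit_rcm(curve, m0)
d = f.derive_params(fit)
print(f"M0 = {m0:.1f} umol/gdw (stable plateau: {stable})")
print(f"reducibility v/a = {d.reducibility:.2e} s^-1")
print(f"composition 1+1/v = {d.composition:.2f}")
print(f"lability = {d.lability:.2e} umol gdw^-1 s^-1")
```

prints

```
M0 = 31.6 umol/gdw (stable plateau: False)
reducibility v/a = 3.32e-04 s^-1
composition 1+1/v = 2.11
lability = 1.05e-02 umol gdw^-1 s^-1
```

With 5% measurement noise the fit recovers the true reducibility
(3.0×10⁻⁴ s⁻¹) to within about 10%; the composition of 2.11 (> 1) says the
pool mixes reactivities rather than being a single uniform phase. The
`stable` flag is honest about this draw: the noisy tail of the curve
wandered by more than the 5% stability window, so the plateau is flagged
rather than silently trusted.

The full pipeline runs from the shell:

```sh
fjordfe simulate --out-dir data --seed 4          # synthetic field campaign
fjordfe run-all --input-dir data --out-dir out --seed 4
```

which reports per-vessel fits, per-transect exponential gradients with R²
and slope p-values, farthest/nearest fold changes, and depth-integrated
sulfate reduction rates.

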