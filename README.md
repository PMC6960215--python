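# hydropol

Hydration-layer analysis of polymer/water systems: hydrogen-bond
densities, polymer–water distance statistics with double-Gaussian shell
decomposition, rolling-ball contact area, three-component
composite-material decomposition of property-vs-moisture curves, and
detection of the moisture-induced crossover by two-segment fitting.

## The problem

Hydrophilic biopolymers (hemicelluloses such as softwood
arabinoglucuronoxylan, amorphous cellulose, starches) change their
thermodynamic and mechanical behaviour drastically with moisture content
*m* = *m*<sub>w</sub>/*m*<sub>p</sub> (water mass over dry polymer
mass).  Many properties — heat of adsorption *Q*, thermal expansion
coefficient *α*, heat capacity *C*<sub>p</sub>, bulk/Young's/shear
moduli *K*, *E*, *G*, Poisson's ratio — show **two linear regimes**
separated by a crossover near *m* ≈ 30 wt%.  The microscopic picture is
double-layer adsorption: water within ~4.5 Å of the polymer forms a
first ("bound") layer that saturates, after which additional water
accumulates in a second, bulk-like layer from 4.5 to 20 Å.

`hydropol` implements, as a tested reusable pipeline, the
post-simulation statistics with which such a crossover is identified and
decomposed, plus a synthetic-data module that generates configurations
and curves with the same statistical structure so every stage is
testable without running molecular dynamics.

## What it computes

* **Hydrogen bonds** — geometric criteria: donor-O–acceptor-O distance
  *r* < 0.35 nm and the angle *α* < 30° at the **donor oxygen** between
  the O→acceptor-O and O→H directions.  Counts per class
  (polymer–polymer, polymer–water, water–water) are normalised by the
  dry volume *V*<sub>0</sub> to give densities #HB/*V*<sub>0</sub>.
* **Hydration layers** — *d*<sub>pw</sub>, the minimum-image distance
  from each water oxygen to its nearest polymer atom; time-averaged
  population histograms *N*<sub>water</sub>(*m*, *d*<sub>pw</sub>); a
  double-Gaussian decomposition (DGD) of the two shells (typically
  centred near 2.8 Å and 5.6 Å); layer assignment at 4.5 Å / 20 Å and
  layer volume fractions.
* **Contact area** — Shrake–Rupley rolling-ball surface areas with
  periodic images (probe radius 1 Å) and
  *A*<sub>contact</sub> = *A*<sup>polymer</sup> + *A*<sup>water</sup> −
  *A*<sup>system</sup>, whose saturation signals that new water binds to
  water rather than polymer.
* **Composite decomposition** — a property *X*<sub>c</sub> of the
  hydrated material as a three-phase composite of polymer, first and
  second water layer with volume fractions *f*<sub>v,p</sub>,
  *f*<sub>v,w1</sub>, *f*<sub>v,w2</sub>:

  mixture rule / parallel: *X*<sub>c</sub> = *f*<sub>v,p</sub>*X*<sub>p</sub> + *f*<sub>v,w1</sub>*X*<sub>w1</sub> + *f*<sub>v,w2</sub>*X*<sub>w2</sub>

  series: 1/*X*<sub>c</sub> = *f*<sub>v,p</sub>/*X*<sub>p</sub> + *f*<sub>v,w1</sub>/*X*<sub>w1</sub> + *f*<sub>v,w2</sub>/*X*<sub>w2</sub>

  `CompositeModel.fit()` inverts these by least squares to recover the
  phase properties with standard errors.  Moduli conventionally follow
  the series law, scalar heats the mixture rule, thermal expansion the
  parallel law; the isotropic relation *G* = 3*KE*/(9*K* − *E*) links
  the moduli.
* **Crossover** — `TwoSegmentModel.fit()` finds the breakpoint *m*\* of
  a continuous two-segment linear fit, with a seeded residual-bootstrap
  CI and a permutation test deciding whether a crossover is present at
  all.
* **Property estimators** — standard reductions of observable series:
  *α*<sub>X</sub> from box length vs temperature, *C*<sub>p</sub> from
  enthalpy vs temperature, moduli from stress–strain slopes, Poisson's
  ratio from transverse vs axial strain, heat of adsorption from
  potential energies referenced to vapor-phase water.

## Worked example

```python
import numpy as np
from hydropol import (
    generate_polymer_configuration, generate_hydrated_configuration,
    generate_fraction_schedule, generate_property_curve,
    polymer_water_distances, population_histogram, fit_double_gaussian,
    fit_composite, fit_two_segment,
)

# a 5-chain x 100-bead polymer at 1.3 g/cm^3, hydrated to m = 0.3 with
# shells prescribed at 0.28 / 0.56 nm
polymer = generate_polymer_configuration(5, 100, target_density=1.3, seed=7)
hydrated = generate_hydrated_configuration(polymer, 0.3, seed=7)
d = polymer_water_distances(hydrated)
dgd = fit_double_gaussian(population_histogram(d, bin_width=0.01, d_max=2.0, m=0.3))
print(dgd.summary())
```

```
Double-Gaussian decomposition
===============================================
component          amp   mean (nm)   sd (nm)
shell 1         54.055      0.2761    0.0491
shell 2         11.962      0.5425    0.1506
rss: 1081.45
===============================================
```

The fitted first-shell centre, 0.2761 nm = 2.76 Å, recovers the
generator's 2.8 Å shell to better than 0.05 Å; the second shell sits at
5.4 Å (its far tail is truncated by the largest voids the packing
offers).  Decomposing a noisy synthetic heat-of-adsorption curve and
locating its crossover:

```python
schedule = generate_fraction_schedule(np.linspace(0, 0.6, 25), m_sat=0.3, f_w1_max=0.2)
curve = generate_property_curve("mixture", 3340, 1110, 2660, schedule,
                                noise_sd=11.0, seed=42, property="Q", units="kJ/kg")
print(fit_composite("mixture", curve).summary())
print(fit_two_segment(curve, seed=42).summary())
```

```
Composite decomposition
===============================================
model kind:      mixture
n points:        25
weighted rss:    1917.93
-----------------------------------------------
phase           estimate       std err
X_p              3335.42          4.69
X_w1             1145.28          37.8
X_w2             2642.51          26.4
===============================================
Two-segment crossover fit
===============================================
breakpoint m*:   0.2988  (95% CI 0.2750 – 0.3250)
slope (low m):   -1649.39
slope (high m):  -650.297
rss 2-segment:   1915.63
rss 1-segment:   52754.5
permutation p:   0.0050  -> crossover
===============================================
```

The phase properties (3340, 1110, 2660) kJ/kg are recovered within a
few standard errors, and the breakpoint lands at *m*\* = 0.299 — the
first-layer saturation point the schedule was built with.

## Command line

```sh
hydropol generate --n-chains 5 --beads-per-chain 100 --m 0.3 --out sys.gro
hydropol hbonds sys.gro --out hbonds.csv
hydropol layers sys.gro --out-prefix sys
hydropol contact-area sys.gro --out area.csv
hydropol decompose curve.csv schedule.csv --out fit.json
hydropol crossover curve.csv --out crossover.json
hydropol run --output-dir out --seed 1        # full pipeline + manifest
```

Every output carries the parameter set that produced it (CSV comment
headers, JSON `parameters` blocks, and a `manifest.json` for full runs).

## Documentation

`docs/methods.md` describes the models, the synthetic-data generators
and their limitations, numerical choices and defaults.
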