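# Methods

This note documents the models and procedures implemented in
`hydropol`, the defaults and the reasoning behind them, what the
synthetic-data generators do and do not emulate, and the numerical
choices that matter.

## Data model and units

A `Configuration` is one frame of a polymer/water system in an
orthorhombic periodic box: per-atom positions, roles (polymer /
water oxygen / water hydrogen), elements, van der Waals radii, masses
and molecule ids.  The internal length unit is the nanometre
everywhere; ångströms appear only at presentation boundaries (shell
centres are conventionally quoted in Å).  A single unit internally
prevents silent factor-of-10 errors between the hydrogen-bond, layer
and surface-area stages.

Moisture content *m* is always computed from the atom masses
(water mass over dry polymer mass, IUPAC masses, water = 18.015 g/mol),
never stored, so it cannot drift from the atomistic content.  Only
orthorhombic boxes are supported; triclinic input is rejected rather
than silently mishandled.  Distances use the minimum-image convention
on wrapped coordinates.  Van der Waals radii default to the Bondi set
keyed by element and can be overridden per atom; unknown species in
imported files (e.g. coarse-grained bead labels) fall back to carbon
values with a warning.

## Hydrogen bonds

Geometric definition: a (donor O–H, acceptor O) triple is a hydrogen
bond when the O–O distance is below 0.35 nm and the angle at the
**donor oxygen** — between the O→acceptor-O and O→H vectors — is below
30°.  Note this is the oxygen-centred angle convention, not the
H-centred angle many trajectory tools use; at these cutoffs the two
conventions select measurably different bond sets.

Donatable hydrogens are those covalently bound to an oxygen.  With no
explicit topology, covalency is inferred geometrically: the nearest
oxygen of the same molecule within 0.12 nm, falling back to the
nearest oxygen of any molecule (the same-molecule preference keeps the
pairing chemically correct when unconstrained synthetic waters
overlap).  Both polymer and water oxygens may donate and accept.  A
hydrogen satisfying the criteria with several acceptors contributes
one bond per acceptor; no exclusivity rule is imposed.

Densities divide class counts (polymer–polymer, polymer–water,
water–water) by the *dry* material volume V0, so curves at different
moisture contents share one denominator.  Across frames the
time-averaged count is used.

The production detector uses a periodic KD-tree over oxygen pairs; the
test suite holds it to exact agreement with a brute-force all-triples
oracle on systems up to ~500 atoms.

## Hydration layers

The layering coordinate is d_pw: for each water molecule, the
minimum-image distance from its oxygen to the nearest polymer atom.
"Polymer atom" includes polymer hydrogens by default (configurable to
heavy atoms only).  Population histograms use half-open bins of width
0.01 nm from 0 to 2.0 nm, averaged over frames; counts beyond the last
edge are reported as a truncation figure rather than dropped silently.
The 0.01 nm bin resolves shells at ~0.28/0.56 nm and the valley near
0.45 nm while keeping per-bin counts statistically stable at a few
thousand molecules.

The double-Gaussian decomposition (DGD) fits
a1·N(μ1, σ1) + a2·N(μ2, σ2) to the raw per-bin counts by bounded
least squares (`scipy.curve_fit`), reporting components in ascending
mean order.  Raw count histograms carry Poisson spikes that can strand
a single-start optimiser in a poor local optimum, so the fit is
multi-started (smoothed-peak, quantile-based and single-shell starts)
and the best optimum kept; a user-supplied start bypasses the
multi-start.  A fit is flagged *degenerate* when the data do not
support two resolved shells: a vanishing amplitude, a width collapsed
to its bound, or means closer than half the wider component's σ.

Layer assignment uses fixed cutoffs with conventional defaults —
first layer d_pw < 0.45 nm, second layer 0.45–2.0 nm, beyond
otherwise — rather than re-deriving the valley per dataset; the
cutoffs are parameters, and a caller wanting a data-driven boundary
can pass the fitted inter-peak minimum.  Layer volume fractions assign
each counted molecule a fixed molecular volume (0.0299 nm³ = 18.015
g/mol at 1.0 g/cm³, configurable) and close the balance with the
polymer fraction: f_wi = n_wi·v_w/V, f_p = 1 − f_w1 − f_w2.  The box
volume of the analysed frame is used; an implied water volume
exceeding the box is an error, not a clamp.

## Surface areas and contact area

Shrake–Rupley with periodic images: each atom's expanded sphere
(r_vdw + probe) is sampled with n quasi-uniform points from the
deterministic golden-spiral lattice (no RNG); a point is exposed if it
lies outside every other expanded sphere, tested under the minimum
image.  Defaults: probe 0.1 nm — the rolling-ball radius used for
polymer–water contact analysis, deliberately not the 0.14 nm water
probe of protein SASA conventions — and 960 points per atom, which
agrees with 4× denser sampling to well under 1% on the systems the
tests exercise.  The contact area is the inclusion–exclusion
combination A_contact = A_polymer + A_water − A_system; it is zero for
non-touching groups by construction and its plateau with growing
moisture is the geometric signature of first-layer saturation.

## Composite models and their inversion

The hydrated material is treated as a three-phase composite (polymer,
first layer, second layer) with fractions summing to one.  Mixture
rule and parallel model are the fraction-weighted arithmetic mean of
phase properties; the series model is the harmonic mean (so series ≤
mixture for any positive phases, which the tests check by random
sampling).  Default law per property: K, E, G → series; Q, C_p →
mixture; α → parallel; overridable.

`CompositeModel.fit()`:

* **Mixture/parallel** is a linear least-squares solve (weighted by
  inverse variances when the curve carries an sd column), with exact
  covariances.
* **Series** is fitted in the reciprocal parametrisation β_j = 1/X_j:
  1/X_c is linear in β, giving a closed-form start, followed by a
  bounded least-squares refinement of the *original-scale* residuals
  over β.  The reciprocal space is where the likelihood stays well
  conditioned — a phase that contributes little information drives
  X → ∞, which is the finite boundary β → 0.  Covariances transform
  back by the delta method and each standard error is floored by a
  seeded residual-bootstrap estimate (a fast weighted linear solve in
  reciprocal space, var(1/y) ≈ σ²/ŷ⁴, 200 resamples): at realistic
  noise the sampling distribution of 1/β̂ is skewed and the linearised
  errors alone under-state it.  The reported error is the larger of
  the two, i.e. deliberately conservative.

A rank-deficient fraction design (fractions that never vary
independently across the grid) raises an identifiability error naming
the parameter dominating the null space, rather than returning an
arbitrary solution.

The isotropy relation G = 3KE/(9K − E) requires 9K > E and is exposed
as a plain function.

## Crossover detection

The two-regime structure is modelled as a continuous piecewise-linear
function y = b0 + b1·m + b2·(m − m*)₊ (four free parameters;
continuity is enforced because the regimes of the curves this is built
for visually meet).  Candidate breakpoints are the interior data
points with at least three points strictly on each side; the best
candidate is polished by a bounded continuous search accepted only
when it strictly lowers the rss.  Candidates at data points (rather
than between them) make the noise-free case exact: data generated with
a break at a grid point return that point.

Uncertainty: seeded residual bootstrap (200 resamples, grid-only
refits) gives a percentile CI for m*.  Presence of a crossover is a
permutation test: residuals of the single-line fit are permuted, the
two-segment gain in rss recomputed each time, and the observed gain —
computed grid-only, exactly like the permuted ones — compared against
that null distribution (199 permutations; "no crossover" declared at
p > 0.05).  The observed/permuted symmetry matters: polishing only the
observed statistic makes the test anti-conservative.  Under
straight-line nulls the measured false-positive rate is at the nominal
level.

## Synthetic data

The generators produce inputs with the statistical structure the
analysis assumes; they are first-class, tested code.

* **Polymer**: self-avoiding random-walk bead chains (bond 0.4 nm,
  non-bonded exclusion 0.35 nm, bead radius 0.25 nm, one bead per
  monomer at 132.1 g/mol) in a cubic periodic box whose edge is set by
  mass conservation from the target density, so the realised dry
  density equals the target exactly.  Default study conditions: 5
  chains × 100 beads at 1.3 g/cm³, giving a ~4.4 nm box.  Growth that
  stalls restarts the chain; infeasible densities raise a packing
  error.  The bead representation carries no chemistry — the analyses
  here are purely geometric (positions, radii, roles).
* **Hydration**: N_w = round(m·M_p/18.015) waters.  Each oxygen's
  nearest-polymer distance is drawn from a two-Gaussian shell mixture
  (defaults 0.28/0.56 nm, sd 0.05/0.15 nm, weight 0.6) and realised by
  rejection sampling uniform box points until one matches the drawn
  distance within ±0.005 nm — unbiased in d_pw for any polymer
  geometry, where stepping a distance d from a random polymer atom
  would tilt the distribution by the local atom density.  Within the
  tolerance window the candidate closest to the target is taken
  (symmetric, no half-window bias).  Distances the geometry cannot
  offer (deep inside beads; voids larger than the packing provides,
  in practice d ≳ 0.8 nm at the default density) are redrawn after a
  bounded candidate budget and counted in a report — the realised
  mixture is truncated to achievable distances, which slightly
  shortens the far tail of the second shell.  Hydrogens are attached
  at 0.1 nm with the rigid-water 104.5° angle in random orientation.
  No water–water exclusion and no energetics: the generator emulates
  the distance structure only, so tests passing on it say nothing
  about force fields, equilibration or dynamics.
* **Fraction schedules**: piecewise linear in m.  The first layer
  fills linearly and saturates exactly at m_sat
  (f_w1 = f_w1_max·min(m, m_sat)/m_sat, defaults m_sat = 0.3,
  f_w1_max = 0.2); total water volume fraction is the secant
  linearisation v(m_sat)/m_sat·m of the additive-volume fraction
  v(m) = (m/ρ_w)/(1/ρ_p + m/ρ_w); the second layer carries the
  difference — a small linear trickle before saturation, all new water
  after.  This shape was a genuinely open design point.  A smooth
  exponential approach to saturation was considered and rejected: its
  curvature concentrates well below m_sat, and the exact
  additive-volume fraction is concave, so either choice displaces the
  two-segment breakpoint of derived property curves away from the
  saturation moisture the schedule is supposed to encode.  With the
  piecewise-linear schedule, any mixture/parallel property curve is
  exactly two linear regimes meeting at m_sat, and the series curves
  are near-linear on each side — the structure the crossover stage is
  designed to detect.
* **Property curves**: composite-law evaluation over a schedule plus
  i.i.d. Gaussian noise of a stated sd (zero noise gives exact model
  values); linear series for the estimator suite.

All generators are deterministic given a seed.

## Property estimators

Standard reductions, each an ordinary least-squares slope over the
window supplied by the caller: α_X = (1/L(T₀))·dL/dT with T₀ required
inside the fitted range; C_p = (dH/dT)/mass; moduli as stress–strain
slopes restricted to |ε| ≤ max_strain (the same estimator serves
uniaxial, volumetric and shear loadings — the loading protocol decides
the interpretation); ν = −slope of transverse vs axial strain.  The
integral heat of adsorption is
Q = [U_dry + N_w·u_vapor − U_hydrated]/(N_w·M_w), referenced to
isolated vapor-phase water so large uptake tends to the bulk latent
heat scale; the reference energy is a required argument, never
defaulted silently.  Window selection is deliberately the caller's
responsibility: these are definitions, not protocol reconstructions.

## Problem sizes and defaults in the test/acceptance runs

The shipped tests and the acceptance script run entirely on generated
data: the standard dry fixture is 5 × 100 beads (500 atoms, ~84 nm³);
hydrated fixtures carry 1100–2200 waters (3.8–7.1 k atoms); curves use
25 grid points on m ∈ [0, 0.6]; parameter-recovery suites use 200
seeded replicates.  These sizes give the structural statistics a few
thousand counts per estimate — enough for the shell centres to be
determined to a few hundredths of an Å and breakpoints to well under
one percentage point of moisture — while keeping the whole suite in
the tens of seconds.

## Known limitations

* The hydration generator reproduces the marginal distribution of
  d_pw, not water–water structure, orientation statistics or dynamics;
  residence times and H-bond lifetimes are out of scope.
* The second shell's far tail is truncated by the void structure of
  the bead packing; fitted second-shell centres sit slightly below the
  nominal mixture mean at the default density.
* Composite inversion assumes the supplied volume fractions are exact;
  uncertainty in the fractions is not propagated.
* The crossover model fits exactly one breakpoint; multi-break
  segmentation and smooth (sigmoid) transitions are non-goals.
* Hydrogen-bond analysis has no energetic definition and no
  exclusivity rule; counts are purely geometric.
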